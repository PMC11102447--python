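"""Map loci underlying the deviation values: 1000-permutation genome-wide
threshold, per-gRNA scans, 2-unit -log10(p) drop intervals, 100 kb peak
separation and 10 kb cis exclusion; baseline fitness is mapped with the
same machinery."""

import json

import pandas as pd

from common import parse_args
from perturbmap.pipeline import stage_linkage

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    stage_linkage(cfg, out, force)
    thr = json.loads((out / "linkage_threshold.json").read_text())
    peaks = pd.read_csv(out / "peaks.tsv", sep="\t")
    floci = pd.read_csv(out / "fitness_loci.tsv", sep="\t")
    trans = peaks[~peaks["cis_excluded"]] if len(peaks) else peaks
    print(f"threshold -log10(p) >= {thr['neglog10p_cutoff']:.2f} "
          f"({thr['n_permutations']} permutations)")
    print(f"{len(trans)} trans loci for "
          f"{trans['trait'].nunique() if len(trans) else 0} gRNAs "
          f"({int(peaks['cis_excluded'].sum()) if len(peaks) else 0} cis-excluded); "
          f"{len(floci)} baseline-fitness loci")
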