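"""Estimate per-lineage relative fitness in each assay from the count
trajectories, apply the QC filters, and put all assays on the
control-gRNA reference scale (mean control-assay fitness exactly zero)."""

import pandas as pd

from common import parse_args
from perturbmap.pipeline import stage_fitness

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    stage_fitness(cfg, out, force)
    fit = pd.read_csv(out / "fitness.tsv", sep="\t")
    kept = fit[fit["retained"]]
    print(f"estimated fitness for {len(fit)} lineages; "
          f"{len(kept)} retained after QC")
    print(kept.groupby("assay")["fitness"].describe()[["mean", "std"]])
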