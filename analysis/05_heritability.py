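"""Decompose each background effect: broad-sense H2 from replicate
lineages (ANOVA), narrow-sense h2 from the marker relationship matrix
(REML), and the higher-order-epistasis share 1 - h2/H2."""

import pandas as pd

from common import parse_args
from perturbmap.pipeline import stage_heritability

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    stage_heritability(cfg, out, force)
    h = pd.read_csv(out / "heritability.tsv", sep="\t")
    print(f"heritability for {len(h)} background gRNAs: "
          f"mean H2={h['H2'].mean():.3f}, mean h2={h['h2'].mean():.3f}, "
          f"mean 1-h2/H2={h['epistasis_fraction'].mean():.3f}")
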