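"""Test every gRNA for a mean fitness effect (mixed model, BH, 3-SD null
threshold) and for background effects (segregant-by-gRNA interaction),
then derive per-segregant deviation values for the background gRNAs."""

import pandas as pd

from common import parse_args
from perturbmap.pipeline import stage_effects

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    stage_effects(cfg, out, force)
    res = pd.read_csv(out / "guide_effects.tsv", sep="\t")
    dev = pd.read_csv(out / "deviations.tsv", sep="\t")
    print(f"tested {res['mean_effect'].notna().sum()} gRNAs: "
          f"{int(res['efficacious'].sum())} efficacious, "
          f"{int(res['background'].sum())} with background effects, "
          f"{int(res['polymorphic_excluded'].sum())} excluded at polymorphic "
          "binding sites")
    print(f"deviation matrix: {dev.shape[0]} segregants x "
          f"{dev.shape[1] - 1} gRNAs")
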