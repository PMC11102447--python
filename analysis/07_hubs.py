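"""Find hub loci: stack all drop intervals along the genome, set a
Poisson overlap threshold (0.05 / number of 20 kb bins), call runs of
markers above it, and classify each hub as amplifying or masking from how
its allele contrast scales with member gRNA effect sizes."""

import json

from common import parse_args
from perturbmap.pipeline import stage_hubs

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    stage_hubs(cfg, out, force)
    hubs = json.loads((out / "hubs.json").read_text())
    p = hubs["params"]
    print(f"lambda={p['lam']:.3f}, overlap threshold k={p['k']}")
    for h in hubs["hubs"]:
        print(f"  {h['hub_id']}: {h['chrom']}:{h['marker_pos']} "
              f"({h['classification']}, {len(h['members'])} members, "
              f"sign epistasis={h['sign_epistasis']})")
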