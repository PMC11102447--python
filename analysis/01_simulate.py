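"""Simulate the double-barcoded CRISPRi screen: 169 segregants of a
BY-by-3S-style cross carrying a barcoded gRNA library, competed in two
induced assays and one uninduced control, with PCR chimeras injected.
Writes genotypes, the guide table, raw count tables and the ground truth.
"""

import json

from common import parse_args
from perturbmap.pipeline import stage_simulate
from perturbmap.sim import ChimeraCoefficients

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    if cfg.chimera is None:
        cfg.chimera = ChimeraCoefficients()
    stage_simulate(cfg, out, force)
    truth = json.loads((out / "truth.json").read_text())
    n_eff = sum(1 for v in truth["guide_effect"].values() if v != 0)
    print(f"simulated {len(truth['baseline'])} segregants, "
          f"{len(truth['guide_effect'])} gRNAs ({n_eff} with effects), "
          f"{len(truth['hubs'])} planted hubs -> {out}")
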