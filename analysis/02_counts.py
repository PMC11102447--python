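"""Fit the frequency-linear chimera model on known-invalid barcode
pairings, correct every double barcode's counts, and normalise each time
point to a common depth."""

import json

from common import parse_args
from perturbmap.pipeline import ASSAYS, stage_counts

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    stage_counts(cfg, out, force)
    for assay in ASSAYS:
        path = out / f"chimera_model_{assay}.json"
        if path.exists():
            m = json.loads(path.read_text())
            print(f"{assay}: chimera model intercept={m['intercept']:.3g} "
                  f"a_seg={m['a_seg']:.3g} a_guide={m['a_guide']:.3g}")
    print(f"corrected, depth-normalised counts -> {out}")
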