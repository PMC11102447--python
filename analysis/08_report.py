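"""Summarise the run: efficacious/background counts, loci, hubs,
heritability means and assay-vs-assay fitness correlations - the
synthetic analogues of a screen's headline table."""

import json

from common import parse_args
from perturbmap.pipeline import write_report

if __name__ == "__main__":
    cfg, out, force = parse_args(__doc__)
    report = write_report(out)
    print(json.dumps(report, indent=1))
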