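"""Shared setup for the numbered analysis drivers."""

import argparse
from pathlib import Path

from perturbmap.pipeline import PipelineConfig


def parse_args(description: str) -> tuple[PipelineConfig, Path, bool]:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--config", type=Path, default=None,
                    help="pipeline YAML; defaults to the package defaults")
    ap.add_argument("--out", type=Path, default=Path("results/screen"),
                    help="run directory shared by all stages")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--force", action="store_true",
                    help="recompute even if the stage already ran")
    args = ap.parse_args()
    if args.config is not None:
        cfg = PipelineConfig.from_yaml(args.config)
    else:
        cfg = PipelineConfig(seed=args.seed)
    if args.seed:
        cfg.seed = args.seed
    args.out.mkdir(parents=True, exist_ok=True)
    return cfg, args.out, args.force
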