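"""Shared table schema and plain-text IO for the pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

COUNT_COLS = ["n_t0", "n_t1", "n_t2", "n_t3", "n_t4"]

COUNT_TABLE_COLS = [
    "lineage_id", "segregant_bc", "guide_bc", "segregant_id", "guide_id",
    "assay", "valid",
] + COUNT_COLS


def count_cols(counts: pd.DataFrame) -> list[str]:
    return [c for c in COUNT_COLS if c in counts.columns]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)
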