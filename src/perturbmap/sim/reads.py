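"""Emit paired-end reads for a count table.

Forward reads carry the gRNA barcode immediately upstream of its anchor
(CCCGAGTCGCGATAA); reverse reads carry the segregant barcode upstream of
its own anchor (TACCGTTCGTATAGG). One read pair is emitted per counted
molecule. Base qualities are constant Q37 by default; substitution errors
can be injected at a configurable per-base rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..barcodes import GUIDE_ANCHOR, SEG_ANCHOR
from .assay import COUNT_COLS

BASES = np.array(list("ACGT"))


@dataclass
class ReadLayout:
    read_length: int = 100
    barcode_offset: int = 8        # fixed prefix length before the barcode
    barcode_length: int = 20
    umi_length: int = 8            # 4+4 nt UMI, recorded in the read name
    error_rate: float = 0.0
    quality: int = 37
    prefix: str = "TCGACTAA"       # fixed bases before the barcode

    def __post_init__(self):
        if len(self.prefix) != self.barcode_offset:
            raise ValueError("prefix length must equal barcode_offset")
        need = self.barcode_offset + self.barcode_length + len(GUIDE_ANCHOR)
        if self.read_length < need:
            raise ValueError("read_length shorter than barcode + anchor layout")


def _mutate(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype="S1").astype("U1")
        hits = np.flatnonzero(rng.random(len(arr)) < rate)
        for i in hits:
            arr[i] = rng.choice(BASES[BASES != arr[i]])
        out.append("".join(arr))
    return out


def emit_reads(
    counts: pd.DataFrame,
    layout: ReadLayout | None = None,
    seed: int = 0,
    time_points: list[str] | None = None,
) -> dict[str, list[tuple[SeqRecord, SeqRecord]]]:
    """Read pairs per time point column, one pair per counted molecule."""
    layout = layout or ReadLayout()
    rng = np.random.default_rng(seed)
    tcols = time_points or [c for c in COUNT_COLS if c in counts.columns]
    filler_len = layout.read_length - layout.barcode_offset - layout.barcode_length
    quals = [layout.quality] * layout.read_length
    out: dict[str, list[tuple[SeqRecord, SeqRecord]]] = {}
    for col in tcols:
        pairs = []
        for row in counts.itertuples(index=False):
            n = int(round(getattr(row, col)))
            for _ in range(n):
                umi = "".join(rng.choice(BASES, size=layout.umi_length))
                fwd = (layout.prefix + row.guide_bc + GUIDE_ANCHOR).ljust(
                    layout.read_length, "A")[: layout.read_length]
                rev = (layout.prefix + row.segregant_bc + SEG_ANCHOR).ljust(
                    layout.read_length, "A")[: layout.read_length]
                fwd, rev = _mutate([fwd, rev], layout.error_rate, rng)
                name = f"{row.lineage_id}:{col}:{umi}"
                rf = SeqRecord(Seq(fwd), id=name, description="")
                rr = SeqRecord(Seq(rev), id=name, description="")
                rf.letter_annotations["phred_quality"] = quals
                rr.letter_annotations["phred_quality"] = quals
                pairs.append((rf, rr))
        out[col] = pairs
    return out


def write_fastq_pairs(
    pairs_by_tp: dict[str, list[tuple[SeqRecord, SeqRecord]]], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for col, pairs in pairs_by_tp.items():
        SeqIO.write([p[0] for p in pairs], outdir / f"{col}_R1.fastq", "fastq")
        SeqIO.write([p[1] for p in pairs], outdir / f"{col}_R2.fastq", "fastq")
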