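"""Read-pair barcode extraction and reference-anchored fuzzy matching.

Forward reads carry the gRNA barcode, reverse reads the segregant barcode,
each immediately upstream of a fixed anchor sequence. A read pair is
rejected when the anchor is not found right after the expected barcode
window or when the mean base quality over the first 35 bases of either
read falls below 30.

Observed barcodes are matched against a reference list with a similarity
score 100 * (1 - edit_distance / max(lengths)); scores of at least 90
(roughly a 1-2 nt difference on a 20-mer) count as a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

GUIDE_ANCHOR = "CCCGAGTCGCGATAA"
SEG_ANCHOR = "TACCGTTCGTATAGG"


def umi_space(length: int = 8) -> int:
    """Number of distinct DNA sequences of the given length (4^length)."""
    return 4 ** length


@dataclass
class BarcodeMatch:
    observed: str
    ref_id: str | None
    score: float

    @property
    def matched(self) -> bool:
        return self.ref_id is not None


@dataclass
class Rejection:
    reason: str


def _find_barcode(
    seq: str, anchor: str, offset: int, bc_len: int, max_anchor_mismatch: int
) -> str | Rejection:
    start, end = offset, offset + bc_len
    window = seq[end: end + len(anchor)]
    if len(window) < len(anchor) or len(seq) < end:
        return Rejection("read_too_short")
    mism = sum(a != b for a, b in zip(window, anchor))
    if mism > max_anchor_mismatch:
        return Rejection("anchor_not_found")
    return seq[start:end]


def extract_barcode_pair(
    fwd_seq: str,
    fwd_qual: Iterable[int],
    rev_seq: str,
    rev_qual: Iterable[int],
    barcode_offset: int = 8,
    barcode_length: int = 20,
    min_quality: float = 30.0,
    quality_window: int = 35,
    max_anchor_mismatch: int = 0,
) -> tuple[str, str] | Rejection:
    """(gRNA barcode, segregant barcode) from a read pair, or a Rejection."""
    for qual in (fwd_qual, rev_qual):
        q = np.asarray(list(qual), dtype=float)[:quality_window]
        if len(q) == 0 or q.mean() < min_quality:
            return Rejection("low_quality")
    guide = _find_barcode(fwd_seq, GUIDE_ANCHOR, barcode_offset, barcode_length,
                          max_anchor_mismatch)
    if isinstance(guide, Rejection):
        return guide
    seg = _find_barcode(rev_seq, SEG_ANCHOR, barcode_offset, barcode_length,
                        max_anchor_mismatch)
    if isinstance(seg, Rejection):
        return seg
    return guide, seg


def similarity(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def match_barcode(
    observed: str,
    references: Mapping[str, str] | Iterable[str],
    threshold: float = 90.0,
) -> BarcodeMatch:
    """Best-scoring reference (ties to lexicographically smallest id).

    ``references`` maps reference ids to sequences; a plain iterable of
    sequences uses each sequence as its own id.
    """
    if not isinstance(references, Mapping):
        references = {s: s for s in references}
    if not references:
        raise ValueError("empty reference list")
    if observed in _exact_index(references):
        rid = _exact_index(references)[observed]
        return BarcodeMatch(observed, rid, 100.0)
    best_id, best_score = None, -1.0
    for rid in sorted(references):
        sc = similarity(observed, references[rid])
        if sc > best_score:
            best_id, best_score = rid, sc
    if best_score >= threshold:
        return BarcodeMatch(observed, best_id, best_score)
    return BarcodeMatch(observed, None, best_score)


def _exact_index(references: Mapping[str, str]) -> dict[str, str]:
    # smallest id wins for duplicated sequences
    idx: dict[str, str] = {}
    for rid in sorted(references):
        idx.setdefault(references[rid], rid)
    return idx


class BarcodeMatcher:
    """Reusable matcher with an exact-match fast path and a result cache."""

    def __init__(self, references: Mapping[str, str] | Iterable[str],
                 threshold: float = 90.0):
        if not isinstance(references, Mapping):
            references = {s: s for s in references}
        if not references:
            raise ValueError("empty reference list")
        self.references = dict(references)
        self.threshold = threshold
        self._exact = _exact_index(self.references)
        self._cache: dict[str, BarcodeMatch] = {}

    def match(self, observed: str) -> BarcodeMatch:
        hit = self._exact.get(observed)
        if hit is not None:
            return BarcodeMatch(observed, hit, 100.0)
        if observed not in self._cache:
            self._cache[observed] = match_barcode(observed, self.references,
                                                  self.threshold)
        return self._cache[observed]


def tally_counts(
    pairs_by_timepoint: Mapping[str, Iterable[tuple[str, str]]],
    lineages: pd.DataFrame,
    seg_bc_map: pd.DataFrame,
    guide_bc_map: pd.DataFrame,
    assay: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally matched (guide barcode, segregant barcode) pairs into counts.

    Pairs whose (segregant, gRNA) combination exists in ``lineages`` become
    lineage counts; pairs of two valid barcodes in a combination absent from
    the library are tallied separately as chimera candidates. Returns
    (counts, chimera_candidates), both with one column per time point.
    """
    tcols = list(pairs_by_timepoint)
    tallies: dict[str, dict[tuple[str, str], int]] = {c: {} for c in tcols}
    for col, pairs in pairs_by_timepoint.items():
        t = tallies[col]
        for guide_bc, seg_bc in pairs:
            key = (seg_bc, guide_bc)
            t[key] = t.get(key, 0) + 1

    valid = set(zip(lineages["segregant_bc"], lineages["guide_bc"]))
    keys = sorted({k for t in tallies.values() for k in t})
    rows = []
    for seg_bc, guide_bc in keys:
        rows.append([seg_bc, guide_bc, (seg_bc, guide_bc) in valid]
                    + [tallies[c].get((seg_bc, guide_bc), 0) for c in tcols])
    table = pd.DataFrame(rows, columns=["segregant_bc", "guide_bc", "valid"] + tcols)
    table = table.merge(seg_bc_map.rename(columns={"barcode": "segregant_bc"}),
                        how="left")
    table = table.merge(guide_bc_map.rename(columns={"barcode": "guide_bc"}),
                        how="left")
    table["assay"] = assay
    lin_ids = lineages.set_index(["segregant_bc", "guide_bc"])["lineage_id"]
    idx = pd.MultiIndex.from_frame(table[["segregant_bc", "guide_bc"]])
    table["lineage_id"] = lin_ids.reindex(idx).to_numpy()
    miss = table["lineage_id"].isna()
    table.loc[miss, "lineage_id"] = [f"X{i:07d}" for i in range(int(miss.sum()))]
    cols = ["lineage_id", "segregant_bc", "guide_bc", "segregant_id", "guide_id",
            "assay", "valid"] + tcols
    table = table[cols]
    return (table[table["valid"]].reset_index(drop=True),
            table[~table["valid"]].reset_index(drop=True))
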