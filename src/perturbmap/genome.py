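"""Marker maps and genome coordinates for a yeast-like cross.

Coordinates are 1-based inclusive throughout. Chromosome labels follow the
S. cerevisiae convention (chrI..chrXVI). A marker map is a DataFrame with
columns ``chrom``, ``pos`` and ``marker``; positions are strictly increasing
within a chromosome and marker ids are unique.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def chrom_label(i: int) -> str:
    """Label for the ``i``-th chromosome (0-based)."""
    return f"chr{ROMAN[i]}" if i < len(ROMAN) else f"chr{i + 1}"


def default_marker_map(
    n_chrom: int = 16,
    markers_per_chrom: int = 40,
    spacing: int = 18_750,
    first_pos: int = 10_000,
) -> pd.DataFrame:
    """Evenly spaced marker map totalling ~12 Mb over 16 chromosomes.

    The default spacing gives 640 markers over a genome whose length is on
    the order of the S. cerevisiae genome, which is what matters for hub
    detection (interval lengths enter a Poisson rate per 20 kb bin).
    """
    recs = []
    for c in range(n_chrom):
        lab = chrom_label(c)
        for j in range(markers_per_chrom):
            pos = first_pos + j * spacing
            recs.append((lab, pos, f"{lab}_{j + 1:03d}"))
    mm = pd.DataFrame(recs, columns=["chrom", "pos", "marker"])
    validate_marker_map(mm)
    return mm


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    if marker_map["marker"].duplicated().any():
        raise ValueError("marker ids must be unique")
    for _, sub in marker_map.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
            raise ValueError("positions must be strictly increasing within chromosome")


def chromosome_lengths(marker_map: pd.DataFrame) -> pd.Series:
    """Per-chromosome length, taken as the maximum marker position."""
    return marker_map.groupby("chrom", sort=False)["pos"].max()


def genome_length(marker_map: pd.DataFrame) -> int:
    """Total genome length: sum of per-chromosome maxima."""
    return int(chromosome_lengths(marker_map).sum())
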