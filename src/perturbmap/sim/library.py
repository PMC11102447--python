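"""Simulated gRNA library and barcode assignments.

The library mirrors a pooled inducible-CRISPRi collection integrated next to
a segregant barcode: every gRNA targets a gene promoter (or, for controls,
an intergenic/noncoding site with no target gene), carries one or more 20-nt
barcodes, and binds a fixed genomic coordinate. A configurable number of
gRNAs are planted on top of segregating variants so that exclusion of
polymorphic-binding-site guides can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Distinct random DNA barcodes."""
    out: set[str] = set()
    while len(out) < n:
        draws = rng.integers(0, 4, size=(n - len(out), length))
        out.update("".join(BASES[r]) for r in draws)
    return sorted(out)[:n]


@dataclass
class LibraryConfig:
    n_guides: int = 200
    n_controls: int = 20
    n_polymorphic: int = 0          # guides planted on top of a marker
    barcode_length: int = 20
    min_barcodes_per_guide: int = 1
    max_barcodes_per_guide: int = 3


def simulate_guide_library(
    marker_map: pd.DataFrame,
    config: LibraryConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (guides, guide_barcodes).

    guides: guide_id, target_gene, chrom, pos, is_control, polymorphic.
    guide_barcodes: barcode -> guide_id (one row per barcode).

    Binding positions are drawn uniformly within the simulated genome;
    polymorphic guides are placed exactly on a marker position so their
    20-nt window overlaps a variant.
    """
    config = config or LibraryConfig()
    if config.n_controls >= config.n_guides:
        raise ValueError("n_controls must be smaller than n_guides")
    rng = np.random.default_rng(seed)

    chrom_max = marker_map.groupby("chrom", sort=False)["pos"].max()
    chroms = chrom_max.index.to_numpy()
    n = config.n_guides
    rows = []
    poly_idx = set(
        rng.choice(n - config.n_controls, size=config.n_polymorphic, replace=False)
        if config.n_polymorphic
        else []
    )
    marker_by_chrom = {c: sub for c, sub in marker_map.groupby("chrom", sort=False)}
    for i in range(n):
        is_control = i >= n - config.n_controls
        chrom = chroms[rng.integers(len(chroms))]
        if (not is_control) and i in poly_idx:
            sub = marker_by_chrom[chrom]
            pos = int(sub["pos"].iloc[rng.integers(len(sub))])
            poly = True
        else:
            # keep clear of marker positions so the 20-nt window is invariant
            pos = int(rng.integers(1, chrom_max[chrom] - 20))
            while (np.abs(marker_by_chrom[chrom]["pos"].to_numpy() - pos) < 25).any():
                pos = int(rng.integers(1, chrom_max[chrom] - 20))
            poly = False
        gid = f"ctrl{i + 1:04d}" if is_control else f"gRNA{i + 1:04d}"
        gene = "" if is_control else f"GENE{i + 1:04d}"
        rows.append((gid, gene, chrom, pos, is_control, poly))
    guides = pd.DataFrame(
        rows,
        columns=["guide_id", "target_gene", "chrom", "pos", "is_control", "polymorphic"],
    )

    n_bc = rng.integers(
        config.min_barcodes_per_guide, config.max_barcodes_per_guide + 1, size=n
    )
    seqs = random_barcodes(int(n_bc.sum()), config.barcode_length, rng)
    order = rng.permutation(len(seqs))
    bc_rows, k = [], 0
    for gid, m in zip(guides["guide_id"], n_bc):
        for _ in range(m):
            bc_rows.append((seqs[order[k]], gid))
            k += 1
    guide_barcodes = pd.DataFrame(bc_rows, columns=["barcode", "guide_id"])
    return guides, guide_barcodes


def simulate_segregant_barcodes(
    segregants: list[str],
    barcode_length: int = 20,
    multi_barcode_fraction: float = 0.18,
    seed: int = 0,
) -> pd.DataFrame:
    """One barcode per segregant, with a fraction carrying 2-3 barcodes.

    Mirrors a panel where most strains carry a single tag but some carry
    replicates for reproducibility checks.
    """
    rng = np.random.default_rng(seed)
    n_multi = int(round(multi_barcode_fraction * len(segregants)))
    multi = set(rng.choice(len(segregants), size=n_multi, replace=False))
    counts = [int(rng.integers(2, 4)) if i in multi else 1 for i in range(len(segregants))]
    seqs = random_barcodes(sum(counts), barcode_length, rng)
    order = rng.permutation(len(seqs))
    rows, k = [], 0
    for seg, m in zip(segregants, counts):
        for _ in range(m):
            rows.append((seqs[order[k]], seg))
            k += 1
    return pd.DataFrame(rows, columns=["barcode", "segregant_id"])
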