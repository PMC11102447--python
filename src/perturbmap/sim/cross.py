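"""Simulate genotypes for a panel of haploid cross segregants.

Each chromosome is modelled as a two-state Markov chain over its markers:
the allele at the first marker is a fair coin flip (0 = lab parent "BY",
1 = clinical parent "3S") and the allele switches between adjacent markers
with a fixed probability (the per-interval recombination fraction). This
yields geometric LD decay, which is all that downstream linkage mapping
relies on; crossover interference and map units are deliberately ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..genome import validate_marker_map


def segregant_ids(n: int) -> list[str]:
    return [f"seg{i + 1:04d}" for i in range(n)]


def simulate_cross(
    n_segregants: int,
    marker_map: pd.DataFrame,
    recomb_fraction: float = 0.12,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype matrix (segregants x markers) with alleles in {0, 1}.

    Parameters
    ----------
    n_segregants
        Number of haploid progeny to draw (>= 2).
    marker_map
        DataFrame with columns ``chrom``, ``pos``, ``marker``.
    recomb_fraction
        Probability that the allele switches between adjacent markers on the
        same chromosome; must lie in [0, 0.5]. 0 gives one non-recombinant
        block per chromosome, 0.5 gives free recombination.
    seed
        Seed for the generator; output is deterministic given the seed.
    """
    if not 0.0 <= recomb_fraction <= 0.5:
        raise ValueError(f"recomb_fraction must be in [0, 0.5], got {recomb_fraction}")
    if n_segregants < 2:
        raise ValueError("need at least 2 segregants")
    validate_marker_map(marker_map)

    rng = np.random.default_rng(seed)
    blocks = []
    for _, sub in marker_map.groupby("chrom", sort=False):
        m = len(sub)
        start = rng.random(n_segregants) < 0.5
        switches = rng.random((n_segregants, m - 1)) < recomb_fraction
        # cumulative XOR of switch indicators gives the Markov chain
        state = np.empty((n_segregants, m), dtype=bool)
        state[:, 0] = start
        if m > 1:
            state[:, 1:] = switches
            np.logical_xor.accumulate(state, axis=1, out=state)
        blocks.append(pd.DataFrame(state.astype(np.int8), columns=sub["marker"].to_numpy()))
    geno = pd.concat(blocks, axis=1)
    geno.index = pd.Index(segregant_ids(n_segregants), name="segregant")
    geno.columns.name = "marker"
    return geno
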