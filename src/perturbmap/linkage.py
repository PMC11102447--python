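"""Linkage mapping of deviation values (and baseline fitness).

Each trait (one gRNA's deviation values, or segregant baseline fitness) is
scanned genome-wide with per-marker simple linear regressions
``trait ~ allele``. Genome-wide significance uses a permutation scheme
that preserves LD: a random trait is chosen, its values are shuffled
across segregants, the genome is rescanned and the minimum p value saved;
the 5th percentile of 1000 such minima is the threshold. Peaks above the
threshold receive confidence intervals from a 2-unit drop in -log10(p)
(the LOD-drop analogue), peaks are greedily accepted in order of
significance subject to a 100 kb interval-separation rule, and peaks
within 10 kb of the trait gRNA's own binding site are flagged as cis
artifacts and excluded from trans analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


def _scan_one(y: np.ndarray, X: np.ndarray):
    """Slope, R^2 and -log10 p of trait ~ marker for every marker column."""
    ok = np.isfinite(y)
    y, X = y[ok], X[ok]
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc ** 2).sum(axis=0)
    syy = float((yc ** 2).sum())
    sxy = yc @ Xc
    mono = sxx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
        r2 = np.where(mono | (syy == 0), 0.0, sxy ** 2 / (sxx * syy))
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.sqrt(np.maximum(r2, 0.0) * (n - 2) / np.maximum(1e-300, 1.0 - r2))
    p = 2.0 * stats.t.sf(tstat, df=max(n - 2, 1))
    p = np.where(mono, 1.0, np.clip(p, P_FLOOR, 1.0))
    return slope, r2, p, n


def scan_trait(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    trait_id: str = "trait",
    min_segregants: int = 30,
) -> pd.DataFrame:
    """Genome scan of one trait; one row per marker, in map order."""
    y = trait.reindex(genotypes.index).to_numpy(dtype=float)
    if np.isfinite(y).sum() < min_segregants:
        raise ValueError(
            f"trait {trait_id!r} observed in {np.isfinite(y).sum()} segregants "
            f"(< {min_segregants})"
        )
    X = genotypes[marker_map["marker"]].to_numpy(dtype=float)
    slope, r2, p, n = _scan_one(y, X)
    out = marker_map[["chrom", "pos", "marker"]].copy()
    out.insert(0, "trait", trait_id)
    out["slope"] = slope
    out["r2"] = r2
    out["neglog10p"] = -np.log10(p)
    out["n"] = n
    return out


def min_p_scan(y: np.ndarray, X: np.ndarray) -> float:
    _, _, p, _ = _scan_one(y, X)
    return float(p.min())


def permutation_threshold(
    deviations: pd.DataFrame,
    genotypes: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    quantile: float = 0.05,
) -> float:
    """Permutation-based genome-wide threshold, returned as -log10(p).

    Each permutation picks a random trait column, shuffles its observed
    values across segregants (genotype rows untouched, preserving LD),
    rescans the genome and keeps the minimum p value; the threshold is
    the ``quantile`` quantile of these minima.
    """
    if deviations.shape[1] == 0:
        raise ValueError("no traits to permute")
    rng = np.random.default_rng(seed)
    X = genotypes.to_numpy(dtype=float)
    Y = deviations.reindex(genotypes.index).to_numpy(dtype=float)
    min_p = np.empty(n_perm)
    cols = rng.integers(0, Y.shape[1], size=n_perm)
    for i, j in enumerate(cols):
        y = Y[:, j].copy()
        obs = np.flatnonzero(np.isfinite(y))
        y[obs] = y[obs[rng.permutation(len(obs))]]
        min_p[i] = min_p_scan(y, X)
    return float(-np.log10(np.quantile(min_p, quantile)))


@dataclass
class LinkagePeak:
    trait: str
    chrom: str
    pos: int
    marker: str
    neglog10p: float
    start: int
    end: int
    slope: float
    r2: float
    cis_excluded: bool = False
    prop_h2: float = np.nan


def _drop_interval(sub: pd.DataFrame, idx: int, drop: float = 2.0):
    """Markers within ``drop`` units of the peak's -log10 p, contiguously."""
    v = sub["neglog10p"].to_numpy()
    lo = hi = idx
    while lo > 0 and v[lo - 1] >= v[idx] - drop:
        lo -= 1
    while hi < len(v) - 1 and v[hi + 1] >= v[idx] - drop:
        hi += 1
    return int(sub["pos"].iloc[lo]), int(sub["pos"].iloc[hi])


def call_peaks(
    scan: pd.DataFrame,
    cutoff: float,
    min_separation: int = 100_000,
    cis_exclusion: int = 10_000,
    guide_position: tuple[str, int] | None = None,
    drop: float = 2.0,
) -> list[LinkagePeak]:
    """Significant, well-separated peaks with 2-unit-drop intervals.

    Local maxima above ``cutoff`` are accepted greedily in decreasing
    significance; a candidate is rejected when its drop interval comes
    within ``min_separation`` of an already-accepted interval on the same
    chromosome. Peaks whose marker lies within ``cis_exclusion`` of the
    trait gRNA's binding site are flagged ``cis_excluded``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    peaks: list[LinkagePeak] = []
    cands = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        v = sub["neglog10p"].to_numpy()
        for i in range(len(sub)):
            if v[i] < cutoff:
                continue
            if (i > 0 and v[i - 1] > v[i]) or (i < len(v) - 1 and v[i + 1] > v[i]):
                continue
            cands.append((v[i], chrom, i, sub))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken: dict[str, list[tuple[int, int]]] = {}
    for val, chrom, i, sub in cands:
        start, end = _drop_interval(sub, i, drop)
        clash = any(
            start - min_separation <= e and end + min_separation >= s
            for s, e in taken.get(chrom, [])
        )
        if clash:
            continue
        taken.setdefault(chrom, []).append((start, end))
        row = sub.iloc[i]
        cis = False
        if guide_position is not None:
            gchrom, gpos = guide_position
            cis = (chrom == gchrom) and (abs(int(row["pos"]) - gpos) < cis_exclusion)
        peaks.append(LinkagePeak(
            trait=row["trait"], chrom=chrom, pos=int(row["pos"]),
            marker=row["marker"], neglog10p=float(val), start=start, end=end,
            slope=float(row["slope"]), r2=float(row["r2"]), cis_excluded=cis,
        ))
    return peaks


def peaks_frame(peaks: list[LinkagePeak]) -> pd.DataFrame:
    df = pd.DataFrame([vars(p) for p in peaks])
    if df.empty:
        df = pd.DataFrame(columns=[
            "trait", "chrom", "pos", "marker", "neglog10p", "start", "end",
            "slope", "r2", "cis_excluded", "prop_h2",
        ])
    return df


def locus_effect(
    trait: pd.Series,
    allele: pd.Series,
    H2: float | None = None,
) -> dict:
    """Allele effect (3S minus BY mean), R^2, and share of H2 explained."""
    df = pd.DataFrame({"y": trait, "x": allele}).dropna()
    g1, g0 = df.loc[df["x"] == 1, "y"], df.loc[df["x"] == 0, "y"]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("monomorphic marker: effect undefined")
    effect = float(g1.mean() - g0.mean())
    yc = df["y"] - df["y"].mean()
    xc = df["x"] - df["x"].mean()
    r2 = float((xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))) if (yc @ yc) > 0 else 0.0
    out = {"effect": effect, "r2": r2}
    if H2 is not None and H2 > 0:
        prop = r2 / H2
        out["prop_h2"] = min(prop, 1.0)
        out["prop_h2_capped"] = prop > 1.0
    return out
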