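"""Broad- and narrow-sense heritability of gRNA background effects.

Broad-sense heritability H2 uses the replication in the data: every
lineage of a gRNA provides a guide-effect estimate (induced lineage
fitness minus its segregant's control baseline), and a one-way ANOVA with
segregant as the grouping factor gives H2 = SS_between / SS_total.

Narrow-sense heritability h2 comes from genomic relatedness: markers are
centred by allele frequency and scaled by sqrt(p(1-p)), the additive
relationship matrix is A = Z Z' / n_markers, and the variance components
of y = mu + g + e with g ~ N(0, sigma_a^2 A), e ~ N(0, sigma_e^2 I) are
estimated by restricted maximum likelihood, profiled to a one-dimensional
search over the variance ratio after rotating into the eigenbasis of A
restricted to the complement of the intercept.

1 - h2/H2 then estimates the share of the genetic basis attributable to
non-additive (higher-order epistatic) variation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


def guide_effect_per_lineage(
    fitness: pd.DataFrame,
    segregant_baseline: pd.Series,
    guide_id: str,
    induced_assay: str = "ATC1",
) -> pd.DataFrame:
    """Per-lineage guide effect: induced fitness minus segregant baseline."""
    sub = fitness[
        (fitness["assay"] == induced_assay)
        & (fitness["guide_id"] == guide_id)
        & fitness["fitness"].notna()
        & fitness.get("retained", pd.Series(True, index=fitness.index))
    ][["lineage_id", "segregant_id", "fitness"]].copy()
    base = segregant_baseline.reindex(sub["segregant_id"]).to_numpy()
    sub["guide_effect"] = sub["fitness"].to_numpy() - base
    return sub.dropna(subset=["guide_effect"])


def segregant_baseline(
    fitness: pd.DataFrame,
    control_guides: list[str] | None = None,
    control_assay: str = "CON",
) -> pd.Series:
    """Mean control-assay fitness per segregant.

    By default restricted to lineages carrying control gRNAs; passing
    ``control_guides=None`` uses every control-assay lineage.
    """
    sub = fitness[
        (fitness["assay"] == control_assay)
        & fitness["fitness"].notna()
        & fitness.get("retained", pd.Series(True, index=fitness.index))
    ]
    if control_guides is not None:
        sub = sub[sub["guide_id"].isin(control_guides)]
    return sub.groupby("segregant_id")["fitness"].mean()


def broad_sense(values: pd.Series | pd.DataFrame, groups: pd.Series = None) -> float:
    """H2 = between-group SS / total SS of a one-way layout.

    Accepts a Series indexed (or paired via ``groups``) by segregant, with
    at least two groups of two or more replicates.
    """
    if isinstance(values, pd.DataFrame):
        groups, values = values["segregant_id"], values["guide_effect"]
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = np.isfinite(y)
    y, g = y[ok], g[ok]
    df = pd.DataFrame({"y": y, "g": g})
    sizes = df.groupby("g")["y"].count()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need >=2 segregants with >=2 replicate lineages")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total sum of squares: H2 undefined")
    means = df.groupby("g")["y"].transform("mean")
    ss_between = ((means - grand) ** 2).sum()
    return float(ss_between / ss_total)


def relationship_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Additive (VanRaden-style) relationship matrix from 0/1 genotypes.

    Monomorphic markers carry no information and are dropped. The diagonal
    averages to ~1 by construction.
    """
    X = genotypes.to_numpy(dtype=float)
    p = X.mean(axis=0)
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all markers monomorphic")
    Xk, pk = X[:, keep], p[keep]
    Z = (Xk - pk) / np.sqrt(pk * (1.0 - pk))
    A = Z @ Z.T / Z.shape[1]
    return pd.DataFrame(A, index=genotypes.index, columns=genotypes.index)


def narrow_sense(
    trait: pd.Series,
    A: pd.DataFrame,
    min_segregants: int = 30,
) -> float:
    """REML narrow-sense heritability from a relationship matrix.

    Returns h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2), clipped to [0, 1].
    """
    y = trait.dropna()
    if len(y) < min_segregants:
        raise ValueError(f"need >= {min_segregants} segregants, got {len(y)}")
    if float(np.var(y)) == 0.0:
        raise ValueError("zero-variance trait")
    ids = y.index
    Asub = A.loc[ids, ids].to_numpy()
    yv = y.to_numpy(dtype=float)
    n = len(yv)

    # orthonormal basis of the complement of the intercept (error contrasts)
    Q, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
    Q2 = Q[:, 1:]
    M = Q2.T @ Asub @ Q2
    lam, V = np.linalg.eigh(M)
    lam = np.clip(lam, 0.0, None)
    u = V.T @ (Q2.T @ yv)
    u2 = u ** 2

    def neg_restricted_ll(log_ratio: float) -> float:
        r = np.exp(log_ratio)                 # sigma_a^2 / sigma_e^2
        w = r * lam + 1.0
        return 0.5 * (np.log(w).sum() + (n - 1) * np.log((u2 / w).sum()))

    res = minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0),
                          method="bounded", options={"xatol": 1e-8})
    ratio = float(np.exp(res.x))
    return float(np.clip(ratio / (1.0 + ratio), 0.0, 1.0))


def epistasis_fraction(h2: float, H2: float) -> float:
    """Higher-order-epistasis share 1 - h2/H2, floored at zero."""
    if not H2 > 0:
        raise ValueError("H2 must be positive")
    return float(max(0.0, 1.0 - h2 / H2))
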