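"""Per-gRNA mean effects, background (segregant x gRNA) effects and
deviation values.

For each gRNA, the lineages carrying it in the control assay (gRNA
indicator 0) and one induced assay (indicator 1) are compared with mixed
effects linear models:

    base:        fitness ~ gRNA        + (1 | segregant)
    interaction: fitness ~ gRNA        + (1 + gRNA | segregant)

The segregant term is random; the gRNA term is fixed and its coefficient
is the mean effect m_g. A likelihood-ratio test between the two models
decides whether the gRNA shows a background-dependent effect; the mean
effect p value is taken from whichever model the LRT selects. Because the
effect is an induced-vs-control contrast within the same lineages, gRNAs
with equal leaky effects in both assays cancel out of m_g by construction.

Deviation values d[g, s] are the segregant-specific predicted gRNA effects
minus the mean effect, i.e. the random-slope BLUPs (shrinkage mode) or the
per-segregant induced-minus-control means re-centred (fixed, no-shrinkage
mode, useful for hand-checkable arithmetic and unattenuated dispersion
estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


@dataclass
class GuideEffectResult:
    guide_id: str
    mean_effect: float
    p_mean: float
    p_interaction: float
    n_segregants: int
    interaction_selected: bool
    singular: bool = False
    slope_sd: float = np.nan          # SD of the random gRNA slope (mixed mode)
    per_segregant_effect: pd.Series = field(default=None, repr=False)
    q_mean: float = np.nan
    q_interaction: float = np.nan
    efficacious: bool = False
    background: bool = False


def test_guide(
    data: pd.DataFrame,
    mode: str = "mixed",
    lrt_alpha: float = 0.05,
) -> GuideEffectResult:
    """Test one gRNA for mean and background effects.

    ``data`` holds one row per lineage with columns ``segregant_id``,
    ``induced`` (0 for control-assay lineages, 1 for induced-assay ones)
    and ``fitness``. In ``fixed`` mode the per-segregant effect is the
    induced-minus-control mean within each segregant (no shrinkage), the
    mean effect is their unweighted average, and p values come from a
    t test across segregant effects (mean) and a one-way F test of
    effect heterogeneity (interaction).
    """
    gid = data["guide_id"].iloc[0] if "guide_id" in data else ""
    d = data.dropna(subset=["fitness"])
    segs = d["segregant_id"].unique()
    if len(segs) < 2:
        return GuideEffectResult(gid, np.nan, np.nan, np.nan, len(segs), False,
                                 singular=True)
    if mode == "fixed":
        return _test_guide_fixed(gid, d)

    endog = d["fitness"].to_numpy(float)
    exog = sm.add_constant(d["induced"].to_numpy(float), has_constant="add")
    groups = d["segregant_id"].to_numpy()
    try:
        base = _fit_mixed(endog, exog, groups, None)
        inter = _fit_mixed(endog, exog, groups, exog)
        # LRT of the random slope (+covariance): 2 extra variance params.
        # A significant result is re-verified with a second optimiser, as
        # an under-converged base fit would inflate the statistic.
        lr = max(0.0, 2.0 * (inter.llf - base.llf))
        p_int = float(stats.chi2.sf(lr, df=2))
        if p_int < lrt_alpha:
            base = _fit_mixed(endog, exog, groups, None, verify=True,
                              best=base)
            inter = _fit_mixed(endog, exog, groups, exog, verify=True,
                               best=inter)
            lr = max(0.0, 2.0 * (inter.llf - base.llf))
            p_int = float(stats.chi2.sf(lr, df=2))
    except (np.linalg.LinAlgError, ValueError):
        return GuideEffectResult(gid, np.nan, np.nan, np.nan, len(segs), False,
                                 singular=True)
    use_inter = p_int < lrt_alpha
    sel = inter if use_inter else base
    m_hat = float(sel.fe_params[1])
    p_mean = float(sel.pvalues[1])

    re = inter.random_effects
    slope = pd.Series({g: float(np.asarray(v)[1]) for g, v in re.items()})
    per_seg = m_hat + slope
    per_seg.index.name = "segregant_id"
    slope_sd = float(np.sqrt(max(np.asarray(inter.cov_re)[1, 1], 0.0)))
    return GuideEffectResult(gid, m_hat, p_mean, p_int, len(segs), use_inter,
                             slope_sd=slope_sd, per_segregant_effect=per_seg)


def _fit_mixed(endog, exog, groups, exog_re, verify=False, best=None):
    """ML fit with optimiser fallbacks; lbfgs occasionally reports a bogus
    infinite likelihood (collapsed variance component) or under-converges.
    With ``verify`` the model is refit with bfgs and the higher-likelihood
    solution kept."""
    methods = ("bfgs",) if verify else ("lbfgs", "bfgs", "cg")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        for method in methods:
            try:
                fit = model.fit(reml=False, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(fit.llf) and np.isfinite(fit.fe_params).all():
                if best is None or fit.llf > best.llf:
                    return fit
                return best
    if best is not None:
        return best
    raise ValueError("mixed model fit failed")


def _test_guide_fixed(gid: str, d: pd.DataFrame) -> GuideEffectResult:
    means = d.groupby(["segregant_id", "induced"])["fitness"].agg(["mean", "count", "var"])
    wide = means["mean"].unstack("induced")
    if 0 not in wide.columns or 1 not in wide.columns:
        return GuideEffectResult(gid, np.nan, np.nan, np.nan, 0, False, singular=True)
    eff = (wide[1] - wide[0]).dropna()
    if len(eff) < 2:
        return GuideEffectResult(gid, np.nan, np.nan, np.nan, len(eff), False,
                                 singular=True)
    m_hat = float(eff.mean())
    t, p_mean = stats.ttest_1samp(eff, 0.0)
    # heterogeneity of per-segregant effects vs within-(segregant, arm) noise
    grp = d[d["segregant_id"].isin(eff.index)].groupby(["segregant_id", "induced"])
    nvar = grp["fitness"].agg(["count", "var"])
    pooled_num = ((nvar["count"] - 1) * nvar["var"].fillna(0.0)).sum()
    pooled_df = (nvar["count"] - 1).sum()
    if pooled_df > 0 and pooled_num > 0:
        s2 = pooled_num / pooled_df
        inv_n = (1.0 / grp["fitness"].count()).groupby("segregant_id").sum()
        w = 1.0 / (s2 * inv_n.loc[eff.index])
        stat = float((w * (eff - m_hat) ** 2).sum())
        p_int = float(stats.chi2.sf(stat, df=len(eff) - 1))
    else:
        p_int = np.nan
    return GuideEffectResult(gid, m_hat, float(p_mean), p_int, len(eff), False,
                             per_segregant_effect=eff)


def run_guide_models(
    fitness: pd.DataFrame,
    guide_ids: list[str] | None = None,
    control_assay: str = "CON",
    induced_assay: str = "ATC1",
    mode: str = "mixed",
    lrt_alpha: float = 0.05,
) -> dict[str, GuideEffectResult]:
    """Fit the per-gRNA models for every guide over one induced assay."""
    fit = fitness[fitness.get("retained", pd.Series(True, index=fitness.index))]
    fit = fit[fit["assay"].isin([control_assay, induced_assay])].copy()
    fit["induced"] = (fit["assay"] == induced_assay).astype(float)
    out: dict[str, GuideEffectResult] = {}
    ids = guide_ids if guide_ids is not None else sorted(fit["guide_id"].unique())
    for gid, sub in fit.groupby("guide_id"):
        if gid not in ids:
            continue
        out[gid] = test_guide(sub, mode=mode, lrt_alpha=lrt_alpha)
    return out


def adjust_fdr(pvals: pd.Series, alpha: float = 0.05) -> pd.Series:
    """Benjamini-Hochberg step-up q values (NaNs passed through)."""
    out = pd.Series(np.nan, index=pvals.index)
    ok = pvals.notna()
    if ok.any():
        out[ok] = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[1]
    return out


@dataclass
class NullModel:
    center: float
    sd: float

    @property
    def cutoff(self) -> float:
        return self.center - 3.0 * self.sd


def efficacy_threshold(
    mean_effects: pd.Series,
    center: str = "median",
    min_guides: int = 50,
) -> NullModel:
    """Null distribution of mean effects from the neutral-or-beneficial side.

    The targeted genes are essential, so true effects are non-positive and
    the upper half of the mean-effect distribution is dominated by inert
    gRNAs. The null SD is estimated by reflecting values at or above the
    center about it; the efficacy cutoff sits three SD below the center.
    """
    m = mean_effects.dropna()
    if len(m) < min_guides:
        raise ValueError(f"need >= {min_guides} mean effects, got {len(m)}")
    c = float(m.median() if center == "median" else m.mean())
    upper = m[m >= c] - c
    if len(upper) == 0:
        raise ValueError("no neutral-or-beneficial effects to fit the null")
    sd = float(np.sqrt((upper ** 2).mean()))
    return NullModel(center=c, sd=sd)


def apply_efficacy(
    results: pd.DataFrame, null: NullModel, q_alpha: float = 0.05
) -> pd.DataFrame:
    """Flag efficacious gRNAs (BH-significant mean effect below the cutoff)
    and, among those, background-effect gRNAs (BH-significant interaction).

    The mean-effect family covers all tested gRNAs; the interaction family
    is adjusted over gRNAs with mean effects only.
    """
    out = results.copy()
    out["q_mean"] = adjust_fdr(out["p_mean"], q_alpha)
    out["efficacious"] = (out["q_mean"] < q_alpha) & (out["mean_effect"] < null.cutoff)
    out["q_interaction"] = np.nan
    fam = out.index[out["efficacious"]]
    out.loc[fam, "q_interaction"] = adjust_fdr(out.loc[fam, "p_interaction"], q_alpha)
    out["background"] = out["efficacious"] & (out["q_interaction"] < q_alpha)
    return out


def results_frame(models: dict[str, GuideEffectResult]) -> pd.DataFrame:
    rows = {
        gid: {
            "mean_effect": r.mean_effect, "p_mean": r.p_mean,
            "p_interaction": r.p_interaction, "n_segregants": r.n_segregants,
            "interaction_selected": r.interaction_selected, "singular": r.singular,
            "slope_sd": r.slope_sd,
        }
        for gid, r in models.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "guide_id"
    return df.sort_index()


def flag_polymorphic_guides(
    guides: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = 20,
) -> pd.Series:
    """gRNAs whose binding window overlaps a segregating variant.

    The window is the ``window``-nt stretch starting at the binding
    coordinate (1-based, inclusive). ``variants`` needs chrom and pos.
    """
    flagged = pd.Series(False, index=guides.index)
    for chrom, sub in variants.groupby("chrom"):
        vpos = np.sort(sub["pos"].to_numpy())
        g = guides["chrom"] == chrom
        if not g.any():
            continue
        start = guides.loc[g, "pos"].to_numpy()
        # any variant in [start, start + window - 1]
        lo = np.searchsorted(vpos, start, side="left")
        hi = np.searchsorted(vpos, start + window - 1, side="right")
        flagged.loc[g] = hi > lo
    return flagged


def compute_deviations(
    models: dict[str, GuideEffectResult],
    background_guides: list[str],
    min_segregants: int = 35,
) -> pd.DataFrame:
    """Deviation matrix (segregants x gRNAs) for background-effect gRNAs.

    d[g, s] = per-segregant predicted gRNA effect minus its mean over the
    segregants with estimates (so deviations for each gRNA are centred at
    zero). gRNAs with estimates for fewer than ``min_segregants``
    segregants are dropped.
    """
    cols = {}
    for gid in background_guides:
        r = models.get(gid)
        if r is None or r.per_segregant_effect is None:
            continue
        eff = r.per_segregant_effect.dropna()
        if len(eff) < min_segregants:
            continue
        cols[gid] = eff - eff.mean()
    dev = pd.DataFrame(cols)
    dev.index.name = "segregant_id"
    dev.columns.name = "guide_id"
    return dev


def select_gene_guides(
    results: pd.DataFrame,
    guides: pd.DataFrame,
    mapped_guides: set[str] | None = None,
) -> pd.DataFrame:
    """One gRNA per targeted gene among background-effect gRNAs.

    Ordered by interaction significance, preferring gRNAs with mapped
    loci, breaking remaining ties by id.
    """
    sub = results[results["background"]].join(
        guides.set_index("guide_id")["target_gene"], how="left"
    )
    mapped = mapped_guides or set()
    sub = sub.assign(
        _unmapped=~sub.index.isin(mapped),          # False (mapped) sorts first
        _q=sub["q_interaction"].fillna(1.0),
    ).reset_index()
    sub = sub.sort_values(["target_gene", "_q", "_unmapped", "guide_id"])
    return (sub.groupby("target_gene", as_index=False).first()
            .drop(columns=["_unmapped", "_q"]))
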