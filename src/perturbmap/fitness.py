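"""Per-lineage relative fitness from count trajectories.

The model: each lineage i grows at a constant per-generation (natural-log)
fitness s_i while the population mean varies over time as lineage
frequencies shift. Expected frequencies obey

    f_i(t) = phi_i * exp(s_i * t) / L(t),
    L(t) = sum_j phi_j * exp(s_j * t),

where phi_i is the lineage's (unobserved) T0 abundance, so the mean
fitness over a transition is dlog(L)/dt. Expected counts are
depth(t) * f_i(t), and observed counts are treated as Poisson around
them. Estimation alternates between (a) holding the population
normaliser L fixed and updating every lineage's (phi_i, s_i) by a
vectorised two-parameter Newton step on its Poisson likelihood -
projected trajectories are compared to observed ones and adjusted - and
(b) recomputing L from the updated parameters, with step damping so the
total deviance never increases. Estimates are reported relative to the
T0-frequency-weighted population mean (centred to zero), mirroring
lineage-tracking fitness estimators of the FitSeq family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .tables import count_cols

S_BOUND = 1.0          # |s| cap: below -1/generation a lineage is effectively
                       # dead within one transfer and the data carry no more
                       # information, so estimates are bounded there
MAX_STEP = 2.0         # Newton step clamp per inner iteration


@dataclass
class PopulationTrajectory:
    generations: np.ndarray
    mean_fitness: np.ndarray      # per time point; 0 at T0 by convention
    fitted_freq: np.ndarray       # lineages x time points
    n_iter: int
    converged: bool
    deviance: float


def _init_params(N: np.ndarray, gens: np.ndarray):
    logf = np.log((N + 0.5) / (N + 0.5).sum(axis=0, keepdims=True))
    g = gens - gens.mean()
    s = (logf * g).sum(axis=1) / (g * g).sum()
    a = logf.mean(axis=1) - s * gens.mean()
    return a, s


def _mu(a, s, gens, logL, logD):
    return np.exp(a[:, None] + s[:, None] * gens[None, :]
                  + logD[None, :] - logL[None, :])


def _logL(a, s, gens):
    return logsumexp(a[:, None] + s[:, None] * gens[None, :], axis=0)


def _deviance(obs: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(obs > 0, obs * np.log(obs / mu), 0.0)
    return float(2.0 * (term - (obs - mu)).sum())


def _newton_step(N, a, s, gens, logL, logD):
    """One damped Newton update of (log-abundance, fitness) per lineage."""
    mu = _mu(a, s, gens, logL, logD)
    r = N - mu
    u1 = r.sum(axis=1)
    u2 = (gens[None, :] * r).sum(axis=1)
    h11 = mu.sum(axis=1)
    h12 = (gens[None, :] * mu).sum(axis=1)
    h22 = (gens[None, :] ** 2 * mu).sum(axis=1)
    det = h11 * h22 - h12 * h12
    det = np.where(det <= 0, np.inf, det)
    da = (h22 * u1 - h12 * u2) / det
    ds = (h11 * u2 - h12 * u1) / det
    np.clip(da, -MAX_STEP, MAX_STEP, out=da)
    np.clip(ds, -MAX_STEP, MAX_STEP, out=ds)
    return a + da, np.clip(s + ds, -S_BOUND, S_BOUND)


def estimate_fitness(
    counts: pd.DataFrame,
    generations: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 10.0),
    max_iter: int = 200,
    tol: float = 1e-6,
    n_inner: int = 4,
) -> tuple[pd.DataFrame, PopulationTrajectory]:
    """Estimate per-lineage fitness for one assay's count table.

    Returns (fitness table, population trajectory). The fitness table keeps
    lineage identity columns and adds ``fitness`` (per generation, relative
    to the T0 population mean), ``score`` (total per-lineage Poisson
    log-likelihood of the fitted trajectory) and an ``all_zero`` flag for
    lineages with no reads anywhere (their fitness is NaN).
    """
    tcols = count_cols(counts)
    gens = np.asarray(generations, dtype=float)[: len(tcols)]
    N_all = counts[tcols].to_numpy(dtype=float)
    live = N_all.sum(axis=1) > 0
    N = N_all[live]
    if N.shape[0] == 0:
        raise ValueError("no lineages with nonzero counts")
    logD = np.log(N.sum(axis=0))

    a, s = _init_params(N, gens)
    logL = _logL(a, s, gens)
    dev = _deviance(N, _mu(a, s, gens, logL, logD))
    n_iter, converged = 0, False
    for n_iter in range(1, max_iter + 1):
        a_new, s_new = a, s
        for _ in range(n_inner):
            a_new, s_new = _newton_step(N, a_new, s_new, gens, logL, logD)
        # damped acceptance: total deviance must not increase
        step = 1.0
        for _ in range(8):
            a_c = a + step * (a_new - a)
            s_c = s + step * (s_new - s)
            logL_c = _logL(a_c, s_c, gens)
            dev_c = _deviance(N, _mu(a_c, s_c, gens, logL_c, logD))
            if dev_c <= dev + 1e-9:
                break
            step /= 2.0
        delta = np.max(np.abs(s_c - s))
        a, s, logL, dev = a_c, s_c, logL_c, dev_c
        if delta < tol:
            converged = True
            break

    w0 = N[:, 0] / N[:, 0].sum()
    s = s - (w0 * s).sum()
    logL = _logL(a, s, gens)
    mu = _mu(a, s, gens, logL, logD)
    fhat = np.exp(a[:, None] + s[:, None] * gens[None, :] - logL[None, :])
    score = (np.where(mu > 0, N * np.log(mu), 0.0) - mu - gammaln(N + 1.0)).sum(axis=1)

    out = counts.drop(columns=tcols).copy()
    out["fitness"] = np.nan
    out.loc[live, "fitness"] = s
    out["score"] = np.nan
    out.loc[live, "score"] = score
    out["all_zero"] = ~live

    mean_fit = np.zeros(len(gens))
    mean_fit[1:] = np.diff(logL) / np.diff(gens)
    traj = PopulationTrajectory(
        generations=gens,
        mean_fitness=mean_fit,
        fitted_freq=fhat,
        n_iter=n_iter,
        converged=converged,
        deviance=dev,
    )
    return out, traj


def qc_filter(
    fitness: pd.DataFrame,
    counts: pd.DataFrame,
    min_t0: int = 5,
    min_guides_per_segregant: int = 100,
    min_segregants_per_guide: int = 2,
    iqr_mult: float = 1.0,
) -> pd.DataFrame:
    """Flag-based quality filters; no silent drops.

    Adds boolean flag columns and ``retained``:

    * ``poor_fit`` - score below Q1 - iqr_mult * IQR of all scores;
    * ``low_t0`` - fewer than ``min_t0`` reads at the first time point;
    * ``removed_segregant`` / ``removed_guide`` - structural filters
      (segregants with too few distinct guides, guides with too few
      distinct segregants), applied iteratively to a fixed point on the
      lineages surviving the first two filters.
    """
    out = fitness.copy()
    t0 = counts.set_index("lineage_id")["n_t0"].reindex(out["lineage_id"])
    out["low_t0"] = (t0.to_numpy() < min_t0) | out["all_zero"].to_numpy()

    scores = out["score"].dropna()
    q1, q3 = scores.quantile([0.25, 0.75])
    thresh = q1 - iqr_mult * (q3 - q1)
    out["poor_fit"] = out["score"].isna() | (out["score"] < thresh)

    out["removed_segregant"] = False
    out["removed_guide"] = False
    alive = ~(out["low_t0"] | out["poor_fit"])
    while True:
        sub = out[alive & ~out["removed_segregant"] & ~out["removed_guide"]]
        g_per_s = sub.groupby("segregant_id")["guide_id"].nunique()
        bad_s = set(g_per_s.index[g_per_s < min_guides_per_segregant])
        s_per_g = sub.groupby("guide_id")["segregant_id"].nunique()
        bad_g = set(s_per_g.index[s_per_g < min_segregants_per_guide])
        if not bad_s and not bad_g:
            break
        out.loc[out["segregant_id"].isin(bad_s), "removed_segregant"] = True
        out.loc[out["guide_id"].isin(bad_g), "removed_guide"] = True
    out["retained"] = (
        alive & ~out["removed_segregant"] & ~out["removed_guide"]
    )
    if not out["retained"].any():
        raise RuntimeError(
            "all lineages removed by QC: "
            f"low_t0={int(out['low_t0'].sum())}, "
            f"poor_fit={int(out['poor_fit'].sum())}, "
            f"removed_segregant={int(out['removed_segregant'].sum())}, "
            f"removed_guide={int(out['removed_guide'].sum())}"
        )
    return out


def normalize_assays(
    fitness: pd.DataFrame,
    control_guides: list[str],
    control_assay: str = "CON",
    sd_mult: float = 2.0,
    min_controls: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Put all assays on the control-gRNA reference scale.

    Per control gRNA and assay, lineage fitnesses are averaged. Control
    gRNAs whose induced-vs-control average difference is inconsistent
    (|difference| beyond ``sd_mult`` standard deviations of all control
    differences) while their average fitness is negative are dropped. Each
    induced assay is then shifted by the difference of retained-control
    medians against the control assay, and finally one global constant is
    added to every assay so the mean control-assay lineage fitness is
    exactly zero. Returns (adjusted fitness, per-control summary).
    """
    fit = fitness[fitness.get("retained", pd.Series(True, index=fitness.index))]
    ctrl = fit[fit["guide_id"].isin(control_guides)]
    if ctrl.empty:
        raise ValueError("no control gRNA lineages present")
    means = (
        ctrl.groupby(["guide_id", "assay"])["fitness"].mean().unstack("assay")
    )
    if control_assay not in means.columns:
        raise ValueError(f"control assay {control_assay!r} missing")
    induced = [a for a in means.columns if a != control_assay]

    diffs = means[induced].sub(means[control_assay], axis=0)
    sd = diffs.stack().std()
    inconsistent = (diffs.abs() > sd_mult * sd).any(axis=1) if sd > 0 else (
        pd.Series(False, index=means.index))
    dropped = inconsistent & (means.mean(axis=1) < 0)
    retained = means[~dropped]
    if len(retained) == 0:
        raise ValueError("all control gRNAs dropped during normalization")
    if len(retained) < min_controls:
        import warnings
        warnings.warn(f"only {len(retained)} control gRNAs retained")

    out = fitness.copy()
    for assay in induced:
        shift = retained[assay].median() - retained[control_assay].median()
        out.loc[out["assay"] == assay, "fitness"] -= shift
    ret = out.get("retained", pd.Series(True, index=out.index))
    con_mean = out.loc[(out["assay"] == control_assay) & ret, "fitness"].mean()
    out["fitness"] -= con_mean
    summary = means.copy()
    summary["dropped"] = dropped
    return out, summary
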