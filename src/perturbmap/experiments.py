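"""Seeded validation studies: recovery of planted truth by every stage.

Each function simulates data with known ground truth under the package's
default study conditions, runs the corresponding part of the analysis
chain, and returns the measured recovery statistics. They are used by the
test suite, the acceptance script and the analysis drivers alike.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import effects as fx
from .chimera import correct_chimeras, fit_chimera_model
from .fitness import estimate_fitness, normalize_assays, qc_filter
from .genome import default_marker_map, genome_length
from .heritability import (
    broad_sense,
    epistasis_fraction,
    narrow_sense,
    relationship_matrix,
    segregant_baseline,
)
from .hubs import call_hubs, hub_allele_summary, hub_count_threshold, overlap_profile
from .linkage import (
    call_peaks,
    peaks_frame,
    permutation_threshold,
    scan_trait,
)
from .sim import (
    ArchitectureConfig,
    ChimeraCoefficients,
    SimConfig,
    build_lineages,
    induced_effect_matrix,
    inject_chimeras,
    simulate_architecture,
    simulate_assay,
    simulate_cross,
    simulate_guide_library,
    simulate_segregant_barcodes,
    true_fitness_matrix,
)
from .tables import count_cols

MARKER_SPACING = 18_750


def _base_panel(seed: int, n_segregants: int = 169):
    mm = default_marker_map()
    geno = simulate_cross(n_segregants, mm, 0.12, seed=seed)
    guides, gbc = simulate_guide_library(mm, seed=seed + 1)
    sbc = simulate_segregant_barcodes(list(geno.index), seed=seed + 2)
    return mm, geno, guides, gbc, sbc


def _simulate_fitness(geno, guides, gbc, sbc, arch, seed, depth=1_000_000,
                      assays=(("ATC1", True), ("CON", False))):
    cfg = SimConfig(seed=seed, depth=depth)
    lin = build_lineages(sbc, gbc, cfg)
    fits, counts_by, truth_by = [], {}, {}
    for k, (assay, induced) in enumerate(assays):
        counts, truth = simulate_assay(arch, geno, lin, cfg, induced, assay,
                                       seed=seed + 10 + k)
        counts_by[assay], truth_by[assay] = counts, truth
        fit, _ = estimate_fitness(counts)
        fits.append(qc_filter(fit, counts))
    fitness = pd.concat(fits, ignore_index=True)
    controls = guides.loc[guides["is_control"], "guide_id"].tolist()
    fitness, _ = normalize_assays(fitness, controls)
    return fitness, counts_by, truth_by, controls


def two_lineage_recovery() -> dict:
    """Noiseless two-lineage pool with fitnesses {0, 0.2}: closed form says
    the relative estimates are {-0.1, +0.1}."""
    gens = (0.0, 2.0, 4.0, 6.0, 10.0)
    s = np.array([0.0, 0.2])
    f = np.array([0.5, 0.5])
    traj = [f.copy()]
    for dt in np.diff(gens):
        f = f * np.exp(s * dt)
        f /= f.sum()
        traj.append(f.copy())
    N = np.array(traj).T * 1e6
    df = pd.DataFrame({"lineage_id": ["a", "b"]})
    for k, col in enumerate(["n_t0", "n_t1", "n_t2", "n_t3", "n_t4"]):
        df[col] = N[:, k]
    fit, _ = estimate_fitness(df, gens)
    est = fit["fitness"].to_numpy()
    return {
        "estimates": est,
        "max_abs_error": float(np.abs(est - np.array([-0.1, 0.1])).max()),
        "final_frequency": float(traj[-1][1]),
    }


def fitness_recovery(seed: int) -> dict:
    """Truth-estimate Pearson r for the default stochastic competition."""
    mm, geno, guides, gbc, sbc = _base_panel(seed)
    arch = simulate_architecture(geno, guides, seed=seed + 3)
    cfg = SimConfig(seed=seed + 4)
    lin = build_lineages(sbc, gbc, cfg)
    counts, truth = simulate_assay(arch, geno, lin, cfg, True, "ATC1",
                                   seed=seed + 5)
    fit, traj = estimate_fitness(counts)
    m = fit.merge(truth[["lineage_id", "true_fitness"]])
    t0 = counts.set_index("lineage_id")["n_t0"].reindex(m["lineage_id"])
    sub = m[(t0.to_numpy() >= 5) & m["fitness"].notna()]
    r = float(np.corrcoef(sub["fitness"], sub["true_fitness"])[0, 1])
    return {"pearson_r": r, "n_lineages": int(len(sub)),
            "converged": traj.converged}


def null_calibration(seed: int, n_null_traits: int = 500) -> dict:
    """False-positive calibration on a fully null architecture.

    No gRNA has any effect; the mixed-model battery should call (almost)
    nothing at BH 0.05, and the permutation threshold should give a ~5%
    genome-wide false-positive rate per null trait.
    """
    mm, geno, guides, gbc, sbc = _base_panel(seed)
    null_cfg = ArchitectureConfig(efficacious_fraction=0.0, n_hubs=0,
                                  hub_styles=())
    arch = simulate_architecture(geno, guides, null_cfg, seed=seed + 3)
    fitness, _, _, controls = _simulate_fitness(geno, guides, gbc, sbc, arch,
                                                seed + 4)
    models = fx.run_guide_models(fitness, mode="mixed")
    res = fx.results_frame(models)
    q_mean = fx.adjust_fdr(res["p_mean"])
    q_int_all = fx.adjust_fdr(res["p_interaction"])
    n = int(res["p_mean"].notna().sum())

    rng = np.random.default_rng(seed + 99)
    null_dev = pd.DataFrame(
        rng.normal(size=(len(geno), n_null_traits)), index=geno.index,
        columns=[f"null{i}" for i in range(n_null_traits)],
    )
    cutoff = permutation_threshold(null_dev, geno, 1000, seed=seed + 100)
    hits = 0
    for c in null_dev.columns:
        sc = scan_trait(null_dev[c], geno, mm, trait_id=c)
        hits += bool((sc["neglog10p"] >= cutoff).any())
    return {
        "n_guides_tested": n,
        "mean_call_rate": float((q_mean < 0.05).sum() / n),
        "interaction_call_rate": float((q_int_all < 0.05).sum() / n),
        "permutation_cutoff": cutoff,
        "fwer": hits / n_null_traits,
        "n_null_traits": n_null_traits,
    }


def _hub_rep(rep_seed: int, mm: pd.DataFrame):
    """One replicate of hub detection from architecture-level deviations."""
    geno = simulate_cross(169, mm, 0.12, seed=rep_seed)
    guides, _ = simulate_guide_library(mm, seed=rep_seed + 1)
    arch = simulate_architecture(geno, guides, seed=rep_seed + 2)
    eff = induced_effect_matrix(arch, geno)
    dev = eff[list(arch.active_guides())].apply(lambda c: c - c.mean())
    thr = permutation_threshold(dev, geno, 1000, seed=rep_seed + 3)
    gp = guides.set_index("guide_id")
    peaks = []
    for gid in dev.columns:
        sc = scan_trait(dev[gid], geno, mm, trait_id=gid)
        pks = call_peaks(sc, thr,
                         guide_position=(gp.loc[gid, "chrom"],
                                         int(gp.loc[gid, "pos"])))
        peaks += [p for p in pks if not p.cis_excluded]
    pk = peaks_frame(peaks)
    params = hub_count_threshold(pk, genome_length(mm))
    hubs = call_hubs(overlap_profile(pk, mm), params, pk)
    indw = true_fitness_matrix(arch, geno, induced=True)
    conw = true_fitness_matrix(arch, geno, induced=False)
    bscan = scan_trait(arch.baseline, geno, mm, trait_id="baseline_fitness")
    bpk = peaks_frame(call_peaks(bscan, thr))
    out = []
    for h in hubs:
        if len(h.members) >= 3:
            h = hub_allele_summary(h, indw, conw, dev, geno, arch.guide_effect,
                                   fitness_loci=bpk)
        out.append(h)
    return arch, out


def hub_recovery(seed: int, n_reps: int = 100) -> dict:
    """Detection and classification of one amplifying + one masking hub,
    over seeded replicates; plus false hubs on one null run."""
    mm = default_marker_map()
    mi = mm.set_index("marker")
    n_ok = {"amplifying": 0, "masking": 0}
    marker_exact = 0
    extra = 0
    for rep in range(n_reps):
        arch, hubs = _hub_rep(seed + 10 * rep, mm)
        for _, th in arch.hubs.iterrows():
            tpos = mi.loc[th["marker"]]
            found = None
            for h in hubs:
                if (h.chrom == tpos["chrom"]
                        and abs(h.marker_pos - tpos["pos"]) <= MARKER_SPACING):
                    found = h
            if found is not None:
                if found.marker_pos == tpos["pos"]:
                    marker_exact += 1
                if found.classification == th["style"]:
                    n_ok[th["style"]] += 1
        extra += sum(
            1 for h in hubs
            if not any(
                mi.loc[t, "chrom"] == h.chrom
                and abs(h.marker_pos - mi.loc[t, "pos"]) <= 2 * MARKER_SPACING
                for t in arch.hubs["marker"]
            )
        )
    # null run: no hubs planted, same trait count
    geno = simulate_cross(169, mm, 0.12, seed=seed + 5000)
    rng = np.random.default_rng(seed + 5001)
    null_dev = pd.DataFrame(rng.normal(size=(len(geno), 500)), index=geno.index,
                            columns=[f"null{i}" for i in range(500)])
    thr = permutation_threshold(null_dev, geno, 1000, seed=seed + 5002)
    peaks = []
    for c in null_dev.columns:
        sc = scan_trait(null_dev[c], geno, mm, trait_id=c)
        peaks += call_peaks(sc, thr)
    pk = peaks_frame(peaks)
    params = hub_count_threshold(pk, genome_length(mm))
    false_hubs = call_hubs(overlap_profile(pk, mm), params, pk) if len(pk) else []
    return {
        "n_reps": n_reps,
        "amplifying_rate": n_ok["amplifying"] / n_reps,
        "masking_rate": n_ok["masking"] / n_reps,
        "marker_exact_rate": marker_exact / (2 * n_reps),
        "extra_hubs_per_rep": extra / n_reps,
        "false_hubs_null_run": len(false_hubs),
    }


def chimera_recovery(seed: int) -> dict:
    """Recovery of planted chimera coefficients and correction gain."""
    mm, geno, guides, gbc, sbc = _base_panel(seed)
    arch = simulate_architecture(geno, guides, seed=seed + 3)
    cfg = SimConfig(seed=seed + 4)
    lin = build_lineages(sbc, gbc, cfg)
    counts, _ = simulate_assay(arch, geno, lin, cfg, True, "ATC1", seed=seed + 5)
    coef = ChimeraCoefficients()
    mixed, chim_truth = inject_chimeras(counts, coef, seed=seed + 6,
                                        barcode_maps=(sbc, gbc))
    model = fit_chimera_model(mixed)
    rel = {
        "a_seg": abs(model.a_seg - coef.a_seg) / coef.a_seg,
        "a_guide": abs(model.a_guide - coef.a_guide) / coef.a_guide,
    }
    corrected = correct_chimeras(mixed, model)

    tcols = count_cols(counts)
    truth_f = counts.set_index("lineage_id")[tcols]
    truth_f = truth_f / truth_f.sum()

    def mae(tab):
        sub = tab[tab["valid"]].set_index("lineage_id")[tcols]
        f = sub / tab.set_index("lineage_id")[tcols].sum()
        err = (f - truth_f.reindex(f.index)).abs()
        return float(err.to_numpy().mean())

    chim_total = chim_truth[tcols].to_numpy().sum()
    frac = chim_total / mixed[tcols].to_numpy().sum()
    return {
        "rel_error_a_seg": float(rel["a_seg"]),
        "rel_error_a_guide": float(rel["a_guide"]),
        "mae_before": mae(mixed),
        "mae_after": mae(corrected),
        "chimeric_read_fraction": float(frac),
    }


def heritability_recovery(seed: int, n_reps: int = 100) -> dict:
    """Additive h2=0.5 recovery, and the epistasis fraction of an
    interaction architecture vs an additive-only baseline."""
    mm = default_marker_map()
    geno = simulate_cross(169, mm, 0.12, seed=seed)
    A = relationship_matrix(geno)
    L = np.linalg.cholesky(A.to_numpy() + 1e-8 * np.eye(len(A)))
    rng = np.random.default_rng(seed + 1)
    ests = []
    for _ in range(n_reps):
        g = L @ rng.normal(size=len(A)) * np.sqrt(0.5)
        e = rng.normal(size=len(A)) * np.sqrt(0.5)
        ests.append(narrow_sense(pd.Series(g + e, index=A.index), A))
    h2_mean = float(np.mean(ests))

    # epistasis fraction: interaction architecture vs additive-only
    guides, _ = simulate_guide_library(mm, seed=seed + 2)
    fractions = {}
    for label, cfg in (
        ("interaction", ArchitectureConfig()),
        ("additive", ArchitectureConfig(tau=0.0, sigma_lin=0.0,
                                        baseline_resid_sd=0.0)),
    ):
        arch = simulate_architecture(geno, guides, cfg, seed=seed + 3)
        eff = induced_effect_matrix(arch, geno)
        hub_guides = arch.interactions["guide_id"].unique()
        fr = []
        for gid in hub_guides:
            per_seg = eff[gid]
            noise_sd = 0.03
            reps = pd.DataFrame({
                "segregant_id": np.repeat(per_seg.index, 2),
                "guide_effect": np.repeat(per_seg.to_numpy(), 2)
                + rng.normal(0, noise_sd, 2 * len(per_seg)),
            })
            H2 = broad_sense(reps)
            dev = per_seg - per_seg.mean() + rng.normal(0, noise_sd / np.sqrt(2),
                                                        len(per_seg))
            h2 = narrow_sense(pd.Series(dev, index=per_seg.index), A)
            if H2 > 0:
                fr.append(epistasis_fraction(h2, H2))
        fractions[label] = float(np.mean(fr))
    return {
        "h2_additive_mean": h2_mean,
        "h2_additive_sd": float(np.std(ests)),
        "n_reps": n_reps,
        "epistasis_fraction_interaction": fractions["interaction"],
        "epistasis_fraction_additive": fractions["additive"],
    }


def deviation_structure(seed: int, depth: int = 4_000_000) -> dict:
    """Recovery of the baseline-coupling slope kappa and the dispersion
    slope tau from a hub-free architecture (deep-sequencing configuration,
    where per-lineage estimator bias is second order)."""
    mm, geno, guides, gbc, sbc = _base_panel(seed)
    cfg = ArchitectureConfig(n_hubs=0, hub_styles=())
    arch = simulate_architecture(geno, guides, cfg, seed=seed + 3)
    fitness, _, _, controls = _simulate_fitness(geno, guides, gbc, sbc, arch,
                                                seed + 4, depth=depth)
    models_f = fx.run_guide_models(fitness, mode="fixed")
    res_f = fx.results_frame(models_f)
    null = fx.efficacy_threshold(res_f["mean_effect"])
    eff_ids = res_f.index[res_f["mean_effect"] < null.cutoff].tolist()

    dev = fx.compute_deviations(models_f, eff_ids)
    base = segregant_baseline(fitness, None)
    pairs = pd.concat([
        pd.DataFrame({"d": dev[g].dropna(),
                      "b": base.reindex(dev[g].dropna().index)})
        for g in dev.columns
    ]).dropna()
    kappa_hat = float(stats.linregress(pairs["b"], pairs["d"]).slope)

    models_m = fx.run_guide_models(fitness, guide_ids=eff_ids, mode="mixed")
    res_m = fx.results_frame(models_m)
    tau_hat = float(stats.linregress(res_m["mean_effect"].abs(),
                                     res_m["slope_sd"]).slope)
    return {
        "kappa_true": arch.kappa, "kappa_hat": kappa_hat,
        "kappa_rel_error": abs(kappa_hat - arch.kappa) / abs(arch.kappa),
        "tau_true": arch.tau, "tau_hat": tau_hat,
        "tau_rel_error": abs(tau_hat - arch.tau) / arch.tau,
        "n_efficacious": len(eff_ids),
    }
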