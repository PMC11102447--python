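"""End-to-end orchestration: simulate -> counts -> fitness -> effects ->
heritability -> linkage -> hubs -> report.

Every stage is a thin wrapper over the library modules, reading only the
artifacts of earlier stages and writing plain-text TSV/JSON outputs under
one run directory. The full configuration (including the master seed) is
serialised into the run directory, and re-running a completed directory
without ``force`` changes nothing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import effects as fx
from . import heritability as h2mod
from . import hubs as hubmod
from . import linkage as lk
from .chimera import correct_chimeras, fit_chimera_model, normalize_depth
from .fitness import estimate_fitness, normalize_assays, qc_filter
from .genome import default_marker_map, genome_length
from .sim import (
    ArchitectureConfig,
    ChimeraCoefficients,
    LibraryConfig,
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
from .tables import COUNT_COLS, count_cols, read_tsv, write_tsv

ASSAYS = ("ATC1", "ATC2", "CON")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_segregants: int = 169
    n_chromosomes: int = 16
    markers_per_chromosome: int = 40
    recomb_fraction: float = 0.12
    library: LibraryConfig = field(default_factory=LibraryConfig)
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    chimera: ChimeraCoefficients | None = None
    chimera_correction: bool = True
    normalize_scale: float = 450_000_000
    generations: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 10.0)
    min_t0: int = 5
    min_guides_per_segregant: int = 100
    min_segregants_per_guide: int = 2
    q_alpha: float = 0.05
    lrt_alpha: float = 0.05
    min_deviation_segregants: int = 35
    deviation_mode: str = "mixed"
    n_permutations: int = 1000
    min_separation: int = 100_000
    cis_exclusion: int = 10_000
    hub_bin_size: int = 20_000
    hub_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        nested = {
            "library": LibraryConfig, "architecture": ArchitectureConfig,
            "sim": SimConfig, "chimera": ChimeraCoefficients,
        }
        kwargs = {}
        for key, val in raw.items():
            if key not in {f.name for f in dataclasses.fields(cls)}:
                raise ValueError(f"unknown config key: {key!r}")
            if key in nested and isinstance(val, dict):
                sub = nested[key]
                bad = set(val) - {f.name for f in dataclasses.fields(sub)}
                if bad:
                    raise ValueError(f"unknown config keys under {key}: {sorted(bad)}")
                val = sub(**val)
            kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        # json round trip turns tuples into lists for clean YAML output
        return json.loads(json.dumps(dataclasses.asdict(self)))


def _done(outdir: Path, stage: str) -> Path:
    return outdir / f".{stage}.done"


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 force: bool = False) -> Path:
    """Run all stages into ``outdir``; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    stage_simulate(config, outdir, force)
    stage_counts(config, outdir, force)
    stage_fitness(config, outdir, force)
    stage_effects(config, outdir, force)
    stage_heritability(config, outdir, force)
    stage_linkage(config, outdir, force)
    stage_hubs(config, outdir, force)
    write_report(outdir)
    return outdir


def stage_simulate(config: PipelineConfig, outdir: Path, force: bool = False):
    if _done(outdir, "simulate").exists() and not force:
        return
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=16)
    mm = default_marker_map(config.n_chromosomes, config.markers_per_chromosome)
    geno = simulate_cross(config.n_segregants, mm, config.recomb_fraction,
                          seed=int(seeds[0]))
    guides, gbc = simulate_guide_library(mm, config.library, seed=int(seeds[1]))
    sbc = simulate_segregant_barcodes(list(geno.index), seed=int(seeds[2]))
    sim = dataclasses.replace(config.sim, seed=int(seeds[3]))
    lineages = build_lineages(sbc, gbc, sim)
    arch = simulate_architecture(geno, guides, config.architecture,
                                 seed=int(seeds[4]))

    write_tsv(mm, outdir / "marker_map.tsv")
    write_tsv(geno.reset_index(), outdir / "genotypes.tsv")
    write_tsv(guides, outdir / "guides.tsv")
    write_tsv(gbc, outdir / "guide_barcodes.tsv")
    write_tsv(sbc, outdir / "segregant_barcodes.tsv")
    truth_all = []
    for k, (assay, induced) in enumerate(
        zip(ASSAYS, (True, True, False))
    ):
        counts, truth = simulate_assay(arch, geno, lineages, sim, induced,
                                       assay, seed=int(seeds[5 + k]))
        if config.chimera is not None:
            counts, chim_truth = inject_chimeras(
                counts, config.chimera, seed=int(seeds[9 + k]),
                barcode_maps=(sbc, gbc),
            )
            write_tsv(chim_truth, outdir / f"chimera_truth_{assay}.tsv")
        write_tsv(counts, outdir / f"counts_raw_{assay}.tsv")
        truth_all.append(truth)
    write_tsv(pd.concat(truth_all), outdir / "true_fitness.tsv")

    truth = {
        "seed": config.seed,
        "baseline": arch.baseline.to_dict(),
        "guide_effect": arch.guide_effect.to_dict(),
        "kappa": arch.kappa, "tau": arch.tau, "sigma_lin": arch.sigma_lin,
        "qtl": arch.qtl.to_dict("records"),
        "hubs": arch.hubs.to_dict("records"),
        "interactions": arch.interactions.to_dict("records"),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    _done(outdir, "simulate").touch()


def stage_counts(config: PipelineConfig, outdir: Path, force: bool = False):
    """Chimera correction and depth normalisation per assay."""
    if _done(outdir, "counts").exists() and not force:
        return
    for assay in ASSAYS:
        counts = read_tsv(outdir / f"counts_raw_{assay}.tsv")
        if config.chimera_correction and (~counts["valid"]).sum() >= 10:
            model = fit_chimera_model(counts)
            (outdir / f"chimera_model_{assay}.json").write_text(json.dumps({
                "intercept": model.intercept, "a_seg": model.a_seg,
                "a_guide": model.a_guide,
                "per_timepoint": model.per_timepoint.to_dict(),
            }, indent=1))
            counts = correct_chimeras(counts, model)
        counts = counts[counts["valid"]].reset_index(drop=True)
        counts = normalize_depth(counts, config.normalize_scale)
        write_tsv(counts, outdir / f"counts_{assay}.tsv")
    _done(outdir, "counts").touch()


def stage_fitness(config: PipelineConfig, outdir: Path, force: bool = False):
    if _done(outdir, "fitness").exists() and not force:
        return
    fits = []
    for assay in ASSAYS:
        counts = read_tsv(outdir / f"counts_{assay}.tsv")
        fit, traj = estimate_fitness(counts, config.generations)
        fit = qc_filter(fit, counts, config.min_t0,
                        config.min_guides_per_segregant,
                        config.min_segregants_per_guide)
        fits.append(fit)
        (outdir / f"trajectory_{assay}.json").write_text(json.dumps({
            "generations": traj.generations.tolist(),
            "mean_fitness": traj.mean_fitness.tolist(),
            "n_iter": traj.n_iter, "converged": traj.converged,
        }, indent=1))
    fitness = pd.concat(fits, ignore_index=True)
    guides = read_tsv(outdir / "guides.tsv")
    controls = guides.loc[guides["is_control"], "guide_id"].tolist()
    fitness, ctrl_summary = normalize_assays(fitness, controls)
    write_tsv(fitness, outdir / "fitness.tsv")
    write_tsv(ctrl_summary.reset_index(), outdir / "control_normalization.tsv")
    _done(outdir, "fitness").touch()


def stage_effects(config: PipelineConfig, outdir: Path, force: bool = False):
    if _done(outdir, "effects").exists() and not force:
        return
    fitness = read_tsv(outdir / "fitness.tsv")
    guides = read_tsv(outdir / "guides.tsv")
    mm = read_tsv(outdir / "marker_map.tsv")

    poly = fx.flag_polymorphic_guides(guides, mm)
    excluded = set(guides.loc[poly, "guide_id"])
    test_ids = [g for g in guides["guide_id"] if g not in excluded]
    models = fx.run_guide_models(fitness, test_ids, mode=config.deviation_mode,
                                 lrt_alpha=config.lrt_alpha)
    res = fx.results_frame(models)
    null = fx.efficacy_threshold(res["mean_effect"])
    res = fx.apply_efficacy(res, null, config.q_alpha)
    res["polymorphic_excluded"] = False
    if excluded:
        extra = pd.DataFrame(index=pd.Index(sorted(excluded), name="guide_id"))
        for col in res.columns:
            extra[col] = False if res[col].dtype == bool else np.nan
        extra["polymorphic_excluded"] = True
        res = pd.concat([res, extra]).sort_index()
    for col in ("efficacious", "background", "polymorphic_excluded"):
        res[col] = res[col].fillna(False).astype(bool)
    write_tsv(res.reset_index(), outdir / "guide_effects.tsv")
    (outdir / "efficacy_null.json").write_text(json.dumps(
        {"center": null.center, "sd": null.sd, "cutoff": null.cutoff}, indent=1))

    dev = fx.compute_deviations(
        models, res.index[res["background"].fillna(False).astype(bool)].tolist(),
        config.min_deviation_segregants)
    write_tsv(dev.reset_index(), outdir / "deviations.tsv")
    _done(outdir, "effects").touch()


def stage_heritability(config: PipelineConfig, outdir: Path, force: bool = False):
    if _done(outdir, "heritability").exists() and not force:
        return
    fitness = read_tsv(outdir / "fitness.tsv")
    guides = read_tsv(outdir / "guides.tsv")
    geno = read_tsv(outdir / "genotypes.tsv").set_index("segregant")
    dev = read_tsv(outdir / "deviations.tsv").set_index("segregant_id")
    controls = guides.loc[guides["is_control"], "guide_id"].tolist()
    base = h2mod.segregant_baseline(fitness, controls)
    A = h2mod.relationship_matrix(geno)
    rows = []
    for gid in dev.columns:
        try:
            per_lin = h2mod.guide_effect_per_lineage(fitness, base, gid)
            H2 = h2mod.broad_sense(per_lin)
            h2 = h2mod.narrow_sense(dev[gid], A)
            frac = h2mod.epistasis_fraction(h2, H2) if H2 > 0 else np.nan
            rows.append((gid, H2, h2, frac))
        except ValueError as err:
            rows.append((gid, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["guide_id", "H2", "h2", "epistasis_fraction"])
    write_tsv(out, outdir / "heritability.tsv")
    _done(outdir, "heritability").touch()


def stage_linkage(config: PipelineConfig, outdir: Path, force: bool = False):
    if _done(outdir, "linkage").exists() and not force:
        return
    geno = read_tsv(outdir / "genotypes.tsv").set_index("segregant")
    mm = read_tsv(outdir / "marker_map.tsv")
    dev = read_tsv(outdir / "deviations.tsv").set_index("segregant_id")
    guides = read_tsv(outdir / "guides.tsv").set_index("guide_id")
    herit = read_tsv(outdir / "heritability.tsv").set_index("guide_id")
    fitness = read_tsv(outdir / "fitness.tsv")
    controls = guides.index[guides["is_control"]].tolist()

    rng = np.random.default_rng(config.seed + 7)
    cutoff = lk.permutation_threshold(dev, geno, config.n_permutations,
                                      seed=int(rng.integers(2**31 - 1)))
    scans, peaks = [], []
    for gid in dev.columns:
        sc = lk.scan_trait(dev[gid], geno, mm, trait_id=gid)
        scans.append(sc)
        gpos = (guides.loc[gid, "chrom"], int(guides.loc[gid, "pos"]))
        H2 = float(herit.loc[gid, "H2"]) if gid in herit.index else None
        for p in lk.call_peaks(sc, cutoff, config.min_separation,
                               config.cis_exclusion, gpos):
            if H2 and H2 > 0:
                p.prop_h2 = min(p.r2 / H2, 1.0)
            peaks.append(p)
    # baseline fitness mapped with the same machinery
    base = h2mod.segregant_baseline(fitness, controls)
    bscan = lk.scan_trait(base, geno, mm, trait_id="baseline_fitness")
    scans.append(bscan)
    bpeaks = lk.call_peaks(bscan, cutoff, config.min_separation)
    write_tsv(pd.concat(scans, ignore_index=True), outdir / "scans.tsv")
    write_tsv(lk.peaks_frame(peaks), outdir / "peaks.tsv")
    write_tsv(lk.peaks_frame(bpeaks), outdir / "fitness_loci.tsv")
    (outdir / "linkage_threshold.json").write_text(
        json.dumps({"neglog10p_cutoff": cutoff,
                    "n_permutations": config.n_permutations}, indent=1))
    _done(outdir, "linkage").touch()


def stage_hubs(config: PipelineConfig, outdir: Path, force: bool = False):
    if _done(outdir, "hubs").exists() and not force:
        return
    mm = read_tsv(outdir / "marker_map.tsv")
    peaks = read_tsv(outdir / "peaks.tsv")
    fitness_loci = read_tsv(outdir / "fitness_loci.tsv")
    geno = read_tsv(outdir / "genotypes.tsv").set_index("segregant")
    dev = read_tsv(outdir / "deviations.tsv").set_index("segregant_id")
    fitness = read_tsv(outdir / "fitness.tsv")
    res = read_tsv(outdir / "guide_effects.tsv").set_index("guide_id")

    trans = peaks[~peaks["cis_excluded"]] if len(peaks) else peaks
    params = hubmod.hub_count_threshold(trans, genome_length(mm),
                                        config.hub_bin_size, config.hub_alpha)
    profile = hubmod.overlap_profile(trans, mm)
    hubs = hubmod.call_hubs(profile, params, trans)

    ind = _fitness_matrix(fitness, "ATC1")
    con = _fitness_matrix(fitness, "CON")
    out = []
    for hub in hubs:
        if len(hub.members) >= 3:
            hub = hubmod.hub_allele_summary(
                hub, ind, con, dev, geno, res["mean_effect"],
                fitness_loci=fitness_loci, alpha=config.hub_alpha)
        d = {k: v for k, v in vars(hub).items() if k != "member_summary"}
        if hub.member_summary is not None:
            d["member_summary"] = hub.member_summary.to_dict("records")
        out.append(d)
    write_tsv(profile, outdir / "overlap_profile.tsv")
    (outdir / "hubs.json").write_text(json.dumps({
        "params": vars(params), "hubs": out}, indent=1, default=float))
    bed = pd.DataFrame({
        "chrom": [h.chrom for h in hubs],
        "start": [h.start - 1 for h in hubs],   # BED half-open, 0-based
        "end": [h.end for h in hubs],
        "name": [h.hub_id for h in hubs],
    })
    bed.to_csv(outdir / "hubs.bed", sep="\t", header=False, index=False)
    _done(outdir, "hubs").touch()


def _fitness_matrix(fitness: pd.DataFrame, assay: str) -> pd.DataFrame:
    """Segregant x guide mean fitness, replicate barcodes averaged first."""
    sub = fitness[(fitness["assay"] == assay) & fitness["fitness"].notna()]
    if "retained" in sub.columns:
        sub = sub[sub["retained"]]
    return sub.pivot_table(index="segregant_id", columns="guide_id",
                           values="fitness", aggfunc="mean")


def write_report(outdir: str | Path) -> dict:
    """Headline summary of a completed run; also written as report.json."""
    outdir = Path(outdir)
    missing = [f for f in ("guide_effects.tsv", "heritability.tsv",
                           "peaks.tsv", "hubs.json", "fitness.tsv")
               if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing artifacts: {missing}")
    res = read_tsv(outdir / "guide_effects.tsv")
    for col in ("efficacious", "background", "polymorphic_excluded"):
        res[col] = res[col].astype(bool)
    herit = read_tsv(outdir / "heritability.tsv")
    peaks = read_tsv(outdir / "peaks.tsv")
    hubs = json.loads((outdir / "hubs.json").read_text())
    fitness = read_tsv(outdir / "fitness.tsv")

    mats = {a: _fitness_matrix(fitness, a) for a in ASSAYS}
    lin = fitness[fitness["fitness"].notna() & fitness.get("retained", True)]
    wide = lin.pivot_table(index="lineage_id", columns="assay", values="fitness")

    def spear(a, b, frame):
        if a in frame.columns and b in frame.columns:
            sub = frame[[a, b]].dropna()
            return float(stats.spearmanr(sub[a], sub[b]).statistic)
        return np.nan

    guide_means = pd.DataFrame({a: m.mean() for a, m in mats.items()})
    eff_ids = res.loc[res["efficacious"].fillna(False), "guide_id"]
    report = {
        "n_lineages_retained": int(len(lin)),
        "n_guides_tested": int(res["mean_effect"].notna().sum()),
        "n_efficacious": int(res["efficacious"].fillna(False).sum()),
        "n_background": int(res["background"].fillna(False).sum()),
        "n_polymorphic_excluded": int(res["polymorphic_excluded"].fillna(False).sum()),
        "n_loci": int((~peaks["cis_excluded"]).sum()) if len(peaks) else 0,
        "n_cis_excluded": int(peaks["cis_excluded"].sum()) if len(peaks) else 0,
        "n_hubs": len(hubs["hubs"]),
        "hub_members": {h["hub_id"]: len(h["members"]) for h in hubs["hubs"]},
        "hub_classes": {h["hub_id"]: h["classification"] for h in hubs["hubs"]},
        "mean_H2": float(herit["H2"].mean()),
        "mean_h2": float(herit["h2"].mean()),
        "mean_epistasis_fraction": float(herit["epistasis_fraction"].mean()),
        "lineage_fitness_spearman": {
            "ATC1_vs_ATC2": spear("ATC1", "ATC2", wide),
            "CON_vs_ATC1": spear("CON", "ATC1", wide),
        },
        "guide_mean_fitness_spearman_efficacious": {
            "ATC1_vs_ATC2": spear("ATC1", "ATC2", guide_means.loc[
                guide_means.index.intersection(eff_ids)]),
            "CON_vs_ATC1": spear("CON", "ATC1", guide_means.loc[
                guide_means.index.intersection(eff_ids)]),
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
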