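"""Pooled serial-transfer competition: lineages, trajectories, read counts.

A lineage is one (segregant barcode, gRNA barcode) pair. All assays (two
induced, one control) are seeded from the same T0 pool, so the lineage
table is built once and shared. Lineage frequencies evolve deterministically
in expectation,

    f_i(t + dt)  propto  f_i(t) * exp(s_i * dt),

renormalised at every transfer (equivalently, growth at s_i minus the
population mean), and the observed counts at each sequenced time point are
a multinomial draw of the configured depth from f(t). An optional bottleneck
resamples the population between transfers to add genetic drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..tables import COUNT_COLS
from .architecture import EffectArchitecture, true_fitness_matrix


@dataclass
class SimConfig:
    time_points: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 10.0)
    depth: int = 1_000_000
    dilution_factor: int = 4
    t0_cv: float = 0.3                 # log-normal CV of T0 lineage abundance
    # barcodes integrated per (segregant barcode, gRNA) combination:
    # probabilities of 1, 2, ... distinct gRNA barcodes (mean ~1.15)
    barcodes_per_combo: tuple[float, ...] = (0.85, 0.15)
    barcode_noise_sd: float = 0.0      # extra per-lineage (per-barcode) fitness noise
    bottleneck: int | None = None      # cells resampled at each transfer; None = off
    sampling: str = "multinomial"      # or "expected" for noiseless counts
    seed: int = 0

    def __post_init__(self):
        tp = self.time_points
        if tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must start at 0 and strictly increase")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def build_lineages(
    segregant_barcodes: pd.DataFrame,
    guide_barcodes: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Lineage table shared by all assays.

    Every (segregant barcode, gRNA) combination receives 1-3 lineages, each
    tagged by a distinct gRNA barcode sampled from that guide's barcode
    pool, emulating independent integration events per transformed strain.
    T0 abundances are log-normal with the configured CV.
    """
    rng0 = np.random.default_rng(config.seed + 1)
    probs = np.asarray(config.barcodes_per_combo, dtype=float)
    probs = probs / probs.sum()
    seg_bcs = segregant_barcodes.rename(columns={"barcode": "segregant_bc"})
    parts = []
    for gid, bcs in guide_barcodes.groupby("guide_id")["barcode"]:
        bcs = bcs.to_numpy()
        k = np.minimum(
            rng0.choice(np.arange(1, len(probs) + 1), size=len(seg_bcs), p=probs),
            len(bcs),
        )
        reps = np.repeat(np.arange(len(seg_bcs)), k)
        # distinct barcode indices per combo: offset a random start
        offs = np.concatenate([np.arange(j) for j in k])
        start = np.repeat(rng0.integers(0, len(bcs), size=len(seg_bcs)), k)
        part = seg_bcs.iloc[reps][["segregant_bc", "segregant_id"]].copy()
        part["guide_bc"] = bcs[(start + offs) % len(bcs)]
        part["guide_id"] = gid
        parts.append(part)
    lin = pd.concat(parts, ignore_index=True)
    lin.insert(0, "lineage_id", [f"L{i:07d}" for i in range(len(lin))])
    rng = np.random.default_rng(config.seed)
    cv = config.t0_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        ab = rng.lognormal(-0.5 * sigma * sigma, sigma, size=len(lin))
    else:
        ab = np.ones(len(lin))
    lin["t0_abundance"] = ab / ab.sum()
    return lin


def simulate_assay(
    arch: EffectArchitecture,
    genotypes: pd.DataFrame,
    lineages: pd.DataFrame,
    config: SimConfig,
    induced: bool,
    assay: str,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one assay; returns (counts, truth).

    counts: lineage_id, segregant_bc, guide_bc, segregant_id, guide_id,
    assay, valid, n_t0..n_t4. truth: lineage_id plus the true per-generation
    fitness used for that lineage in this assay.
    """
    rng = np.random.default_rng(seed)
    w = true_fitness_matrix(arch, genotypes, induced=induced)
    s = w.to_numpy()[
        genotypes.index.get_indexer(lineages["segregant_id"]),
        w.columns.get_indexer(lineages["guide_id"]),
    ]
    if config.barcode_noise_sd > 0:
        s = s + rng.normal(0.0, config.barcode_noise_sd, size=len(s))

    f = lineages["t0_abundance"].to_numpy().astype(float).copy()
    if f.sum() <= 0:
        raise RuntimeError("zero total abundance at T0")
    f /= f.sum()
    tps = np.asarray(config.time_points, dtype=float)
    counts = np.empty((len(f), len(tps)))
    for k, tp in enumerate(tps):
        if k > 0:
            dt = tps[k] - tps[k - 1]
            f = f * np.exp(s * dt)
            tot = f.sum()
            if tot <= 0:
                raise RuntimeError(f"zero total abundance at transfer {k}")
            f /= tot
            if config.bottleneck:
                f = rng.multinomial(config.bottleneck, f).astype(float)
                f /= f.sum()
        if config.sampling == "multinomial":
            counts[:, k] = rng.multinomial(config.depth, f)
        else:
            counts[:, k] = f * config.depth
    out = lineages[
        ["lineage_id", "segregant_bc", "guide_bc", "segregant_id", "guide_id"]
    ].copy()
    out["assay"] = assay
    out["valid"] = True
    for k, col in enumerate(COUNT_COLS[: len(tps)]):
        out[col] = counts[:, k]
    if config.sampling == "multinomial":
        out[COUNT_COLS[: len(tps)]] = out[COUNT_COLS[: len(tps)]].astype(np.int64)
    truth = pd.DataFrame({"lineage_id": lineages["lineage_id"], "true_fitness": s})
    truth["assay"] = assay
    return out, truth


@dataclass
class ChimeraCoefficients:
    intercept: float = 0.0
    a_seg: float = 6e-5
    a_guide: float = 1.2e-4

    def __post_init__(self):
        if min(self.intercept, self.a_seg, self.a_guide) < 0:
            raise ValueError("chimera coefficients must be non-negative")


def inject_chimeras(
    counts: pd.DataFrame,
    coef: ChimeraCoefficients,
    seed: int = 0,
    barcode_maps: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add PCR-chimera reads to a count table.

    For every (segregant barcode, gRNA barcode) pair - valid lineages and
    invalid pairings alike - Poisson counts are added at each time point
    with mean depth * (intercept + a_seg * F_seg + a_guide * F_guide),
    where F are the marginal frequencies of the two barcodes in that time
    point. Returns (combined counts, chimera-only truth counts); invalid
    pairs appear as new rows with valid=False.
    """
    rng = np.random.default_rng(seed)
    tcols = [c for c in COUNT_COLS if c in counts.columns]
    seg_bcs = np.sort(counts["segregant_bc"].unique())
    gui_bcs = np.sort(counts["guide_bc"].unique())
    si = pd.Index(seg_bcs).get_indexer(counts["segregant_bc"])
    gi = pd.Index(gui_bcs).get_indexer(counts["guide_bc"])

    base = np.zeros((len(seg_bcs), len(gui_bcs)))
    chim = {}
    for col in tcols:
        n = counts[col].to_numpy(float)
        depth = n.sum()
        f_seg = np.bincount(si, weights=n, minlength=len(seg_bcs)) / depth
        f_gui = np.bincount(gi, weights=n, minlength=len(gui_bcs)) / depth
        mean = depth * (coef.intercept + coef.a_seg * f_seg[:, None]
                        + coef.a_guide * f_gui[None, :])
        chim[col] = rng.poisson(mean)
        base += chim[col]

    combined = counts.copy()
    valid_flat = si * len(gui_bcs) + gi
    for col in tcols:
        combined[col] = combined[col].to_numpy() + chim[col].ravel()[valid_flat]

    mask = np.ones(base.shape, dtype=bool).ravel()
    mask[valid_flat] = False
    hit = mask & (base.ravel() > 0)
    idx = np.flatnonzero(hit)
    inv = pd.DataFrame({
        "segregant_bc": seg_bcs[idx // len(gui_bcs)],
        "guide_bc": gui_bcs[idx % len(gui_bcs)],
    })
    if barcode_maps is not None:
        seg_map, gui_map = barcode_maps
        inv = inv.merge(seg_map.rename(columns={"barcode": "segregant_bc"}), how="left")
        inv = inv.merge(gui_map.rename(columns={"barcode": "guide_bc"}), how="left")
    else:
        inv["segregant_id"] = pd.NA
        inv["guide_id"] = pd.NA
    inv.insert(0, "lineage_id", [f"X{i:07d}" for i in range(len(inv))])
    inv["assay"] = counts["assay"].iloc[0] if len(counts) else ""
    inv["valid"] = False
    for col in tcols:
        inv[col] = chim[col].ravel()[idx]
    combined = pd.concat([combined, inv[combined.columns]], ignore_index=True)

    truth = counts[["lineage_id", "segregant_bc", "guide_bc"]].copy()
    for col in tcols:
        truth[col] = chim[col].ravel()[valid_flat]
    truth = pd.concat(
        [truth, inv[["lineage_id", "segregant_bc", "guide_bc"] + tcols]],
        ignore_index=True,
    )
    return combined, truth
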