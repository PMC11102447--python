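"""Generative fitness architecture for the simulated cross.

The trait model: every segregant has a baseline (per-generation, natural-log
scale) fitness

    b[s] = sum_l a_l * x[s, l] + Normal(0, baseline_resid_sd)

from a handful of additive fitness QTL. An induced, active gRNA g modifies
the fitness of segregant s to

    w[s, g] = b[s] + m[g] + kappa * b[s] + sum_l beta[g, l] * x[s, l] + eps[s, g]

where m[g] <= 0 is the mean gRNA effect, kappa couples the perturbation
response to baseline fitness (higher-fitness strains are hit harder when
kappa < 0), beta[g, l] are interactions with hub loci, and eps[s, g] ~
Normal(0, tau * |m[g]| + sigma_lin) is a segregant-specific residual whose
dispersion grows with the mean effect. eps is drawn once per
(segregant, gRNA) pair and stored, so it behaves as reproducible
higher-order genetic signal rather than measurement noise.

"Active" means non-control with a nonzero mean effect: control gRNAs and
inert gRNAs leave fitness at b[s] exactly when induced (unless leaky
expression is switched on), so the uninduced control assay and the null
fraction of the library are genuinely neutral.

Hubs come in two styles:

* amplifying - a marker with no baseline effect whose 3S allele becomes
  beneficial under interacting gRNAs, with |beta| proportional to |m|:
  beta = amplify_slope * |m[g]|.
* masking - a marker that is itself a baseline-fitness QTL with effect a,
  whose realised allele effect in the induced state is attenuated to
  exactly a * max(0, 1 - attenuation * |m[g]|); beta therefore equals
  a * max(0, 1 - attenuation * |m[g]|) - (1 + kappa) * a, compensating the
  kappa coupling (which itself carries a kappa * a allele contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ArchitectureConfig:
    n_fitness_qtl: int = 3
    qtl_effect: float = 0.04
    baseline_resid_sd: float = 0.03
    efficacious_fraction: float = 0.35
    effect_low: float = 0.05          # |m| drawn Uniform(effect_low, effect_high)
    effect_high: float = 0.35
    n_hubs: int = 2
    hub_styles: tuple[str, ...] = ("amplifying", "masking")
    guides_per_hub: int = 12
    amplify_slope: float = 0.5
    masking_qtl_effect: float = 0.1   # masking hubs are major fitness loci
    masking_attenuation: float = 3.0
    kappa: float = -0.15
    tau: float = 0.2
    sigma_lin: float = 0.015
    leaky_fraction: float = 0.0       # fraction of active guides expressed in CON


@dataclass
class EffectArchitecture:
    baseline: pd.Series                 # per segregant
    qtl: pd.DataFrame                   # marker, effect
    guide_effect: pd.Series             # m[g] per guide
    interactions: pd.DataFrame          # guide_id, marker, beta, hub
    hubs: pd.DataFrame                  # hub, marker, style, qtl_effect, attenuation
    epsilon: pd.DataFrame               # segregant x guide residuals
    kappa: float
    tau: float
    sigma_lin: float
    leaky: pd.Series                    # bool per guide
    seed: int
    config: ArchitectureConfig = field(repr=False, default=None)

    def active_guides(self) -> pd.Index:
        return self.guide_effect.index[self.guide_effect != 0.0]


def simulate_architecture(
    genotypes: pd.DataFrame,
    guides: pd.DataFrame,
    config: ArchitectureConfig | None = None,
    seed: int = 0,
) -> EffectArchitecture:
    config = config or ArchitectureConfig()
    if len(config.hub_styles) < config.n_hubs:
        raise ValueError("hub_styles must name a style for every hub")
    markers = genotypes.columns.to_numpy()
    if config.n_hubs > len(markers):
        raise ValueError("more hubs than markers")
    rng = np.random.default_rng(seed)
    segs = genotypes.index

    # hubs: distinct chromosomes, away from chromosome edges so drop
    # intervals fit inside; QTL on the remaining markers
    chrom_of = pd.Series([m.rsplit("_", 1)[0] for m in markers], index=markers)
    hub_rows = []
    hub_chroms = rng.choice(chrom_of.unique(), size=config.n_hubs, replace=False)
    for h, (style, chrom) in enumerate(zip(config.hub_styles, hub_chroms)):
        cands = chrom_of.index[chrom_of == chrom]
        lo, hi = len(cands) // 4, 3 * len(cands) // 4
        marker = cands[int(rng.integers(lo, max(hi, lo + 1)))]
        a = config.masking_qtl_effect if style == "masking" else 0.0
        hub_rows.append((f"hub{h + 1}", marker, style, a, config.masking_attenuation))
    hubs = pd.DataFrame(
        hub_rows, columns=["hub", "marker", "style", "qtl_effect", "attenuation"]
    )

    free = np.setdiff1d(markers, hubs["marker"].to_numpy())
    qtl_markers = rng.choice(free, size=min(config.n_fitness_qtl, len(free)), replace=False)
    qtl = pd.DataFrame({"marker": qtl_markers, "effect": config.qtl_effect})
    masking = hubs.loc[hubs["style"] == "masking", ["marker", "qtl_effect"]]
    if len(masking):
        qtl = pd.concat(
            [qtl, masking.rename(columns={"qtl_effect": "effect"})],
            ignore_index=True,
        )
    qtl = qtl[qtl["effect"] != 0.0].reset_index(drop=True)

    baseline = pd.Series(0.0, index=segs, name="baseline")
    for _, row in qtl.iterrows():
        baseline += row["effect"] * genotypes[row["marker"]].astype(float)
    baseline += rng.normal(0.0, config.baseline_resid_sd, size=len(segs))

    # mean gRNA effects
    m = pd.Series(0.0, index=pd.Index(guides["guide_id"], name="guide_id"), name="m")
    noncontrol = guides.loc[~guides["is_control"], "guide_id"].to_numpy()
    n_eff = int(round(config.efficacious_fraction * len(noncontrol)))
    eff_ids = rng.choice(noncontrol, size=n_eff, replace=False)
    m.loc[eff_ids] = -rng.uniform(config.effect_low, config.effect_high, size=n_eff)

    # hub interactions: disjoint guide sets drawn from the efficacious pool
    pool = list(rng.permutation(eff_ids))
    inter_rows = []
    for _, hub in hubs.iterrows():
        take, pool = pool[: config.guides_per_hub], pool[config.guides_per_hub:]
        for gid in take:
            mg = abs(m.loc[gid])
            if hub["style"] == "amplifying":
                beta = config.amplify_slope * mg
            else:
                # beta compensates the kappa*b coupling so the realised
                # induced allele effect is exactly a*max(0, 1 - r|m|)
                a = hub["qtl_effect"]
                target = a * max(0.0, 1.0 - hub["attenuation"] * mg)
                beta = target - (1.0 + config.kappa) * a
            inter_rows.append((gid, hub["marker"], beta, hub["hub"]))
    interactions = pd.DataFrame(inter_rows, columns=["guide_id", "marker", "beta", "hub"])

    # stored per-(segregant, guide) residuals; zero for inert/control guides
    sd = (config.tau * m.abs() + config.sigma_lin).to_numpy()
    sd[m.to_numpy() == 0.0] = 0.0
    eps = rng.normal(0.0, 1.0, size=(len(segs), len(m))) * sd[None, :]
    epsilon = pd.DataFrame(eps, index=segs, columns=m.index)

    leaky = pd.Series(False, index=m.index, name="leaky")
    if config.leaky_fraction > 0 and n_eff:
        n_leaky = int(round(config.leaky_fraction * n_eff))
        leaky.loc[rng.choice(eff_ids, size=n_leaky, replace=False)] = True

    return EffectArchitecture(
        baseline=baseline, qtl=qtl, guide_effect=m, interactions=interactions,
        hubs=hubs, epsilon=epsilon, kappa=config.kappa, tau=config.tau,
        sigma_lin=config.sigma_lin, leaky=leaky, seed=seed, config=config,
    )


def induced_effect_matrix(arch: EffectArchitecture, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-(segregant, guide) perturbation effect: m + kappa*b + beta.x + eps.

    Zero for control and inert guides.
    """
    segs, gids = genotypes.index, arch.guide_effect.index
    active = (arch.guide_effect != 0.0).to_numpy()
    eff = np.tile(arch.guide_effect.to_numpy(), (len(segs), 1))
    eff += arch.kappa * np.outer(arch.baseline.loc[segs].to_numpy(), active.astype(float))
    eff += arch.epsilon.loc[segs, gids].to_numpy()
    out = pd.DataFrame(eff, index=segs, columns=gids)
    for _, row in arch.interactions.iterrows():
        out[row["guide_id"]] += row["beta"] * genotypes[row["marker"]].astype(float)
    out.loc[:, ~active] = 0.0
    return out


def true_fitness_matrix(
    arch: EffectArchitecture, genotypes: pd.DataFrame, induced: bool
) -> pd.DataFrame:
    """Per-(segregant, guide) fitness under the induced or control condition."""
    segs, gids = genotypes.index, arch.guide_effect.index
    base = pd.DataFrame(
        np.tile(arch.baseline.loc[segs].to_numpy()[:, None], (1, len(gids))),
        index=segs, columns=gids,
    )
    eff = induced_effect_matrix(arch, genotypes)
    if induced:
        return base + eff
    if arch.leaky.any():
        leaky_cols = arch.leaky[arch.leaky].index
        base[leaky_cols] = base[leaky_cols] + eff[leaky_cols]
    return base


def true_fitness(
    arch: EffectArchitecture,
    genotypes: pd.DataFrame,
    segregant: str,
    guide: str,
    induced: bool,
) -> float:
    """Fitness of one segregant-gRNA combination (per generation)."""
    if segregant not in genotypes.index:
        raise KeyError(f"unknown segregant {segregant!r}")
    if guide not in arch.guide_effect.index:
        raise KeyError(f"unknown gRNA {guide!r}")
    b = float(arch.baseline.loc[segregant])
    express = induced or bool(arch.leaky.loc[guide])
    if not express or arch.guide_effect.loc[guide] == 0.0:
        return b
    eff = float(arch.guide_effect.loc[guide]) + arch.kappa * b
    eff += float(arch.epsilon.loc[segregant, guide])
    sub = arch.interactions[arch.interactions["guide_id"] == guide]
    for _, row in sub.iterrows():
        eff += row["beta"] * float(genotypes.loc[segregant, row["marker"]])
    return b + eff
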