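"""Hub loci: genomic regions interacting with more gRNAs than chance.

The drop intervals of all detected trans loci are stacked along the
genome. Under a null of randomly placed intervals, the number overlapping
any position is Poisson with rate lambda = (total interval length) /
(genome length). The genome is cut into 20 kb bins, a per-bin significance
level of alpha / n_bins is applied, and the hub-calling threshold k is the
smallest overlap count whose upper-tail Poisson probability falls below
it. Runs of adjacent markers with counts >= k become hubs; the hub marker
is the position with the highest count (ties resolved to the position
closest to the mean of the tied positions), and members are the traits
whose intervals overlap that marker.

Each hub is classified by how its allele contrast scales with the mean
effects of its member gRNAs: amplifying hubs (no baseline-fitness effect
of their own) show allele differences that grow with |m_g|, while masking
hubs coincide with baseline-fitness loci whose effect shrinks with |m_g|.
A sign-epistasis flag marks members for which the favoured allele flips
between the uninduced condition and the induced state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import LinkagePeak


@dataclass
class HubCallParams:
    bin_size: int
    alpha: float
    n_bins: int
    per_bin_alpha: float
    lam: float
    k: int


@dataclass
class Hub:
    hub_id: str
    chrom: str
    start: int
    end: int
    marker: str
    marker_pos: int
    count: int
    members: list[str]
    classification: str = "unclassified"
    slope: float = np.nan
    slope_p: float = np.nan
    is_fitness_locus: bool = False
    sign_epistasis: bool = False
    member_summary: pd.DataFrame = field(default=None, repr=False)


def overlap_profile(
    peaks: pd.DataFrame,
    marker_map: pd.DataFrame,
) -> pd.DataFrame:
    """Number of drop intervals covering each marker position (closed)."""
    out = marker_map[["chrom", "pos", "marker"]].copy()
    counts = np.zeros(len(out), dtype=int)
    cmax = marker_map.groupby("chrom")["pos"].max()
    for _, iv in peaks.iterrows():
        if iv["chrom"] not in cmax.index or iv["end"] > cmax[iv["chrom"]] or iv["start"] < 1:
            raise ValueError(f"interval outside genome: {iv['chrom']}:{iv['start']}-{iv['end']}")
        hit = (out["chrom"] == iv["chrom"]) & (out["pos"] >= iv["start"]) & (out["pos"] <= iv["end"])
        counts[hit.to_numpy()] += 1
    out["count"] = counts
    return out


def hub_count_threshold(
    peaks: pd.DataFrame,
    genome_length: int,
    bin_size: int = 20_000,
    alpha: float = 0.05,
) -> HubCallParams:
    """Poisson overlap threshold k for hub calling."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    total = float((peaks["end"] - peaks["start"] + 1).sum()) if len(peaks) else 0.0
    lam = total / genome_length
    if len(peaks) and lam <= 0:
        raise ValueError("zero interval mass with nonempty peak list")
    n_bins = ceil(genome_length / bin_size)
    thr = alpha / n_bins
    k = 1
    while stats.poisson.sf(k - 1, lam) >= thr:
        k += 1
    return HubCallParams(bin_size, alpha, n_bins, thr, lam, k)


def call_hubs(
    profile: pd.DataFrame,
    params: HubCallParams,
    peaks: pd.DataFrame,
) -> list[Hub]:
    """Runs of adjacent markers with overlap count >= k, with members."""
    hubs: list[Hub] = []
    n = 0
    for chrom, sub in profile.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        above = sub["count"].to_numpy() >= params.k
        i = 0
        while i < len(sub):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and above[j + 1]:
                j += 1
            run = sub.iloc[i: j + 1]
            cmax = run["count"].max()
            tied = run[run["count"] == cmax]
            if len(tied) == 1:
                pick = tied.iloc[0]
            else:
                center = tied["pos"].mean()
                pick = tied.iloc[int(np.argmin(np.abs(tied["pos"] - center)))]
            members = peaks[
                (peaks["chrom"] == chrom)
                & (peaks["start"] <= pick["pos"])
                & (peaks["end"] >= pick["pos"])
            ]["trait"].tolist()
            n += 1
            hubs.append(Hub(
                hub_id=f"hub{n}", chrom=chrom,
                start=int(run["pos"].iloc[0]), end=int(run["pos"].iloc[-1]),
                marker=pick["marker"], marker_pos=int(pick["pos"]),
                count=int(cmax), members=sorted(members),
            ))
            i = j + 1
    return hubs


def hub_allele_summary(
    hub: Hub,
    induced_by_segregant: pd.DataFrame,
    control_by_segregant: pd.DataFrame,
    deviations: pd.DataFrame,
    genotypes: pd.DataFrame,
    mean_effects: pd.Series,
    fitness_loci: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> Hub:
    """Allele-stratified member summaries and hub classification.

    ``induced_by_segregant`` / ``control_by_segregant`` are segregant x
    gRNA matrices of mean fitness (replicate barcodes averaged within each
    genotype before any further averaging). The classification regresses
    |3S-vs-BY mean-fitness difference| on |m_g| over members: a
    significantly positive slope is 'amplifying'; a significantly negative
    slope is 'masking' when the hub also coincides with a baseline-fitness
    locus. Members with only one allele class present are omitted with a
    flag. Sign epistasis: the allele contrast of baseline (control)
    fitness at the marker has one sign, and some member's induced
    contrast has the other.
    """
    if len(hub.members) < 3:
        raise ValueError("hub must have >=3 members for allele summaries")
    x = genotypes[hub.marker]
    segs3, segs0 = x.index[x == 1], x.index[x == 0]
    rows = []
    for gid in hub.members:
        if gid not in induced_by_segregant.columns:
            rows.append((gid, *[np.nan] * 7, True))
            continue
        w = induced_by_segregant[gid]
        w3, w0 = w.reindex(segs3).dropna(), w.reindex(segs0).dropna()
        if len(w3) == 0 or len(w0) == 0:
            rows.append((gid, *[np.nan] * 7, True))
            continue
        d = deviations[gid] if gid in deviations.columns else pd.Series(dtype=float)
        d3, d0 = d.reindex(segs3).dropna(), d.reindex(segs0).dropna()
        ddev = d3.mean() - d0.mean() if len(d3) and len(d0) else np.nan
        rows.append((
            gid, float(mean_effects.get(gid, np.nan)),
            float(w3.mean()), float(w3.sem()), float(w0.mean()), float(w0.sem()),
            float(w3.mean() - w0.mean()), float(ddev), False,
        ))
    summ = pd.DataFrame(rows, columns=[
        "guide_id", "mean_effect", "fitness_3s", "se_3s", "fitness_by", "se_by",
        "allele_diff", "delta_deviation", "omitted",
    ])
    hub.member_summary = summ

    ok = summ[~summ["omitted"] & summ["mean_effect"].notna()]
    if len(ok) >= 3 and ok["mean_effect"].abs().nunique() > 1:
        reg = stats.linregress(ok["mean_effect"].abs(), ok["allele_diff"].abs())
        hub.slope, hub.slope_p = float(reg.slope), float(reg.pvalue)
    if fitness_loci is not None and len(fitness_loci):
        on_chrom = fitness_loci[fitness_loci["chrom"] == hub.chrom]
        hub.is_fitness_locus = bool(
            ((on_chrom["start"] <= hub.marker_pos)
             & (on_chrom["end"] >= hub.marker_pos)).any()
        )
    if np.isfinite(hub.slope) and hub.slope_p < alpha:
        if hub.slope > 0:
            hub.classification = "amplifying"
        elif hub.is_fitness_locus:
            hub.classification = "masking"
        else:
            hub.classification = "attenuating"

    # sign epistasis: favoured allele flips between uninduced and induced.
    # Both contrasts must clear 2 standard errors to count.
    b = control_by_segregant.mean(axis=1)
    b3, b0 = b.reindex(segs3).dropna(), b.reindex(segs0).dropna()
    base_diff = b3.mean() - b0.mean()
    base_sig = abs(base_diff) > 2.0 * (b3.sem() + b0.sem())
    live = summ[~summ["omitted"]]
    strong = live["allele_diff"].abs() > 2.0 * (live["se_3s"] + live["se_by"])
    flipped = np.sign(live["allele_diff"]) == -np.sign(base_diff)
    hub.sign_epistasis = bool(base_sig and (strong & flipped).any())
    return hub
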