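"""Frequency-linear PCR-chimera model: fitting and correction.

Chimeric double barcodes arise when PCR pairs a segregant barcode with a
gRNA barcode from a different template. Their frequency is well described
as linear in the marginal frequencies of the two constituent barcodes:

    freq(chimera pair)  ~  intercept + a_seg * F_seg + a_guide * F_guide.

The model is fit by ordinary least squares on known-invalid barcode
combinations, separately in each of the four early time points, and the
coefficients are averaged. The averaged model then predicts the expected
chimeric frequency of every double barcode (valid or not); corrected
frequencies are floored at zero and rescaled back to counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import COUNT_COLS


@dataclass
class ChimeraModel:
    intercept: float
    a_seg: float
    a_guide: float
    per_timepoint: pd.DataFrame = field(default=None, repr=False)

    def predict(self, f_seg: np.ndarray, f_guide: np.ndarray) -> np.ndarray:
        return self.intercept + self.a_seg * f_seg + self.a_guide * f_guide


def _marginals(counts: pd.DataFrame, col: str):
    n = counts[col].to_numpy(float)
    depth = n.sum()
    f_seg = counts.groupby("segregant_bc")[col].sum() / depth
    f_gui = counts.groupby("guide_bc")[col].sum() / depth
    return n / depth, f_seg, f_gui, depth


def fit_chimera_model(
    counts: pd.DataFrame,
    n_time_points: int = 4,
    min_invalid: int = 10,
) -> ChimeraModel:
    """OLS fit of chimera frequency on marginal barcode frequencies.

    ``counts`` must contain both valid lineages and chimera-candidate rows
    (valid == False). The design includes every invalid (segregant barcode,
    gRNA barcode) combination over the barcodes present in the table, with
    zero counts for unobserved ones, so that sparse observation of rare
    chimeras does not bias the intercept.
    """
    tcols = [c for c in COUNT_COLS if c in counts.columns][:n_time_points]
    invalid = counts.loc[~counts["valid"]]
    if len(invalid) < min_invalid:
        raise ValueError(
            f"need >= {min_invalid} known-invalid combinations, got {len(invalid)}"
        )
    seg_bcs = np.sort(counts["segregant_bc"].unique())
    gui_bcs = np.sort(counts["guide_bc"].unique())
    valid_pairs = set(
        zip(counts.loc[counts["valid"], "segregant_bc"],
            counts.loc[counts["valid"], "guide_bc"])
    )
    grid = pd.MultiIndex.from_product([seg_bcs, gui_bcs],
                                      names=["segregant_bc", "guide_bc"])
    is_valid = np.fromiter(
        ((s, g) in valid_pairs for s, g in grid), bool, len(grid)
    )
    inv_grid = grid[~is_valid]
    obs = invalid.set_index(["segregant_bc", "guide_bc"])

    fits = []
    for col in tcols:
        _, f_seg, f_gui, depth = _marginals(counts, col)
        y = obs[col].reindex(inv_grid).fillna(0.0).to_numpy(float) / depth
        X = np.column_stack([
            np.ones(len(inv_grid)),
            f_seg.reindex(inv_grid.get_level_values(0)).fillna(0.0).to_numpy(),
            f_gui.reindex(inv_grid.get_level_values(1)).fillna(0.0).to_numpy(),
        ])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            raise np.linalg.LinAlgError("rank-deficient chimera design")
        fits.append(coef)
    per_tp = pd.DataFrame(fits, columns=["intercept", "a_seg", "a_guide"],
                          index=tcols)
    mean = per_tp.mean()
    return ChimeraModel(float(mean["intercept"]), float(mean["a_seg"]),
                        float(mean["a_guide"]), per_tp)


def correct_chimeras(counts: pd.DataFrame, model: ChimeraModel) -> pd.DataFrame:
    """Subtract each row's predicted chimera frequency at every time point.

    Corrected frequencies are floored at zero and rescaled to counts at the
    original per-time-point depth. Counts are returned as floats.
    """
    tcols = [c for c in COUNT_COLS if c in counts.columns]
    out = counts.copy()
    for col in tcols:
        f, f_seg, f_gui, depth = _marginals(counts, col)
        pred = model.predict(
            f_seg.reindex(counts["segregant_bc"]).to_numpy(),
            f_gui.reindex(counts["guide_bc"]).to_numpy(),
        )
        out[col] = np.maximum(f - pred, 0.0) * depth
    return out


def normalize_depth(counts: pd.DataFrame, scale: float = 450_000_000) -> pd.DataFrame:
    """Scale every time point to a common total count.

    Each count is divided by its time point's total and multiplied by
    ``scale`` so coverage differences between time points cancel.
    """
    tcols = [c for c in COUNT_COLS if c in counts.columns]
    out = counts.copy()
    for col in tcols:
        tot = counts[col].sum()
        if tot <= 0:
            raise ValueError(f"time point {col} has zero total count")
        out[col] = counts[col] / tot * scale
    return out
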