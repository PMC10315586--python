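"""Scoring of predicted against designed proportions, and composition summaries.

Per cell type: Pearson r (R^2 reported as its square), RMSE and MAE in
proportion units; aggregates are unweighted means across cell types. The
"unknown" remainder column is excluded — designed mixtures place all mass
on the seven cell types. Also provides the glia-to-neuron ratio (GNR),
the GABA/GLU ratio and the within-glia composition used in downstream
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .deconvolve import UNKNOWN, ProportionEstimate
from .hierarchy import ASTROCYTE, GABA, GLU, MICROGLIA, OLIGODENDROCYTE
from .simulate import MixtureTruth

GLIAL_LEAVES = (ASTROCYTE, MICROGLIA, OLIGODENDROCYTE)
NEURONAL_LEAVES = (GABA, GLU)


@dataclass
class EvaluationReport:
    """Per-cell-type and aggregate agreement between predicted and designed
    proportions. ``per_type`` rows: pearson_r, r_squared, rmse, mae."""

    per_type: pd.DataFrame
    average_r_squared: float
    average_rmse: float
    average_mae: float

    def to_dict(self) -> dict:
        return {
            "per_type": {
                ct: {k: _none_if_nan(v) for k, v in row.items()}
                for ct, row in self.per_type.to_dict(orient="index").items()
            },
            "average_r_squared": _none_if_nan(self.average_r_squared),
            "average_rmse": self.average_rmse,
            "average_mae": self.average_mae,
        }

    def summary(self) -> str:
        lines = ["Proportion recovery report", str(self.per_type.round(6))]
        lines.append(
            f"averages: R^2 = {self.average_r_squared:.6f}, "
            f"RMSE = {self.average_rmse:.6f} ({100 * self.average_rmse:.4f}%), "
            f"MAE = {self.average_mae:.6f}"
        )
        return "\n".join(lines)


def _none_if_nan(v):
    return None if (isinstance(v, float) and np.isnan(v)) else v


def _as_frame(props) -> pd.DataFrame:
    if isinstance(props, ProportionEstimate):
        return props.values
    if isinstance(props, MixtureTruth):
        return props.proportions
    return props


def evaluate_proportions(pred, truth) -> EvaluationReport:
    """Per-cell-type Pearson r / R^2, RMSE and MAE of predicted vs designed.

    Sample IDs must match; the unknown column is dropped from predictions.
    A cell type whose designed proportions are constant has undefined r
    (excluded from the R^2 average, with a warning); RMSE/MAE are still
    computed.
    """
    pred = _as_frame(pred)
    truth = _as_frame(truth)
    pred = pred.drop(columns=[UNKNOWN], errors="ignore")
    if set(pred.index) != set(truth.index):
        raise ValidationError("prediction and truth sample IDs differ")
    if set(pred.columns) != set(truth.columns):
        raise ValidationError("prediction and truth cell types differ")
    if len(truth) < 3:
        raise ValidationError("need >=3 samples to evaluate")
    pred = pred.loc[truth.index, truth.columns]
    rows = {}
    for ct in truth.columns:
        p = pred[ct].to_numpy(dtype=float)
        t = truth[ct].to_numpy(dtype=float)
        if np.ptp(t) == 0.0 or np.ptp(p) == 0.0:
            warnings.warn(
                f"correlation undefined for cell type {ct!r} (constant vector)",
                UserWarning,
                stacklevel=2,
            )
            r = np.nan
        else:
            r = float(stats.pearsonr(p, t).statistic)
        rows[ct] = {
            "pearson_r": r,
            "r_squared": r * r if not np.isnan(r) else np.nan,
            "rmse": float(np.sqrt(np.mean((p - t) ** 2))),
            "mae": float(np.mean(np.abs(p - t))),
        }
    per_type = pd.DataFrame.from_dict(rows, orient="index")
    return EvaluationReport(
        per_type=per_type,
        average_r_squared=float(per_type["r_squared"].mean(skipna=True)),
        average_rmse=float(per_type["rmse"].mean()),
        average_mae=float(per_type["mae"].mean()),
    )


def _require_layer2(props: pd.DataFrame, needed: tuple[str, ...], what: str) -> None:
    missing = [c for c in needed if c not in props.columns]
    if missing:
        raise ValidationError(
            f"{what} requires layer-2 proportions; missing columns {missing}"
        )


def glia_neuron_ratio(props) -> pd.Series:
    """Glia-to-neuron ratio per sample: (Astro + Micro + Oligo) / (GABA + GLU).

    A zero neuronal sum yields NaN with a warning."""
    frame = _as_frame(props)
    _require_layer2(frame, GLIAL_LEAVES + NEURONAL_LEAVES, "glia_neuron_ratio")
    glial = frame[list(GLIAL_LEAVES)].sum(axis=1)
    neuronal = frame[list(NEURONAL_LEAVES)].sum(axis=1)
    if (neuronal == 0).any():
        warnings.warn("zero neuronal proportion: GNR undefined for some samples",
                      UserWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = glial / neuronal.replace(0.0, np.nan)
    return out.rename("GNR")


def gaba_glu_ratio(props) -> pd.Series:
    """GABAergic over glutamatergic proportion per sample (NaN when GLU = 0)."""
    frame = _as_frame(props)
    _require_layer2(frame, (GABA, GLU), "gaba_glu_ratio")
    if (frame[GLU] == 0).any():
        warnings.warn("zero GLU proportion: ratio undefined for some samples",
                      UserWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = frame[GABA] / frame[GLU].replace(0.0, np.nan)
    return out.rename("GABA_GLU")


def glial_composition(props) -> pd.DataFrame:
    """Each glial leaf divided by the glial sum (rows sum to 1; NaN when the
    glial sum is zero)."""
    frame = _as_frame(props)
    _require_layer2(frame, GLIAL_LEAVES, "glial_composition")
    glial = frame[list(GLIAL_LEAVES)]
    total = glial.sum(axis=1)
    if (total == 0).any():
        warnings.warn("zero glial proportion: composition undefined for some samples",
                      UserWarning, stacklevel=2)
    return glial.div(total.replace(0.0, np.nan), axis=0)
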