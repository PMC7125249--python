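"""Evaluation statistics for predicted vs experimental observables.

Conventions: the residual is predicted minus experimental, so
underprediction gives negative signed errors; "MSE" throughout this package
is the mean *signed* error (the API says ``mean_signed_error`` to prevent
confusion with mean squared error); the descriptive regression is ordinary
least squares of the predicted values on the experimental ones, and R^2 is
the squared Pearson correlation (identical to the OLS R^2 in simple
regression).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import CoverageError, ValidationError


@dataclass(frozen=True)
class MetricsReport:
    """Error and regression statistics of one prediction set.

    ``slope``/``intercept``/``r_squared`` are NaN when only error metrics
    were requested or the regression is undefined.
    """

    rmse: float
    mae: float
    mean_signed_error: float
    slope: float
    intercept: float
    r_squared: float
    n: int

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "mean_signed_error": self.mean_signed_error,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
        }


class RegressionLine(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def _paired(predicted: Sequence[float], experimental: Sequence[float]):
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise ValidationError(
            f"predicted and experimental must be equal-length 1-d sequences, "
            f"got {pred.shape} vs {exp.shape}"
        )
    if pred.size == 0:
        raise ValidationError("need at least one pair of values")
    return pred, exp


def error_metrics(
    predicted: Sequence[float], experimental: Sequence[float]
) -> MetricsReport:
    """RMSE, MAE and mean signed error of paired predictions."""
    pred, exp = _paired(predicted, experimental)
    residuals = pred - exp
    return MetricsReport(
        rmse=float(np.sqrt(np.mean(residuals**2))),
        mae=float(np.mean(np.abs(residuals))),
        mean_signed_error=float(np.mean(residuals)),
        slope=float("nan"),
        intercept=float("nan"),
        r_squared=float("nan"),
        n=int(pred.size),
    )


def descriptive_regression(
    predicted: Sequence[float], experimental: Sequence[float]
) -> RegressionLine:
    """OLS line of predicted on experimental: slope m', intercept b', R^2."""
    pred, exp = _paired(predicted, experimental)
    if pred.size < 3:
        raise ValidationError("descriptive regression needs at least 3 pairs")
    if np.ptp(exp) == 0:
        raise ValidationError(
            "experimental values are constant; regression is degenerate"
        )
    fit = linregress(exp, pred)
    return RegressionLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def evaluate_predictions(
    predicted: Sequence[float], experimental: Sequence[float]
) -> MetricsReport:
    """Full report: error metrics plus descriptive regression."""
    base = error_metrics(predicted, experimental)
    line = descriptive_regression(predicted, experimental)
    return MetricsReport(
        rmse=base.rmse,
        mae=base.mae,
        mean_signed_error=base.mean_signed_error,
        slope=line.slope,
        intercept=line.intercept,
        r_squared=line.r_squared,
        n=base.n,
    )


def leave_one_out_impact(
    predicted: Sequence[float],
    experimental: Sequence[float],
    labels: Sequence[str],
) -> pd.DataFrame:
    """RMSE impact of removing each molecule in turn.

    Returns a frame with one row per molecule: its signed error, the RMSE of
    the remaining n-1 pairs, and the impact (full-set RMSE minus the
    leave-one-out RMSE), sorted by decreasing impact so the dominant outlier
    comes first.
    """
    pred, exp = _paired(predicted, experimental)
    if pred.size < 2:
        raise ValidationError("leave-one-out needs at least 2 pairs")
    if len(labels) != pred.size:
        raise ValidationError("labels must match the number of pairs")
    residuals = pred - exp
    sq = residuals**2
    total = sq.sum()
    rmse_full = float(np.sqrt(total / pred.size))
    rows = [
        {
            "label": label,
            "signed_error": float(residuals[i]),
            "rmse_without": float(np.sqrt((total - sq[i]) / (pred.size - 1))),
        }
        for i, label in enumerate(labels)
    ]
    frame = pd.DataFrame(rows)
    frame["impact"] = rmse_full - frame["rmse_without"]
    return frame.sort_values(
        ["impact", "label"], ascending=[False, True], ignore_index=True
    )


def group_error_decomposition(
    errors_per_solvent: Mapping[str, Mapping[str, float]],
    class_labels: Mapping[str, str],
    reference: str = "water",
    sort_solvent: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decompose per-molecule errors by compound class and solvent.

    Parameters
    ----------
    errors_per_solvent : mapping
        ``{solvent: {molecule: signed error}}``; all solvents must share the
        same molecule keys.
    class_labels : mapping
        ``{molecule: class}`` covering exactly the shared molecules.
    reference : str
        Solvent whose error is the minuend of the per-molecule difference
        (reference minus other solvent).
    sort_solvent : str, optional
        Solvent whose error orders molecules ascending within each class;
        defaults to the first non-reference solvent.

    Returns
    -------
    (summary, detail)
        ``summary``: per (class, solvent) mean and median error plus the
        mean difference vs the reference.  ``detail``: per molecule, its
        class, error in every solvent and the differences, sorted ascending
        by ``sort_solvent`` error within class.
    """
    solvents = list(errors_per_solvent)
    if not solvents:
        raise ValidationError("need at least one solvent")
    keysets = {s: set(m) for s, m in errors_per_solvent.items()}
    shared = keysets[solvents[0]]
    for s, keys in keysets.items():
        if keys != shared:
            raise CoverageError(f"solvent {s} does not share the molecule set")
    unknown = shared.symmetric_difference(class_labels)
    if unknown:
        raise KeyError(
            "class_labels and error tables disagree on molecule(s): "
            + ", ".join(sorted(unknown))
        )
    if sort_solvent is None:
        others = [s for s in solvents if s != reference]
        sort_solvent = others[0] if others else solvents[0]
    detail = pd.DataFrame(
        {
            "molecule_id": sorted(shared),
        }
    )
    detail["class"] = [class_labels[m] for m in detail["molecule_id"]]
    for s in solvents:
        detail[f"error_{s}"] = [errors_per_solvent[s][m] for m in detail["molecule_id"]]
    for s in solvents:
        if s != reference and reference in solvents:
            detail[f"diff_{reference}_minus_{s}"] = (
                detail[f"error_{reference}"] - detail[f"error_{s}"]
            )
    detail = detail.sort_values(
        ["class", f"error_{sort_solvent}", "molecule_id"], ignore_index=True
    )
    summary_rows = []
    for cls, grp in detail.groupby("class", sort=True):
        for s in solvents:
            row = {
                "class": cls,
                "solvent": s,
                "mean_error": float(grp[f"error_{s}"].mean()),
                "median_error": float(grp[f"error_{s}"].median()),
                "n": int(len(grp)),
            }
            if s != reference and reference in solvents:
                row["mean_diff_vs_reference"] = float(
                    grp[f"diff_{reference}_minus_{s}"].mean()
                )
            summary_rows.append(row)
    return pd.DataFrame(summary_rows), detail


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero at a fixed decimal count.

    Used when comparing recomputed statistics to values printed in
    reference tables, where conventional half-up rounding applies.
    """
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(value)).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    )
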