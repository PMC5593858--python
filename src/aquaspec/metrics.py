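"""Model evaluation metrics and cross-model comparison arithmetic.

All metrics operate on water content as a fraction.  The coefficient of
determination is computed in its ratio form

    R^2 = sum((yhat_i - ybar)^2) / sum((y_i - ybar)^2),

i.e. predicted spread about the *observed* mean over observed spread.  On
in-sample OLS predictions with an intercept this equals the familiar
1 - SSE/SST; on held-out predictions the two differ and the ratio form can
exceed 1 for biased predictions — it is reported as-is.  The complement form
is available via ``form="complement"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationReport",
    "rmse",
    "relative_error",
    "r_squared",
    "relative_difference",
    "evaluate",
    "comparison_table",
]


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: observed {y.shape} vs predicted {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error sqrt(mean((y - yhat)^2))."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def relative_error(y, yhat) -> float:
    """Mean absolute relative error (1/n) * sum(|y - yhat| / |y|)."""
    y, yhat = _check_pair(y, yhat)
    if np.any(y == 0):
        raise ValueError("relative error undefined: observed value equal to zero")
    return float(np.mean(np.abs((y - yhat) / y)))


def r_squared(y, yhat, form: str = "ratio") -> float:
    y, yhat = _check_pair(y, yhat)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant observations")
    if form == "ratio":
        return float(np.sum((yhat - y.mean()) ** 2) / sst)
    if form == "complement":
        return float(1.0 - np.sum((y - yhat) ** 2) / sst)
    raise ValueError(f"unknown R^2 form {form!r}")


def relative_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to reference ``b``: 100 * (a - b) / b.

    Positive means ``a`` exceeds the reference.  Returned unrounded; reports
    render to 2 d.p.
    """
    if b == 0:
        raise ValueError("relative difference undefined for zero reference")
    return 100.0 * (a - b) / b


@dataclass
class EvaluationReport:
    """Goodness-of-fit summary for one subset (fraction units throughout)."""

    subset: str
    n: int
    r2: float
    rmse: float
    re: float

    def to_dict(self) -> dict[str, float | int | str]:
        return {
            "subset": self.subset,
            "n": self.n,
            "r2": round(self.r2, 4),
            "rmse": round(self.rmse, 4),
            "re": round(self.re, 4),
        }


def evaluate(y, yhat, subset: str = "", r2_form: str = "ratio") -> EvaluationReport:
    y, yhat = _check_pair(y, yhat)
    return EvaluationReport(
        subset=subset,
        n=int(y.size),
        r2=r_squared(y, yhat, form=r2_form),
        rmse=rmse(y, yhat),
        re=relative_error(y, yhat),
    )


def comparison_table(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Side-by-side metric table (rows = models) plus pairwise percent differences.

    With exactly two models the second row is treated as the reference and a
    ``*_diff_pct`` block states how much the first exceeds it, matching the
    usual "method A improved R^2 by x%" phrasing.
    """
    rows = {name: {"r2": r.r2, "rmse": r.rmse, "re": r.re, "n": r.n} for name, r in reports.items()}
    df = pd.DataFrame(rows).T
    if len(reports) == 2:
        (name_a, rep_a), (name_b, rep_b) = reports.items()
        for metric in ("r2", "rmse", "re"):
            df.loc[name_a, f"{metric}_vs_{name_b}_pct"] = round(
                relative_difference(getattr(rep_a, metric), getattr(rep_b, metric)), 2
            )
    return df
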