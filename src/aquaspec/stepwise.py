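"""Stepwise multiple linear regression with partial-F entry/removal tests.

Variable selection alternates two moves until neither fires:

* **entry** — among candidates outside the model, compute the partial F for
  adding each one,

      F_enter = V_i / (SS_res(model + x_i) / (n - l - 2)),

  where ``V_i`` is the drop in residual sum of squares achieved by adding
  ``x_i`` to the ``l`` variables already in the model; the augmented model has
  residual degrees of freedom ``n - l - 2``.  The candidate with the largest F
  enters if its P-value (F distribution with (1, n - l - 2) df) is below
  ``alpha_in``.

* **removal** — among the ``l`` variables in the model, compute

      F_remove = V_i / (SS_res(model) / (n - l - 1)),

  with ``V_i`` the rise in residual sum of squares caused by deleting ``x_i``;
  the variable with the smallest F leaves while its P-value (df (1, n - l - 1))
  exceeds ``alpha_out``.

Both statistics equal the classic nested-model F computed from two explicit
least-squares fits; the implementation literally performs those paired fits,
trading a little arithmetic for transparency.  Model diagnosis reports the
overall F-test of the final equation (required P <= 0.05 for the model to be
flagged usable), per-variable significance, and the Durbin-Watson statistic
for first-order residual autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cross_variables import CrossVariableMatrix

__all__ = [
    "RegressionState",
    "StepwiseModel",
    "SingularDesignError",
    "InsufficientDataError",
    "ols_fit",
    "partial_f_enter",
    "partial_f_remove",
    "stepwise_select",
    "durbin_watson",
]

#: Cap applied when a perfect fit drives the partial F to infinity.
F_CAP = 1e12

#: Residual sums of squares below this fraction of the total sum of squares are
#: treated as an exact fit; further entry tests would only compare rounding noise.
EXACT_FIT_RTOL = 1e-12


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


class InsufficientDataError(ValueError):
    """Raised when a test has no residual degrees of freedom left."""


@dataclass
class RegressionState:
    """One least-squares fit: coefficients plus its sum-of-squares decomposition."""

    names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    n: int
    ss_total: float
    ss_resid: float
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def ss_regression(self) -> float:
        return self.ss_total - self.ss_resid

    @property
    def n_variables(self) -> int:
        return len(self.names)

    @property
    def df_resid(self) -> int:
        return self.n - self.n_variables - 1


def ols_fit(X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None) -> RegressionState:
    """Least squares of ``y`` on ``X`` plus an intercept, via SVD (stable).

    ``X`` may have zero columns (intercept-only fit).  A rank-deficient design
    raises :class:`SingularDesignError` naming the collinear columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(y.size, 0)
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y row counts differ")
    if names is None:
        names = tuple(f"x{j + 1}" for j in range(p))
    names = tuple(names)
    if n <= p + 1:
        raise InsufficientDataError(f"need n > p + 1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        collinear = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise SingularDesignError(f"design is rank deficient; collinear columns: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    return RegressionState(
        names=names,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        n=n,
        ss_total=float(np.sum((y - y.mean()) ** 2)),
        ss_resid=float(np.sum(resid**2)),
        fitted=fitted,
        residuals=resid,
    )


def _f_pvalue(f: float, df2: int) -> float:
    return float(stats.f.sf(f, 1, df2))


def partial_f_enter(
    X_current: np.ndarray,
    y: np.ndarray,
    candidate: np.ndarray,
) -> tuple[float, float]:
    """Partial F and P-value for adding ``candidate`` to the current variables.

    Computed from two explicit fits: the current model and the model augmented
    with the candidate.  A candidate that drives the residual sum of squares
    to (numerical) zero gets a capped F and P = 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    X_current = np.asarray(X_current, dtype=float)
    if X_current.ndim == 1:
        X_current = X_current[:, None]
    if X_current.size == 0:
        X_current = X_current.reshape(y.size, 0)
    n, l = X_current.shape
    df2 = n - l - 2
    if df2 <= 0:
        raise InsufficientDataError(
            f"entry test needs n - l - 2 > 0 (n={n}, l={l} variables in model)"
        )
    reduced = ols_fit(X_current, y)
    X_aug = np.column_stack([X_current, np.asarray(candidate, dtype=float).ravel()])
    try:
        full = ols_fit(X_aug, y)
    except SingularDesignError:
        return 0.0, 1.0  # candidate adds no information beyond the current span
    v = max(reduced.ss_resid - full.ss_resid, 0.0)
    denom = full.ss_resid / df2
    if denom <= EXACT_FIT_RTOL * max(full.ss_total, 1.0) / df2:
        return (F_CAP, 0.0) if v > 0 else (0.0, 1.0)
    f = min(v / denom, F_CAP)
    return f, _f_pvalue(f, df2)


def partial_f_remove(
    X_full: np.ndarray,
    y: np.ndarray,
    member: int,
) -> tuple[float, float]:
    """Partial F and P-value for deleting column ``member`` from the model.

    ``X_full`` holds the ``l`` variables currently in the model; the statistic
    uses the full-model residual mean square with ``n - l - 1`` degrees of
    freedom.  A member whose deletion leaves the residual sum of squares
    unchanged (e.g. a duplicated column) gets F = 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    X_full = np.asarray(X_full, dtype=float)
    if X_full.ndim == 1:
        X_full = X_full[:, None]
    n, l = X_full.shape
    if not 0 <= member < l:
        raise IndexError(f"member index {member} outside model of size {l}")
    df2 = n - l - 1
    if df2 <= 0:
        raise InsufficientDataError(
            f"removal test needs n - l - 1 > 0 (n={n}, l={l} variables in model)"
        )
    try:
        full_ss_resid = ols_fit(X_full, y).ss_resid
        full_ss_total = float(np.sum((y - y.mean()) ** 2))
    except SingularDesignError:
        # duplicated information: the minimum-norm fit still defines the
        # residual SS, and a redundant member costs nothing to delete
        design = np.column_stack([np.ones(y.size), X_full])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        full_ss_resid = float(np.sum((y - design @ beta) ** 2))
        full_ss_total = float(np.sum((y - y.mean()) ** 2))
    reduced = ols_fit(np.delete(X_full, member, axis=1), y)
    v = max(reduced.ss_resid - full_ss_resid, 0.0)
    denom = full_ss_resid / df2
    if denom <= EXACT_FIT_RTOL * max(full_ss_total, 1.0) / df2:
        return (F_CAP, 0.0) if v > 0 else (0.0, 1.0)
    f = min(v / denom, F_CAP)
    return f, _f_pvalue(f, df2)


def durbin_watson(residuals: np.ndarray) -> float:
    """First-order autocorrelation statistic sum(diff(e)^2) / sum(e^2), in [0, 4].

    Near 2 for independent residuals, toward 0 under positive and toward 4
    under negative autocorrelation.  All-zero residuals give NaN (not
    applicable).
    """
    e = np.asarray(residuals, dtype=float).ravel()
    if e.size < 3:
        raise ValueError("Durbin-Watson needs at least 3 residuals")
    denom = float(np.sum(e**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(np.diff(e) ** 2) / denom)


@dataclass
class StepwiseModel:
    """Final selected equation with per-variable tests, step log and diagnostics."""

    variable_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    partial_f: dict[str, float]
    partial_p: dict[str, float]
    step_log: list[dict] = field(default_factory=list)
    n: int = 0
    r2: float = float("nan")
    overall_f: float = float("nan")
    overall_p: float = float("nan")
    durbin_watson: float = float("nan")
    dw_band: tuple[float, float] = (1.5, 2.5)

    @property
    def usable(self) -> bool:
        """Model-diagnosis rule: the overall F-test must reach P <= 0.05."""
        return bool(np.isfinite(self.overall_p) and self.overall_p <= 0.05)

    @property
    def dw_ok(self) -> bool:
        lo, hi = self.dw_band
        return bool(np.isfinite(self.durbin_watson) and lo <= self.durbin_watson <= hi)

    def predict(self, Z: CrossVariableMatrix | np.ndarray) -> np.ndarray:
        if isinstance(Z, CrossVariableMatrix):
            X = np.column_stack([Z.column(name) for name in self.variable_names]) if self.variable_names else np.zeros((Z.n_samples, 0))
        else:
            X = np.atleast_2d(np.asarray(Z, dtype=float))
            if X.shape[1] != len(self.variable_names):
                raise ValueError("prediction matrix width does not match selected variables")
        return self.intercept + (X @ self.coefficients if X.shape[1] else np.zeros(X.shape[0]))

    def equation(self, decimals: int = 4) -> str:
        terms = [f"{self.intercept:.{decimals}f}"]
        for name, b in zip(self.variable_names, self.coefficients):
            sign = "-" if b < 0 else "+"
            terms.append(f"{sign} {abs(b):.{decimals}f} * {name}")
        return "Y = " + " ".join(terms)

    def report(self) -> str:
        lines = [self.equation(), f"n = {self.n}, R^2 = {self.r2:.4f}"]
        lines.append(
            f"overall F = {self.overall_f:.4f} (P = {self.overall_p:.4g}) -> "
            + ("usable" if self.usable else "NOT usable (P > 0.05)")
        )
        for name in self.variable_names:
            lines.append(
                f"  {name}: partial F = {self.partial_f[name]:.4f}, P = {self.partial_p[name]:.4g}"
            )
        lines.append(
            f"Durbin-Watson = {self.durbin_watson:.4f} "
            + ("(within" if self.dw_ok else "(outside")
            + f" {self.dw_band[0]}-{self.dw_band[1]} band)"
        )
        return "\n".join(lines)


def _as_matrix(Z) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(Z, CrossVariableMatrix):
        return Z.values, Z.names
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return Z, tuple(f"Z{j + 1}" for j in range(Z.shape[1]))


def stepwise_select(
    Z,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
    f_in: float | None = None,
    f_out: float | None = None,
    max_steps: int = 50,
) -> StepwiseModel:
    """Run the full entry/removal iteration over candidate variables.

    ``Z`` is a :class:`~aquaspec.cross_variables.CrossVariableMatrix` or a
    plain ``(n, p)`` array.  Significance control is by P-value thresholds
    (``alpha_in``/``alpha_out``); passing ``f_in``/``f_out`` switches to fixed
    critical F values instead.  Ties on F break toward the lowest column
    index; the selected set is invariant to candidate order.  A repeating
    enter/remove cycle terminates with a warning; exceeding ``max_steps``
    raises with the step log attached.
    """
    X_all, default_names = _as_matrix(Z)
    names = tuple(names) if names is not None else default_names
    y = np.asarray(y, dtype=float).ravel()
    n, p = X_all.shape
    if p < 1:
        raise ValueError("at least one candidate variable required")
    if names is not None and len(names) != p:
        raise ValueError("one name required per candidate column")
    if f_in is None and not alpha_in <= alpha_out:
        raise ValueError("alpha_in must not exceed alpha_out (risk of cycling)")

    in_model: list[int] = []
    log: list[dict] = []
    history: list[tuple[str, int]] = []
    ss_total = float(np.sum((y - y.mean()) ** 2))

    def fires_entry(f: float, pval: float) -> bool:
        return f > f_in if f_in is not None else pval < alpha_in

    def fires_removal(f: float, pval: float) -> bool:
        return f <= f_out if f_out is not None else pval > alpha_out

    steps = 0
    while True:
        changed = False
        # entry move: skip when the fit is already numerically exact
        current_ssr = ols_fit(X_all[:, in_model], y).ss_resid if in_model else ss_total
        can_enter = (
            n - len(in_model) - 2 > 0 and current_ssr > EXACT_FIT_RTOL * max(ss_total, 1.0)
        )
        if can_enter:
            best: tuple[float, float, int] | None = None
            for j in range(p):
                if j in in_model:
                    continue
                f, pval = partial_f_enter(X_all[:, in_model], y, X_all[:, j])
                if best is None or f > best[0]:
                    best = (f, pval, j)
            if best is not None and fires_entry(best[0], best[1]):
                f, pval, j = best
                in_model.append(j)
                log.append({"step": steps, "action": "enter", "variable": names[j], "F": f, "P": pval})
                history.append(("enter", j))
                changed = True
                steps += 1
        # removal moves
        while in_model:
            worst: tuple[float, float, int] | None = None
            for pos, j in enumerate(in_model):
                f, pval = partial_f_remove(X_all[:, in_model], y, pos)
                if worst is None or f < worst[0]:
                    worst = (f, pval, j)
            assert worst is not None
            if not fires_removal(worst[0], worst[1]):
                break
            f, pval, j = worst
            in_model.remove(j)
            log.append({"step": steps, "action": "remove", "variable": names[j], "F": f, "P": pval})
            history.append(("remove", j))
            changed = True
            steps += 1
            if len(history) >= 4 and history[-4:] == [
                ("enter", j), ("remove", j), ("enter", j), ("remove", j),
            ]:
                warnings.warn(f"stepwise cycling on {names[j]}; terminating selection")
                changed = False
                break
        if not changed:
            break
        if steps >= max_steps:
            raise RuntimeError(f"stepwise exceeded {max_steps} steps; log: {log}")

    in_model.sort()
    selected = tuple(names[j] for j in in_model)
    if in_model:
        final = ols_fit(X_all[:, in_model], y, names=selected)
        intercept, coefs = final.intercept, final.coefficients
        resid = final.residuals
        r2 = final.ss_regression / ss_total if ss_total > 0 else float("nan")
        l = len(in_model)
        ms_reg = final.ss_regression / l
        ms_res = final.ss_resid / final.df_resid if final.df_resid > 0 else np.nan
        overall_f = ms_reg / ms_res if ms_res and ms_res > 0 else float("inf")
        overall_p = float(stats.f.sf(overall_f, l, final.df_resid))
        pf, pp = {}, {}
        for pos, name in enumerate(selected):
            f, pval = partial_f_remove(X_all[:, in_model], y, pos)
            pf[name], pp[name] = f, pval
        dw = durbin_watson(resid)
    else:
        intercept, coefs = float(y.mean()), np.array([])
        r2, overall_f, overall_p, dw = 0.0, float("nan"), float("nan"), float("nan")
        pf, pp = {}, {}
    return StepwiseModel(
        variable_names=selected,
        intercept=intercept,
        coefficients=np.asarray(coefs, dtype=float),
        partial_f=pf,
        partial_p=pp,
        step_log=log,
        n=n,
        r2=float(r2),
        overall_f=float(overall_f),
        overall_p=float(overall_p),
        durbin_watson=float(dw),
    )
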