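"""Weighted functional ANOVA on smoothed daily activity profiles.

The smoothed profiles ``y_i(t) = phi(t)' c_i`` are decomposed as

    y_{i,g}(t) = alpha_0(t) + alpha_g(t) + eps_{i,g}(t)

where ``alpha_0`` is the profile of the reference category and each
``alpha_g`` is a time-specific contrast of a non-reference level, extended
additively to several categorical covariates (no interactions).  Because
responses and coefficient functions share one basis and the model is
linear, the fit is a single weighted least-squares regression of the
child-level basis coefficients on the design matrix; it is exactly
equivalent to a pointwise weighted regression at every grid minute.

Inverse-probability weights enter here (between-child selection
correction), not in the per-child smoothing (within-child).

Inference: a permutation functional F test on the maximum over the grid
of the pointwise (weighted) F statistic, and pointwise percentile
bootstrap confidence bands over children.  A coefficient function can be
summarised over a clock-time window by its length-normalised integral,
computed exactly from the piecewise-polynomial representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .smoothing import BasisSystem, SmoothedDataset
from .timegrid import MINUTE_GRID, format_clock


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Factor:
    """One categorical covariate with a declared reference level."""

    name: str
    reference: str
    levels: tuple[str, ...] | None = None  # declared order; None = observed, sorted


@dataclass(frozen=True)
class DesignSpec:
    factors: tuple[Factor, ...]

    @classmethod
    def from_refs(cls, refs: dict[str, str]) -> "DesignSpec":
        return cls(tuple(Factor(name, ref) for name, ref in refs.items()))


def build_design(covariates: pd.DataFrame, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Reference-coded design: intercept plus one indicator per non-reference level.

    Columns are labelled ``covariate=level``.  An observed level missing
    from the declaration, or a declared non-reference level never
    observed, is an error.
    """
    n = len(covariates)
    columns = [np.ones(n)]
    labels = ["intercept"]
    for factor in spec.factors:
        if factor.name not in covariates.columns:
            raise DesignError(f"covariate {factor.name!r} not in table")
        observed = covariates[factor.name].astype(str)
        levels = factor.levels
        if levels is None:
            levels = tuple(sorted(observed.unique()))
        if factor.reference not in levels:
            raise DesignError(f"reference level {factor.reference!r} not among levels of {factor.name!r}")
        unknown = set(observed.unique()) - set(levels)
        if unknown:
            bad = observed.isin(unknown)
            child = covariates.loc[bad, "child_id"].iloc[0] if "child_id" in covariates else covariates.index[bad][0]
            raise DesignError(
                f"unknown level {sorted(unknown)[0]!r} of covariate {factor.name!r} (child {child})"
            )
        for level in levels:
            if level == factor.reference:
                continue
            if not (observed == level).any():
                raise DesignError(f"declared level {level!r} of {factor.name!r} never observed")
            columns.append((observed == level).to_numpy(dtype=float))
            labels.append(f"{factor.name}={level}")
    return np.column_stack(columns), labels


@dataclass
class FanovaFit:
    """Coefficient functions with per-child residual functions.

    ``coefficients[j]`` holds the basis coefficients of the j-th design
    column's coefficient function (row 0 = intercept ``alpha_0``).  The
    decomposition identity ``C = X @ coefficients + residuals`` holds to
    machine precision for every child.
    """

    basis: BasisSystem
    labels: list[str]
    design: np.ndarray  # (n, p)
    coefficients: np.ndarray  # (p, k)
    residuals: np.ndarray  # (n, k)
    weights: np.ndarray  # (n,)
    child_ids: list[str]

    def curve(self, label: str, times=None) -> np.ndarray:
        t = MINUTE_GRID if times is None else times
        j = self.labels.index(label)
        return self.basis.evaluate(t) @ self.coefficients[j]

    def contrast_labels(self) -> list[str]:
        return [lab for lab in self.labels if lab != "intercept"]


def fit_fanova(
    smoothed: SmoothedDataset,
    design: np.ndarray,
    labels: list[str],
    weights: np.ndarray | None = None,
) -> FanovaFit:
    """Weighted least squares of child basis coefficients on the design."""
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    C = smoothed.coefficients
    if C.shape[0] != n:
        raise ValueError("design rows do not match number of smoothed profiles")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    Xw = X * w[:, None]
    gram = X.T @ Xw
    if np.linalg.matrix_rank(gram) < p:
        # name the columns involved in the deficiency
        _, r = np.linalg.qr(X * np.sqrt(w)[:, None])
        dep = [labels[j] for j in range(p) if abs(r[j, j]) < 1e-8 * max(abs(r[0, 0]), 1.0)]
        raise DesignError(f"rank-deficient design; collinear columns: {dep or labels}")
    B = np.linalg.solve(gram, Xw.T @ C)
    return FanovaFit(
        basis=smoothed.basis,
        labels=list(labels),
        design=X,
        coefficients=B,
        residuals=C - X @ B,
        weights=w,
        child_ids=list(smoothed.child_ids),
    )


def functional_mean(smoothed: SmoothedDataset, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted mean of the child coefficient vectors (the cohort's smoothed
    mean activity function, in basis coefficients)."""
    if smoothed.n == 0:
        raise ValueError("empty dataset")
    w = np.ones(smoothed.n) if weights is None else np.asarray(weights, dtype=float)
    return (w[:, None] * smoothed.coefficients).sum(axis=0) / w.sum()


def pointwise_F(fit: FanovaFit, times=None) -> np.ndarray:
    """Pointwise F statistic: weighted variance of fitted values over
    weighted mean squared residual, at each grid time.

    Times with zero residual variance are reported as ``+inf``.
    """
    if fit.design.shape[1] < 2:
        raise ValueError("pointwise F needs at least one non-intercept design column")
    t = MINUTE_GRID if times is None else times
    Phi = fit.basis.evaluate(t)
    fitted = (fit.design @ fit.coefficients) @ Phi.T  # (n, m)
    resid = fit.residuals @ Phi.T
    w = fit.weights
    wsum = w.sum()
    mean = (w @ fitted) / wsum
    num = (w @ (fitted - mean) ** 2) / wsum
    den = (w @ resid**2) / wsum
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return F


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    statistic: str = "max"


def _f_statistic(F: np.ndarray, statistic: str) -> float:
    if statistic == "max":
        return float(np.max(F))
    if statistic == "integral":
        return float(np.mean(F))
    raise ValueError("statistic must be 'max' or 'integral'")


def permutation_F_test(
    smoothed: SmoothedDataset,
    covariates: pd.DataFrame,
    spec: DesignSpec,
    nperm: int,
    seed: int,
    weights: np.ndarray | None = None,
    statistic: str = "max",
) -> PermutationResult:
    """Permutation functional F test of profile-covariate association.

    The null is generated by permuting whole covariate rows (weights
    travelling with their rows) against the fixed profiles, which
    preserves the joint covariate distribution.  The p-value is
    ``(1 + #{perm >= observed}) / (1 + nperm)``.
    """
    if nperm < 1:
        raise ValueError("nperm must be at least 1")
    X, labels = build_design(covariates, spec)
    n = X.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    def max_f(Xp: np.ndarray, wp: np.ndarray) -> float:
        fit = fit_fanova(smoothed, Xp, labels, wp)
        return _f_statistic(pointwise_F(fit), statistic)

    observed = max_f(X, w)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    permuted = np.empty(nperm)
    for b in range(nperm):
        idx = rng.permutation(n)
        permuted[b] = max_f(X[idx], w[idx])
    p = (1.0 + np.count_nonzero(permuted >= observed)) / (1.0 + nperm)
    return PermutationResult(observed, permuted, p, nperm, seed, statistic)


@dataclass
class ConfidenceBand:
    """Pointwise percentile band for one coefficient function."""

    label: str
    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_bootstrap: int
    seed: int


@dataclass
class BootstrapResult:
    """Bootstrap-over-children replicates of all coefficient functions."""

    fit: FanovaFit
    replicates: np.ndarray  # (B, p, k)
    level: float
    seed: int
    n_redraws: int

    def band(self, label: str, times=None) -> ConfidenceBand:
        t = MINUTE_GRID if times is None else np.asarray(times, dtype=float)
        Phi = self.fit.basis.evaluate(t)
        j = self.fit.labels.index(label)
        curves = self.replicates[:, j, :] @ Phi.T  # (B, m)
        alpha = (1.0 - self.level) / 2.0
        lo = np.quantile(curves, alpha, axis=0)
        hi = np.quantile(curves, 1.0 - alpha, axis=0)
        est = Phi @ self.fit.coefficients[j]
        # percentile bands are widened, if needed, to bracket the estimate
        return ConfidenceBand(label, t, est, np.minimum(lo, est), np.maximum(hi, est),
                              self.level, self.replicates.shape[0], self.seed)

    def window_ci(self, label: str, window: tuple[float, float]) -> tuple[float, float, float]:
        """(estimate, lower, upper) for the window-averaged coefficient."""
        j = self.fit.labels.index(label)
        est = window_average(self.fit.basis, self.fit.coefficients[j], window)
        reps = np.array(
            [window_average(self.fit.basis, rep[j], window) for rep in self.replicates]
        )
        alpha = (1.0 - self.level) / 2.0
        lo = min(float(np.quantile(reps, alpha)), est)
        hi = max(float(np.quantile(reps, 1.0 - alpha)), est)
        return est, lo, hi


def bootstrap_ci(
    smoothed: SmoothedDataset,
    covariates: pd.DataFrame,
    spec: DesignSpec,
    n_bootstrap: int,
    seed: int,
    weights: np.ndarray | None = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap children with replacement (carrying their weights) and
    refit the FANOVA per replicate; percentile bands are pointwise.

    Replicates with a rank-deficient design are redrawn (counted); more
    than 50% redraws aborts.
    """
    if n_bootstrap < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    X, labels = build_design(covariates, spec)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    fit = fit_fanova(smoothed, X, labels, w)
    C = smoothed.coefficients

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    reps = np.empty((n_bootstrap, p, C.shape[1]))
    redraws = 0
    b = 0
    while b < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        Xb, wb = X[idx], w[idx]
        gram = Xb.T @ (Xb * wb[:, None])
        if np.linalg.matrix_rank(gram) < p:
            redraws += 1
            if redraws > 0.5 * n_bootstrap:
                raise RuntimeError("more than 50% of bootstrap replicates were rank-deficient")
            continue
        reps[b] = np.linalg.solve(gram, (Xb * wb[:, None]).T @ C[idx])
        b += 1
    return BootstrapResult(fit=fit, replicates=reps, level=level, seed=seed, n_redraws=redraws)


def window_average(basis: BasisSystem, coefficients: np.ndarray, window: tuple[float, float]) -> float:
    """Length-normalised exact integral of a coefficient function.

    Units are counts per minute, so a contrast constant over the window
    summarises to that constant.
    """
    a, b = float(window[0]), float(window[1])
    lo, hi = basis.domain
    if b <= a:
        raise ValueError("empty or reversed window")
    if a < lo or b > hi:
        raise ValueError(f"window [{a}, {b}] outside domain [{lo}, {hi}]")
    spline = basis.spline(np.asarray(coefficients, dtype=float))
    return float(spline.integrate(a, b)) / (b - a)


def report_tables(
    fit: FanovaFit,
    bootstrap: BootstrapResult | None,
    windows: dict[str, tuple[float, float]],
    spec: DesignSpec,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coefficient table (per-contrast window averages with CIs, reference
    rows marked "Ref") and the contrast-curve grid table."""
    full_day = (float(fit.basis.domain[0]), float(fit.basis.domain[1]))
    all_windows = {"full-day": full_day, **windows}

    rows = []
    for factor in spec.factors:
        observed = covariates[factor.name].astype(str)
        levels = factor.levels or tuple(sorted(observed.unique()))
        # reference category first, as in the usual reporting convention
        levels = (factor.reference,) + tuple(lv for lv in levels if lv != factor.reference)
        for level in levels:
            n_level = int((observed == level).sum())
            if level == factor.reference:
                row = {"covariate": factor.name, "level": level, "n": n_level}
                for name in all_windows:
                    row[f"{name}"] = "Ref"
                rows.append(row)
                continue
            label = f"{factor.name}={level}"
            row = {"covariate": factor.name, "level": level, "n": n_level}
            for name, win in all_windows.items():
                if bootstrap is not None:
                    est, lo, hi = bootstrap.window_ci(label, win)
                    row[name] = f"{est:.6g} ({lo:.6g}; {hi:.6g})"
                else:
                    est = window_average(fit.basis, fit.coefficients[fit.labels.index(label)], win)
                    row[name] = f"{est:.6g}"
            rows.append(row)
    table = pd.DataFrame(rows)

    curve_cols = {"minute": MINUTE_GRID, "clock": [format_clock(t) for t in MINUTE_GRID]}
    for label in fit.contrast_labels():
        if bootstrap is not None:
            band = bootstrap.band(label)
            curve_cols[f"{label}"] = band.estimate
            curve_cols[f"{label}.lo"] = band.lower
            curve_cols[f"{label}.hi"] = band.upper
        else:
            curve_cols[f"{label}"] = fit.curve(label)
    curves = pd.DataFrame(curve_cols)
    return table, curves
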