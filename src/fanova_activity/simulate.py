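"""Synthetic accelerometer data with known ground truth.

Emulates per-epoch activity counts for a cohort of school-age children:
15-second nonnegative integer counts over waking hours, a diurnal mean with
commute / break / lunch / after-school peaks, variance linear in the mean
(overdispersion), categorical covariate effects localised in clock time,
inverse-probability weights from a logistic nonresponse model, and a
variable number of (possibly degraded) days per child.

Noise model
-----------
Counts are negative binomial, parameterised so that ``Var = phi * mean``
exactly (size ``mu/(phi-1)``, success probability ``1/phi``).  Because the
success probability does not depend on the mean, the sum of the four 15-s
epochs of a minute is again negative binomial with the minute mean and the
same ``phi``: drawing at minute resolution is distributionally identical to
drawing 15-s epochs and aggregating.  ``simulate_minute_profiles`` uses
that identity as a fast path; ``generate_dataset`` writes genuine 15-s
epochs so downstream aggregation is exercised on files.

The latent mean curve is treated as piecewise constant within each minute
(every 15-s epoch of minute ``m`` has mean ``curve(t_m)/4``), so the
expected minute-aggregated count equals the curve value exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf, expit

from .timegrid import COMMON_END, COMMON_START, MINUTE_GRID

_SQRT2 = math.sqrt(2.0)
_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)

#: Counts-per-minute floor applied to every realised mean curve before
#: noise generation; avoids degenerate negative-binomial size parameters.
MEAN_FLOOR = 1.0


@dataclass(frozen=True)
class GaussianBump:
    """A smooth bump ``height * exp(-(t - center)^2 / (2 width^2))``.

    ``center`` and ``width`` are in minutes since midnight / minutes;
    ``height`` in counts per minute (may be negative for deficits).
    """

    center: float
    width: float
    height: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        z = (t - self.center) / self.width
        return self.height * np.exp(-0.5 * z * z)

    def integral(self, a: float, b: float) -> float:
        """Exact integral over ``[a, b]`` (closed form via erf)."""
        s = self.width
        return (
            self.height
            * s
            * _SQRT_HALF_PI
            * (erf((b - self.center) / (s * _SQRT2)) - erf((a - self.center) / (s * _SQRT2)))
        )

    def window_average(self, a: float, b: float) -> float:
        return self.integral(a, b) / (b - a)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth contrast function for one non-reference covariate level.

    The reference level of every covariate has the identically-zero effect
    and therefore never carries an EffectSpec.
    """

    covariate: str
    level: str
    bumps: tuple[GaussianBump, ...] = ()
    constant: float = 0.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.constant, dtype=float)
        for bump in self.bumps:
            out += bump(t)
        return out

    def window_average(self, a: float, b: float) -> float:
        """Length-normalised integral over ``[a, b]``, closed form."""
        return self.constant + sum(b_.integral(a, b) for b_ in self.bumps) / (b - a)


@dataclass(frozen=True)
class MeanCurve:
    """Baseline diurnal mean: a constant level plus smooth peaks."""

    base: float
    bumps: tuple[GaussianBump, ...]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.base, dtype=float)
        for bump in self.bumps:
            out += bump(t)
        return out


def calibrated_bump(center: float, width: float, window: tuple[float, float], target_average: float) -> GaussianBump:
    """Bump whose length-normalised integral over ``window`` equals ``target_average``."""
    unit = GaussianBump(center, width, 1.0).window_average(*window)
    return GaussianBump(center, width, target_average / unit)


def default_mean_function() -> MeanCurve:
    """Baseline activity curve for the cohort (counts per minute).

    Local maxima at the morning commute (~08:45), morning break (~10:30),
    lunch (~12:30) and after school (~15:30), with a mid-lesson trough.
    Magnitudes are in the few-hundreds-of-counts-per-minute range typical
    of hip-worn uniaxial accelerometry in 7-year-olds.
    """
    return MeanCurve(
        base=300.0,
        bumps=(
            GaussianBump(center=525.0, width=15.0, height=250.0),  # 08:45 commute
            GaussianBump(center=630.0, width=12.0, height=150.0),  # 10:30 break
            GaussianBump(center=750.0, width=25.0, height=200.0),  # 12:30 lunch
            GaussianBump(center=930.0, width=30.0, height=250.0),  # 15:30 after school
        ),
    )


def default_effect_specs() -> tuple[EffectSpec, ...]:
    """Ground-truth contrasts: a lunchtime sex deficit and a morning-commute
    deficit for children driven to school.

    Heights are calibrated so the named window's average equals the target
    deficit: girls average -70 counts/min over 12:00-13:30; car travel
    averages -75 counts/min over 08:30-09:30.
    """
    return (
        EffectSpec(
            covariate="sex",
            level="Female",
            bumps=(calibrated_bump(765.0, 20.0, (720.0, 810.0), -70.0),),
        ),
        EffectSpec(
            covariate="transport",
            level="Car",
            bumps=(calibrated_bump(540.0, 18.0, (510.0, 570.0), -75.0),),
        ),
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``covariates`` maps covariate name to an ordered {level: probability}
    table; the first level is the reference.  ``propensity`` holds the
    logistic nonresponse model: an intercept plus per-(covariate, level)
    log-odds offsets; inverse probabilities become weights, rescaled to
    mean 1.  ``dispersion`` is the variance-to-mean ratio of the counts at
    15-s epoch scale (and, by closure of the NB family, at minute scale).
    """

    n_children: int = 400
    covariates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "sex": {"Male": 0.51, "Female": 0.49},
            "transport": {"Active": 0.60, "Car": 0.40},
        }
    )
    baseline: MeanCurve = field(default_factory=default_mean_function)
    effects: tuple[EffectSpec, ...] = field(default_factory=default_effect_specs)
    dispersion: float = 5.0
    days_per_child: tuple[int, int] = (2, 7)
    propensity_intercept: float = 1.0
    propensity_offsets: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("sex", "Female"): -0.3, ("transport", "Car"): -0.2}
    )
    degrade_prob: float = 0.15
    epoch_seconds: int = 15
    day_span: tuple[int, int] = (420, 1200)  # epochs generated 07:00-20:00
    seed: int = 0

    def validate(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be positive")
        for name, table in self.covariates.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"level probabilities for {name!r} sum to {total}, not 1")
        if self.dispersion <= 1.0:
            raise ValueError("dispersion must exceed 1 (Poisson limit needs the explicit flag)")
        lo, hi = self.days_per_child
        if not (1 <= lo <= hi):
            raise ValueError("days_per_child must be an increasing positive range")
        for cov, level in self.propensity_offsets:
            if cov not in self.covariates or level not in self.covariates[cov]:
                raise ValueError(f"propensity offset refers to unknown level {cov}={level}")
        base = self.baseline(MINUTE_GRID)
        if np.any(base < 0):
            raise ValueError("baseline mean is negative on the evaluation grid")

    def reference_levels(self) -> dict[str, str]:
        return {name: next(iter(table)) for name, table in self.covariates.items()}


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score estimates against."""

    baseline: MeanCurve
    effects: tuple[EffectSpec, ...]
    dispersion: float
    covariates: pd.DataFrame  # child_id, levels, weight, propensity
    seed: int

    def effect_for(self, covariate: str, level: str) -> EffectSpec | None:
        for spec in self.effects:
            if spec.covariate == covariate and spec.level == level:
                return spec
        return None

    def child_mean_curve(self, row: pd.Series, times=None) -> np.ndarray:
        """Realised mean curve: baseline plus the child's level effects,
        floored at MEAN_FLOOR counts/min."""
        t = MINUTE_GRID if times is None else np.asarray(times, dtype=float)
        mean = self.baseline(t).copy()
        for spec in self.effects:
            if row[spec.covariate] == spec.level:
                mean += spec(t)
        return np.maximum(mean, MEAN_FLOOR)

    def to_json(self) -> dict:
        def bump(b: GaussianBump) -> dict:
            return {"center": b.center, "width": b.width, "height": b.height}

        return {
            "seed": self.seed,
            "dispersion": self.dispersion,
            "baseline": {"base": self.baseline.base, "bumps": [bump(b) for b in self.baseline.bumps]},
            "effects": [
                {
                    "covariate": e.covariate,
                    "level": e.level,
                    "constant": e.constant,
                    "bumps": [bump(b) for b in e.bumps],
                }
                for e in self.effects
            ],
        }


def generate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-child covariate table with inverse-probability weights."""
    config.validate()
    n = config.n_children
    data = {"child_id": [f"C{i:05d}" for i in range(n)]}
    for name, table in config.covariates.items():
        levels = list(table)
        probs = np.array([table[lv] for lv in levels], dtype=float)
        data[name] = rng.choice(levels, size=n, p=probs / probs.sum())
    frame = pd.DataFrame(data)

    logit = np.full(n, config.propensity_intercept, dtype=float)
    for (cov, level), offset in config.propensity_offsets.items():
        logit += offset * (frame[cov].to_numpy() == level)
    propensity = expit(logit)
    weights = 1.0 / propensity
    frame["weight"] = weights / weights.mean()
    frame["propensity"] = propensity
    return frame


def generate_counts(
    mean_per_epoch: np.ndarray,
    dispersion: float,
    rng: np.random.Generator,
    *,
    poisson: bool = False,
) -> np.ndarray:
    """Integer counts with ``E = mean_per_epoch`` and ``Var = dispersion * mean``.

    ``poisson=True`` is the explicit ``phi -> 1`` limit; otherwise
    ``dispersion`` must exceed 1.
    """
    mu = np.asarray(mean_per_epoch, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mean curve must be nonnegative")
    if poisson:
        return rng.poisson(mu)
    if dispersion <= 1.0:
        raise ValueError("dispersion must exceed 1; pass poisson=True for the limit")
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    size = mu[pos] / (dispersion - 1.0)
    out[pos] = rng.negative_binomial(size, 1.0 / dispersion)
    return out


def simulate_minute_profiles(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, pd.DataFrame, GroundTruth]:
    """Fast path: one complete 660-minute profile per child, no files.

    Equivalent in distribution to generating 15-s epochs and aggregating
    (see module docstring); used by simulation-heavy validation.
    Returns ``(Y, covariates, truth)`` with ``Y`` of shape (n, 660).
    """
    config.validate()
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    cov = generate_covariates(config, rng)
    truth = GroundTruth(config.baseline, config.effects, config.dispersion, cov, use_seed)
    n = config.n_children
    means = np.empty((n, MINUTE_GRID.size))
    for i in range(n):
        means[i] = truth.child_mean_curve(cov.iloc[i])
    counts = generate_counts(means, config.dispersion, rng).astype(float)
    return counts, cov, truth


def _degrade(present: np.ndarray, rng: np.random.Generator, n_epochs_per_min: int) -> None:
    """Drop a contiguous block of 60-480 minutes of epochs, in place."""
    n_min = present.size // n_epochs_per_min
    length = int(rng.integers(60, 481))
    start = int(rng.integers(0, max(n_min - 1, 1)))
    a = start * n_epochs_per_min
    b = min((start + length) * n_epochs_per_min, present.size)
    present[a:b] = False


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, GroundTruth]:
    """Write the epoch CSV, covariate CSV and ground-truth JSON.

    Each child contributes a number of days drawn from ``days_per_child``;
    a fraction ``degrade_prob`` of days lose a contiguous block of epochs
    so the wear-time and completeness filters are exercised downstream.

    Returns ``(epoch_csv_path, covariate_csv_path, truth)``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    cov = generate_covariates(config, rng)
    truth = GroundTruth(config.baseline, config.effects, config.dispersion, cov, config.seed)

    epl = config.epoch_seconds
    if 60 % epl:
        raise ValueError("epoch_seconds must divide 60")
    per_min = 60 // epl
    span_start, span_end = config.day_span
    minutes = np.arange(span_start, span_end)
    epoch_times = np.repeat(minutes * 60, per_min) + np.tile(np.arange(per_min) * epl, minutes.size)

    start_date = pd.Timestamp("2008-03-03")
    lo, hi = config.days_per_child
    frames = []
    for i in range(config.n_children):
        row = cov.iloc[i]
        mean_min = np.maximum(
            truth.baseline(minutes.astype(float))
            + sum(
                spec(minutes.astype(float))
                for spec in truth.effects
                if row[spec.covariate] == spec.level
            ),
            MEAN_FLOOR,
        )
        mean_epoch = np.repeat(mean_min / per_min, per_min)
        n_days = int(rng.integers(lo, hi + 1))
        for d in range(n_days):
            counts = generate_counts(mean_epoch, config.dispersion, rng)
            present = np.ones(counts.size, dtype=bool)
            if rng.random() < config.degrade_prob:
                _degrade(present, rng, per_min)
            date = (start_date + pd.Timedelta(days=d)).date().isoformat()
            secs = epoch_times[present]
            frames.append(
                pd.DataFrame(
                    {
                        "child_id": row["child_id"],
                        "date": date,
                        "time": [f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}" for s in secs],
                        "epoch_seconds": epl,
                        "counts": counts[present],
                    }
                )
            )

    epochs = pd.concat(frames, ignore_index=True)
    epoch_path = out / "epochs.csv"
    epochs.to_csv(epoch_path, index=False)

    cov_path = out / "covariates.csv"
    cov.drop(columns=["propensity"]).to_csv(cov_path, index=False)

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=2)
    return epoch_path, cov_path, truth
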