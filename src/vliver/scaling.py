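"""Scaling ALT-in-Mouse-Body to plasma ALT, and validation helpers.

The mean plasma concentration is a linear map of the mean number of ALT
objects in Mouse Body,

    Y_t = S * X_t + eps,

with ``S`` in IU ml^-1 per ALT object.  An individual animal's value is
modelled as a per-animal multiplicative skew of the population curve,

    y_{i,t} = delta_i * (S * X_t + eps),

and the individualized mapping criterion requires the delta_i sample mean
to lie within a tolerance of 1.0 (default +/- 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import VExperimentConfig, dose_objects_from_mgkg
from .errors import ConfigurationError

DEFAULT_S = 1.72  # IU ml^-1 per ALT object


@dataclass
class ScalingParams:
    """Linear scaling constant and optional additive-noise model."""

    s: float = DEFAULT_S
    epsilon_model: str = "none"  # "none" | "gaussian"
    epsilon_sd: float = 0.0

    def validate(self) -> None:
        if self.s <= 0:
            raise ConfigurationError(f"scaling constant S must be positive, got {self.s}")
        if self.epsilon_model not in ("none", "gaussian"):
            raise ConfigurationError("epsilon_model must be 'none' or 'gaussian'")
        if self.epsilon_sd < 0:
            raise ConfigurationError("epsilon_sd must be non-negative")


@dataclass
class MappingCriterion:
    target_mean: float = 1.0
    tolerance: float = 0.1

    def validate(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")


@dataclass
class DeltaSet:
    """Per-animal skew factors with their summary statistics."""

    deltas: np.ndarray
    animal_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, dtype=float)
        if len(self.deltas) == 0:
            raise ConfigurationError("DeltaSet requires at least one delta")
        if np.any(self.deltas <= 0):
            raise ConfigurationError("all delta_i must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.deltas))

    @property
    def variance(self) -> float:
        return float(np.var(self.deltas, ddof=1))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def cv(self) -> float:
        return self.sd / self.mean


def scale_to_plasma(x: np.ndarray, params: ScalingParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Map a Body-ALT series to plasma IU/ml: ``Y = S*X + eps``."""
    params.validate()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ConfigurationError("Body-ALT amounts must be non-negative")
    y = params.s * x
    if params.epsilon_model == "gaussian" and params.epsilon_sd > 0:
        if rng is None:
            raise ConfigurationError("gaussian epsilon requires an rng")
        y = y + rng.normal(0.0, params.epsilon_sd, size=y.shape)
    return y


def estimate_delta(y_obs: float, x_t: float, params: ScalingParams) -> float:
    """Per-animal skew ``delta_i = y / (S * X_t)`` (noise-free inversion)."""
    params.validate()
    if x_t <= 0:
        raise ConfigurationError("delta is undefined for X_t <= 0")
    return float(y_obs) / (params.s * float(x_t))


def estimate_deltas_from_table(
    table: pd.DataFrame,
    body_alt: pd.Series | dict,
    params: ScalingParams,
) -> DeltaSet:
    """One delta per animal from a plasma table (``animal_id,time_h,alt_iu_ml``).

    ``body_alt`` maps measurement time (h) to the mean Body-ALT amount.
    Each animal is measured once, at its own time point.
    """
    required = {"animal_id", "time_h", "alt_iu_ml"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"plasma table must have columns {sorted(required)}")
    lookup = dict(body_alt) if not isinstance(body_alt, pd.Series) else body_alt.to_dict()
    deltas, ids = [], []
    for _, row in table.iterrows():
        t = float(row["time_h"])
        if t not in lookup:
            raise ConfigurationError(f"no Body-ALT reference value for t={t} h")
        deltas.append(estimate_delta(float(row["alt_iu_ml"]), float(lookup[t]), params))
        ids.append(row["animal_id"])
    return DeltaSet(np.array(deltas), ids)


def delta_summary(deltas: DeltaSet, criterion: MappingCriterion | None = None) -> dict:
    """Summary statistics and the individualized-mapping pass/fail verdict."""
    criterion = criterion or MappingCriterion()
    criterion.validate()
    if len(deltas.deltas) < 2:
        raise ConfigurationError("delta_summary requires at least two deltas")
    return {
        "n": len(deltas.deltas),
        "mean": deltas.mean,
        "variance": deltas.variance,
        "sd": deltas.sd,
        "cv": deltas.cv,
        "passes": abs(deltas.mean - criterion.target_mean) <= criterion.tolerance,
    }


@dataclass
class TargetBand:
    """User-supplied plasma-ALT validation corridor over time."""

    time_h: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.time_h) == len(self.lower) == len(self.upper)):
            raise ConfigurationError("band arrays must have equal length")
        if np.any(self.lower > self.upper):
            raise ConfigurationError("band lower bound exceeds upper bound")

    @classmethod
    def from_csv(cls, path) -> "TargetBand":
        df = pd.read_csv(path)
        return cls(df["time_h"].values, df["lower"].values, df["upper"].values)


def _has_single_inflection(y: np.ndarray, window: int) -> bool:
    """Sigmoid proxy: the smoothed second difference changes sign exactly once."""
    if window > 1:
        kernel = np.ones(window) / window
        y = np.convolve(y, kernel, mode="valid")
    d2 = np.diff(y, 2)
    d2 = d2[np.abs(d2) > 1e-12 * max(1.0, np.abs(y).max())]
    if len(d2) == 0:
        return False
    signs = np.sign(d2)
    changes = int(np.sum(signs[1:] != signs[:-1]))
    return changes == 1


def band_check(
    time_h: np.ndarray,
    plasma: np.ndarray,
    band: TargetBand,
    smooth_window: int = 5,
) -> dict:
    """Check a scaled plasma series against a target corridor.

    Passes iff the series lies within ``[lower, upper]`` (closed interval)
    at every evaluated time and has a sigmoidal shape, operationalised as
    non-decreasing with exactly one inflection of the smoothed series.
    """
    time_h = np.asarray(time_h, dtype=float)
    plasma = np.asarray(plasma, dtype=float)
    if time_h.min() < band.time_h.min() or time_h.max() > band.time_h.max():
        raise ConfigurationError("band does not cover the evaluated time range")
    lo = np.interp(time_h, band.time_h, band.lower)
    hi = np.interp(time_h, band.time_h, band.upper)
    inside = (plasma >= lo) & (plasma <= hi)
    nondecreasing = bool(np.all(np.diff(plasma) >= 0))
    sigmoid = nondecreasing and _has_single_inflection(plasma, smooth_window)
    return {
        "passes": bool(inside.all()) and sigmoid,
        "within_band": bool(inside.all()),
        "sigmoidal": sigmoid,
        "report": pd.DataFrame(
            {"time_h": time_h, "plasma": plasma, "lower": lo, "upper": hi, "inside": inside}
        ),
    }


DOSE_LABELS = {"low": 150.0, "medium": 300.0, "high": 600.0}


def dose_response_eval(
    results: dict,
    params: ScalingParams,
    times_h: tuple[float, ...] = (4.5, 12.0),
) -> pd.DataFrame:
    """Tabulate mean +/- range scaled ALT at the requested times per dose.

    ``results`` maps dose labels (low/medium/high) to vExperiment results.
    """
    params.validate()
    missing = [k for k in DOSE_LABELS if k not in results]
    if missing:
        raise ConfigurationError(f"dose_response_eval requires runs for {missing}")
    rows = []
    for label, mgkg in DOSE_LABELS.items():
        res = results[label]
        series = res.body_series("ALT")
        for t_h in times_h:
            cycle = int(round(t_h * 3600))
            i = int(np.argmin(np.abs(res.cycles - cycle)))
            rows.append(
                {
                    "dose_label": label,
                    "dose_mgkg": mgkg,
                    "dose_objects": dose_objects_from_mgkg(mgkg),
                    "time_h": t_h,
                    "cycle": int(res.cycles[i]),
                    "body_alt_mean": float(series["mean"][i]),
                    "plasma_alt_mean": float(params.s * series["mean"][i]),
                    "plasma_alt_min": float(params.s * series["min"][i]),
                    "plasma_alt_max": float(params.s * series["max"][i]),
                }
            )
    return pd.DataFrame(rows)


def scale_experiment(cfg: VExperimentConfig, result, params: ScalingParams) -> pd.DataFrame:
    """Convenience: scaled mean plasma curve for a vExperiment result."""
    y = scale_to_plasma(result.body_alt_mean, params)
    return pd.DataFrame({"cycle": result.cycles, "time_h": result.cycles / 3600.0, "plasma_alt": y})
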