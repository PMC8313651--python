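"""Correlation of the landmark score with similarity parameters and the
bootstrap-calibrated accept/repeat/reject decision model.

The cohort (one record per patient: score D plus the six masked similarity
parameters) is split into the ``n_insufficient`` lowest-score registrations
and the acceptable remainder.  The mean of the chosen parameter (MI by
default) is bootstrapped within each subset; the two 95% percentile
intervals become the reject and accept zones, and a new registration whose
MI falls in the gap between them must be repeated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CalibrationError, DegenerateInputError, ValidationError

__all__ = ["CorrelationResult", "BootstrapResult", "DecisionModel",
           "correlate", "fisher_ci", "split_cohort", "bootstrap_mean_ci",
           "calibrate", "classify"]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of score D with one similarity parameter."""

    parameter: str
    rho: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n: int

    def __post_init__(self):
        if not (-1 <= self.ci_lower <= self.rho <= self.ci_upper <= 1):
            raise ValidationError("correlation CI must bracket rho in [-1, 1]")


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValidationError("Fisher CI needs n >= 4")
    if abs(r) >= 1.0:           # transform degenerates at |r| = 1
        return float(r), float(r)
    z = np.arctanh(r)
    zcrit = sps.norm.ppf(0.5 + level / 2)
    half = zcrit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlate(cohort: pd.DataFrame, parameter: str,
              score_col: str = "score", level: float = 0.95) -> CorrelationResult:
    """Correlate score D with one (dis)similarity parameter.

    rho is the Pearson product-moment correlation, the p-value comes from
    the t-statistic with n-2 degrees of freedom, and the CI from the Fisher
    z-transform.
    """
    x = np.asarray(cohort[score_col], float)
    y = np.asarray(cohort[parameter], float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError("need at least 3 finite records")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError(
            f"zero variance in {'score' if np.all(x == x[0]) else parameter}")
    r, p = sps.pearsonr(x, y)
    lo, hi = fisher_ci(float(r), len(x), level)
    return CorrelationResult(parameter=parameter, rho=float(r),
                             p_value=float(p), ci_lower=lo, ci_upper=hi,
                             n=len(x))


def split_cohort(cohort: pd.DataFrame, n_insufficient: int = 7,
                 score_col: str = "score"):
    """Split into (acceptable, insufficient) by registration quality.

    The ``n_insufficient`` lowest-score records form the insufficient
    subset; ties are broken by patient order (index), deterministically.
    """
    if not (0 < n_insufficient < len(cohort)):
        raise ValidationError(
            f"n_insufficient must be in (0, {len(cohort)}), got {n_insufficient}")
    ranked = cohort.iloc[np.argsort(cohort[score_col].to_numpy(),
                                    kind="stable")]
    insufficient = ranked.iloc[:n_insufficient]
    acceptable = ranked.iloc[n_insufficient:]
    return acceptable, insufficient


@dataclass(frozen=True)
class BootstrapResult:
    ci_lower: float
    ci_upper: float
    mean: float
    bias: float


def bootstrap_mean_ci(values, n_bootstrap: int = 10_000, seed: int = 0,
                      level: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap CI of the mean.

    Resamples with replacement (same size as the input) ``n_bootstrap``
    times, takes the mean of each resample and trims (1-level)/2 from both
    tails.  Bias is the mean of the bootstrap means minus the sample mean.
    Fully reproducible from ``seed``.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValidationError("need at least 2 values to bootstrap")
    if n_bootstrap < 1000:
        raise ValidationError("n_bootstrap must be >= 1000")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_bootstrap, values.size))
    means = values[idx].mean(axis=1)
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(means, [tail, 100 - tail])
    sample_mean = float(values.mean())
    return BootstrapResult(ci_lower=float(lo), ci_upper=float(hi),
                           mean=sample_mean,
                           bias=float(means.mean() - sample_mean))


@dataclass(frozen=True)
class DecisionModel:
    """Calibrated accept/repeat/reject intervals for one parameter."""

    accept_interval: tuple[float, float]
    reject_interval: tuple[float, float]
    mean_acceptable: float
    mean_insufficient: float
    bias_acceptable: float
    bias_insufficient: float
    parameter: str = "mi"
    n_bootstrap: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.reject_interval[1] >= self.accept_interval[0]:
            raise CalibrationError(
                f"reject interval {self.reject_interval} is not entirely "
                f"below accept interval {self.accept_interval}")
        a, b = self.accept_interval
        r0, r1 = self.reject_interval
        if not (a <= self.mean_acceptable <= b
                and r0 <= self.mean_insufficient <= r1):
            raise CalibrationError("subset means fall outside their intervals")

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["accept_interval"] = list(self.accept_interval)
        payload["reject_interval"] = list(self.reject_interval)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "DecisionModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        payload["accept_interval"] = tuple(payload["accept_interval"])
        payload["reject_interval"] = tuple(payload["reject_interval"])
        return cls(**payload)


def calibrate(cohort: pd.DataFrame, parameter: str = "mi",
              n_insufficient: int = 7, n_bootstrap: int = 10_000,
              seed: int = 0, level: float = 0.95,
              score_col: str = "score") -> DecisionModel:
    """Calibrate the decision model on a scored cohort.

    The reject interval is the bootstrap CI of the insufficient subset's
    mean, the accept interval that of the acceptable subset; calibration
    fails if the two intervals overlap (the method presumes separation).
    """
    acceptable, insufficient = split_cohort(cohort, n_insufficient, score_col)
    ss = np.random.SeedSequence(seed)
    s_ins, s_acc = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    boot_ins = bootstrap_mean_ci(insufficient[parameter], n_bootstrap,
                                 seed=s_ins, level=level)
    boot_acc = bootstrap_mean_ci(acceptable[parameter], n_bootstrap,
                                 seed=s_acc, level=level)
    return DecisionModel(
        accept_interval=(boot_acc.ci_lower, boot_acc.ci_upper),
        reject_interval=(boot_ins.ci_lower, boot_ins.ci_upper),
        mean_acceptable=boot_acc.mean,
        mean_insufficient=boot_ins.mean,
        bias_acceptable=boot_acc.bias,
        bias_insufficient=boot_ins.bias,
        parameter=parameter, n_bootstrap=n_bootstrap, seed=seed)


def classify(value: float, model: DecisionModel) -> str:
    """Triage one similarity value against a calibrated model.

    Values at or above the accept interval's lower bound are accepted,
    values at or below the reject interval's upper bound are rejected, and
    the gap in between asks for a repeated registration.  Both decision
    regions are closed at their boundary and extended outward (a higher
    similarity is never worse).
    """
    if value >= model.accept_interval[0]:
        return "accept"
    if value <= model.reject_interval[1]:
        return "reject"
    return "repeat"
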