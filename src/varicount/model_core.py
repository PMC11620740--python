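"""Binomial-variance estimation of precursor numbers.

When each of ``n`` precursors independently carries a fluorescent marker
with probability ``p``, the marker fraction observed in the progeny of a
group of such pools is binomially dispersed: the variance of the fraction
across animals is ``p(1-p)/n``.  Inverting this relation turns the
*dispersion* of marker frequencies across a cohort into an estimate of the
number of precursors actively contributing to the measured population::

    n_hat = p_hat * (1 - p_hat) / sigma_hat**2

equivalently, on the log10 scale,

    lg(n_hat) = lg[p_hat * (1 - p_hat)] - 2 * lg(sigma_hat)

or in coefficient-of-variation form (CV = sigma / p)::

    n_hat = (1 - p_hat) / (p_hat * CV**2)

This module holds the estimator, its CV-form twin, the log-linear
regression diagnostics (in both orientations, because the theoretical
slope of -2 belongs to the regression of lg(n) on lg(sigma)), and the
small pieces of arithmetic used around it: labeling-efficiency
normalization and expected seeding doses for transplantation designs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

logger = logging.getLogger("varicount")

__all__ = [
    "EstimationError",
    "InfiniteEstimateError",
    "DegenerateLabelingError",
    "FrequencySeries",
    "EstimateResult",
    "LogLinearFit",
    "estimate_from_sd",
    "estimate_from_cv",
    "fit_log_linear",
    "fit_sigma_on_n",
    "fit_n_on_sigma",
    "normalize_to_total",
    "expected_seeded",
]


class EstimationError(ValueError):
    """Base class for estimator domain errors."""


class InfiniteEstimateError(EstimationError):
    """All fractions identical (sigma = 0): the precursor number lies
    beyond the measurable range and the estimate diverges."""


class DegenerateLabelingError(EstimationError):
    """Mean fraction is 0 or 1: the marker carries no information."""


@dataclass(frozen=True)
class FrequencySeries:
    """Per-sample marker fractions for one cohort.

    Parameters
    ----------
    values
        Marker fractions, each in [0, 1].  Values supplied as percentages
        (any value > 1) are auto-rescaled by 1/100 with a logged warning
        unless ``percent_autoscale=False``.
    sample_ids
        Unique identifiers parallel to ``values``; generated as
        ``s0, s1, ...`` when omitted.
    marker
        Name of the fraction measured (e.g. ``"RFP_Conf"``).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    marker: str = "FP"

    def __init__(
        self,
        values: Sequence[float],
        sample_ids: Sequence[str] | None = None,
        marker: str = "FP",
        percent_autoscale: bool = True,
    ):
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must all be finite")
        if percent_autoscale and np.any(vals > 1.0):
            logger.warning(
                "marker %r: values exceed 1, interpreting as percentages "
                "and rescaling to [0, 1]",
                marker,
            )
            vals = vals / 100.0
        if np.any(vals < 0.0) or np.any(vals > 1.0):
            raise ValueError("values must lie in [0, 1] (or [0, 100] as percent)")
        if sample_ids is None:
            ids = tuple(f"s{i}" for i in range(vals.size))
        else:
            ids = tuple(str(s) for s in sample_ids)
        if len(ids) != vals.size:
            raise ValueError("sample_ids and values must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "marker", marker)

    def __len__(self) -> int:
        return int(self.values.size)

    def subset(self, keep: Sequence[str]) -> "FrequencySeries":
        """Return a new series restricted to ``keep`` ids, order preserved."""
        keepset = set(keep)
        mask = [sid in keepset for sid in self.sample_ids]
        return FrequencySeries(
            self.values[mask],
            [s for s, m in zip(self.sample_ids, mask) if m],
            marker=self.marker,
            percent_autoscale=False,
        )


@dataclass(frozen=True)
class EstimateResult:
    """A precursor-number estimate together with its ingredients.

    ``n_hat`` is ``None`` when the cohort was flagged (no valid estimate);
    ``flags`` then says why.  ``n_samples_used + len(exclusions)`` always
    equals the number of samples that entered the computation.
    """

    n_hat: float | None
    fp_mean_hat: float | None
    sigma_hat: float | None
    cv_hat: float | None
    n_samples_used: int
    exclusions: tuple[tuple[str, str], ...] = ()
    marker: str = "FP"
    flags: tuple[str, ...] = ()
    group: dict | None = None
    n_hat_total: float | None = None
    labeling_fraction: float | None = None

    @property
    def flagged(self) -> bool:
        return len(self.flags) > 0


@dataclass(frozen=True)
class LogLinearFit:
    """Ordinary least squares fit on the lg-lg (base-10) scale."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_stderr: float
    slope_ci95: tuple[float, float]
    response: str  # which variable sat on the left-hand side

    def ci_contains(self, value: float) -> bool:
        lo, hi = self.slope_ci95
        return lo <= value <= hi


def estimate_from_sd(series: FrequencySeries) -> EstimateResult:
    """Estimate the precursor number from the dispersion of fractions.

    Uses the arithmetic mean as ``p_hat`` and the sample standard
    deviation (``n - 1`` denominator) as ``sigma_hat``; returns
    ``n_hat = p_hat (1 - p_hat) / sigma_hat**2``.  No sample filtering
    happens here — that lives in :mod:`varicount.preprocess`.

    Raises
    ------
    DegenerateLabelingError
        If the mean fraction is 0 or 1 (marker absent or saturated).
    InfiniteEstimateError
        If all values are identical (sigma = 0).
    """
    vals = series.values
    if vals.size < 2:
        raise EstimationError("need at least 2 samples to estimate dispersion")
    p_hat = float(vals.mean())
    if not (0.0 < p_hat < 1.0):
        raise DegenerateLabelingError(
            f"mean fraction {p_hat} is degenerate (must be strictly in (0,1))"
        )
    sigma_hat = float(vals.std(ddof=1))
    # identical values can leave a ~1e-17 rounding residue in the SD
    if sigma_hat == 0.0 or np.all(vals == vals[0]):
        raise InfiniteEstimateError(
            "all fractions identical (sigma = 0): precursor number beyond "
            "measurable range"
        )
    n_hat = p_hat * (1.0 - p_hat) / sigma_hat**2
    return EstimateResult(
        n_hat=n_hat,
        fp_mean_hat=p_hat,
        sigma_hat=sigma_hat,
        cv_hat=sigma_hat / p_hat,
        n_samples_used=int(vals.size),
        marker=series.marker,
    )


def estimate_from_cv(fp_mean: float, cv: float) -> float:
    """CV-form of the estimator: ``n_hat = (1 - p) / (p * CV**2)``.

    Algebraically identical to :func:`estimate_from_sd` when
    ``CV = sigma / p``.
    """
    if not (0.0 < fp_mean < 1.0):
        raise DegenerateLabelingError("fp_mean must be strictly in (0, 1)")
    if cv < 0:
        raise EstimationError("cv must be non-negative")
    if cv == 0:
        raise InfiniteEstimateError("cv = 0: estimate diverges")
    return (1.0 - fp_mean) / (fp_mean * cv * cv)


def _ols_lg(x: np.ndarray, y: np.ndarray, response: str) -> LogLinearFit:
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise ValueError("predictor has no variation; fit is degenerate")
    res = _stats.linregress(lx, ly)
    n = lx.size
    # 95% CI on the slope from the t distribution with n-2 dof
    tcrit = float(_stats.t.ppf(0.975, n - 2)) if n > 2 else math.inf
    half = tcrit * res.stderr
    return LogLinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(n),
        slope_stderr=float(res.stderr),
        slope_ci95=(float(res.slope - half), float(res.slope + half)),
        response=response,
    )


def _check_positive_pairs(
    n_values: Sequence[float], sigma_values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    n_arr = np.asarray(n_values, dtype=float)
    s_arr = np.asarray(sigma_values, dtype=float)
    if n_arr.shape != s_arr.shape or n_arr.ndim != 1:
        raise ValueError("n_values and sigma_values must be 1-D and paired")
    if n_arr.size < 3:
        raise ValueError("need at least 3 points for a log-linear fit")
    if np.any(n_arr <= 0) or np.any(s_arr <= 0):
        raise ValueError("all counts and dispersions must be strictly positive")
    return n_arr, s_arr


def fit_sigma_on_n(
    n_values: Sequence[float], sigma_values: Sequence[float]
) -> LogLinearFit:
    """OLS of lg(sigma) on lg(n).  Theoretical slope: -1/2."""
    n_arr, s_arr = _check_positive_pairs(n_values, sigma_values)
    return _ols_lg(n_arr, s_arr, response="lg_sigma")


def fit_n_on_sigma(
    n_values: Sequence[float], sigma_values: Sequence[float]
) -> LogLinearFit:
    """OLS of lg(n) on lg(sigma).

    This is the orientation with the theoretical slope of -2 and
    intercept lg[p(1-p)]; silent orientation swaps halve/double slopes,
    hence the two explicitly named entry points.
    """
    n_arr, s_arr = _check_positive_pairs(n_values, sigma_values)
    return _ols_lg(s_arr, n_arr, response="lg_n")


def fit_log_linear(
    n_values: Sequence[float],
    sigma_values: Sequence[float],
    response: str = "lg_n",
) -> LogLinearFit:
    """Log-linear diagnostic fit in either orientation.

    ``response="lg_n"`` regresses lg(n) on lg(sigma) (theoretical slope
    -2); ``response="lg_sigma"`` regresses lg(sigma) on lg(n)
    (theoretical slope -1/2).
    """
    if response == "lg_n":
        return fit_n_on_sigma(n_values, sigma_values)
    if response == "lg_sigma":
        return fit_sigma_on_n(n_values, sigma_values)
    raise ValueError("response must be 'lg_n' or 'lg_sigma'")


def normalize_to_total(n_labeled: float, labeling_fraction: float) -> float:
    """Convert a labeled-compartment estimate to a total precursor count.

    Only a fraction of precursors carries any label; dividing the
    labeled-subset estimate by that labeling efficiency recovers the
    total (e.g. 831 labeled clones at 30% efficiency -> 2770 total).
    """
    if not (0.0 < labeling_fraction <= 1.0):
        raise ValueError("labeling_fraction must be in (0, 1]")
    if n_labeled < 0:
        raise ValueError("n_labeled must be non-negative")
    return n_labeled / labeling_fraction


def expected_seeded(
    dose_cells: float, precursor_frequency: float, survival_rate: float = 1.0
) -> float:
    """Expected number of precursors seeded by a transplanted dose.

    ``dose * frequency * survival``; e.g. 0.25e6 cells at a precursor
    frequency of 1e-5 seed ~2.5 precursors.
    """
    if dose_cells <= 0:
        raise ValueError("dose_cells must be positive")
    if not (0.0 < precursor_frequency <= 1.0):
        raise ValueError("precursor_frequency must be in (0, 1]")
    if not (0.0 < survival_rate <= 1.0):
        raise ValueError("survival_rate must be in (0, 1]")
    return dose_cells * precursor_frequency * survival_rate
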