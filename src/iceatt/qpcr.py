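"""Relative quantification of excision and integration from qPCR Cq values.

The quantification chain mirrors standard reference-gene-normalized qPCR:

1. Fit a standard curve Cq = slope * log10(copies) + intercept from a
   dilution series; amplification efficiency = 10^(-1/slope) - 1.
2. Invert the curve to convert replicate Cq values to copy numbers, combined
   by geometric mean (arithmetic mean on the Cq scale, where the noise is
   additive).
3. Form normalized ratios:
   - excision frequency: (empty site / reference)_sample divided by the same
     ratio in a cured strain, which represents 100% excision;
   - circle:empty ratio: (circle / reference) / (empty / reference), then
     normalized to wild type;
   - integration ratio: (junction / reference)_pool over a positive-control
     strain carrying the insertion in every chromosome.

All ratios are scale-invariant in the copy numbers and self-normalize to 1.
A sample whose Cq exceeds the top of the dilution series by more than a set
number of cycles is flagged below the limit of detection rather than
extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrMeasurement",
    "Quantification",
    "ExcisionResult",
    "fit_standard_curve",
    "quantify",
    "excision_frequency",
    "circle_metrics",
    "integration_ratio",
    "mating_excision_fold",
]


class FitError(ValueError):
    """Raised when a standard curve cannot be fit."""


@dataclass(frozen=True)
class StandardCurve:
    """A fitted qPCR standard curve Cq = slope * log10(copies) + intercept.

    ``efficiency`` is the per-cycle amplification gain minus one:
    10^(-1/slope) - 1, so a perfectly doubling assay (slope = -1/log10(2)
    ~ -3.32) has efficiency 1.0. ``cq_max`` records the highest Cq observed
    in the dilution series and anchors the limit-of-detection rule.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    cq_max: float | None = None

    @property
    def efficiency_ok(self) -> bool:
        """True when efficiency lies in the conventional 0.5-1.5 sanity band."""
        return 0.5 <= self.efficiency <= 1.5


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Cq values for one (sample, target) pair."""

    sample_id: str
    target: str
    cq_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cq_values) < 1:
            raise ValueError("at least one replicate Cq is required")
        object.__setattr__(self, "cq_values", tuple(float(c) for c in self.cq_values))

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq_values))


@dataclass(frozen=True)
class Quantification:
    """Copy-number estimate from replicate Cq values.

    ``copies`` is the geometric mean over replicates; ``geometric_sd`` is the
    multiplicative dispersion (1.0 when replicates agree exactly or n = 1).
    ``below_lod`` flags measurements past the limit of detection; their
    ``copies`` is the extrapolated value and should be read as an upper bound.
    """

    copies: float
    geometric_sd: float
    below_lod: bool = False
    replicate_copies: tuple[float, ...] = ()


@dataclass(frozen=True)
class ExcisionResult:
    """Normalized excision quantities for one strain/sample."""

    sample_id: str
    excision_frequency: float
    circle_to_empty_ratio: float | None = None
    below_lod: bool = False


def fit_standard_curve(
    dilutions: Iterable[tuple[float, float]] | Sequence[Sequence[float]],
) -> StandardCurve:
    """Fit a standard curve by ordinary least squares.

    Parameters
    ----------
    dilutions
        Pairs of (log10 copies, Cq); at least 3 points spanning at least
        2 logs of input.

    Raises
    ------
    FitError
        Fewer than 3 points, span under 2 logs, or zero variance in x.
    """
    pts = [(float(x), float(y)) for x, y in dilutions]
    if len(pts) < 3:
        raise FitError("a standard curve needs at least 3 dilution points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) < 2.0:
        raise FitError("dilution series must span at least 2 log10 units")
    if np.allclose(x, x[0]):
        raise FitError("zero variance in log10 copies")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope == 0:
        raise FitError("degenerate standard curve: slope is zero")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=float(efficiency),
        cq_max=float(y.max()),
    )


def quantify(
    measurement: QpcrMeasurement,
    curve: StandardCurve,
    *,
    lod_cycles: float = 2.0,
) -> Quantification:
    """Invert a standard curve: copies = 10^((Cq - intercept) / slope).

    Replicates are combined by geometric mean of copies, equivalent to the
    arithmetic mean of Cq under the log-linear model. A measurement whose
    mean Cq exceeds the highest dilution-series Cq by more than ``lod_cycles``
    is flagged below the limit of detection.
    """
    if curve.slope == 0:
        raise FitError("degenerate standard curve: slope is zero")
    cqs = np.array(measurement.cq_values)
    log10_copies = (cqs - curve.intercept) / curve.slope
    rep_copies = 10.0 ** log10_copies
    copies = float(10.0 ** log10_copies.mean())
    if len(cqs) > 1:
        gsd = float(10.0 ** np.std(log10_copies, ddof=1))
    else:
        gsd = 1.0
    below = bool(
        curve.cq_max is not None and cqs.mean() > curve.cq_max + lod_cycles
    )
    return Quantification(
        copies=copies,
        geometric_sd=gsd,
        below_lod=below,
        replicate_copies=tuple(float(c) for c in rep_copies),
    )


def _copies(x: float | Quantification, what: str) -> float:
    v = x.copies if isinstance(x, Quantification) else float(x)
    if not v > 0:
        raise ValueError(f"{what} copy number must be positive, got {v}")
    return v


def _is_below_lod(*xs: float | Quantification) -> bool:
    return any(isinstance(x, Quantification) and x.below_lod for x in xs)


def excision_frequency(
    sample: tuple[float | Quantification, float | Quantification],
    cured: tuple[float | Quantification, float | Quantification],
) -> float:
    """Excision frequency: empty-site abundance per chromosome, normalized to
    a cured strain representing 100% excision.

        f = (empty/reference)_sample / (empty/reference)_cured

    Each argument is a pair (empty-site copies, reference-gene copies). The
    cured strain self-normalizes to exactly 1.
    """
    se, sr = (_copies(v, n) for v, n in zip(sample, ("sample empty", "sample reference")))
    ce, cr = (_copies(v, n) for v, n in zip(cured, ("cured empty", "cured reference")))
    return (se / sr) / (ce / cr)


def circle_metrics(
    sample: tuple[float | Quantification, float | Quantification, float | Quantification],
    wild_type: tuple[float | Quantification, float | Quantification, float | Quantification],
) -> float:
    """Circle-to-empty-site ratio, normalized to wild type.

    Each argument is a (circle copies, empty-site copies, reference copies)
    triple. The reference normalization cancels within each sample but is
    kept explicit to match the measurement design:

        ratio = [(circle/ref) / (empty/ref)]_sample
              / [(circle/ref) / (empty/ref)]_wt
    """
    sc, se, sr = (_copies(v, n) for v, n in zip(sample, ("circle", "empty", "reference")))
    wc, we, wr = (
        _copies(v, n) for v, n in zip(wild_type, ("wt circle", "wt empty", "wt reference"))
    )
    return ((sc / sr) / (se / sr)) / ((wc / wr) / (we / wr))


@dataclass(frozen=True)
class IntegrationRatio:
    """Integration-site abundance relative to a 100%-integrated control.

    When the pool's junction signal is below the limit of detection the
    ratio is not numeric; ``upper_bound`` carries the LOD-implied bound.
    """

    value: float | None
    below_lod: bool
    upper_bound: float | None = None


def integration_ratio(
    pool: tuple[float | Quantification, float | Quantification],
    control: tuple[float | Quantification, float | Quantification],
) -> IntegrationRatio:
    """Fraction of chromosomes in a pool carrying an insertion at a given
    site, relative to a control strain with the insertion in every cell:

        (junction/reference)_pool / (junction/reference)_control

    Each argument is a (junction copies, reference copies) pair. If the
    pool's junction measurement is flagged below the limit of detection the
    result is reported as a bound, not a number.
    """
    ratio = (
        _copies(pool[0], "pool junction") / _copies(pool[1], "pool reference")
    ) / (
        _copies(control[0], "control junction") / _copies(control[1], "control reference")
    )
    if _is_below_lod(pool[0]):
        return IntegrationRatio(value=None, below_lod=True, upper_bound=ratio)
    return IntegrationRatio(value=ratio, below_lod=False)


def mating_excision_fold(relative_excision: float, relative_mating: float) -> float:
    """Fold difference between relative excision and relative mating
    efficiency (each expressed as a fraction of the primary-site strain).

    If the excised circle is stable, mating should be proportional to
    excision and the fold is ~1; a large fold indicates loss of the excised
    circle between excision and transfer.
    """
    if not relative_excision > 0 or not relative_mating > 0:
        raise ValueError("relative excision and mating must both be positive")
    return relative_excision / relative_mating
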