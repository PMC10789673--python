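"""Dilution-series standard curves: efficiency and absolute quantification.

Each qPCR plate carries a 7-point two-fold dilution series of a
plasmid-borne copy-number standard (5×10⁵ down to ~7.8×10³ copies).
Regressing mean Ct on log10(copies) yields the reaction efficiency
E = 10^(−1/slope) for that plate; the short-fragment curve additionally
anchors absolute quantification of LINE-1 template copies per cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .core import CtValue, UnquantifiableSampleError, aggregate_replicates

__all__ = [
    "DilutionSeries",
    "StandardCurveFit",
    "CopyNumberEstimate",
    "InvalidCurveError",
    "ExtrapolationWarning",
    "make_twofold_series",
    "fit_standard_curve",
    "quantify_copies",
    "per_cell_copies",
]


class InvalidCurveError(ValueError):
    """A standard curve that cannot support quantification (slope >= 0, too few points)."""


class ExtrapolationWarning(UserWarning):
    """A Ct quantified outside the fitted standard-curve range."""


@dataclass(frozen=True, init=False)
class DilutionSeries:
    """Ordered standard-curve points: (known copies, replicate Ct wells)."""

    points: tuple[tuple[float, tuple[CtValue, ...]], ...]
    target: str = "short"  # "short" or "long"

    def __init__(self, points, target: str = "short"):
        pts = tuple((float(c), tuple(cts)) for c, cts in points)
        if target not in ("short", "long"):
            raise ValueError(f"unknown target {target!r}")
        copies = [c for c, _ in pts]
        if len(set(copies)) < 3:
            raise ValueError("a dilution series needs >= 3 distinct copy-number points")
        if any(b >= a for a, b in zip(copies, copies[1:])):
            raise ValueError("copy numbers must be strictly decreasing along the series")
        if any(c <= 0 for c in copies):
            raise ValueError("copy numbers must be positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "target", target)


@dataclass(frozen=True)
class StandardCurveFit:
    """Ct = slope · log10(copies) + intercept, with derived efficiency.

    ``efficiency = 10**(-1/slope)``, the universal qPCR convention: a
    perfect-doubling reaction gives slope −1/log10(2) ≈ −3.32 and E = 2.
    ``ct_range`` bounds the Cts seen during fitting, for extrapolation
    warnings at quantification time.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    target: str = "short"
    ct_range: tuple[float, float] = (-math.inf, math.inf)
    n_points: int = 0


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    copies_in_well: float
    copies_per_cell: float
    scaling_factor: float


def make_twofold_series(start_copies: float, n_points: int) -> np.ndarray:
    """Copy numbers of a two-fold serial dilution: start / 2**k, k = 0..n-1.

    The assay's default series is ``make_twofold_series(5e5, 7)``, ending
    at 7812.5 (~7.8×10³) copies.
    """
    if not start_copies > 0:
        raise ValueError("start_copies must be positive")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return start_copies / np.power(2.0, np.arange(n_points))


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """OLS fit of mean Ct on log10(known copies); efficiency from the slope.

    Replicate wells are averaged to one Ct per dilution point first
    (censored wells drop out; points whose wells are all censored are
    skipped).  A non-negative slope — Ct failing to rise with dilution —
    marks the curve invalid.
    """
    log_copies, mean_cts = [], []
    for copies, cts in series.points:
        try:
            m, _, _ = aggregate_replicates(cts)
        except UnquantifiableSampleError:
            continue
        log_copies.append(math.log10(copies))
        mean_cts.append(m)
    if len(log_copies) < 3:
        raise InvalidCurveError(
            f"only {len(log_copies)} usable dilution points; need >= 3"
        )
    res = _sps.linregress(log_copies, mean_cts)
    if res.slope >= 0:
        raise InvalidCurveError(
            f"standard-curve slope {res.slope:.3f} >= 0: Ct does not rise with "
            "dilution; curve invalid"
        )
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=10.0 ** (-1.0 / res.slope),
        target=series.target,
        ct_range=(min(mean_cts), max(mean_cts)),
        n_points=len(log_copies),
    )


def quantify_copies(ct: float, fit: StandardCurveFit) -> float:
    """Invert a standard curve: copies = 10**((ct − intercept) / slope).

    Emits :class:`ExtrapolationWarning` when ``ct`` lies outside the Ct
    span of the fitted dilution points — the curve is then being used
    beyond its calibrated range and the estimate is an extrapolation.
    """
    if fit.slope >= 0:
        raise InvalidCurveError("cannot quantify against an invalid curve (slope >= 0)")
    if not math.isfinite(ct):
        raise ValueError("ct must be finite")
    lo, hi = fit.ct_range
    if not lo <= ct <= hi:
        warnings.warn(
            f"Ct {ct:.2f} outside fitted range [{lo:.2f}, {hi:.2f}]: "
            "copy number is extrapolated",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return 10.0 ** ((ct - fit.intercept) / fit.slope)


def per_cell_copies(
    copies_in_well: float,
    lysate_volume_ul: float = 40.0,
    template_volume_ul: float = 2.0,
    sample_id: str = "",
) -> CopyNumberEstimate:
    """Scale a per-well copy count to the whole single-cell lysate.

    One cell is lysed in ``lysate_volume_ul`` (default 40 µl) and
    ``template_volume_ul`` (default 2 µl) goes into each well, so the
    whole-cell count is the well count times lysate/template (default 20).
    """
    if copies_in_well <= 0:
        raise ValueError("copies_in_well must be positive")
    if lysate_volume_ul <= 0 or template_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    if template_volume_ul > lysate_volume_ul:
        raise ValueError("template volume cannot exceed lysate volume")
    factor = lysate_volume_ul / template_volume_ul
    return CopyNumberEstimate(
        sample_id=sample_id,
        copies_in_well=copies_in_well,
        copies_per_cell=copies_in_well * factor,
        scaling_factor=factor,
    )
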