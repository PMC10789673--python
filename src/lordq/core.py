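"""Core data model and the LORD-Q lesion estimator.

LORD-Q (long-run real-time PCR DNA-damage quantification) amplifies a long
amplicon and an internally nested short amplicon from the same template.
Polymerase-blocking lesions suppress amplification of the long product in
proportion to the damage level, while the short product (too short for
lesions to land in at realistic rates) tracks template input.  The damage
statistic compares a sample's (Ct_L, Ct_S) pair against the geometric mean
of a set of presumed-undamaged controls and converts the normalised
amplification ratio into lesions per 10 kb via the long-amplicon length.

The variant implemented here targets LINE-1 (L1) repeats, whose ~55,000
genomic copies per diploid mouse cell supply enough template to run the
assay on a single cell.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AmpliconPair",
    "CtValue",
    "SampleCtSummary",
    "ControlSet",
    "EfficiencyPair",
    "LesionResult",
    "FragmentProfile",
    "UnquantifiableSampleError",
    "EfficiencyWarning",
    "aggregate_replicates",
    "summarize_sample",
    "lesion_rate",
    "fragment_length_to_breaks",
    "breaks_to_fragment_length",
    "DEFAULT_AMPLICON",
]

# Highest per-cycle amplification accepted before an efficiency is rejected
# outright; values in (2.0, 2.2] exceed perfect doubling but are tolerated
# (with a warning) as standard-curve measurement noise.
MAX_EFFICIENCY = 2.2


class UnquantifiableSampleError(ValueError):
    """Raised when a sample cannot yield a numeric damage estimate.

    The typical cause is every long-fragment well failing to cross the
    fluorescence threshold within the cycle limit: damage above the
    dynamic range, not a number.
    """


class EfficiencyWarning(UserWarning):
    """An amplification efficiency slightly above the theoretical maximum 2."""


@dataclass(frozen=True)
class AmpliconPair:
    """Geometry of the long/short amplicon pair.

    Parameters
    ----------
    long_length_bp : int
        Length of the damage-probing long fragment (the symbol ``a``).
    short_length_bp : int
        Length of the nested normalisation fragment (``s``).
    label : str
        Free-text identifier for the pair.
    """

    long_length_bp: int = 3494
    short_length_bp: int = 66
    label: str = "L1-ORF2"

    def __post_init__(self) -> None:
        if not 0 < self.short_length_bp < self.long_length_bp:
            raise ValueError(
                "amplicon lengths must satisfy 0 < short < long, got "
                f"short={self.short_length_bp}, long={self.long_length_bp}"
            )


#: The mouse LINE-1 ORF2 pair used throughout as the default geometry.
DEFAULT_AMPLICON = AmpliconPair()


@dataclass(frozen=True)
class CtValue:
    """A single well's threshold cycle, possibly censored.

    A censored value means the reaction never crossed the fluorescence
    threshold within ``max_cycles`` (reported as "undetermined" by
    instrument software).
    """

    cycles: float = float("nan")
    censored: bool = False
    max_cycles: int = 40

    def __post_init__(self) -> None:
        if not self.censored:
            if not math.isfinite(self.cycles):
                raise ValueError("non-censored CtValue requires a finite cycle count")
            if not 0 < self.cycles <= self.max_cycles:
                raise ValueError(
                    f"Ct {self.cycles} outside (0, {self.max_cycles}]; "
                    "mark the well censored instead"
                )


@dataclass(frozen=True)
class SampleCtSummary:
    """Replicate-aggregated Ct pair for one sample."""

    sample_id: str
    group: str
    ct_long_mean: float
    ct_short_mean: float
    ct_long_sd: float = 0.0
    ct_short_sd: float = 0.0
    n_long: int = 1
    n_short: int = 1

    def __post_init__(self) -> None:
        if self.n_long < 1 or self.n_short < 1:
            raise ValueError("a usable sample needs >= 1 replicate per target")
        if self.ct_long_sd < 0 or self.ct_short_sd < 0:
            raise ValueError("replicate SDs must be non-negative")


@dataclass(frozen=True, init=False)
class ControlSet:
    """The presumed-undamaged reference samples the estimator normalises to."""

    controls: tuple[SampleCtSummary, ...]

    def __init__(self, controls: Iterable[SampleCtSummary]):
        object.__setattr__(self, "controls", tuple(controls))
        if self.n < 1:
            raise ValueError("control set must contain at least one sample")

    @property
    def n(self) -> int:
        return len(self.controls)

    def mean_ct_long(self) -> float:
        return sum(c.ct_long_mean for c in self.controls) / self.n

    def mean_ct_short(self) -> float:
        return sum(c.ct_short_mean for c in self.controls) / self.n


@dataclass(frozen=True)
class EfficiencyPair:
    """Per-cycle amplification efficiencies for the two reactions.

    ``source`` records whether the pair came from a plate's own standard
    curve or from configured defaults (the assay's published means are
    E_L = 1.82, E_S = 1.98).
    """

    e_long: float = 1.82
    e_short: float = 1.98
    source: str = "configured_default"

    def __post_init__(self) -> None:
        for name, e in (("e_long", self.e_long), ("e_short", self.e_short)):
            if not 1.0 < e <= MAX_EFFICIENCY:
                raise ValueError(
                    f"{name}={e} outside (1, {MAX_EFFICIENCY}]: not a usable efficiency"
                )
            if e > 2.0:
                warnings.warn(
                    f"{name}={e:.4f} exceeds the theoretical maximum 2 "
                    "(tolerated as standard-curve noise)",
                    EfficiencyWarning,
                    stacklevel=3,
                )


@dataclass(frozen=True)
class LesionResult:
    """Signed damage estimate for one sample, with its input provenance."""

    sample_id: str
    lesions_per_10kb: float
    inputs_snapshot: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FragmentProfile:
    """Mean fragment length of a sheared DNA sample (e.g. from a Bioanalyzer)."""

    sample_id: str
    mean_fragment_length_bp: float

    def __post_init__(self) -> None:
        if not self.mean_fragment_length_bp > 0:
            raise ValueError("mean fragment length must be positive")


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

def aggregate_replicates(
    values: Sequence[CtValue],
    *,
    drop_outliers: bool = False,
    outlier_cycles: float = 0.5,
) -> tuple[float, float, int]:
    """Collapse replicate wells to (mean, sample SD, n used).

    Censored wells are excluded before averaging.  With ``drop_outliers``
    a replicate more than ``outlier_cycles`` from the replicate median is
    also discarded — common qPCR QC practice, off by default.

    Raises
    ------
    UnquantifiableSampleError
        If every well is censored: the sample carries more damage than the
        assay's dynamic range resolves and has no numeric Ct.
    """
    usable = [v.cycles for v in values if not v.censored]
    if not usable:
        raise UnquantifiableSampleError(
            "all replicate wells censored — damage above dynamic range"
        )
    if drop_outliers and len(usable) >= 3:
        med = statistics.median(usable)
        kept = [c for c in usable if abs(c - med) <= outlier_cycles]
        if kept:  # never discard everything
            usable = kept
    n = len(usable)
    mean = sum(usable) / n
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(sum((c - mean) ** 2 for c in usable) / (n - 1))
    return mean, sd, n


def summarize_sample(
    sample_id: str,
    group: str,
    ct_long: Sequence[CtValue],
    ct_short: Sequence[CtValue],
    **agg_kwargs,
) -> SampleCtSummary:
    """Aggregate both targets' replicates into a :class:`SampleCtSummary`."""
    ml, sl, nl = aggregate_replicates(ct_long, **agg_kwargs)
    ms, ss, ns = aggregate_replicates(ct_short, **agg_kwargs)
    return SampleCtSummary(
        sample_id=sample_id, group=group,
        ct_long_mean=ml, ct_short_mean=ms,
        ct_long_sd=sl, ct_short_sd=ss,
        n_long=nl, n_short=ns,
    )


# ---------------------------------------------------------------------------
# The lesion estimator
# ---------------------------------------------------------------------------

def lesion_rate(
    sample: SampleCtSummary,
    controls: ControlSet,
    eff: EfficiencyPair,
    amplicon: AmpliconPair = DEFAULT_AMPLICON,
) -> LesionResult:
    """Estimate polymerase-blocking lesions per 10 kb for one sample.

    The statistic is

    .. math::

        \\frac{\\mathrm{lesions}}{10\\,\\mathrm{kb}} = 10^4 \\left[
          \\left( \\frac{E_L^{Ct_L(s)} E_S^{-Ct_S(s)}}
          {\\left[\\prod_c E_L^{Ct_L(c)} E_S^{-Ct_S(c)}\\right]^{1/n}}
          \\right)^{1/a} - 1 \\right]

    where :math:`a` is the long-amplicon length and the product runs over
    the :math:`n` control samples.  It is evaluated in log space — the
    geometric mean over controls becomes an arithmetic mean of control
    Cts — which is algebraically identical to the product form but immune
    to overflow for large Ct and large ``n``::

        lesions = 1e4 * (exp((lnE_L*(CtL_s - mean_c CtL)
                              - lnE_S*(CtS_s - mean_c CtS)) / a) - 1)

    The estimate is signed: a sample amplifying *better* than the control
    average comes out negative and is reported as-is (clamping to zero
    would bias group means).
    """
    for name, ct in (("ct_long_mean", sample.ct_long_mean),
                     ("ct_short_mean", sample.ct_short_mean)):
        if not math.isfinite(ct):
            raise ValueError(f"sample {sample.sample_id}: non-finite {name}")
    for c in controls.controls:
        if not (math.isfinite(c.ct_long_mean) and math.isfinite(c.ct_short_mean)):
            raise ValueError(f"control {c.sample_id}: non-finite mean Ct")

    a = amplicon.long_length_bp
    d_long = sample.ct_long_mean - controls.mean_ct_long()
    d_short = sample.ct_short_mean - controls.mean_ct_short()
    log_ratio = math.log(eff.e_long) * d_long - math.log(eff.e_short) * d_short
    lesions = 1e4 * math.expm1(log_ratio / a)
    return LesionResult(
        sample_id=sample.sample_id,
        lesions_per_10kb=lesions,
        inputs_snapshot={
            "ct_long_mean": sample.ct_long_mean,
            "ct_short_mean": sample.ct_short_mean,
            "control_mean_ct_long": controls.mean_ct_long(),
            "control_mean_ct_short": controls.mean_ct_short(),
            "n_controls": controls.n,
            "e_long": eff.e_long,
            "e_short": eff.e_short,
            "efficiency_source": eff.source,
            "long_length_bp": a,
        },
    )


# ---------------------------------------------------------------------------
# Fragment-length <-> breaks conversion
# ---------------------------------------------------------------------------

def fragment_length_to_breaks(profile: FragmentProfile | float) -> float:
    """Convert a mean fragment length (bp) to double-strand breaks per 10 kb.

    A mean fragment of L bp means one break every L bases on average,
    i.e. ``10000 / L`` breaks per 10 kb.  Accepts either a
    :class:`FragmentProfile` or a bare length.
    """
    length = (
        profile.mean_fragment_length_bp
        if isinstance(profile, FragmentProfile)
        else float(profile)
    )
    if not length > 0:
        raise ValueError("mean fragment length must be positive")
    return 10000.0 / length


def breaks_to_fragment_length(breaks_per_10kb: float) -> float:
    """Inverse of :func:`fragment_length_to_breaks` (bp per break count)."""
    if not breaks_per_10kb > 0:
        raise ValueError("breaks per 10 kb must be positive")
    return 10000.0 / breaks_per_10kb
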