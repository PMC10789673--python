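"""Mechanistic plate simulator: Poisson lesions blocking long-run qPCR.

The generative model formalises the assay's two working assumptions:

1. lesions land on the template as a homogeneous per-base Poisson process
   with rate λ (per bp), so a stretch of ``L`` bp is lesion-free with
   probability ``exp(-λ·L)``;
2. a single lesion anywhere in the amplicon blocks the polymerase, so a
   template contributes to amplification iff it is lesion-free
   (all-or-nothing blocking).

For a cell carrying ``n0`` template copies, the number of amplifiable
templates per target is Binomial(n0, exp(-λ·length)).  The effective copy
number maps to a threshold cycle through the standard exponential
amplification model ``Ct = log_E(Q / n_eff)`` with fluorescence-threshold
quantity Q, plus Gaussian cycle noise.  The true damage level of a
simulated cell is 10⁴·λ lesions per 10 kb, recorded alongside the plate.

One binomial survival draw is made per cell per target — the same lysate
feeds all replicate wells — so replicate scatter is Ct noise only,
mirroring the single-cell lysate design the assay uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AmpliconPair, CtValue, DEFAULT_AMPLICON
from .standards import DilutionSeries, make_twofold_series

__all__ = ["SimConfig", "SimulatedPlate", "surviving_templates",
           "ct_from_copies", "simulate_experiment"]


def _default_lambda_map() -> dict[str, float]:
    # Control plus three graded damage levels (3, 6, 9 lesions / 10 kb),
    # echoing a UV dose-response design with increasing lesion rates.
    return {"control": 0.0, "dose1": 3e-4, "dose2": 6e-4, "dose3": 9e-4}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a simulated experiment.

    Attributes
    ----------
    n0_copies : int
        LINE-1 template copies per diploid cell (~55,000 in mouse).
    lambda_per_bp : dict[str, float]
        Per-base lesion rate λ per group label; must include a control
        group at λ = 0.  10⁴·λ is the group's true lesions/10 kb.
    e_long, e_short : float
        Amplification efficiencies of the two reactions.
    ct_noise_sd : float
        Gaussian replicate noise on the cycle scale (shared by targets).
    threshold_quantity : float
        Template count Q at the fluorescence threshold.  Arbitrary — it
        cancels in the ΔCt statistic; the default keeps Cts in the
        observed 15–35 window for n0 ≈ 55,000.
    lysate_volume_ul, template_volume_ul : float
        One cell is lysed in the former; each well receives the latter,
        so a well holds ``n_surviving × template/lysate`` copies.
    short_fragment_damageable : bool
        When True (default) the short fragment is also hit with
        probability 1 − exp(−λ·s), reproducing the assay's slight
        built-in underestimation; False idealises s → 0.
    """

    n0_copies: int = 55_000
    lambda_per_bp: dict[str, float] = field(default_factory=_default_lambda_map)
    control_group: str = "control"
    e_long: float = 1.82
    e_short: float = 1.98
    ct_noise_sd: float = 0.2
    threshold_quantity: float = 1e10
    max_cycles: int = 40
    cells_per_group: int = 12
    replicates_per_cell: int = 3
    seed: int = 0
    amplicon: AmpliconPair = DEFAULT_AMPLICON
    lysate_volume_ul: float = 40.0
    template_volume_ul: float = 2.0
    standard_start_copies: float = 5e5
    standard_n_points: int = 7
    standard_replicates: int = 3
    short_fragment_damageable: bool = True

    def __post_init__(self) -> None:
        if not self.lambda_per_bp:
            raise ValueError("lambda_per_bp group map must not be empty")
        if self.control_group not in self.lambda_per_bp:
            raise ValueError(f"control group {self.control_group!r} missing from group map")
        if any(lam < 0 for lam in self.lambda_per_bp.values()):
            raise ValueError("lesion rates must be non-negative")
        for name, e in (("e_long", self.e_long), ("e_short", self.e_short)):
            if not 1.0 < e <= 2.0:
                raise ValueError(f"{name}={e} outside (1, 2]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be non-negative")
        if self.threshold_quantity <= 0:
            raise ValueError("threshold_quantity must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        """A copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulatedPlate:
    """Well-level Ct table, per-target standards, and the ground truth."""

    wells: pd.DataFrame  # columns: well, sample_id, group, target, replicate, ct
    standards: dict[str, DilutionSeries]
    truth: dict[str, float]  # sample_id -> true lesions / 10 kb
    config: SimConfig


def surviving_templates(
    n0: int, lambda_per_bp: float, length_bp: int, rng: np.random.Generator
) -> int:
    """Number of lesion-free (amplifiable) templates among ``n0`` copies.

    Binomial(n0, exp(−λ·length)): a template amplifies only if it carries
    zero Poisson lesions over the amplicon length.
    """
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    if lambda_per_bp < 0:
        raise ValueError("lesion rate must be non-negative")
    p_intact = math.exp(-lambda_per_bp * length_bp)
    return int(rng.binomial(n0, p_intact))


def ct_from_copies(
    n_eff: float,
    efficiency: float,
    threshold_quantity: float,
    noise_sd: float,
    max_cycles: int,
    rng: np.random.Generator,
) -> CtValue:
    """Threshold cycle of a well holding ``n_eff`` amplifiable copies.

    Exponential growth n·E^t reaches the threshold quantity Q at
    ``Ct = ln(Q/n) / ln(E)``; Gaussian cycle noise is added on top.
    Wells with no amplifiable template, or whose Ct lands beyond
    ``max_cycles``, are censored ("undetermined").
    """
    if threshold_quantity <= 0:
        raise ValueError("threshold_quantity must be positive")
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    if n_eff <= 0:
        return CtValue(censored=True, max_cycles=max_cycles)
    ct = math.log(threshold_quantity / n_eff) / math.log(efficiency)
    if noise_sd > 0:
        ct += rng.normal(0.0, noise_sd)
    if ct > max_cycles:
        return CtValue(censored=True, max_cycles=max_cycles)
    # noise can only push Ct below zero if the well nearly holds the
    # threshold quantity already; clamp to keep the value representable
    ct = max(ct, 1e-9)
    return CtValue(cycles=ct, max_cycles=max_cycles)


def _simulate_standards(config: SimConfig, rng: np.random.Generator) -> dict[str, DilutionSeries]:
    copies = make_twofold_series(config.standard_start_copies, config.standard_n_points)
    out = {}
    for target, eff in (("short", config.e_short), ("long", config.e_long)):
        points = []
        for c in copies:
            cts = tuple(
                ct_from_copies(c, eff, config.threshold_quantity,
                               config.ct_noise_sd, config.max_cycles, rng)
                for _ in range(config.standard_replicates)
            )
            points.append((float(c), cts))
        out[target] = DilutionSeries(points, target=target)
    return out


def simulate_experiment(config: SimConfig) -> SimulatedPlate:
    """Generate a full plate: samples for every group, standards, truth.

    Deterministic for a fixed config (including seed): identical configs
    yield bit-identical plates.
    """
    rng = np.random.default_rng(config.seed)
    standards = _simulate_standards(config, rng)

    a = config.amplicon.long_length_bp
    s = config.amplicon.short_length_bp if config.short_fragment_damageable else 0
    frac = config.template_volume_ul / config.lysate_volume_ul

    rows = []
    truth: dict[str, float] = {}
    well_idx = 0
    for group, lam in config.lambda_per_bp.items():
        for j in range(config.cells_per_group):
            sample_id = f"{group}_cell{j + 1:02d}"
            truth[sample_id] = 1e4 * lam
            # one lysate per cell: a single survival draw per target
            # feeds all replicate wells
            surv = {
                "long": surviving_templates(config.n0_copies, lam, a, rng),
                "short": (surviving_templates(config.n0_copies, lam, s, rng)
                          if s > 0 else config.n0_copies),
            }
            for target in ("short", "long"):
                eff = config.e_short if target == "short" else config.e_long
                n_well = surv[target] * frac
                for rep in range(1, config.replicates_per_cell + 1):
                    ctv = ct_from_copies(n_well, eff, config.threshold_quantity,
                                         config.ct_noise_sd, config.max_cycles, rng)
                    well_idx += 1
                    rows.append({
                        "well": f"W{well_idx:03d}",
                        "sample_id": sample_id,
                        "group": group,
                        "target": target,
                        "replicate": rep,
                        "ct": float("nan") if ctv.censored else ctv.cycles,
                    })
    wells = pd.DataFrame(rows, columns=["well", "sample_id", "group",
                                        "target", "replicate", "ct"])
    return SimulatedPlate(wells=wells, standards=standards, truth=truth, config=config)
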