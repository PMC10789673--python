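"""Delimited-text I/O, run configuration, and pipeline orchestration.

Interchange formats are plain CSV/TSV (auto-detected): a plate table
(well, sample_id, group, target, replicate, ct — "undetermined"/"NA" mark
censored wells), a standards table (target, known_copies, replicate, ct),
and a fragment-profile table (sample_id, mean_fragment_length_bp).  The
schemas mirror the fields instrument exports carry, so vendor adapters
are a column mapping away.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AmpliconPair,
    ControlSet,
    CtValue,
    EfficiencyPair,
    UnquantifiableSampleError,
    fragment_length_to_breaks,
    lesion_rate,
    summarize_sample,
)
from .simulate import SimConfig, SimulatedPlate, simulate_experiment
from .standards import (
    DilutionSeries,
    StandardCurveFit,
    fit_standard_curve,
    per_cell_copies,
    quantify_copies,
)
from .stats import GroupedMeasurements, compare_groups

__all__ = [
    "PlateSchemaError",
    "RunConfig",
    "read_plate",
    "write_plate",
    "read_standards",
    "write_standards",
    "read_fragments",
    "run_pipeline",
    "write_simulated_plate",
]

log = logging.getLogger("lordq")

PLATE_COLUMNS = ["well", "sample_id", "group", "target", "replicate", "ct"]
STANDARD_COLUMNS = ["target", "known_copies", "replicate", "ct"]
FRAGMENT_COLUMNS = ["sample_id", "mean_fragment_length_bp"]
CENSORED_TOKENS = {"undetermined", "na", "nan", ""}
VALID_TARGETS = {"short", "long"}


class PlateSchemaError(ValueError):
    """Malformed input table (missing columns, duplicates, bad labels)."""


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_ct_column(df: pd.DataFrame, path) -> pd.Series:
    """Map 'undetermined'/'NA'/blank to NaN (censored), numbers to float."""
    def parse(raw, line_no):
        token = str(raw).strip().lower()
        if token in CENSORED_TOKENS:
            return float("nan")
        try:
            return float(raw)
        except ValueError:
            raise PlateSchemaError(
                f"{path}, line {line_no}: unparseable ct value {raw!r}"
            ) from None
    # +2: header line plus 1-based numbering
    return pd.Series(
        [parse(v, i + 2) for i, v in enumerate(df["ct"])],
        index=df.index, dtype=float,
    )


def read_plate(path: str | Path) -> pd.DataFrame:
    """Parse and validate a plate table.

    Returns a DataFrame with the canonical columns; censored wells have
    ct = NaN.  Raises :class:`PlateSchemaError` (with line numbers where
    possible) on schema violations.
    """
    df = _read_table(path, PLATE_COLUMNS)
    df["target"] = df["target"].str.strip().str.lower()
    bad = df.loc[~df["target"].isin(VALID_TARGETS)]
    if not bad.empty:
        lines = [str(i + 2) for i in bad.index[:5]]
        raise PlateSchemaError(
            f"{path}: unknown target label(s) {sorted(bad['target'].unique())} "
            f"on line(s) {', '.join(lines)}"
        )
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise PlateSchemaError(f"{path}: non-integer replicate index ({exc})") from None
    df["ct"] = _parse_ct_column(df, path)

    dup = df.duplicated(subset=["sample_id", "target", "replicate"], keep=False)
    if dup.any():
        lines = [str(i + 2) for i in df.index[dup][:5]]
        raise PlateSchemaError(
            f"{path}: duplicate (sample_id, target, replicate) key(s) on "
            f"line(s) {', '.join(lines)}"
        )
    per_sample = df.groupby("sample_id")["target"].agg(set)
    incomplete = per_sample[per_sample != VALID_TARGETS]
    if len(incomplete):
        raise PlateSchemaError(
            f"{path}: sample(s) missing a target: {sorted(incomplete.index)}"
        )
    return df[PLATE_COLUMNS].reset_index(drop=True)


def write_plate(table: pd.DataFrame, path: str | Path) -> None:
    """Write a plate table; censored Cts serialise as 'undetermined'."""
    out = table[PLATE_COLUMNS].copy()
    out["ct"] = out["ct"].map(
        lambda v: "undetermined" if math.isnan(v) else repr(float(v))
    )
    out.to_csv(path, index=False)


def read_standards(path: str | Path, max_cycles: int = 40) -> dict[str, DilutionSeries]:
    """Parse a standards table into one DilutionSeries per target."""
    df = _read_table(path, STANDARD_COLUMNS)
    df["target"] = df["target"].str.strip().str.lower()
    bad = sorted(set(df["target"]) - VALID_TARGETS)
    if bad:
        raise PlateSchemaError(f"{path}: unknown target label(s) {bad}")
    df["known_copies"] = df["known_copies"].astype(float)
    df["ct"] = _parse_ct_column(df, path)

    series: dict[str, DilutionSeries] = {}
    for target, sub in df.groupby("target"):
        points = []
        for copies, wells in sub.groupby("known_copies", sort=False):
            cts = tuple(
                CtValue(censored=True, max_cycles=max_cycles) if math.isnan(ct)
                else CtValue(cycles=ct, max_cycles=max_cycles)
                for ct in wells["ct"]
            )
            points.append((copies, cts))
        points.sort(key=lambda p: -p[0])
        series[target] = DilutionSeries(points, target=target)
    return series


def write_standards(standards: dict[str, DilutionSeries], path: str | Path) -> None:
    rows = []
    for target, series in standards.items():
        for copies, cts in series.points:
            for rep, ctv in enumerate(cts, start=1):
                rows.append({
                    "target": target,
                    "known_copies": repr(copies),
                    "replicate": rep,
                    "ct": "undetermined" if ctv.censored else repr(float(ctv.cycles)),
                })
    pd.DataFrame(rows, columns=STANDARD_COLUMNS).to_csv(path, index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, FRAGMENT_COLUMNS)
    df["mean_fragment_length_bp"] = df["mean_fragment_length_bp"].astype(float)
    if (df["mean_fragment_length_bp"] <= 0).any():
        raise PlateSchemaError(f"{path}: non-positive fragment length")
    return df[FRAGMENT_COLUMNS]


def write_simulated_plate(plate: SimulatedPlate, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated experiment as the same text schemas the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plate": out_dir / "plate.csv",
        "standards": out_dir / "standards.csv",
        "truth": out_dir / "truth.csv",
    }
    write_plate(plate.wells, paths["plate"])
    write_standards(plate.standards, paths["standards"])
    pd.DataFrame(
        [{"sample_id": sid, "true_lesions_per_10kb": repr(float(v))}
         for sid, v in plate.truth.items()]
    ).to_csv(paths["truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis-run settings; defaults are the assay's published values."""

    long_length_bp: int = 3494
    short_length_bp: int = 66
    default_e_long: float = 1.82
    default_e_short: float = 1.98
    control_group: str = "control"
    lysate_volume_ul: float = 40.0
    template_volume_ul: float = 2.0
    max_cycles: int = 40
    alpha: float = 0.05
    pairwise_stats: bool = False
    seed: int = 0
    output_dir: str = "lordq_out"
    simulator: dict = field(default_factory=dict)

    @property
    def amplicon(self) -> AmpliconPair:
        return AmpliconPair(self.long_length_bp, self.short_length_bp)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PlateSchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulator)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("e_long", self.default_e_long)
        kwargs.setdefault("e_short", self.default_e_short)
        kwargs.setdefault("control_group", self.control_group)
        kwargs.setdefault("max_cycles", self.max_cycles)
        kwargs.setdefault("lysate_volume_ul", self.lysate_volume_ul)
        kwargs.setdefault("template_volume_ul", self.template_volume_ul)
        kwargs["amplicon"] = self.amplicon
        return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _plate_to_summaries(plate: pd.DataFrame, max_cycles: int):
    """Aggregate the well table into per-sample Ct summaries.

    Samples whose long-fragment wells are all censored are skipped with a
    warning in the log (damage above dynamic range — no numeric estimate).
    """
    summaries, skipped = [], []
    for sid, sub in plate.groupby("sample_id", sort=False):
        group = sub["group"].iloc[0]
        cts = {}
        for target in ("long", "short"):
            cts[target] = [
                CtValue(censored=True, max_cycles=max_cycles) if math.isnan(ct)
                else CtValue(cycles=ct, max_cycles=max_cycles)
                for ct in sub.loc[sub["target"] == target, "ct"]
            ]
        try:
            summaries.append(summarize_sample(sid, group, cts["long"], cts["short"]))
        except UnquantifiableSampleError:
            skipped.append(sid)
    if skipped:
        log.warning("skipped %d unquantifiable sample(s) (all wells censored): %s",
                    len(skipped), ", ".join(skipped))
    return summaries, skipped


def run_pipeline(
    config: RunConfig,
    plate_path: str | Path,
    standards_path: str | Path | None = None,
    fragments_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """End-to-end analysis: Ct table in, damage estimates and stats out.

    Stages: parse plate -> fit per-plate standard curves (or fall back to
    configured default efficiencies) -> estimate lesions/10 kb per sample
    against the declared control group -> absolute L1 copy numbers per
    cell (short-fragment curve, when standards are present) -> optional
    fragment-length conversion -> group statistics.  Every table is
    written to ``out_dir`` together with a run manifest.
    """
    out_dir = Path(out_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("reading plate table %s", plate_path)
    plate = read_plate(plate_path)
    summaries, skipped = _plate_to_summaries(plate, config.max_cycles)
    if not summaries:
        raise UnquantifiableSampleError("no quantifiable samples on the plate")

    # --- efficiencies -------------------------------------------------
    fits: dict[str, StandardCurveFit] = {}
    if standards_path is not None:
        log.info("fitting standard curves from %s", standards_path)
        for target, series in read_standards(standards_path, config.max_cycles).items():
            fits[target] = fit_standard_curve(series)
            log.info("  %s: slope=%.4f  E=%.4f  r2=%.5f", target,
                     fits[target].slope, fits[target].efficiency,
                     fits[target].r_squared)
    if {"short", "long"} <= set(fits):
        eff = EfficiencyPair(e_long=fits["long"].efficiency,
                             e_short=fits["short"].efficiency,
                             source="plate_standard_curve")
    else:
        eff = EfficiencyPair(e_long=config.default_e_long,
                             e_short=config.default_e_short,
                             source="configured_default")
        log.info("using configured default efficiencies E_L=%.3f E_S=%.3f",
                 eff.e_long, eff.e_short)

    # --- lesion estimates ---------------------------------------------
    controls = [s for s in summaries if s.group == config.control_group]
    if not controls:
        raise PlateSchemaError(
            f"control group {config.control_group!r} absent from plate "
            f"(groups present: {sorted({s.group for s in summaries})})"
        )
    control_set = ControlSet(controls)
    log.info("normalising %d samples against %d control(s)",
             len(summaries), control_set.n)
    lesion_rows = []
    for smp in summaries:
        res = lesion_rate(smp, control_set, eff, config.amplicon)
        lesion_rows.append({
            "sample_id": smp.sample_id,
            "group": smp.group,
            "lesions_per_10kb": res.lesions_per_10kb,
            "ct_long_mean": smp.ct_long_mean,
            "ct_short_mean": smp.ct_short_mean,
            "ct_long_sd": smp.ct_long_sd,
            "ct_short_sd": smp.ct_short_sd,
            "n_long": smp.n_long,
            "n_short": smp.n_short,
            "e_long": eff.e_long,
            "e_short": eff.e_short,
            "efficiency_source": eff.source,
        })
    lesions = pd.DataFrame(lesion_rows)
    lesions.to_csv(out_dir / "lesions.csv", index=False)

    # --- efficiency report --------------------------------------------
    eff_rows = [{
        "target": t,
        "slope": f.slope, "intercept": f.intercept,
        "r_squared": f.r_squared, "efficiency": f.efficiency,
        "n_points": f.n_points,
    } for t, f in fits.items()]
    if not eff_rows:
        eff_rows = [
            {"target": "long", "slope": np.nan, "intercept": np.nan,
             "r_squared": np.nan, "efficiency": eff.e_long, "n_points": 0},
            {"target": "short", "slope": np.nan, "intercept": np.nan,
             "r_squared": np.nan, "efficiency": eff.e_short, "n_points": 0},
        ]
    efficiency_report = pd.DataFrame(eff_rows)
    efficiency_report.to_csv(out_dir / "efficiencies.csv", index=False)

    # --- absolute copy numbers (short curve) --------------------------
    copy_numbers = None
    if "short" in fits:
        rows = []
        for smp in summaries:
            copies = quantify_copies(smp.ct_short_mean, fits["short"])
            est = per_cell_copies(copies, config.lysate_volume_ul,
                                  config.template_volume_ul, sample_id=smp.sample_id)
            rows.append({
                "sample_id": smp.sample_id, "group": smp.group,
                "copies_in_well": est.copies_in_well,
                "copies_per_cell": est.copies_per_cell,
                "scaling_factor": est.scaling_factor,
            })
        copy_numbers = pd.DataFrame(rows)
        copy_numbers.to_csv(out_dir / "copy_numbers.csv", index=False)

    # --- fragment conversion ------------------------------------------
    fragments = None
    if fragments_path is not None:
        frag = read_fragments(fragments_path)
        frag["breaks_per_10kb"] = frag["mean_fragment_length_bp"].map(
            fragment_length_to_breaks
        )
        fragments = frag
        frag.to_csv(out_dir / "fragment_breaks.csv", index=False)

    # --- group statistics ---------------------------------------------
    group_stats = None
    by_group = lesions.groupby("group")["lesions_per_10kb"].agg(list)
    if len(by_group) >= 2 and len(lesions) >= 3:
        gm = GroupedMeasurements(by_group.to_dict())
        group_stats = compare_groups(gm, alpha=config.alpha,
                                     pairwise=config.pairwise_stats)
        group_stats.to_csv(out_dir / "group_stats.csv", index=False)
        omni = group_stats.iloc[0]
        log.info("Kruskal-Wallis H=%.3f df=%d p=%.4g",
                 omni["statistic"], omni["df"], omni["p_value"])

    manifest = {
        "software": "lordq",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "config": asdict(config),
        "inputs": {
            "plate": str(plate_path),
            "standards": str(standards_path) if standards_path else None,
            "fragments": str(fragments_path) if fragments_path else None,
        },
        "n_samples": len(summaries),
        "n_skipped_unquantifiable": len(skipped),
        "efficiency_source": eff.source,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "lesions": lesions,
        "efficiencies": efficiency_report,
        "copy_numbers": copy_numbers,
        "fragments": fragments,
        "group_stats": group_stats,
        "manifest": manifest,
        "out_dir": out_dir,
    }


def simulate_to_files(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Simulate an experiment from the config's simulator block and write it."""
    plate = simulate_experiment(config.sim_config())
    return write_simulated_plate(plate, Path(out_dir or config.output_dir))
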