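"""Delimited-text readers/writers and the end-to-end pipeline runner.

File dialects
-------------
miners.csv
    ``miner_id,birth_year,exposure_start_year,exposure_end_year,diagnosis_year``
    one row per exposure segment; an empty diagnosis field means no diagnosis.
rate_table.csv
    ``age_lo,age_hi,period_lo,period_hi,cohort_lo,cohort_hi,cases,person_years``
    one row per Lexis cell (band bounds inclusive).
future_pyears.csv
    ``age_lo,age_hi,period_lo,period_hi,person_years``.

All numeric output is written with 10 significant digits, making
write/read round-trips lossless at that precision.
"""

from __future__ import annotations

import csv
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandScheme
from .cohort import MinerRecord, RateTable, tabulate
from .design import ReferenceSpec
from .errors import ConfigurationError, ValidationError
from .model import APCModel, compare_models
from .project import ExtrapolationConfig, project
from .simulate import (
    SimConfig,
    make_future_pyears,
    simulate_events,
    simulate_miners,
)

__all__ = [
    "read_miners",
    "write_miners",
    "read_rate_table",
    "write_rate_table",
    "read_future_pyears",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("apcrate")

MINERS_HEADER = [
    "miner_id",
    "birth_year",
    "exposure_start_year",
    "exposure_end_year",
    "diagnosis_year",
]
FLOAT_FMT = "%.10g"


def read_miners(path: str | Path) -> list[MinerRecord]:
    """Read a miners.csv file, assembling multi-segment miners by id.

    All per-row problems are collected and raised together as one
    :class:`ValidationError` citing line numbers.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigurationError(f"{path}: empty file, expected header") from None
        if header != MINERS_HEADER:
            raise ConfigurationError(
                f"{path}: bad header {header!r}, expected {MINERS_HEADER!r}"
            )
        problems: list[str] = []
        by_id: dict[str, dict] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                problems.append(f"line {lineno}: expected 5 fields, got {len(row)}")
                continue
            mid, birth, s, e, diag = (c.strip() for c in row)
            try:
                birth_y, s_y, e_y = int(birth), int(s), int(e)
                diag_y = int(diag) if diag else None
            except ValueError:
                problems.append(f"line {lineno}: non-integer year field")
                continue
            if e_y < s_y:
                problems.append(
                    f"line {lineno}: exposure_end_year {e_y} before exposure_start_year {s_y}"
                )
                continue
            entry = by_id.setdefault(
                mid, {"birth": birth_y, "segments": [], "diag": None}
            )
            if entry["birth"] != birth_y:
                problems.append(f"line {lineno}: miner {mid} has conflicting birth years")
            entry["segments"].append((s_y, e_y))
            if diag_y is not None:
                if entry["diag"] is not None and entry["diag"] != diag_y:
                    problems.append(
                        f"line {lineno}: miner {mid} has conflicting diagnosis years"
                    )
                entry["diag"] = diag_y
    records = []
    for mid, entry in by_id.items():
        rec = MinerRecord(
            miner_id=mid,
            birth_year=entry["birth"],
            exposure_segments=tuple(sorted(entry["segments"])),
            diagnosis_year=entry["diag"],
        )
        try:
            rec.validate()
        except ValidationError as exc:
            problems.append(str(exc))
            continue
        records.append(rec)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return records


def write_miners(records: list[MinerRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MINERS_HEADER)
        for rec in records:
            diag = "" if rec.diagnosis_year is None else rec.diagnosis_year
            for s, e in rec.exposure_segments:
                writer.writerow([rec.miner_id, rec.birth_year, s, e, diag])


def write_rate_table(table: RateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_rate_table(path: str | Path) -> RateTable:
    """Reconstruct a :class:`RateTable` from rate_table.csv (full-grid layout)."""
    frame = pd.read_csv(path)
    required = {"age_lo", "age_hi", "period_lo", "period_hi", "cases", "person_years"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    def _scheme(prefix: str) -> BandScheme:
        los = np.sort(frame[f"{prefix}_lo"].unique())
        width = int(frame[f"{prefix}_hi"].iloc[0] - frame[f"{prefix}_lo"].iloc[0] + 1)
        if len(los) > 1 and not np.all(np.diff(los) == width):
            raise ConfigurationError(f"{path}: {prefix} bands are not contiguous")
        return BandScheme(start=int(los[0]), width=width, count=len(los))

    age_scheme = _scheme("age")
    period_scheme = _scheme("period")
    a, p = age_scheme.count, period_scheme.count
    cases = np.zeros((a, p))
    pyears = np.zeros((a, p))
    for rec in frame.itertuples(index=False):
        i = age_scheme.index_of(int(rec.age_lo))
        j = period_scheme.index_of(int(rec.period_lo))
        cases[i - 1, j - 1] = rec.cases
        pyears[i - 1, j - 1] = rec.person_years
    return RateTable(age_scheme, period_scheme, cases, pyears)


def read_future_pyears(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"age_lo", "age_hi", "period_lo", "period_hi", "person_years"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# run configuration

_KNOWN_KEYS = {
    "schemes": {"age_start", "age_width", "age_count",
                "period_start", "period_width", "period_count"},
    "references": {"age", "period", "cohorts", "single_cohort"},
    "extrapolation": {"period_method", "cohort_method", "n_future_periods"},
    "simulate": {"n_miners", "birth_year_lo", "birth_year_hi", "start_age_mean",
                 "start_age_sd", "duration_mean", "duration_sd", "true_mu"},
    "io": {"miners", "future_pyears", "out_dir"},
    "run": {"seed", "log_level"},
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with study-design defaults."""

    age_scheme: BandScheme = field(default_factory=lambda: BandScheme(30, 5, 8))
    period_scheme: BandScheme = field(default_factory=lambda: BandScheme(1960, 5, 9))
    refs: ReferenceSpec | None = None
    extrapolation: ExtrapolationConfig = field(default_factory=ExtrapolationConfig)
    sim: SimConfig | None = None
    miners_path: Path | None = None
    future_pyears_path: Path | None = None
    out_dir: Path = Path("apcrate_out")
    seed: int = 20180814
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        for section, keys in data.items():
            if section not in _KNOWN_KEYS:
                raise ConfigurationError(f"unknown config section [{section}]")
            unknown = set(keys) - _KNOWN_KEYS[section]
            if unknown:
                raise ConfigurationError(
                    f"unknown key(s) {sorted(unknown)} in section [{section}]"
                )
        cfg = cls()
        s = data.get("schemes", {})
        cfg.age_scheme = BandScheme(
            s.get("age_start", 30), s.get("age_width", 5), s.get("age_count", 8)
        )
        cfg.period_scheme = BandScheme(
            s.get("period_start", 1960), s.get("period_width", 5), s.get("period_count", 9)
        )
        r = data.get("references", {})
        if r:
            cfg.refs = ReferenceSpec(
                age_ref=r["age"],
                period_ref=r["period"],
                cohort_refs=tuple(r["cohorts"]),
                single_cohort_ref=r.get("single_cohort"),
            )
        e = data.get("extrapolation", {})
        cfg.extrapolation = ExtrapolationConfig(
            period_method=e.get("period_method", "linear-trend"),
            cohort_method=e.get("cohort_method", "nearest-estimated"),
            n_future_periods=e.get("n_future_periods", 4),
        )
        run = data.get("run", {})
        cfg.seed = run.get("seed", cfg.seed)
        cfg.log_level = run.get("log_level", cfg.log_level)
        sim = data.get("simulate", {})
        sim_kwargs = {}
        if "birth_year_lo" in sim or "birth_year_hi" in sim:
            sim_kwargs["birth_year_range"] = (
                sim.get("birth_year_lo", 1891),
                sim.get("birth_year_hi", 1974),
            )
        for key in ("n_miners", "start_age_mean", "start_age_sd",
                    "duration_mean", "duration_sd", "true_mu"):
            if key in sim:
                sim_kwargs[key] = sim[key]
        cfg.sim = SimConfig(
            seed=cfg.seed,
            age_scheme=cfg.age_scheme,
            period_scheme=cfg.period_scheme,
            **sim_kwargs,
        )
        io_sec = data.get("io", {})
        if "miners" in io_sec:
            cfg.miners_path = Path(io_sec["miners"])
        if "future_pyears" in io_sec:
            cfg.future_pyears_path = Path(io_sec["future_pyears"])
        cfg.out_dir = Path(io_sec.get("out_dir", "apcrate_out"))
        return cfg

    def sim_config(self) -> SimConfig:
        if self.sim is None:
            self.sim = SimConfig(
                seed=self.seed,
                age_scheme=self.age_scheme,
                period_scheme=self.period_scheme,
            )
        return self.sim


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Tabulate, compare the seven models, fit the full model, and project.

    Writes rate_table.csv, comparison_report.csv, fit_report.csv,
    projection.csv and run_metadata.json into ``config.out_dir`` and
    returns the paths.  Fully deterministic for a given config and seed.
    """
    from . import __version__

    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.miners_path is not None:
        log.info("reading miners from %s", config.miners_path)
        records = read_miners(config.miners_path)
    else:
        sim = config.sim_config()
        log.info("simulating %d miners (seed %d)", sim.n_miners, sim.seed)
        records = simulate_events(simulate_miners(sim), sim)

    table = tabulate(records, config.age_scheme, config.period_scheme)
    log.info(
        "tabulated %.0f person-years, %.0f cases (%.0f py / %d cases out of window)",
        table.total_pyears, table.total_cases,
        table.remainder_pyears, table.remainder_cases,
    )
    paths["rate_table"] = out / "rate_table.csv"
    write_rate_table(table, paths["rate_table"])

    refs = config.refs or ReferenceSpec.study_default(table)
    comparison = compare_models(table, refs)
    paths["comparison_report"] = out / "comparison_report.csv"
    comparison.frame.to_csv(paths["comparison_report"], float_format=FLOAT_FMT)
    log.info("model selection: %s", comparison.selected)

    results = APCModel(table, "APC", refs).fit()
    paths["fit_report"] = out / "fit_report.csv"
    results.to_frame().to_csv(paths["fit_report"], index=False, float_format=FLOAT_FMT)

    if config.future_pyears_path is not None:
        future = read_future_pyears(config.future_pyears_path)
    else:
        horizon = BandScheme(
            config.period_scheme.end,
            config.period_scheme.width,
            config.extrapolation.n_future_periods,
        )
        future = make_future_pyears(records, config.sim_config(), horizon)
    projection = project(results, future, config.extrapolation)
    paths["projection"] = out / "projection.csv"
    rows = projection.rows.copy()
    rows["rounded_cases"] = ""
    totals = projection.period_totals.copy()
    totals.insert(0, "age_band", "TOTAL")
    totals["cohort_band"] = ""
    grand = pd.DataFrame(
        [{
            "age_band": "TOTAL", "period_band": "ALL", "cohort_band": "",
            "density": projection.overall_density,
            "person_years": projection.total_person_years,
            "expected_cases": projection.total_cases,
            "rounded_cases": projection.rounded_total,
        }]
    )
    pd.concat([rows, totals, grand], ignore_index=True)[
        ["age_band", "period_band", "cohort_band", "density",
         "person_years", "expected_cases", "rounded_cases"]
    ].to_csv(paths["projection"], index=False, float_format=FLOAT_FMT)

    paths["metadata"] = out / "run_metadata.json"
    meta = {
        "package": "apcrate",
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "age_scheme": [config.age_scheme.start, config.age_scheme.width,
                       config.age_scheme.count],
        "period_scheme": [config.period_scheme.start, config.period_scheme.width,
                          config.period_scheme.count],
        "references": {
            "age": refs.age_ref, "period": refs.period_ref,
            "cohorts": list(refs.cohort_refs),
        },
        "extrapolation": {
            "period_method": config.extrapolation.period_method,
            "cohort_method": config.extrapolation.cohort_method,
            "n_future_periods": config.extrapolation.n_future_periods,
        },
        "selected_model": comparison.selected,
        "total_projected_cases": projection.total_cases,
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    log.info("wrote %d artifacts to %s", len(paths), out)
    return paths
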