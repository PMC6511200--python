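"""Validated table loading, packaged reference data, and the full pipeline.

Table schemas
-------------
``fame_wide``    fatty_acid, <strain>@<D>, ...   ("–"/empty cells = absent)
``fame_long``    strain, dilution_rate, fatty_acid, percent
``timeseries``   strain, day, mode, dilution_rate, biomass_gL, fv_fm
``composition``  strain, dilution_rate, lipid_pct, fame_pct, protein_pct
``rlc``          sample_id, step, par, f, fm_prime   (par = 0 rows carry F0/Fm)

In the FAME schemas the tokens "–", "-", "" and "NA" mean an absent fatty
acid and map to 0; in the measurement schemas empty cells are missing
values.  :func:`run_pipeline` composes the whole strain evaluation —
saturation summaries, fuel properties and compliance, steady-state
productivity sweeps with strain ranking, and rapid-light-curve fits — into
a deterministic report bundle stamped with the package version and a hash
of the run configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fame_profile as fp
from . import fuel_properties as fuel
from .culture_productivity import (
    CultureTimeSeries,
    DailyRecord,
    DilutionSweep,
    SteadyStateRecord,
    detect_steady_state,
    flag_washout,
    select_optimum,
)
from .photosynthesis import RapidLightCurve, fit_platt

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "load_table",
    "Dataset",
    "ReportBundle",
    "run_pipeline",
    "write_report",
    "load_reference_profiles",
    "load_reference_class_sums",
    "load_reference_property_table",
]

MISSING_TOKENS = {"", "na", "nan", "none"}


class SchemaError(ValueError):
    """A table failed validation; the message lists the offending cells."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...]
    key: tuple[str, ...] = ()
    absent_is_zero: bool = False  # FAME convention: "–" means exactly 0
    dynamic_columns: bool = False  # fame_wide: condition columns vary

    def validate(self, frame: pd.DataFrame) -> pd.DataFrame:
        if frame.empty and len(frame.columns) == 0:
            raise SchemaError(f"{self.name}: empty table")
        problems: list[str] = []
        missing = [c for c in self.required if c not in frame.columns]
        if missing:
            raise SchemaError(f"{self.name}: missing columns {missing}")
        if not self.dynamic_columns:
            unknown = [c for c in frame.columns if c not in self.required]
            if unknown:
                raise SchemaError(f"{self.name}: unknown columns {unknown}")
        out = frame.copy()
        numeric = list(self.numeric)
        if self.dynamic_columns:
            numeric += [c for c in out.columns if c not in self.required]
        for col in numeric:
            parsed = []
            for i, cell in enumerate(out[col]):
                parsed.append(self._parse_cell(col, cell, i, problems))
            out[col] = parsed
        if self.key:
            dups = out.duplicated(subset=list(self.key))
            if dups.any():
                rows = out.loc[dups, list(self.key)].to_dict("records")
                problems.append(f"duplicate keys {rows}")
        if problems:
            raise SchemaError(f"{self.name}: " + "; ".join(problems))
        return out

    def _parse_cell(self, col, cell, row, problems):
        if cell is None or (isinstance(cell, float) and pd.isna(cell)):
            return 0.0 if self.absent_is_zero else np.nan
        text = str(cell).strip()
        if self.absent_is_zero and text.lower() in fp.ABSENT_TOKENS:
            return 0.0
        if not self.absent_is_zero and text.lower() in MISSING_TOKENS:
            return np.nan
        try:
            return float(text)
        except ValueError:
            problems.append(f"non-numeric cell {cell!r} at row {row}, "
                            f"column {col!r}")
            return np.nan


SCHEMAS: dict[str, TableSchema] = {
    "fame_wide": TableSchema(
        name="fame_wide", required=("fatty_acid",), numeric=(),
        key=("fatty_acid",), absent_is_zero=True, dynamic_columns=True,
    ),
    "fame_long": TableSchema(
        name="fame_long",
        required=("strain", "dilution_rate", "fatty_acid", "percent"),
        numeric=("dilution_rate", "percent"),
        key=("strain", "dilution_rate", "fatty_acid"),
        absent_is_zero=True,
    ),
    "timeseries": TableSchema(
        name="timeseries",
        required=("strain", "day", "mode", "dilution_rate", "biomass_gL",
                  "fv_fm"),
        numeric=("day", "dilution_rate", "biomass_gL", "fv_fm"),
        key=("strain", "dilution_rate", "day"),
    ),
    "composition": TableSchema(
        name="composition",
        required=("strain", "dilution_rate", "lipid_pct", "fame_pct",
                  "protein_pct"),
        numeric=("dilution_rate", "lipid_pct", "fame_pct", "protein_pct"),
        key=("strain", "dilution_rate"),
    ),
    "rlc": TableSchema(
        name="rlc",
        required=("sample_id", "step", "par", "f", "fm_prime"),
        numeric=("step", "par", "f", "fm_prime"),
        key=("sample_id", "step"),
    ),
}


def load_table(path, schema_id: str) -> pd.DataFrame:
    """Read a CSV and validate it against a registered schema."""
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}; "
                       f"registered: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{schema_id}: {path} is empty") from exc
    return SCHEMAS[schema_id].validate(frame)


@dataclass
class Dataset:
    """Validated input tables keyed by role."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)
    validation: list[str] = field(default_factory=list)

    @classmethod
    def from_paths(cls, **paths) -> "Dataset":
        """Build a dataset from CSV paths keyed by role.

        Roles: ``fame_profiles`` (wide), ``fame_profiles_long``,
        ``timeseries``, ``composition``, ``rlc``.
        """
        role_schema = {
            "fame_profiles": "fame_wide",
            "fame_profiles_long": "fame_long",
            "timeseries": "timeseries",
            "composition": "composition",
            "rlc": "rlc",
        }
        ds = cls()
        for role, path in paths.items():
            if path is None:
                continue
            if role not in role_schema:
                raise KeyError(f"unknown dataset role {role!r}")
            frame = load_table(path, role_schema[role])
            ds.tables[role] = frame
            ds.sources[role] = str(path)
            ds.validation.append(
                f"{role}: {len(frame)} rows x {len(frame.columns)} columns OK"
            )
        return ds


# ---------------------------------------------------------------------------
# Packaged reference data
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("algafuel.data").joinpath(name)


def load_reference_profiles() -> list[fp.FameProfile]:
    """The packaged steady-state FAME composition table (wide format).

    22 strain x dilution-rate conditions over 15 fatty-acid species, for
    marine/freshwater isolates of Chlorella, Scenedesmus, Nitzschia and
    Tetraselmis.  See ``data/FIXTURE_NOTES.md`` for known internal
    inconsistencies of some columns.
    """
    with resources.as_file(_data_path("reference_fame_profiles.csv")) as path:
        return fp.read_profiles_wide(path)


def load_reference_class_sums() -> pd.DataFrame:
    """Published SFA/MUFA/PUFA class sums for the reference conditions.

    An expected-output asset for validation only; the analysis always
    recomputes class sums from the profiles.
    """
    with resources.as_file(_data_path("reference_class_sums.csv")) as path:
        return pd.read_csv(path, index_col=0)


def load_reference_property_table() -> pd.DataFrame:
    """Published biodiesel-property values for the reference conditions.

    An expected-output asset for validation only — never an input to the
    property predictions.
    """
    with resources.as_file(_data_path("reference_fuel_properties.csv")) as path:
        return pd.read_csv(path, index_col=0)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance metadata."""

    metadata: dict
    tables: dict[str, pd.DataFrame]


def _timeseries_objects(frame: pd.DataFrame) -> list[CultureTimeSeries]:
    series = []
    for (strain, d), group in frame.groupby(["strain", "dilution_rate"],
                                            sort=True):
        group = group.sort_values("day")
        records = [
            DailyRecord(
                day=float(r.day), mode=str(r.mode),
                biomass_g_per_l=float(r.biomass_gL),
                fv_fm=None if pd.isna(r.fv_fm) else float(r.fv_fm),
            )
            for r in group.itertuples(index=False)
        ]
        series.append(CultureTimeSeries(strain=str(strain),
                                        dilution_rate=float(d),
                                        records=records))
    return series


def run_pipeline(
    dataset: Dataset,
    criterion: str = "lipid",
    standards: Sequence[fuel.StandardSpec] = (fuel.ASTM_D6751, fuel.EN_14214),
    washout_threshold: float = 0.15,
) -> ReportBundle:
    """Run every analysis stage the dataset's tables support.

    Stages and their required tables:

    * FAME stage (``fame_profiles`` or ``fame_profiles_long``): saturation
      summaries, predicted fuel properties, per-standard compliance.
    * productivity stage (``timeseries`` + ``composition``): steady-state
      records per strain x D, washout flags, per-strain optimum and a
      strain ranking under ``criterion``.
    * RLC stage (``rlc``): one Platt fit per sample.

    The productivity stage raises if only one of its two tables is present,
    naming the stage.  Output is deterministic for identical inputs.
    """
    tables: dict[str, pd.DataFrame] = {}

    profiles = None
    if "fame_profiles" in dataset.tables:
        frame = dataset.tables["fame_profiles"]
        fas = [fp.parse_fatty_acid(n) for n in frame["fatty_acid"]]
        profiles = []
        for col in frame.columns[1:]:
            strain, _, rate = col.partition("@")
            fractions = {fa: float(v) for fa, v in zip(fas, frame[col])
                         if float(v) > 0}
            profiles.append(fp.FameProfile(strain=strain,
                                           dilution_rate=float(rate),
                                           fractions=fractions))
    elif "fame_profiles_long" in dataset.tables:
        long = dataset.tables["fame_profiles_long"]
        profiles = []
        for (strain, d), group in long.groupby(["strain", "dilution_rate"],
                                               sort=True):
            fractions = {
                fp.parse_fatty_acid(r.fatty_acid): float(r.percent)
                for r in group.itertuples(index=False) if float(r.percent) > 0
            }
            profiles.append(fp.FameProfile(strain=str(strain),
                                           dilution_rate=float(d),
                                           fractions=fractions))

    if profiles is not None:
        summaries = {p.condition: fp.saturation_summary(p) for p in profiles}
        tables["saturation"] = pd.DataFrame(
            {
                cond: [round(s.sfa, 2), round(s.mufa, 2), round(s.pufa, 2),
                       round(s.average_unsaturation, 4)]
                for cond, s in summaries.items()
            },
            index=["sfa", "mufa", "pufa", "average_unsaturation"],
        )
        tables["fuel_properties"] = fuel.property_table(profiles,
                                                        standards=standards)
        rows = []
        for p in profiles:
            props = fuel.predict_properties(summaries[p.condition])
            for spec in standards:
                report = fuel.check_compliance(props, spec)
                for v in report.violations:
                    rows.append({
                        "condition": p.condition, "standard": spec.name,
                        "property": v.prop, "limit": v.limit,
                        "value": round(v.value, 4),
                        "margin": round(v.margin, 4),
                    })
        tables["violations"] = pd.DataFrame(
            rows, columns=["condition", "standard", "property", "limit",
                           "value", "margin"])

    has_ts = "timeseries" in dataset.tables
    has_comp = "composition" in dataset.tables
    if has_ts != has_comp:
        missing = "composition" if has_ts else "timeseries"
        raise ValueError(
            f"productivity stage requires both timeseries and composition "
            f"tables; missing {missing!r}"
        )
    if has_ts:
        comp = dataset.tables["composition"].set_index(
            ["strain", "dilution_rate"])
        per_strain: dict[str, list[SteadyStateRecord]] = {}
        rows = []
        for ts in _timeseries_objects(dataset.tables["timeseries"]):
            window = detect_steady_state(ts)
            key = (ts.strain, ts.dilution_rate)
            w_lip = w_fame = w_prot = 0.0
            if key in comp.index:
                row = comp.loc[key]
                w_lip = float(row["lipid_pct"])
                w_fame = float(row["fame_pct"])
                w_prot = float(row["protein_pct"])
            record = SteadyStateRecord(
                strain=ts.strain, dilution_rate=ts.dilution_rate,
                x_ss=window.mean_biomass, lipid_fraction=w_lip,
                fame_fraction=w_fame, protein_fraction=w_prot,
            )
            per_strain.setdefault(ts.strain, []).append(record)
            rows.append({
                "strain": ts.strain, "dilution_rate": ts.dilution_rate,
                "x_ss_gL": round(record.x_ss, 4),
                "cv_biomass": round(window.cv_biomass, 4),
                "biomass_productivity_gLd": round(
                    record.biomass_productivity, 4),
                "lipid_productivity_mgLd": round(
                    record.lipid_productivity, 2),
                "fame_productivity_mgLd": round(record.fame_productivity, 2),
            })
        tables["steady_states"] = pd.DataFrame(rows)
        ranking = []
        for strain in sorted(per_strain):
            sweep = DilutionSweep(strain=strain, records=sorted(
                per_strain[strain], key=lambda r: r.dilution_rate))
            d_opt, best = select_optimum(sweep, criterion=criterion)
            washout = (flag_washout(sweep, washout_threshold)
                       if len(sweep.records) >= 2 else None)
            ranking.append({
                "strain": strain, "optimal_D": d_opt,
                "biomass_productivity_gLd": round(
                    best.biomass_productivity, 4),
                "lipid_productivity_mgLd": round(best.lipid_productivity, 2),
                "fame_productivity_mgLd": round(best.fame_productivity, 2),
                "washout_D": washout,
            })
        rank_key = {
            "lipid": "lipid_productivity_mgLd",
            "fame": "fame_productivity_mgLd",
            "biomass": "biomass_productivity_gLd",
            "combined": "lipid_productivity_mgLd",
        }[criterion]
        tables["ranking"] = (
            pd.DataFrame(ranking)
            .sort_values([rank_key, "strain"], ascending=[False, True])
            .reset_index(drop=True)
        )

    if "rlc" in dataset.tables:
        fits = []
        for sample, group in dataset.tables["rlc"].groupby("sample_id",
                                                           sort=True):
            group = group.sort_values("par")
            curve = RapidLightCurve.from_fluorescence(
                par=group["par"].to_numpy(float),
                f=group["f"].to_numpy(float),
                fm_prime=group["fm_prime"].to_numpy(float),
            )
            fit = fit_platt(curve)
            fits.append({
                "sample_id": sample, "alpha": round(fit.alpha, 6),
                "beta": round(fit.beta, 6), "ps": round(fit.ps, 4),
                "retr_max": round(fit.retr_max, 4), "ik": round(fit.ik, 2),
                "mqy": round(fit.mqy, 4), "rss": round(fit.rss, 6),
                "converged": fit.converged,
            })
        tables["rlc_fits"] = pd.DataFrame(fits)

    config = {
        "criterion": criterion,
        "standards": [s.name for s in standards],
        "washout_threshold": washout_threshold,
        "sources": dict(sorted(dataset.sources.items())),
    }
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    from . import __version__

    metadata = {"package": "algafuel", "version": __version__,
                "config_hash": digest, "config": config,
                "validation": list(dataset.validation)}
    return ReportBundle(metadata=metadata, tables=tables)


def write_report(bundle: ReportBundle, outdir) -> list[Path]:
    """Write every report table as CSV plus a metadata sidecar JSON.

    Each CSV carries the package version and config hash as a leading
    comment line; re-running the same configuration on the same inputs
    yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = (f"# algafuel {bundle.metadata['version']} "
             f"config={bundle.metadata['config_hash']}\n")
    written = []
    for name, frame in sorted(bundle.tables.items()):
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(stamp)
            frame.to_csv(fh)
        written.append(path)
    meta_path = outdir / "metadata.json"
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
    written.append(meta_path)
    return written
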