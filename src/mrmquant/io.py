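"""Readers, writers and packaged defaults.

CSV interchange is comma-separated UTF-8 with '.' decimals and a required
header row; floats round-trip at full precision (display rounding is the
report renderer's job, not the writer's). The packaged default assay
configuration encodes the six-analyte calibration/QC design; the packaged
dose-count table encodes the published per-dose sample counts and
concentration summaries of the cardiovascular cohort the assay was
applied to.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .assay import AnalyteSpec, PeakRecord, Role
from .cohort import CohortRecord, DoseSummary
from .errors import ConfigError, SchemaError

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "COHORT_TABLE_COLUMNS",
    "read_peak_table",
    "write_peak_table",
    "read_cohort_table",
    "write_cohort_table",
    "load_assay_config",
    "load_dose_counts",
    "counts_to_records",
    "dose_summaries_to_frame",
    "RunManifest",
    "build_manifest",
]

logger = logging.getLogger("mrmquant")

PEAK_TABLE_COLUMNS = (
    "sample_id",
    "analyte",
    "role",
    "nominal_conc",
    "analyte_area",
    "is_area",
    "run_id",
    "matrix_lot",
    "condition",
)

COHORT_TABLE_COLUMNS = (
    "patient_id",
    "visit",
    "drug",
    "dose_mg",
    "adherent",
    "storage_days",
    "analyte",
    "conc",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_peak_table(
    path,
    strict: bool = True,
    errors: Optional[list[tuple[int, str]]] = None,
) -> list[PeakRecord]:
    """Read a peak-area CSV into validated records.

    With ``strict=False`` invalid rows are skipped; each rejection is
    logged and appended to ``errors`` as (1-based data line, message).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PEAK_TABLE_COLUMNS, path)
    records: list[PeakRecord] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        data = row._asdict()
        try:
            records.append(
                PeakRecord(
                    sample_id=str(data["sample_id"]),
                    analyte=str(data["analyte"]),
                    role=Role(data["role"]),
                    nominal_conc=_opt_float(data["nominal_conc"]),
                    analyte_area=float(data["analyte_area"]),
                    is_area=_opt_float(data["is_area"]),
                    run_id=str(data["run_id"]),
                    matrix_lot=_opt_str(data["matrix_lot"]),
                    condition=_opt_str(data["condition"]),
                )
            )
        except Exception as exc:  # noqa: BLE001 - row-level collection is the point
            if strict:
                raise SchemaError(f"{path} line {line_no}: {exc}") from exc
            logger.warning("rejected row %d of %s: %s", line_no, path, exc)
            if errors is not None:
                errors.append((line_no, str(exc)))
    return records


def _opt_float(v) -> Optional[float]:
    return None if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else float(v)


def _opt_str(v) -> Optional[str]:
    return None if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else str(v)


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def write_peak_table(records: Sequence[PeakRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "analyte": r.analyte,
                "role": r.role.value,
                "nominal_conc": r.nominal_conc,
                "analyte_area": r.analyte_area,
                "is_area": r.is_area,
                "run_id": r.run_id,
                "matrix_lot": r.matrix_lot,
                "condition": r.condition,
            }
            for r in records
        ],
        columns=list(PEAK_TABLE_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort_table(path) -> list[CohortRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COHORT_TABLE_COLUMNS, path)
    return [
        CohortRecord(
            patient_id=str(row.patient_id),
            visit=str(row.visit),
            drug=str(row.drug),
            dose_mg=float(row.dose_mg),
            adherent=_opt_bool(row.adherent),
            storage_days=_opt_float(row.storage_days),
            analyte=str(row.analyte),
            conc=_opt_float(row.conc),
        )
        for row in df.itertuples(index=False)
    ]


def write_cohort_table(records: Sequence[CohortRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "visit": r.visit,
                "drug": r.drug,
                "dose_mg": r.dose_mg,
                "adherent": r.adherent,
                "storage_days": r.storage_days,
                "analyte": r.analyte,
                "conc": r.conc,
            }
            for r in records
        ],
        columns=list(COHORT_TABLE_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")


def load_assay_config(path=None) -> dict[str, AnalyteSpec]:
    """Load an assay configuration (JSON or YAML by extension).

    With no path, the packaged six-analyte default is returned.
    """
    if path is None:
        text = resources.files("mrmquant.data").joinpath("assay_default.json").read_text("utf-8")
        raw = json.loads(text)
    else:
        text = Path(path).read_text("utf-8")
        if str(path).endswith((".yaml", ".yml")):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    if "analytes" not in raw:
        raise ConfigError(f"{path or 'default config'}: missing top-level 'analytes' list")
    specs = {}
    for entry in raw["analytes"]:
        spec = AnalyteSpec(**entry)
        specs[spec.name] = spec
    return specs


def load_dose_counts(path=None) -> pd.DataFrame:
    """Per-dose eligible/above-LLOQ counts with median (IQR) summaries."""
    if path is None:
        with resources.files("mrmquant.data").joinpath("cohort_dose_counts.csv").open("rb") as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def counts_to_records(counts: pd.DataFrame, specs: Mapping[str, AnalyteSpec]) -> list[CohortRecord]:
    """Expand a dose-count table into individual cohort records.

    Each stratum contributes ``n_above_lloq`` records at the stratum's
    median concentration and ``n_eligible - n_above_lloq`` records at half
    the analyte's LLOQ (below the limit by construction); proportions —
    the statistics the expansion preserves — are then recomputable by the
    ordinary summarisation path.
    """
    _require_columns(counts, ("analyte", "visit", "dose_mg", "n_eligible", "n_above_lloq"), "counts")
    records: list[CohortRecord] = []
    serial = 0
    for row in counts.itertuples(index=False):
        if row.analyte not in specs:
            raise ConfigError(f"no analyte spec for {row.analyte!r}")
        lloq = specs[row.analyte].lloq
        n_above = int(row.n_above_lloq)
        n_below = int(row.n_eligible) - n_above
        if n_below < 0:
            raise ConfigError(f"{row.analyte} {row.visit} {row.dose_mg}: above > eligible")
        above_conc = float(getattr(row, "median", float("nan")))
        if pd.isna(above_conc):
            above_conc = 2.0 * lloq
        for conc, n in ((above_conc, n_above), (lloq / 2.0, n_below)):
            for _ in range(n):
                serial += 1
                records.append(
                    CohortRecord(
                        patient_id=f"X{serial:05d}",
                        visit=str(row.visit),
                        drug=str(row.analyte),
                        dose_mg=float(row.dose_mg),
                        analyte=str(row.analyte),
                        conc=conc,
                    )
                )
    return records


def dose_summaries_to_frame(summaries: Sequence[DoseSummary]) -> pd.DataFrame:
    """Dose summaries as a tidy frame (one row per analyte x visit x dose)."""
    from .cohort import round_half_away

    return pd.DataFrame(
        [
            {
                "analyte": s.analyte,
                "visit": s.visit,
                "dose_mg": s.dose_mg,
                "n_eligible": s.n_eligible,
                "n_above_lloq": s.n_above_lloq,
                "pct_above_lloq": round_half_away(s.pct_above_lloq, 1),
                "median": s.median,
                "q1": s.iqr[0] if s.iqr else None,
                "q3": s.iqr[1] if s.iqr else None,
            }
            for s in summaries
        ]
    )


class RunManifest(BaseModel):
    """Provenance for one CLI run: inputs/outputs with content hashes."""

    model_config = ConfigDict(frozen=True)

    run_id: str
    date: str
    analytes: tuple[str, ...]
    files: dict[str, str]
    hashes: dict[str, str]
    seed: Optional[int] = None
    software_version: str = ""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    run_id: str,
    analytes: Sequence[str],
    files: Mapping[str, str],
    seed: Optional[int] = None,
) -> RunManifest:
    from . import __version__

    return RunManifest(
        run_id=run_id,
        date=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        analytes=tuple(analytes),
        files=dict(files),
        hashes={name: _sha256(p) for name, p in files.items() if Path(p).exists()},
        seed=seed,
        software_version=__version__,
    )
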