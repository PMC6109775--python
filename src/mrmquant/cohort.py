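"""Sparse-pharmacokinetic cohort analysis with below-LLOQ censoring.

Steady-state drug concentrations measured once or twice per patient (an
early visit M1 ~one month after discharge, and M12 ~twelve months) are
summarised per dose as median (IQR), with concentrations below the
assay's LLOQ censored — excluded from every summary statistic rather than
imputed. Between-visit tracking is assessed by Pearson correlation of the
paired log10 concentrations, and the influence of long-term frozen
storage is assessed by linear regression of log10 concentration on
storage duration (days), optionally adjusted for dose.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict
from scipy import stats as sps

from .assay import AnalyteSpec
from .errors import (
    CollinearityError,
    ConfigError,
    InsufficientPairsError,
)

__all__ = [
    "CohortRecord",
    "DoseSummary",
    "StorageRegressionResult",
    "censor_below_lloq",
    "summarize_by_dose",
    "overall_above_lloq",
    "correlate_visits",
    "storage_regression",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention for
    percentages), unlike builtin banker's rounding."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


class CohortRecord(BaseModel):
    """One patient-visit concentration for one analyte."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    visit: Literal["M1", "M12"]
    drug: str
    dose_mg: float
    analyte: str
    adherent: Optional[bool] = None
    storage_days: Optional[float] = None
    conc: Optional[float] = None  # ng/mL; None when not quantifiable
    censored: bool = False


class DoseSummary(BaseModel):
    """Per analyte x visit x dose summary of uncensored concentrations."""

    model_config = ConfigDict(frozen=True)

    analyte: str
    visit: str
    dose_mg: float
    n_eligible: int
    n_above_lloq: int
    pct_above_lloq: float  # full precision; round for display
    median: Optional[float] = None
    iqr: Optional[tuple[float, float]] = None


class StorageRegressionResult(BaseModel):
    """Effect of storage duration on log10 concentration.

    ``b`` is the unstandardized coefficient for storage days (log10 ng/mL
    per day); ``r2_storage`` is the share of variance attributed to the
    storage variable — the increase in model R^2 when storage is added to
    the dose-only model (squared semi-partial correlation), or the plain
    model R^2 when unadjusted.
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    b: float
    b_se: float
    r2_storage: float
    p_value: float
    dose_adjusted: bool
    n: int


def censor_below_lloq(
    records: Sequence[CohortRecord],
    specs: Mapping[str, AnalyteSpec],
    lloq_override: Mapping[str, float] | None = None,
) -> list[CohortRecord]:
    """Flag records whose concentration is below the analyte's LLOQ.

    'Below' is strict: a concentration exactly at the LLOQ is kept.
    ``lloq_override`` substitutes a per-analyte LLOQ (e.g. relaxing the
    lactone metabolite's limit to that of the parent compound for
    cross-analyte consistency). Records with a missing concentration are
    censored: they cannot enter any summary.
    """
    lloq_override = lloq_override or {}
    out = []
    for rec in records:
        if rec.analyte not in specs:
            raise ConfigError(f"no analyte spec for {rec.analyte!r}")
        lloq = lloq_override.get(rec.analyte, specs[rec.analyte].lloq)
        censored = rec.conc is None or rec.conc < lloq
        out.append(rec.model_copy(update={"censored": censored}))
    return out


def summarize_by_dose(records: Sequence[CohortRecord]) -> list[DoseSummary]:
    """Median (IQR) and above-LLOQ proportion per analyte x visit x dose.

    Censored records count toward eligibility but never toward the
    quantiles. Quantiles use linear interpolation. An empty stratum (all
    censored) yields n_above_lloq = 0 and absent quantiles.
    """
    df = pd.DataFrame(
        {
            "analyte": [r.analyte for r in records],
            "visit": [r.visit for r in records],
            "dose_mg": [r.dose_mg for r in records],
            "conc": [r.conc for r in records],
            "censored": [r.censored for r in records],
        }
    )
    summaries: list[DoseSummary] = []
    for (analyte, visit, dose), grp in df.groupby(["analyte", "visit", "dose_mg"], sort=True):
        n_eligible = len(grp)
        above = grp.loc[~grp["censored"], "conc"].astype(float)
        n_above = len(above)
        if n_above:
            q1, med, q3 = above.quantile([0.25, 0.5, 0.75], interpolation="linear")
            median, iqr = float(med), (float(q1), float(q3))
        else:
            median, iqr = None, None
        summaries.append(
            DoseSummary(
                analyte=analyte,
                visit=visit,
                dose_mg=float(dose),
                n_eligible=n_eligible,
                n_above_lloq=n_above,
                pct_above_lloq=n_above / n_eligible * 100.0,
                median=median,
                iqr=iqr,
            )
        )
    return summaries


def overall_above_lloq(summaries: Sequence[DoseSummary]) -> dict[tuple[str, str], float]:
    """Overall % above LLOQ per (analyte, visit): summed per-dose
    above-LLOQ counts over the summed eligible n."""
    counts: dict[tuple[str, str], list[int]] = {}
    for s in summaries:
        above, total = counts.setdefault((s.analyte, s.visit), [0, 0])
        counts[(s.analyte, s.visit)] = [above + s.n_above_lloq, total + s.n_eligible]
    return {key: above / total * 100.0 for key, (above, total) in counts.items()}


def correlate_visits(
    m1_records: Sequence[CohortRecord],
    m12_records: Sequence[CohortRecord],
) -> tuple[float, float, int]:
    """Pearson correlation of paired M1/M12 log10 concentrations.

    Pairs on patient_id within one analyte; a pair is dropped when either
    visit is censored. Returns (r, two-sided p, n pairs).
    """
    analytes = {r.analyte for r in m1_records} | {r.analyte for r in m12_records}
    if len(analytes) > 1:
        raise ConfigError(f"correlate_visits expects a single analyte, got {sorted(analytes)}")
    m1 = {r.patient_id: r for r in m1_records if not r.censored}
    m12 = {r.patient_id: r for r in m12_records if not r.censored}
    shared = sorted(set(m1) & set(m12))
    if len(shared) < 3:
        raise InsufficientPairsError(f"only {len(shared)} complete pairs; need >= 3")
    x = np.log10([m1[p].conc for p in shared])
    y = np.log10([m12[p].conc for p in shared])
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(shared)


def storage_regression(
    records: Sequence[CohortRecord],
    adjust_for_dose: bool = False,
) -> StorageRegressionResult:
    """OLS of log10 concentration on storage duration (days).

    Uses uncensored records with a storage duration. When adjusting, dose
    (mg) enters as a numeric covariate and ``r2_storage`` is the increase
    in R^2 over the dose-only model.
    """
    analytes = {r.analyte for r in records}
    if len(analytes) != 1:
        raise ConfigError(f"storage_regression expects a single analyte, got {sorted(analytes)}")
    rows = [
        (r.storage_days, r.dose_mg, math.log10(r.conc))
        for r in records
        if not r.censored and r.storage_days is not None
    ]
    if len(rows) < 4:
        raise InsufficientPairsError(f"only {len(rows)} usable records")
    storage = np.array([row[0] for row in rows], dtype=float)
    dose = np.array([row[1] for row in rows], dtype=float)
    y = np.array([row[2] for row in rows], dtype=float)
    if np.ptp(storage) == 0:
        raise CollinearityError("storage_days is constant")
    cols = {"storage_days": storage}
    if adjust_for_dose:
        if np.ptp(dose) == 0:
            raise CollinearityError("dose_mg is constant; cannot adjust for dose")
        cols["dose_mg"] = dose
    X = sm.add_constant(pd.DataFrame(cols))
    model = sm.OLS(y, X).fit()
    b = float(model.params["storage_days"])
    p = float(model.pvalues["storage_days"])
    if adjust_for_dose:
        reduced = sm.OLS(y, sm.add_constant(pd.DataFrame({"dose_mg": dose}))).fit()
        r2_storage = float(model.rsquared - reduced.rsquared)
    else:
        r2_storage = float(model.rsquared)
    return StorageRegressionResult(
        analyte=analytes.pop(),
        b=b,
        b_se=float(model.bse["storage_days"]),
        r2_storage=r2_storage,
        p_value=p,
        dose_adjusted=adjust_for_dose,
        n=len(rows),
    )
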