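"""Bioanalytical method-validation battery.

Implements the full validation suite a regulated bioanalytical lab runs on
a quantitative LC-MS/MS assay — selectivity, carryover, LLOQ adequacy,
within/between-run accuracy and precision, matrix effect and extraction
recovery (post- vs pre-extraction spiking against neat solution, per
matrix lot), stability under stress conditions, dilution integrity, and
acid/lactone interconversion accounting — each with its explicit
acceptance thresholds, and assembles the results into a serialisable
per-analyte report.

Threshold conventions follow the wording of each rule: "less than"
criteria (selectivity, carryover) are strict inequalities; "within 15%"
and "<= 15%" criteria are inclusive. Displayed percentages are rounded to
one decimal but every pass/fail verdict is computed at full precision.
"""

from __future__ import annotations

import math
import statistics
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .assay import AnalyteSpec, CalibrationFit, PeakRecord, Role, back_calculate
from .errors import (
    ConfigError,
    DesignIncompleteError,
    InsufficientReplicatesError,
    InvalidReferenceError,
    PairingError,
    UndefinedProportionError,
)

__all__ = [
    "Thresholds",
    "ReplicateStats",
    "SelectivityResult",
    "CarryoverResult",
    "LloqCheckResult",
    "MatrixEffectResult",
    "AccuracyPrecisionResult",
    "StabilityResult",
    "InterconversionResult",
    "ValidationReport",
    "replicate_stats",
    "assess_selectivity",
    "assess_carryover",
    "check_lloq",
    "accuracy_precision_battery",
    "matrix_effect_recovery",
    "stability_assessment",
    "interconversion_assessment",
    "dilution_integrity",
    "build_validation_report",
]

QC_LEVEL_NAMES = ("lloq", "low", "medium", "high")


class Thresholds(BaseModel):
    """Acceptance thresholds, in percent.

    Defaults are the standard regulatory bioanalytical criteria: blank
    interference below 20% of the LLOQ response (5% for the IS), carryover
    below the same bounds, LLOQ signal at least 5x the mean blank, QC
    accuracy/precision within 15% (20% at the LLOQ), IS-normalised matrix
    effect CV at most 15%, and dilution/stability within 15%.
    """

    model_config = ConfigDict(frozen=True)

    selectivity_analyte_pct: float = 20.0
    selectivity_is_pct: float = 5.0
    carryover_analyte_pct: float = 20.0
    carryover_is_pct: float = 5.0
    lloq_blank_ratio: float = 5.0
    qc_accuracy_pct: float = 15.0
    lloq_accuracy_pct: float = 20.0
    qc_cv_pct: float = 15.0
    lloq_cv_pct: float = 20.0
    me_cv_pct: float = 15.0
    dilution_pct: float = 15.0
    stability_pct: float = 15.0


class ReplicateStats(BaseModel):
    """Accuracy and precision of a replicate set against a nominal value."""

    model_config = ConfigDict(frozen=True)

    n: int
    mean: float
    accuracy_pct: float
    cv_pct: float


def replicate_stats(measured: Sequence[float], nominal: float) -> ReplicateStats:
    """Accuracy (% of nominal) and precision (CV %) of replicates.

    CV uses the sample standard deviation (n-1 denominator), the
    conventional bioanalytical definition.
    """
    if len(measured) < 2:
        raise InsufficientReplicatesError(f"need >= 2 replicates, got {len(measured)}")
    if nominal <= 0:
        raise ConfigError(f"nominal concentration must be positive, got {nominal}")
    mean = statistics.fmean(measured)
    sd = statistics.stdev(measured)
    return ReplicateStats(
        n=len(measured),
        mean=mean,
        accuracy_pct=mean / nominal * 100.0,
        cv_pct=sd / mean * 100.0 if mean != 0 else math.inf,
    )


class SelectivityResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    per_lot_analyte_pct: dict[str, float]
    per_lot_is_pct: dict[str, float]
    passed: bool

    def recompute_pass(self, thresholds: "Thresholds") -> bool:
        return all(
            v < thresholds.selectivity_analyte_pct for v in self.per_lot_analyte_pct.values()
        ) and all(v < thresholds.selectivity_is_pct for v in self.per_lot_is_pct.values())


def _mean_area(records: Sequence[PeakRecord], attr: str) -> float:
    vals = [getattr(r, attr) for r in records if getattr(r, attr) is not None]
    if not vals:
        raise InvalidReferenceError(f"no {attr} values among {len(records)} records")
    return statistics.fmean(vals)


def assess_selectivity(
    blank_records: Sequence[PeakRecord],
    lloq_records: Sequence[PeakRecord],
    is_reference: Sequence[PeakRecord],
    thresholds: Thresholds | None = None,
) -> SelectivityResult:
    """Interference in blank plasma from individual matrix lots.

    For each lot, the blank's analyte-region area is expressed as a
    percentage of the mean LLOQ response (n >= 6 replicates) and the
    blank's IS-region area as a percentage of the mean IS response. The
    battery passes when every lot shows < 20% analyte interference and
    < 5% IS interference (strict).
    """
    thresholds = thresholds or Thresholds()
    if len(lloq_records) < 6:
        raise InvalidReferenceError(
            f"selectivity requires >= 6 LLOQ replicates for the reference mean, got {len(lloq_records)}"
        )
    mean_lloq = _mean_area(lloq_records, "analyte_area")
    if mean_lloq == 0:
        raise InvalidReferenceError("mean LLOQ analyte response is zero")
    mean_is = _mean_area(is_reference, "is_area")
    if mean_is == 0:
        raise InvalidReferenceError("mean IS response is zero")
    per_lot_analyte: dict[str, float] = {}
    per_lot_is: dict[str, float] = {}
    for rec in blank_records:
        lot = rec.matrix_lot or rec.sample_id
        per_lot_analyte[lot] = rec.analyte_area / mean_lloq * 100.0
        per_lot_is[lot] = (rec.is_area or 0.0) / mean_is * 100.0
    result = SelectivityResult(
        per_lot_analyte_pct=per_lot_analyte, per_lot_is_pct=per_lot_is, passed=True
    )
    return result.model_copy(update={"passed": result.recompute_pass(thresholds)})


class CarryoverResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    analyte_pct: float
    is_pct: float
    passed: bool

    def recompute_pass(self, thresholds: "Thresholds") -> bool:
        return (
            self.analyte_pct < thresholds.carryover_analyte_pct
            and self.is_pct < thresholds.carryover_is_pct
        )


def assess_carryover(
    post_uloq_blank: PeakRecord,
    lloq_mean_area: float,
    is_mean_area: float,
    thresholds: Thresholds | None = None,
) -> CarryoverResult:
    """Residual signal in a blank injected right after the top standard.

    Expressed as a percentage of the mean LLOQ response (analyte) and of
    the mean IS response (IS); pass requires < 20% and < 5% (strict).
    """
    thresholds = thresholds or Thresholds()
    if lloq_mean_area <= 0 or is_mean_area <= 0:
        raise InvalidReferenceError("reference mean responses must be positive")
    result = CarryoverResult(
        analyte_pct=post_uloq_blank.analyte_area / lloq_mean_area * 100.0,
        is_pct=(post_uloq_blank.is_area or 0.0) / is_mean_area * 100.0,
        passed=True,
    )
    return result.model_copy(update={"passed": result.recompute_pass(thresholds)})


class LloqCheckResult(BaseModel):
    # 'constants' keeps an infinite ratio (clean blank) JSON-serialisable
    model_config = ConfigDict(frozen=True, ser_json_inf_nan="constants")

    ratio: float  # may be inf when the blank is clean
    passed: bool

    def recompute_pass(self, thresholds: "Thresholds") -> bool:
        return self.ratio >= thresholds.lloq_blank_ratio


def check_lloq(
    lloq_records: Sequence[PeakRecord],
    blank_records: Sequence[PeakRecord],
    thresholds: Thresholds | None = None,
) -> LloqCheckResult:
    """Signal adequacy at the LLOQ: mean LLOQ response >= 5x mean blank.

    A zero mean blank response gives an infinite ratio, which passes.
    """
    thresholds = thresholds or Thresholds()
    if not lloq_records or not blank_records:
        raise InvalidReferenceError("need at least one LLOQ and one blank record")
    mean_lloq = _mean_area(lloq_records, "analyte_area")
    mean_blank = _mean_area(blank_records, "analyte_area")
    ratio = math.inf if mean_blank == 0 else mean_lloq / mean_blank
    res = LloqCheckResult(ratio=ratio, passed=True)
    return res.model_copy(update={"passed": res.recompute_pass(thresholds)})


class AccuracyPrecisionResult(BaseModel):
    """Within-run (per run) and between-run (pooled) accuracy/precision."""

    model_config = ConfigDict(frozen=True)

    within_run: dict[str, dict[str, ReplicateStats]]  # run_id -> level -> stats
    between_run: dict[str, ReplicateStats]  # level -> stats (pooled replicates)
    passed: bool

    def recompute_pass(self, thresholds: "Thresholds") -> bool:
        ok = True
        all_stats = [
            (level, st)
            for per_run in self.within_run.values()
            for level, st in per_run.items()
        ] + list(self.between_run.items())
        for level, st in all_stats:
            acc_tol = thresholds.lloq_accuracy_pct if level == "lloq" else thresholds.qc_accuracy_pct
            cv_tol = thresholds.lloq_cv_pct if level == "lloq" else thresholds.qc_cv_pct
            ok &= abs(st.accuracy_pct - 100.0) <= acc_tol and st.cv_pct <= cv_tol
        return ok


def _qc_level_name(nominal: float, spec: AnalyteSpec) -> Optional[str]:
    for name, level in zip(QC_LEVEL_NAMES, (spec.lloq, *spec.qc_levels)):
        if math.isclose(nominal, level, rel_tol=1e-9):
            return name
    return None


def accuracy_precision_battery(
    runs: Mapping[str, Sequence[PeakRecord]],
    fits: Mapping[str, CalibrationFit],
    spec: AnalyteSpec,
    thresholds: Thresholds | None = None,
    n_replicates: int = 6,
) -> AccuracyPrecisionResult:
    """Accuracy/precision over runs x replicates x four levels.

    Each run's QC records (LLOQ plus low/medium/high QCs) are
    back-calculated against that run's own calibration fit. Within-run
    statistics are per run and level (n = replicates per run); between-run
    statistics pool every replicate across runs at each level. Pass
    requires accuracy within 15% of nominal and CV <= 15% at the QCs
    (20%/20% at the LLOQ) for every cell.
    """
    thresholds = thresholds or Thresholds()
    gaps: list[str] = []
    within: dict[str, dict[str, ReplicateStats]] = {}
    pooled: dict[str, list[float]] = {name: [] for name in QC_LEVEL_NAMES}
    nominal_by_level = dict(zip(QC_LEVEL_NAMES, (spec.lloq, *spec.qc_levels)))
    for run_id, records in runs.items():
        if run_id not in fits:
            gaps.append(f"run {run_id}: no calibration fit")
            continue
        fit = fits[run_id]
        per_level: dict[str, list[float]] = {name: [] for name in QC_LEVEL_NAMES}
        for rec in records:
            if rec.role is not Role.QC or rec.analyte != spec.name:
                continue
            level = _qc_level_name(rec.nominal_conc, spec)
            if level is None:
                continue
            per_level[level].append(back_calculate(fit, rec.analyte_area, rec.is_area))
        within[run_id] = {}
        for level, vals in per_level.items():
            if len(vals) < n_replicates:
                gaps.append(f"run {run_id}, level {level}: {len(vals)} < {n_replicates} replicates")
                continue
            within[run_id][level] = replicate_stats(vals, nominal_by_level[level])
            pooled[level].extend(vals)
    if gaps:
        raise DesignIncompleteError(
            "incomplete accuracy/precision design: " + "; ".join(gaps), gaps=gaps
        )
    between = {
        level: replicate_stats(vals, nominal_by_level[level]) for level, vals in pooled.items()
    }
    res = AccuracyPrecisionResult(within_run=within, between_run=between, passed=True)
    return res.model_copy(update={"passed": res.recompute_pass(thresholds)})


class MatrixEffectResult(BaseModel):
    """Matrix effect and extraction recovery across matrix lots.

    Per lot, ME = post-extraction-spiked area / neat-solution area x 100,
    computed separately for analyte and IS; the IS-normalised ME is
    analyte ME / IS ME x 100. Extraction recovery ER = pre-extraction
    spiked / post-extraction spiked x 100. Acceptance rides on the CV of
    the IS-normalised ME across lots (<= 15%).
    """

    model_config = ConfigDict(frozen=True)

    lots: tuple[str, ...]
    per_lot_me: tuple[float, ...]
    per_lot_is_me: tuple[float, ...]
    is_normalised_me: tuple[float, ...]
    mean_pct: float
    cv_pct: float
    recovery_per_lot: tuple[float, ...]
    recovery_mean_pct: float
    recovery_cv_pct: float
    passed: bool

    def recompute_pass(self, thresholds: "Thresholds") -> bool:
        return self.cv_pct <= thresholds.me_cv_pct


def _by_lot(records: Sequence[PeakRecord]) -> dict[str, list[PeakRecord]]:
    grouped: dict[str, list[PeakRecord]] = {}
    for rec in records:
        if rec.matrix_lot is None:
            raise PairingError(f"record {rec.sample_id} has no matrix lot")
        grouped.setdefault(rec.matrix_lot, []).append(rec)
    return grouped


def matrix_effect_recovery(
    neat: Sequence[PeakRecord],
    post_spiked: Sequence[PeakRecord],
    pre_spiked: Sequence[PeakRecord],
    thresholds: Thresholds | None = None,
) -> MatrixEffectResult:
    """Matrix effect and recovery from the three-preparation design.

    ``neat`` are analyte+IS in clean injection solvent (the lot-free
    reference); ``post_spiked`` are blank extracts from each lot spiked
    after extraction; ``pre_spiked`` are the same lots spiked before
    extraction. Lots must match between post- and pre-extraction sets.
    """
    thresholds = thresholds or Thresholds()
    if not neat:
        raise PairingError("no neat-solution records")
    neat_analyte = _mean_area(neat, "analyte_area")
    neat_is = _mean_area(neat, "is_area")
    post_by_lot = _by_lot(post_spiked)
    pre_by_lot = _by_lot(pre_spiked)
    if set(post_by_lot) != set(pre_by_lot):
        raise PairingError(
            f"unmatched lots: post={sorted(post_by_lot)} pre={sorted(pre_by_lot)}"
        )
    lots = tuple(sorted(post_by_lot))
    me, is_me, norm, er = [], [], [], []
    for lot in lots:
        post_a = _mean_area(post_by_lot[lot], "analyte_area")
        post_i = _mean_area(post_by_lot[lot], "is_area")
        pre_a = _mean_area(pre_by_lot[lot], "analyte_area")
        me.append(post_a / neat_analyte * 100.0)
        is_me.append(post_i / neat_is * 100.0)
        norm.append(me[-1] / is_me[-1] * 100.0)
        er.append(pre_a / post_a * 100.0)
    norm_mean = statistics.fmean(norm)
    norm_cv = statistics.stdev(norm) / norm_mean * 100.0 if len(norm) > 1 else 0.0
    er_mean = statistics.fmean(er)
    er_cv = statistics.stdev(er) / er_mean * 100.0 if len(er) > 1 else 0.0
    res = MatrixEffectResult(
        lots=lots,
        per_lot_me=tuple(me),
        per_lot_is_me=tuple(is_me),
        is_normalised_me=tuple(norm),
        mean_pct=norm_mean,
        cv_pct=norm_cv,
        recovery_per_lot=tuple(er),
        recovery_mean_pct=er_mean,
        recovery_cv_pct=er_cv,
        passed=True,
    )
    return res.model_copy(update={"passed": res.recompute_pass(thresholds)})


class StabilityResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    condition: str
    pct_nominal: dict[str, float]  # level name ("low"/"high") -> % of nominal
    passed: bool

    def recompute_pass(self, thresholds: "Thresholds") -> bool:
        return all(abs(v - 100.0) <= thresholds.stability_pct for v in self.pct_nominal.values())


def stability_assessment(
    condition: str,
    stressed: Sequence[PeakRecord],
    fresh_fit: CalibrationFit,
    thresholds: Thresholds | None = None,
) -> StabilityResult:
    """Stability of stressed QC samples against a fresh calibration.

    Stressed replicates at low and high QC are back-calculated against the
    fresh fit; the mean, as a percentage of nominal, must stay within
    100 +/- 15% (inclusive) at each level.
    """
    thresholds = thresholds or Thresholds()
    if not fresh_fit.accepted:
        raise ConfigError("fresh calibration fit is not accepted")
    per_nominal: dict[float, list[float]] = {}
    for rec in stressed:
        if rec.role is not Role.STABILITY or rec.analyte != fresh_fit.analyte:
            continue
        per_nominal.setdefault(rec.nominal_conc, []).append(
            back_calculate(fresh_fit, rec.analyte_area, rec.is_area)
        )
    if not per_nominal:
        raise DesignIncompleteError(f"no stability records for condition {condition!r}")
    names = {min(per_nominal): "low", max(per_nominal): "high"}
    pct = {
        names.get(nom, f"{nom:g}"): statistics.fmean(vals) / nom * 100.0
        for nom, vals in per_nominal.items()
    }
    res = StabilityResult(condition=condition, pct_nominal=pct, passed=True)
    return res.model_copy(update={"passed": res.recompute_pass(thresholds)})


class InterconversionResult(BaseModel):
    """Acid/lactone interconversion for one stressed condition.

    The tracked quantity is the proportion (by ng/mL concentration) of the
    *product* species in the acid+lactone pair: the lactone proportion for
    acid->lactone conversion, the acid proportion for lactone->acid.
    Conversion is the change in that proportion from baseline. Context
    bounds: 0.3% for acid->lactone, 5% for lactone->acid at room
    temperature, 1.5% for lactone->acid on ice.
    """

    model_config = ConfigDict(frozen=True)

    direction: str  # "acid_to_lactone" | "lactone_to_acid"
    lactone_proportion_pct: float
    product_proportion_pct: float
    conversion_pct: float
    bound_pct: float
    within_bound: bool


INTERCONVERSION_BOUNDS = {
    "acid_to_lactone": 0.3,
    "lactone_to_acid": 5.0,
    "lactone_to_acid_on_ice": 1.5,
}


def interconversion_assessment(
    acid_conc: float,
    lactone_conc: float,
    baseline_proportion_pct: float = 0.0,
    direction: str = "acid_to_lactone",
    on_ice: bool = False,
) -> InterconversionResult:
    """Quantify acid<->lactone interconversion against its context bound.

    Proportions are on a mass-concentration (ng/mL) basis.
    """
    if acid_conc < 0 or lactone_conc < 0:
        raise ConfigError("concentrations must be non-negative")
    total = acid_conc + lactone_conc
    if total == 0:
        raise UndefinedProportionError("acid and lactone concentrations are both zero")
    lactone_prop = lactone_conc / total * 100.0
    if direction == "acid_to_lactone":
        product_prop = lactone_prop
        bound = INTERCONVERSION_BOUNDS["acid_to_lactone"]
    elif direction == "lactone_to_acid":
        product_prop = acid_conc / total * 100.0
        bound = INTERCONVERSION_BOUNDS[
            "lactone_to_acid_on_ice" if on_ice else "lactone_to_acid"
        ]
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    conversion = product_prop - baseline_proportion_pct
    return InterconversionResult(
        direction=direction,
        lactone_proportion_pct=lactone_prop,
        product_proportion_pct=product_prop,
        conversion_pct=conversion,
        bound_pct=bound,
        within_bound=conversion <= bound,
    )


class DilutionResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    stats: ReplicateStats
    dilution_factor: float
    passed: bool

    def recompute_pass(self, thresholds: "Thresholds") -> bool:
        return (
            abs(self.stats.accuracy_pct - 100.0) <= thresholds.dilution_pct
            and self.stats.cv_pct <= thresholds.dilution_pct
        )


def dilution_integrity(
    high_samples: Sequence[PeakRecord],
    dilution_factor: float,
    fit: CalibrationFit,
    thresholds: Thresholds | None = None,
) -> DilutionResult:
    """Accuracy/precision of above-ULOQ samples measured after dilution.

    Replicates spiked above the ULOQ are diluted (typically 20-fold) into
    blank plasma; back-calculation applies the dilution factor. The
    diluted nominal must fall inside the calibration range; accuracy and
    CV against the undiluted nominal must be within 15% (inclusive).
    """
    thresholds = thresholds or Thresholds()
    recs = [r for r in high_samples if r.role is Role.DILUTION and r.analyte == fit.analyte]
    if not recs:
        raise DesignIncompleteError("no dilution records supplied")
    nominals = {r.nominal_conc for r in recs}
    if len(nominals) != 1:
        raise ConfigError(f"mixed dilution nominals {sorted(nominals)}")
    nominal = nominals.pop()
    diluted_nominal = nominal / dilution_factor
    if not (fit.lloq <= diluted_nominal <= fit.uloq):
        raise ConfigError(
            f"diluted nominal {diluted_nominal:g} outside calibration range "
            f"[{fit.lloq:g}, {fit.uloq:g}]"
        )
    vals = [
        back_calculate(fit, r.analyte_area, r.is_area, dilution_factor=dilution_factor)
        for r in recs
    ]
    stats = replicate_stats(vals, nominal)
    res = DilutionResult(stats=stats, dilution_factor=dilution_factor, passed=True)
    return res.model_copy(update={"passed": res.recompute_pass(thresholds)})


class ValidationReport(BaseModel):
    """Per-analyte validation summary with pass flags.

    Mirrors the standard reporting layout: selectivity, calibration r,
    dilution integrity, carryover, IS-normalised matrix effect, recovery,
    within- and between-run accuracy/precision, and stability per stress
    condition. Every flag is a pure function of the stored numbers and the
    thresholds (``recompute_pass`` re-derives it).
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    thresholds: Thresholds
    selectivity: Optional[SelectivityResult] = None
    calibration_r: Optional[float] = None
    calibration_accepted: Optional[bool] = None
    lloq_check: Optional[LloqCheckResult] = None
    carryover: Optional[CarryoverResult] = None
    accuracy_precision: Optional[AccuracyPrecisionResult] = None
    matrix_effect_low: Optional[MatrixEffectResult] = None
    matrix_effect_high: Optional[MatrixEffectResult] = None
    stability: dict[str, StabilityResult] = {}
    dilution: Optional[DilutionResult] = None
    interconversion: dict[str, InterconversionResult] = {}
    missing: tuple[str, ...] = ()

    @property
    def validated(self) -> bool:
        """True when every computed battery passes and none is missing."""
        flags = self.pass_flags()
        return not self.missing and all(flags.values())

    def pass_flags(self) -> dict[str, bool]:
        flags: dict[str, bool] = {}
        if self.selectivity is not None:
            flags["selectivity"] = self.selectivity.passed
        if self.calibration_accepted is not None:
            flags["calibration"] = self.calibration_accepted
        if self.lloq_check is not None:
            flags["lloq"] = self.lloq_check.passed
        if self.carryover is not None:
            flags["carryover"] = self.carryover.passed
        if self.accuracy_precision is not None:
            flags["accuracy_precision"] = self.accuracy_precision.passed
        if self.matrix_effect_low is not None:
            flags["matrix_effect_low"] = self.matrix_effect_low.passed
        if self.matrix_effect_high is not None:
            flags["matrix_effect_high"] = self.matrix_effect_high.passed
        for cond, st in self.stability.items():
            flags[f"stability_{cond}"] = st.passed
        if self.dilution is not None:
            flags["dilution"] = self.dilution.passed
        for cond, ic in self.interconversion.items():
            flags[f"interconversion_{cond}"] = ic.within_bound
        return flags

    def to_text(self) -> str:
        """Human-readable aligned table (one decimal display rounding)."""
        lines = [f"Validation summary — {self.analyte}", "=" * 40]

        def row(label: str, value: str, ok: bool | None = None) -> None:
            flag = "" if ok is None else ("  PASS" if ok else "  FAIL")
            lines.append(f"{label:<38}{value:>10}{flag}")

        if self.selectivity:
            worst = max(self.selectivity.per_lot_analyte_pct.values())
            row("Selectivity, worst lot (% LLOQ)", f"{worst:.1f}", self.selectivity.passed)
            worst_is = max(self.selectivity.per_lot_is_pct.values())
            row("Selectivity, worst lot IS (% IS)", f"{worst_is:.2f}")
        if self.calibration_r is not None:
            row("Calibration r", f"{self.calibration_r:.4f}", self.calibration_accepted)
        if self.dilution:
            row("Dilution accuracy (%)", f"{self.dilution.stats.accuracy_pct:.1f}", self.dilution.passed)
            row("Dilution CV (%)", f"{self.dilution.stats.cv_pct:.1f}")
        if self.carryover:
            row("Carryover (% LLOQ)", f"{self.carryover.analyte_pct:.1f}", self.carryover.passed)
            row("Carryover IS (% IS)", f"{self.carryover.is_pct:.1f}")
        for tag, me in (("low", self.matrix_effect_low), ("high", self.matrix_effect_high)):
            if me:
                row(f"IS-normalised ME mean, {tag} QC (%)", f"{me.mean_pct:.1f}", me.passed)
                row(f"IS-normalised ME CV, {tag} QC (%)", f"{me.cv_pct:.1f}")
                row(f"Recovery mean, {tag} QC (%)", f"{me.recovery_mean_pct:.1f}")
        if self.accuracy_precision:
            for level, st in self.accuracy_precision.between_run.items():
                row(f"Between-run accuracy, {level} (%)", f"{st.accuracy_pct:.1f}")
                row(f"Between-run CV, {level} (%)", f"{st.cv_pct:.1f}")
            row("Accuracy/precision battery", "", self.accuracy_precision.passed)
        for cond, st in self.stability.items():
            for level, pct in st.pct_nominal.items():
                row(f"Stability {cond}, {level} (% nominal)", f"{pct:.1f}", st.passed)
        for cond, ic in self.interconversion.items():
            row(
                f"Interconversion {cond} ({ic.direction})",
                f"{ic.conversion_pct:.2f}%",
                ic.within_bound,
            )
        if self.missing:
            lines.append(f"MISSING batteries: {', '.join(self.missing)}")
        lines.append(f"{'Overall validated':<38}{str(self.validated):>10}")
        return "\n".join(lines)


def build_validation_report(
    analyte: str,
    thresholds: Thresholds | None = None,
    *,
    selectivity: SelectivityResult | None = None,
    fit: CalibrationFit | None = None,
    lloq_check: LloqCheckResult | None = None,
    carryover: CarryoverResult | None = None,
    accuracy_precision: AccuracyPrecisionResult | None = None,
    matrix_effect_low: MatrixEffectResult | None = None,
    matrix_effect_high: MatrixEffectResult | None = None,
    stability: Mapping[str, StabilityResult] | None = None,
    dilution: DilutionResult | None = None,
    interconversion: Mapping[str, InterconversionResult] | None = None,
    expected: Sequence[str] = (
        "selectivity",
        "calibration",
        "lloq_check",
        "carryover",
        "accuracy_precision",
        "matrix_effect_low",
        "matrix_effect_high",
        "dilution",
    ),
) -> ValidationReport:
    """Assemble the per-analyte report; absent batteries are listed in
    ``missing`` (a partial report is allowed but cannot be 'validated')."""
    thresholds = thresholds or Thresholds()
    provided = {
        "selectivity": selectivity,
        "calibration": fit,
        "lloq_check": lloq_check,
        "carryover": carryover,
        "accuracy_precision": accuracy_precision,
        "matrix_effect_low": matrix_effect_low,
        "matrix_effect_high": matrix_effect_high,
        "dilution": dilution,
    }
    missing = tuple(name for name in expected if provided.get(name) is None)
    return ValidationReport(
        analyte=analyte,
        thresholds=thresholds,
        selectivity=selectivity,
        calibration_r=fit.r if fit else None,
        calibration_accepted=fit.accepted if fit else None,
        lloq_check=lloq_check,
        carryover=carryover,
        accuracy_precision=accuracy_precision,
        matrix_effect_low=matrix_effect_low,
        matrix_effect_high=matrix_effect_high,
        stability=dict(stability or {}),
        dilution=dilution,
        interconversion=dict(interconversion or {}),
        missing=missing,
    )


def run_validation_battery(
    runs: Mapping[str, Sequence[PeakRecord]],
    spec: AnalyteSpec,
    thresholds: Thresholds | None = None,
    dilution_factor: float = 20.0,
) -> ValidationReport:
    """Run the whole battery on raw per-run peak records for one analyte.

    Each run is expected to carry its own calibration standards; the
    single-run batteries (selectivity, carryover, matrix effect,
    stability, dilution) are evaluated on the first run, the
    accuracy/precision battery across all runs.
    """
    from .assay import fit_calibration

    thresholds = thresholds or Thresholds()
    runs = {rid: [r for r in recs if r.analyte == spec.name] for rid, recs in runs.items()}
    fits = {rid: fit_calibration(recs, spec, thresholds) for rid, recs in runs.items()}
    first_id = next(iter(runs))
    first, fit = runs[first_id], fits[first_id]

    def of_role(role: Role, recs=None) -> list[PeakRecord]:
        return [r for r in (first if recs is None else recs) if r.role is role]

    double_blanks = of_role(Role.DOUBLE_BLANK)
    blanks_with_is = of_role(Role.BLANK_WITH_IS)
    lloq_qcs = [r for r in of_role(Role.QC) if math.isclose(r.nominal_conc, spec.lloq, rel_tol=1e-9)]

    selectivity = assess_selectivity(double_blanks, lloq_qcs, blanks_with_is, thresholds)
    lloq_res = check_lloq(lloq_qcs, double_blanks, thresholds)
    mean_lloq_area = _mean_area(lloq_qcs, "analyte_area")
    mean_is_area = _mean_area(blanks_with_is, "is_area")
    carry_recs = of_role(Role.CARRYOVER_BLANK)
    carryover = (
        assess_carryover(carry_recs[0], mean_lloq_area, mean_is_area, thresholds)
        if carry_recs
        else None
    )
    accuracy = accuracy_precision_battery(runs, fits, spec, thresholds)

    me_results: dict[str, MatrixEffectResult] = {}
    for tag, level in (("low", spec.qc_low), ("high", spec.qc_high)):
        at_level = lambda recs: [
            r for r in recs if math.isclose(r.nominal_conc, level, rel_tol=1e-9)
        ]
        neat = at_level(of_role(Role.NEAT_SOLUTION))
        post = at_level(of_role(Role.POST_EXTRACTION_SPIKED))
        pre = at_level(of_role(Role.PRE_EXTRACTION_SPIKED))
        if neat and post and pre:
            me_results[tag] = matrix_effect_recovery(neat, post, pre, thresholds)

    stability: dict[str, StabilityResult] = {}
    for condition in sorted({r.condition for r in of_role(Role.STABILITY) if r.condition}):
        stressed = [r for r in of_role(Role.STABILITY) if r.condition == condition]
        stability[condition] = stability_assessment(condition, stressed, fit, thresholds)

    dil_recs = of_role(Role.DILUTION)
    dilution = dilution_integrity(dil_recs, dilution_factor, fit, thresholds) if dil_recs else None

    return build_validation_report(
        spec.name,
        thresholds,
        selectivity=selectivity,
        fit=fit,
        lloq_check=lloq_res,
        carryover=carryover,
        accuracy_precision=accuracy,
        matrix_effect_low=me_results.get("low"),
        matrix_effect_high=me_results.get("high"),
        stability=stability,
        dilution=dilution,
    )
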