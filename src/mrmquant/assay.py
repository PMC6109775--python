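"""Assay configuration and weighted calibration-curve fitting.

Quantification in a targeted LC-MS/MS assay goes through the analyte/IS
peak-area ratio: each analyte is paired with a stable-isotope-labelled
internal standard (IS), and the response ``y = analyte_area / is_area`` is
regressed on nominal concentration ``x`` with weighted least squares.
Detector noise in this kind of assay is close to proportional to signal, so
the standard weighting schemes ``1/x`` and ``1/x**2`` are used; a quadratic
model absorbs the mild detector saturation seen for the high-range analyte.
Unknowns are quantified by inverting the fitted curve (back-calculation).
"""

from __future__ import annotations

import enum
import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import (
    ConfigError,
    DegenerateDesignError,
    FitRejectedError,
    InversionError,
    UndefinedRatioError,
    WeightingDomainError,
)

__all__ = [
    "Role",
    "AnalyteSpec",
    "PeakRecord",
    "CalibrationFit",
    "StandardPoint",
    "weight_function",
    "fit_calibration",
    "predict_response",
    "back_calculate",
    "evaluate_standards",
]


class Role(str, enum.Enum):
    """What a single injection is, within the run design."""

    DOUBLE_BLANK = "double_blank"
    BLANK_WITH_IS = "blank_with_is"
    CALIBRATION_STANDARD = "calibration_standard"
    QC = "qc"
    CARRYOVER_BLANK = "carryover_blank"
    NEAT_SOLUTION = "neat_solution"
    POST_EXTRACTION_SPIKED = "post_extraction_spiked"
    PRE_EXTRACTION_SPIKED = "pre_extraction_spiked"
    STABILITY = "stability"
    DILUTION = "dilution"
    PATIENT = "patient"


#: Roles whose records must carry a nominal concentration.
_ROLES_WITH_NOMINAL = {
    Role.CALIBRATION_STANDARD,
    Role.QC,
    Role.STABILITY,
    Role.DILUTION,
}


class AnalyteSpec(BaseModel):
    """One analyte's calibration/QC design and model choices.

    Concentrations are ng/mL throughout. The LLOQ is by construction the
    lowest calibration standard and the ULOQ the highest, so both may be
    omitted and are then derived from ``calibration_levels``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    calibration_levels: tuple[float, ...]
    qc_low: float
    qc_mid: float
    qc_high: float
    lloq: Optional[float] = None
    uloq: Optional[float] = None
    model_order: Literal["linear", "quadratic"] = "linear"
    weighting: Literal["1/x", "1/x^2"] = "1/x"
    is_name: str = ""
    retention_time_min: Optional[float] = None
    mrm_transition: Optional[str] = None

    @model_validator(mode="after")
    def _check_design(self) -> "AnalyteSpec":
        levels = self.calibration_levels
        if len(levels) < 2:
            raise ConfigError(f"{self.name}: need at least two calibration levels")
        if any(c <= 0 for c in levels):
            raise ConfigError(
                f"{self.name}: calibration levels must be strictly positive "
                "(1/x-family weights are undefined at zero)"
            )
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigError(f"{self.name}: calibration levels must be strictly increasing")
        lo, hi = levels[0], levels[-1]
        object.__setattr__(self, "lloq", lo if self.lloq is None else self.lloq)
        object.__setattr__(self, "uloq", hi if self.uloq is None else self.uloq)
        if self.lloq != lo:
            raise ConfigError(f"{self.name}: lloq {self.lloq} != lowest calibration level {lo}")
        if self.uloq != hi:
            raise ConfigError(f"{self.name}: uloq {self.uloq} != highest calibration level {hi}")
        for qc in (self.qc_low, self.qc_mid, self.qc_high):
            if qc <= 0:
                raise ConfigError(f"{self.name}: QC levels must be strictly positive")
        if not (self.qc_low > self.lloq):
            raise ConfigError(f"{self.name}: QC low ({self.qc_low}) must exceed the LLOQ ({self.lloq})")
        if not (self.qc_high < self.uloq):
            raise ConfigError(f"{self.name}: QC high ({self.qc_high}) must be below the ULOQ ({self.uloq})")
        if not (self.qc_low < self.qc_mid < self.qc_high):
            raise ConfigError(f"{self.name}: QC levels must be ordered low < mid < high")
        return self

    @property
    def qc_levels(self) -> tuple[float, float, float]:
        return (self.qc_low, self.qc_mid, self.qc_high)


class PeakRecord(BaseModel):
    """One injection's integrated peak areas for one analyte.

    ``analyte_area`` and ``is_area`` are detector counts from upstream peak
    integration; ``nominal_conc`` is the known spiked concentration for
    roles that have one.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    analyte: str
    role: Role
    nominal_conc: Optional[float] = None
    analyte_area: float = Field(ge=0.0)
    is_area: Optional[float] = Field(default=None, ge=0.0)
    run_id: str = "run1"
    matrix_lot: Optional[str] = None
    condition: Optional[str] = None

    @model_validator(mode="after")
    def _check_role(self) -> "PeakRecord":
        if self.role in _ROLES_WITH_NOMINAL and self.nominal_conc is None:
            raise ConfigError(
                f"record {self.sample_id}: role {self.role.value} requires a nominal concentration"
            )
        return self


class StandardPoint(BaseModel):
    """Back-calculated result for one calibration standard."""

    nominal: float
    back_calculated: float
    accuracy_pct: float


class CalibrationFit(BaseModel):
    """A fitted calibration curve ``y = a0 + a1*x + a2*x**2``.

    ``r`` is the signed square root of the weighted coefficient of
    determination (weighted residual vs weighted total sum of squares about
    the weighted mean response), taking the sign of the slope.
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    a0: float
    a1: float
    a2: float = 0.0
    weighting: Literal["1/x", "1/x^2"]
    r: float
    standards_back_calc: tuple[StandardPoint, ...] = ()
    accepted: bool = True
    lloq: float
    uloq: float

    @model_validator(mode="after")
    def _check(self) -> "CalibrationFit":
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ConfigError(f"r = {self.r} outside [-1, 1]")
        return self

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a0, self.a1, self.a2)


def weight_function(weighting: str) -> "np.ufunc":
    """Return w(x) for a weighting scheme name ('1/x' or '1/x^2')."""
    if weighting == "1/x":
        return np.reciprocal
    if weighting in ("1/x^2", "1/x2", "1/x**2"):
        return lambda x: 1.0 / np.square(x)
    raise ConfigError(f"unknown weighting scheme {weighting!r}")


def _is_monotone_increasing(a1: float, a2: float, lo: float, hi: float) -> bool:
    # derivative a1 + 2*a2*x is linear in x: check the endpoints
    return (a1 + 2.0 * a2 * lo) > 0.0 and (a1 + 2.0 * a2 * hi) > 0.0


def fit_calibration(
    standards: Sequence[PeakRecord],
    spec: AnalyteSpec,
    thresholds=None,
) -> CalibrationFit:
    """Fit the weighted calibration curve for one analyte.

    All calibration-standard records passed in are pooled into a single fit
    (an analytical run carries a full calibration line at the beginning and
    at the end; pooling the duplicates uses all information and is
    injection-order independent). Minimises
    ``sum(w(x_i) * (y_i - yhat_i)**2)`` with ``y = analyte_area / is_area``
    and ``w`` per the analyte's weighting scheme.

    Parameters
    ----------
    standards
        Calibration-standard records for this analyte (other roles and
        other analytes are ignored).
    spec
        The analyte's design; fixes model order, weighting and range.
    thresholds
        Optional :class:`~mrmquant.validation.Thresholds` used for the
        standard acceptance rule; defaults apply when omitted.

    Raises
    ------
    DegenerateDesignError
        Fewer distinct levels than the model order requires.
    WeightingDomainError
        A standard has a non-positive nominal concentration.
    UndefinedRatioError
        A standard has a zero or missing internal-standard area.
    FitRejectedError
        The fitted curve is not strictly increasing on [LLOQ, ULOQ].
    """
    pts = [
        rec
        for rec in standards
        if rec.role is Role.CALIBRATION_STANDARD and rec.analyte == spec.name
    ]
    if not pts:
        raise DegenerateDesignError(f"{spec.name}: no calibration-standard records supplied")
    for rec in pts:
        if rec.nominal_conc is None or rec.nominal_conc <= 0:
            raise WeightingDomainError(
                f"{spec.name}: standard {rec.sample_id} has non-positive nominal "
                f"concentration {rec.nominal_conc}"
            )
        if not rec.is_area:
            raise UndefinedRatioError(f"{spec.name}: standard {rec.sample_id} has no IS area")

    x = np.array([rec.nominal_conc for rec in pts], dtype=float)
    y = np.array([rec.analyte_area / rec.is_area for rec in pts], dtype=float)

    n_params = 2 if spec.model_order == "linear" else 3
    n_distinct = len(np.unique(x))
    if n_distinct < n_params + 1:
        raise DegenerateDesignError(
            f"{spec.name}: {n_distinct} distinct levels < {n_params + 1} required "
            f"for a {spec.model_order} fit"
        )

    w = weight_function(spec.weighting)(x)
    sw = np.sqrt(w)
    cols = [np.ones_like(x), x] + ([x**2] if n_params == 3 else [])
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    a0, a1 = float(beta[0]), float(beta[1])
    a2 = float(beta[2]) if n_params == 3 else 0.0

    if not _is_monotone_increasing(a1, a2, spec.lloq, spec.uloq):
        raise FitRejectedError(
            f"{spec.name}: fitted response is not strictly increasing on "
            f"[{spec.lloq}, {spec.uloq}] (a1={a1:.4g}, a2={a2:.4g})"
        )

    yhat = design @ beta
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r = math.copysign(math.sqrt(min(max(r2, 0.0), 1.0)), a1)

    fit = CalibrationFit(
        analyte=spec.name,
        a0=a0,
        a1=a1,
        a2=a2,
        weighting=spec.weighting,
        r=r,
        accepted=True,
        lloq=spec.lloq,
        uloq=spec.uloq,
    )
    points = tuple(
        StandardPoint(
            nominal=float(xi),
            back_calculated=(bc := _invert(fit, float(yi))),
            accuracy_pct=bc / float(xi) * 100.0,
        )
        for xi, yi in zip(x, y)
    )
    fit = fit.model_copy(update={"standards_back_calc": points})
    accepted = evaluate_standards(fit, spec, thresholds)
    return fit.model_copy(update={"accepted": accepted})


def predict_response(fit: CalibrationFit, conc: float) -> float:
    """Forward model: expected analyte/IS ratio at a concentration."""
    if conc < 0:
        raise ConfigError(f"negative concentration {conc}")
    return fit.a0 + fit.a1 * conc + fit.a2 * conc * conc


def _invert(fit: CalibrationFit, y: float) -> float:
    """Invert the calibration model at response ratio ``y``.

    For a quadratic, the root on the increasing branch inside
    [0, 1.2*ULOQ] is selected; responses above the ULOQ belong to diluted
    re-assay, not to extrapolation.
    """
    if fit.a2 == 0.0:
        if fit.a1 == 0.0:
            raise InversionError(f"{fit.analyte}: zero slope, cannot invert")
        return (y - fit.a0) / fit.a1
    disc = fit.a1 * fit.a1 - 4.0 * fit.a2 * (fit.a0 - y)
    if disc < 0:
        raise InversionError(
            f"{fit.analyte}: no real root at ratio y={y:.6g} (discriminant {disc:.3g})"
        )
    sq = math.sqrt(disc)
    hi = 1.2 * fit.uloq
    tol = 1e-9 * max(1.0, fit.uloq)
    candidates = [(-fit.a1 + sq) / (2.0 * fit.a2), (-fit.a1 - sq) / (2.0 * fit.a2)]
    admissible = [
        x
        for x in candidates
        if (fit.a1 + 2.0 * fit.a2 * x) > 0.0 and -tol <= x <= hi + tol
    ]
    if not admissible:
        raise InversionError(
            f"{fit.analyte}: no root on the increasing branch within [0, {hi:.6g}] "
            f"at ratio y={y:.6g} (candidates {candidates})"
        )
    return max(admissible[0], 0.0)


def back_calculate(
    fit: CalibrationFit,
    analyte_area: float,
    is_area: float,
    dilution_factor: float = 1.0,
) -> float:
    """Back-calculate a concentration (ng/mL) from peak areas.

    The analyte/IS ratio is inverted through the calibration model; the
    result is multiplied by ``dilution_factor`` (e.g. 20 for samples
    diluted 20-fold in blank plasma before extraction).
    """
    if is_area is None or is_area == 0:
        raise UndefinedRatioError(f"{fit.analyte}: IS area is zero, ratio undefined")
    if dilution_factor <= 0:
        raise ConfigError(f"dilution factor must be positive, got {dilution_factor}")
    return _invert(fit, analyte_area / is_area) * dilution_factor


def evaluate_standards(fit: CalibrationFit, spec: AnalyteSpec, thresholds=None) -> bool:
    """Acceptance decision for a fitted calibration line.

    A standard passes when its back-calculated accuracy is within +/-15% of
    nominal (+/-20% at the LLOQ, inclusive); the curve is accepted when at
    least 75% of standards, and at least six, pass.
    """
    if thresholds is None:
        from .validation import Thresholds

        thresholds = Thresholds()
    if not fit.standards_back_calc:
        raise ConfigError(f"{fit.analyte}: fit carries no back-calculated standards")
    n_pass = 0
    for pt in fit.standards_back_calc:
        tol = (
            thresholds.lloq_accuracy_pct
            if pt.nominal == spec.lloq
            else thresholds.qc_accuracy_pct
        )
        if abs(pt.accuracy_pct - 100.0) <= tol:
            n_pass += 1
    n = len(fit.standards_back_calc)
    return n_pass >= 6 and n_pass / n >= 0.75
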