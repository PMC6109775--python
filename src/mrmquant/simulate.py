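"""Synthetic peak-area and cohort generators.

Emulates the statistical structure the analysis layer assumes, so the
whole pipeline is exercisable with no instrument or patient data:

* heteroscedastic detector noise proportional to signal (constant CV) —
  the structure that motivates 1/x-family weighting in the first place;
* per-matrix-lot ionisation suppression/enhancement (multiplicative ME
  factors, shared between analyte and IS through a coupling exponent, so
  IS-normalised ME sits near 100% when coupling is 1);
* extraction recovery applied to analyte and IS alike (both pass through
  the extraction when spiked pre-extraction, so recovery cancels in the
  analyte/IS ratio, as it does on a real instrument);
* carryover into the blank injected immediately after the top standard;
* blank matrix background counts and mild detector saturation (negative
  quadratic term) for the high-range analyte;
* acid<->lactone interconversion as a pre-noise transfer of
  concentration-equivalent response between paired species;
* log-normal per-dose patient concentrations with between-visit
  correlation, a non-adherent near-zero mixture component, and a
  storage-duration drift on the log10 scale.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .assay import AnalyteSpec, PeakRecord, Role
from .errors import ConfigError, PairingError
from .cohort import CohortRecord

__all__ = [
    "AnalyteSimConfig",
    "DoseGroup",
    "CohortSimConfig",
    "SimulationConfig",
    "STABILITY_CONDITIONS",
    "default_sim_config",
    "default_cohort_config",
    "simulate_validation_run",
    "simulate_validation_study",
    "simulate_qc_replicates",
    "simulate_interconversion",
    "simulate_cohort",
]

STABILITY_CONDITIONS = ("benchtop_4h", "freeze_thaw_3", "long_term_3m", "autosampler_24h")

MATRIX_LOTS = ("lot1", "lot2", "lot3", "lot4", "lot5", "lot6")


class AnalyteSimConfig(BaseModel):
    """Detector/extraction model for one analyte.

    Response coefficients are in ratio units per ng/mL; areas in counts.
    The defaults put every analyte's LLOQ response near 2000 counts over a
    150-count matrix background, proportional noise at 5% CV, recovery at
    95%, and six matrix lots whose ME factors include two extremes
    standing in for a lipaemic and a haemolysed donor.
    """

    model_config = ConfigDict(frozen=True)

    a0: float = 0.0
    a1: float = Field(gt=0.0)
    a2: float = 0.0
    noise_cv_pct: float = Field(default=5.0, ge=0.0)
    is_noise_cv_pct: float = Field(default=2.0, ge=0.0)
    blank_background: float = Field(default=150.0, ge=0.0)
    is_blank_background: float = Field(default=50.0, ge=0.0)
    is_nominal_area: float = Field(default=1e5, gt=0.0)
    lot_me_factors: tuple[float, ...] = (1.0, 0.95, 1.05, 0.9, 0.8, 1.15)
    me_is_coupling: float = 1.0
    recovery: float = Field(default=0.95, ge=0.0, le=1.2)
    carryover_fraction: float = Field(default=2e-4, ge=0.0)
    dilution_nominal: float = Field(gt=0.0)
    dilution_factor: float = Field(default=20.0, gt=0.0)
    stability_factors: dict[str, float] = {}  # condition -> multiplicative drift
    lactone_partner: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "AnalyteSimConfig":
        if any(f <= 0 for f in self.lot_me_factors):
            raise ConfigError("lot ME factors must be positive")
        return self


class DoseGroup(BaseModel):
    model_config = ConfigDict(frozen=True)

    dose_mg: float
    weight: float = 1.0
    log10_mean: float
    log10_sd: float = 0.4


class CohortSimConfig(BaseModel):
    """Cohort generator for one analyte/drug.

    True per-visit log10 concentrations are bivariate normal with
    between-visit correlation ``rho``; non-adherent patients are drawn
    from a near-zero mixture component that falls below the LLOQ with
    high probability. Storage drift adds ``b_true * storage_days`` to the
    M1 log10 concentration; storage duration is normal (clipped >= 1 day)
    around a multi-year mean, as in long-banked biobank plasma.
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    drug: str
    doses: tuple[DoseGroup, ...]
    rho: float = Field(default=0.5, ge=-1.0, le=1.0)
    adherence_rate: float = Field(default=0.95, ge=0.0, le=1.0)
    nonadherent_log10_mean: float = -1.3
    nonadherent_log10_sd: float = 0.5
    b_true: float = 0.0  # log10 ng/mL per storage day
    storage_mean_days: float = 2317.0
    storage_sd_days: float = 470.0
    m12_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    measurement_cv_pct: float = Field(default=5.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CohortSimConfig":
        if not self.doses:
            raise ConfigError(f"{self.analyte}: empty dose distribution")
        if any(d.weight < 0 for d in self.doses) or sum(d.weight for d in self.doses) <= 0:
            raise ConfigError(f"{self.analyte}: invalid dose weights")
        return self


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    analytes: dict[str, AnalyteSimConfig]
    cohort: dict[str, CohortSimConfig] = {}


def default_sim_config(noise_cv_pct: float = 5.0) -> SimulationConfig:
    """Simulation defaults for the six-analyte assay.

    Slopes reflect each IS's working concentration (the analyte/IS ratio
    is near concentration/IS-concentration); the high-range analyte
    (clopidogrel carboxylic acid) carries a mild saturating quadratic
    term. Dilution-integrity spikes sit 8-20x above each ULOQ.
    """

    def cfg(a1: float, dilution_nominal: float, a2: float = 0.0, partner: str | None = None):
        return AnalyteSimConfig(
            a1=a1,
            a2=a2,
            noise_cv_pct=noise_cv_pct,
            dilution_nominal=dilution_nominal,
            lactone_partner=partner,
        )

    return SimulationConfig(
        analytes={
            "ATV": cfg(0.04, 1000.0, partner="ATV L"),
            "2-OH ATV": cfg(0.04, 1000.0, partner="2-OH ATV L"),
            "ATV L": cfg(1.0 / 55.0, 800.0),
            "2-OH ATV L": cfg(1.0 / 55.0, 1000.0),
            "BSP": cfg(0.04, 1000.0),
            "CLP-CA": cfg(1.0 / 750.0, 30000.0, a2=-4e-8),
        },
        cohort={name: c for name, c in default_cohort_config().items()},
    )


def noiseless_sim_config() -> SimulationConfig:
    """Zero noise, unit ME/recovery, no background or carryover.

    Under this configuration the full pipeline is an exact identity:
    back-calculated concentrations equal the injected truths.
    """
    base = default_sim_config(noise_cv_pct=0.0)
    clean = {
        name: cfg.model_copy(
            update=dict(
                is_noise_cv_pct=0.0,
                blank_background=0.0,
                is_blank_background=0.0,
                lot_me_factors=(1.0,) * 6,
                me_is_coupling=1.0,
                recovery=1.0,
                carryover_fraction=0.0,
            )
        )
        for name, cfg in base.analytes.items()
    }
    return base.model_copy(update={"analytes": clean})


def default_cohort_config() -> dict[str, CohortSimConfig]:
    """Cohort scenarios for the six analytes at realistic dose mixes.

    Per-dose log10 means sit where this drug class's steady-state medians
    do (single-digit ng/mL for the statins and beta blocker, high hundreds
    for the clopidogrel metabolite); spreads near 0.4 log10 units
    reproduce the wide IQRs of sparse real-world sampling.
    """
    atv_doses = (
        DoseGroup(dose_mg=40, weight=44, log10_mean=np.log10(4.86)),
        DoseGroup(dose_mg=80, weight=674, log10_mean=np.log10(5.67)),
    )
    return {
        "ATV": CohortSimConfig(analyte="ATV", drug="atorvastatin", doses=atv_doses, rho=0.35),
        "2-OH ATV": CohortSimConfig(
            analyte="2-OH ATV",
            drug="atorvastatin",
            doses=(
                DoseGroup(dose_mg=40, weight=44, log10_mean=np.log10(5.85)),
                DoseGroup(dose_mg=80, weight=674, log10_mean=np.log10(7.49)),
            ),
            rho=0.29,
        ),
        "ATV L": CohortSimConfig(
            analyte="ATV L",
            drug="atorvastatin",
            doses=(
                DoseGroup(dose_mg=40, weight=44, log10_mean=np.log10(3.98)),
                DoseGroup(dose_mg=80, weight=674, log10_mean=np.log10(4.94)),
            ),
            rho=0.32,
        ),
        "2-OH ATV L": CohortSimConfig(
            analyte="2-OH ATV L",
            drug="atorvastatin",
            doses=(
                DoseGroup(dose_mg=40, weight=44, log10_mean=np.log10(4.64)),
                DoseGroup(dose_mg=80, weight=674, log10_mean=np.log10(7.49)),
            ),
            rho=0.27,
        ),
        "BSP": CohortSimConfig(
            analyte="BSP",
            drug="bisoprolol",
            doses=(
                DoseGroup(dose_mg=1.25, weight=141, log10_mean=np.log10(5.67)),
                DoseGroup(dose_mg=2.5, weight=320, log10_mean=np.log10(10.83)),
                DoseGroup(dose_mg=5.0, weight=174, log10_mean=np.log10(23.14)),
                DoseGroup(dose_mg=10.0, weight=50, log10_mean=np.log10(43.93)),
            ),
            rho=0.64,
        ),
        "CLP-CA": CohortSimConfig(
            analyte="CLP-CA",
            drug="clopidogrel",
            doses=(DoseGroup(dose_mg=75, weight=1, log10_mean=np.log10(736.94)),),
            rho=0.26,
        ),
    }


def _response(cfg: AnalyteSimConfig, conc: float) -> float:
    return cfg.a0 + cfg.a1 * conc + cfg.a2 * conc * conc


def _noise(rng: np.random.Generator, cv_pct: float) -> float:
    # one draw consumed regardless of CV, so the stream layout is stable
    eps = rng.standard_normal()
    return max(1.0 + eps * cv_pct / 100.0, 0.0)


def _make_record(
    cfg: AnalyteSimConfig,
    analyte: str,
    rng: np.random.Generator,
    *,
    sample_id: str,
    role: Role,
    conc: float,
    run_id: str,
    matrix_lot: str | None = None,
    condition: str | None = None,
    me_factor: float = 1.0,
    in_matrix: bool = True,
    extracted: bool = True,
    with_is: bool = True,
    nominal_conc: float | None = None,
    scale: float = 1.0,
) -> PeakRecord:
    """Synthesize one injection.

    ``extracted`` applies recovery to analyte and IS alike (both species
    pass through the extraction), so recovery cancels in the ratio;
    ``in_matrix`` switches the matrix background on.
    """
    recovery = cfg.recovery if extracted else 1.0
    me_is = me_factor**cfg.me_is_coupling
    bg = cfg.blank_background if in_matrix else 0.0
    is_bg = cfg.is_blank_background if in_matrix else 0.0
    analyte_area = (
        _response(cfg, conc) * cfg.is_nominal_area * me_factor * recovery * _noise(rng, cfg.noise_cv_pct)
        + bg * _noise(rng, cfg.noise_cv_pct)
    ) * scale
    if with_is:
        is_area = cfg.is_nominal_area * me_is * recovery * _noise(rng, cfg.is_noise_cv_pct) * scale
    else:
        is_area = is_bg * _noise(rng, cfg.is_noise_cv_pct) * scale
    return PeakRecord(
        sample_id=sample_id,
        analyte=analyte,
        role=role,
        nominal_conc=nominal_conc,
        analyte_area=analyte_area,
        is_area=is_area,
        run_id=run_id,
        matrix_lot=matrix_lot,
        condition=condition,
    )


def simulate_validation_run(
    spec: AnalyteSpec,
    sim: SimulationConfig,
    seed: int,
    run_id: str = "run1",
    n_replicates: int = 6,
    n_me_replicates: int = 3,
    stability_conditions: Sequence[str] = STABILITY_CONDITIONS,
) -> list[PeakRecord]:
    """One full validation run's worth of injections for one analyte.

    Emits, in injection-plausible order: six-lot double blanks and blanks
    with IS, a full calibration line, the carryover blank right after the
    top standard, a second full calibration line, LLOQ+QC replicates,
    six-lot neat / post-extraction / pre-extraction ME sets at low and
    high QC, stability replicates per condition, and the
    dilution-integrity set. Deterministic given (config, seed).
    """
    if spec.name not in sim.analytes:
        raise ConfigError(f"no simulation config for analyte {spec.name!r}")
    cfg = sim.analytes[spec.name]
    rng = np.random.default_rng(seed)
    records: list[PeakRecord] = []
    mk = lambda **kw: records.append(_make_record(cfg, spec.name, rng, run_id=run_id, **kw))

    for lot in MATRIX_LOTS:
        mk(sample_id=f"{run_id}-dblank-{lot}", role=Role.DOUBLE_BLANK, conc=0.0,
           matrix_lot=lot, with_is=False)
    for lot in MATRIX_LOTS:
        mk(sample_id=f"{run_id}-blank-{lot}", role=Role.BLANK_WITH_IS, conc=0.0, matrix_lot=lot)

    for line in ("A", "B"):
        for level in spec.calibration_levels:
            mk(sample_id=f"{run_id}-cal{line}-{level:g}", role=Role.CALIBRATION_STANDARD,
               conc=level, nominal_conc=level)
        if line == "A":
            # solvent blank injected immediately after the top standard
            uloq_resp = _response(cfg, spec.uloq) * cfg.is_nominal_area * cfg.recovery
            rec = PeakRecord(
                sample_id=f"{run_id}-carryover",
                analyte=spec.name,
                role=Role.CARRYOVER_BLANK,
                analyte_area=cfg.carryover_fraction * uloq_resp * _noise(rng, cfg.noise_cv_pct),
                is_area=cfg.carryover_fraction * cfg.is_nominal_area * _noise(rng, cfg.is_noise_cv_pct),
                run_id=run_id,
            )
            records.append(rec)

    qc_levels = {"lloq": spec.lloq, "low": spec.qc_low, "medium": spec.qc_mid, "high": spec.qc_high}
    for name, level in qc_levels.items():
        for i in range(n_replicates):
            mk(sample_id=f"{run_id}-qc-{name}-{i + 1}", role=Role.QC, conc=level,
               nominal_conc=level)

    for tag, level in (("low", spec.qc_low), ("high", spec.qc_high)):
        for i in range(n_replicates):
            mk(sample_id=f"{run_id}-neat-{tag}-{i + 1}", role=Role.NEAT_SOLUTION, conc=level,
               nominal_conc=level, in_matrix=False, extracted=False)
        for lot, me in zip(MATRIX_LOTS, cfg.lot_me_factors):
            for i in range(n_me_replicates):
                mk(sample_id=f"{run_id}-post-{tag}-{lot}-{i + 1}", role=Role.POST_EXTRACTION_SPIKED,
                   conc=level, nominal_conc=level, matrix_lot=lot, me_factor=me, extracted=False)
        for lot, me in zip(MATRIX_LOTS, cfg.lot_me_factors):
            for i in range(n_me_replicates):
                mk(sample_id=f"{run_id}-pre-{tag}-{lot}-{i + 1}", role=Role.PRE_EXTRACTION_SPIKED,
                   conc=level, nominal_conc=level, matrix_lot=lot, me_factor=me)

    for condition in stability_conditions:
        drift = cfg.stability_factors.get(condition, 1.0)
        for tag, level in (("low", spec.qc_low), ("high", spec.qc_high)):
            for i in range(n_replicates):
                mk(sample_id=f"{run_id}-stab-{condition}-{tag}-{i + 1}", role=Role.STABILITY,
                   conc=level * drift, nominal_conc=level, condition=condition)

    diluted = cfg.dilution_nominal / cfg.dilution_factor
    for i in range(n_replicates):
        mk(sample_id=f"{run_id}-dil-{i + 1}", role=Role.DILUTION, conc=diluted,
           nominal_conc=cfg.dilution_nominal)

    return records


def simulate_validation_study(
    spec: AnalyteSpec,
    sim: SimulationConfig,
    seed: int,
    n_runs: int = 3,
    **kwargs,
) -> dict[str, list[PeakRecord]]:
    """Three independent runs (separate days/operators in the design)."""
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    return {
        f"run{i + 1}": simulate_validation_run(
            spec, sim, seed=int(s.generate_state(1)[0] % (2**31)), run_id=f"run{i + 1}", **kwargs
        )
        for i, s in enumerate(child_seeds)
    }


def simulate_qc_replicates(
    spec: AnalyteSpec,
    sim: SimulationConfig,
    conc: float,
    n: int,
    seed: int,
    run_id: str = "run1",
) -> list[PeakRecord]:
    """n QC replicates at one concentration (for distributional checks)."""
    cfg = sim.analytes[spec.name]
    rng = np.random.default_rng(seed)
    return [
        _make_record(
            cfg, spec.name, rng, sample_id=f"{run_id}-qcrep-{i + 1}", role=Role.QC,
            conc=conc, nominal_conc=conc, run_id=run_id,
        )
        for i in range(n)
    ]


def simulate_interconversion(
    records: Sequence[PeakRecord],
    rate_pct: float,
    direction: str,
    pairs: Mapping[str, str],
) -> list[PeakRecord]:
    """Transfer ``rate_pct`` of one species' concentration to its partner.

    ``pairs`` maps acid analyte name -> lactone analyte name. Operates on
    the nominal (true) concentrations of matched records — the transfer
    happens chemically before detection, so apply it before synthesizing
    areas. Records are matched by sample_id within each acid/lactone pair.
    """
    if rate_pct < 0:
        raise ConfigError("rate_pct must be >= 0")
    if direction not in ("acid_to_lactone", "lactone_to_acid"):
        raise ConfigError(f"unknown direction {direction!r}")
    lactone_of = dict(pairs)
    acid_of = {v: k for k, v in pairs.items()}
    paired_names = set(lactone_of) | set(acid_of)
    by_key: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(records):
        if rec.analyte in paired_names:
            by_key[(rec.sample_id, rec.analyte)] = i
    out = list(records)
    frac = rate_pct / 100.0
    for (sample_id, name), i in by_key.items():
        if name not in lactone_of:  # iterate acids only; partner handled jointly
            continue
        partner = lactone_of[name]
        j = by_key.get((sample_id, partner))
        if j is None:
            raise PairingError(f"sample {sample_id}: no {partner!r} record to pair with {name!r}")
        acid, lactone = records[i], records[j]
        a = acid.nominal_conc or 0.0
        l = lactone.nominal_conc or 0.0
        if direction == "acid_to_lactone":
            moved = a * frac
            new_a, new_l = a - moved, l + moved
        else:
            moved = l * frac
            new_a, new_l = a + moved, l - moved
        out[i] = acid.model_copy(update={"nominal_conc": new_a})
        out[j] = lactone.model_copy(update={"nominal_conc": new_l})
    return out


def simulate_cohort(
    n_patients: int,
    cfg: CohortSimConfig,
    seed: int,
) -> list[CohortRecord]:
    """Sparse-PK cohort records for one analyte.

    Every patient contributes an M1 record; a configurable fraction also
    contributes M12. Concentrations are log-normal per dose with
    between-visit correlation ``rho``; non-adherent patients come from the
    near-zero mixture component. The storage drift ``b_true`` acts on the
    M1 log10 concentration (M12 samples are analysed after much shorter
    storage and carry no storage_days here). Deterministic given
    (config, seed). Censoring flags are left False — run
    :func:`mrmquant.cohort.censor_below_lloq` afterwards.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([d.weight for d in cfg.doses], dtype=float)
    weights /= weights.sum()
    records: list[CohortRecord] = []
    # explicit bivariate construction; stays valid at rho = +/-1
    rho_ortho = math.sqrt(max(1.0 - cfg.rho**2, 0.0))
    for i in range(n_patients):
        dose_idx = int(rng.choice(len(cfg.doses), p=weights))
        dose = cfg.doses[dose_idx]
        adherent = bool(rng.random() < cfg.adherence_rate)
        z1, z2 = rng.standard_normal(2)
        z = np.array([z1, cfg.rho * z1 + rho_ortho * z2])
        if adherent:
            log10_true = dose.log10_mean + dose.log10_sd * z
        else:
            log10_true = cfg.nonadherent_log10_mean + cfg.nonadherent_log10_sd * z
        storage = max(float(rng.normal(cfg.storage_mean_days, cfg.storage_sd_days)), 1.0)
        has_m12 = bool(rng.random() < cfg.m12_fraction)
        noise = rng.standard_normal(2) * cfg.measurement_cv_pct / 100.0
        m1_conc = 10.0 ** (log10_true[0] + cfg.b_true * storage) * max(1.0 + noise[0], 1e-6)
        records.append(
            CohortRecord(
                patient_id=f"P{i + 1:05d}",
                visit="M1",
                drug=cfg.drug,
                dose_mg=dose.dose_mg,
                analyte=cfg.analyte,
                adherent=adherent,
                storage_days=storage,
                conc=m1_conc,
            )
        )
        if has_m12:
            m12_conc = 10.0 ** log10_true[1] * max(1.0 + noise[1], 1e-6)
            records.append(
                CohortRecord(
                    patient_id=f"P{i + 1:05d}",
                    visit="M12",
                    drug=cfg.drug,
                    dose_mg=dose.dose_mg,
                    analyte=cfg.analyte,
                    adherent=adherent,
                    storage_days=None,
                    conc=m12_conc,
                )
            )
    return records
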