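import numpy as np
import pytest

import mrmquant as mq
from mrmquant.assay import AnalyteSpec, CalibrationFit, PeakRecord, Role


@pytest.fixture(scope="session")
def specs():
    return mq.load_assay_config()


@pytest.fixture(scope="session")
def noiseless_sim():
    return mq.noiseless_sim_config()


@pytest.fixture(scope="session")
def default_sim():
    return mq.default_sim_config()


def make_spec(
    levels,
    model_order="linear",
    weighting="1/x",
    name="X",
) -> AnalyteSpec:
    """Ad-hoc analyte spec with QCs placed inside the range."""
    levels = tuple(sorted(levels))
    lo, hi = levels[0], levels[-1]
    return AnalyteSpec(
        name=name,
        calibration_levels=levels,
        qc_low=lo + 0.25 * (hi - lo),
        qc_mid=lo + 0.5 * (hi - lo),
        qc_high=lo + 0.75 * (hi - lo),
        model_order=model_order,
        weighting=weighting,
        is_name=f"{name}-d5",
    )


def standards_from_xy(x, y, analyte="X", run_id="run1"):
    """Calibration-standard records with IS area 1, so ratio == y."""
    return [
        PeakRecord(
            sample_id=f"std-{i}",
            analyte=analyte,
            role=Role.CALIBRATION_STANDARD,
            nominal_conc=float(xi),
            analyte_area=float(yi),
            is_area=1.0,
            run_id=run_id,
        )
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


def make_fit(a0=0.0, a1=1.0, a2=0.0, lloq=0.5, uloq=125.0, analyte="X", weighting="1/x"):
    """A CalibrationFit with given coefficients, for arithmetic tests."""
    return CalibrationFit(
        analyte=analyte, a0=a0, a1=a1, a2=a2, weighting=weighting, r=1.0,
        accepted=True, lloq=lloq, uloq=uloq,
    )


def qc_record(analyte, nominal, analyte_area, is_area=1.0, run_id="run1", i=0, role=Role.QC, **kw):
    return PeakRecord(
        sample_id=f"{run_id}-{role.value}-{nominal:g}-{i}",
        analyte=analyte,
        role=role,
        nominal_conc=nominal,
        analyte_area=analyte_area,
        is_area=is_area,
        run_id=run_id,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
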