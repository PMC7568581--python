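import numpy as np
import pytest

from nutrisurf import GeneratorConfig, default_design, generate_cohort
from nutrisurf.cohort import MouseRecord
from nutrisurf.diet_design import IntakeRecord


def make_records(xyz, y, outcome="body_weight", group="control"):
    """Minimal MouseRecords with given intake coordinates and one outcome.

    All other fields take innocuous defaults; used to feed surface fits
    with hand-constructed data.
    """
    records = []
    for i, ((p, c, f), val) in enumerate(zip(np.asarray(xyz), np.asarray(y))):
        fields = {
            "cl_count": 0,
            "body_weight": 20.0,
            "fat_mass": 3.0,
            "lean_mass": 15.0,
            "adiponectin": 15000.0,
            "cholesterol": 55.0,
            "triglycerides": 50.0,
            "fasting_glucose": 9.0,
            "adipocyte_area": 1600.0,
        }
        fields[outcome] = int(val) if outcome == "cl_count" else float(val)
        total = float(p + c + f)
        records.append(
            MouseRecord(
                mouse_id=f"m{i:04d}",
                group=group,
                diet_id="dX",
                cage_id=f"cage{i:04d}",
                food_g=total / 16.0,
                intake=IntakeRecord(
                    p_kj=float(p), c_kj=float(c), f_kj=float(f),
                    total_kj=total, food_g=total / 16.0,
                ),
                gtt=(9.0, 15.0, 14.0, 11.0, 10.0),
                estrous_seq="PEMDPEMDPEM",
                dht=0.3, dht_nd=False,
                testosterone=0.07, testosterone_nd=False,
                lh=0.4, lh_nd=False, fsh=2.0, fsh_nd=False,
                **fields,
            )
        )
    return records


@pytest.fixture(scope="session")
def diets():
    return default_design()


@pytest.fixture(scope="session")
def default_cohort(diets):
    """One default-size synthetic cohort (10 mice/diet/group, seed 7)."""
    return generate_cohort(diets, GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def cl_fits(default_cohort):
    """Corpora-lutea surfaces for both groups on the default cohort."""
    from nutrisurf import fit_surface

    return {
        g: fit_surface(default_cohort, "cl_count", g, "negbin-log")
        for g in ("control", "PCOS")
    }


@pytest.fixture(scope="session")
def bw_fits(default_cohort):
    """Body-weight surfaces for both groups on the default cohort."""
    from nutrisurf import fit_surface

    return {
        g: fit_surface(default_cohort, "body_weight", g, "gaussian-identity")
        for g in ("control", "PCOS")
    }
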