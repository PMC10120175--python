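import numpy as np
import pytest

from refractive_outcomes.acuity import VAMeasure
from refractive_outcomes.cohorts import Cohort, EyeRecord
from refractive_outcomes.refraction import Refraction


def make_record(
    preop=(-3.0, -1.0, 90.0, 12.0),
    target=(0.0, 0.0, 180.0, 0.0),
    postop=(0.0, 0.0, 180.0, 0.0),
    preop_cdva=(20, 0),
    postop_cdva=(20, 0),
    postop_udva=(20, 0),
    seq_series=(None,) * 5,
):
    return EyeRecord(
        preop=Refraction(*preop),
        preop_cdva=VAMeasure(*preop_cdva),
        target=Refraction(*target),
        postop=Refraction(*postop),
        postop_cdva=VAMeasure(*postop_cdva),
        postop_udva=VAMeasure(*postop_udva),
        seq_series=seq_series,
    )


@pytest.fixture
def perfect_cohort():
    """Every eye lands exactly on its plano target with unchanged acuity.

    Preop refractions vary so that regressions are well-posed; postop
    equals target and every acuity is 20/20, so all indices are 1, all
    errors 0, CI = 1 and AoE = 0 throughout.
    """
    rng = np.random.default_rng(42)
    records = []
    for _ in range(40):
        sphere = float(rng.uniform(-6, -1))
        cyl = float(rng.uniform(0.5, 3.0))
        axis = float(rng.uniform(1, 180))
        records.append(
            make_record(preop=(sphere, -cyl, axis, 12.0))
        )
    return Cohort(name="perfect", records=tuple(records))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
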