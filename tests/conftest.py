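import dataclasses

import numpy as np
import pytest

import mrnapk as mp
from mrnapk.reference import RIBOMAB01_PARAMS, RIBOMAB02_PARAMS


@pytest.fixture(scope="session")
def ribomab01():
    return RIBOMAB01_PARAMS


@pytest.fixture(scope="session")
def ribomab02():
    return RIBOMAB02_PARAMS


@pytest.fixture
def mono_profile():
    """Exact samples of C(t) = 10·exp(−0.1 t) over five half-lives."""
    t = np.linspace(0.0, 35, 24)
    return t, 10.0 * np.exp(-0.1 * t)


@pytest.fixture
def small_dataset():
    """One subject, bolus 100 µg at t=0, three observations."""
    doses = [mp.DoseEvent("s1", 0.0, 100.0)]
    recs = [
        mp.ConcentrationRecord("s1", "human", 70.0, 1.0, 0.05),
        mp.ConcentrationRecord("s1", "human", 70.0, 24.0, 0.0696),
        mp.ConcentrationRecord("s1", "human", 70.0, 168.0, 0.03),
    ]
    return mp.PKDataset(records=recs, doses=doses)


def four_species_design(n_subjects=12, schedule=(1, 3, 6, 12, 24, 48, 72, 120,
                                                 168, 240, 336, 504)):
    arms = tuple(
        mp.StudyArm(species=s, body_weight=w, n_subjects=n_subjects,
                    dose_amounts=(100.0 * w,), sampling_times=tuple(schedule))
        for s, w in [("mouse", 0.025), ("rat", 0.25), ("nhp", 2.5),
                     ("human", 70.0)]
    )
    return mp.StudyDesign("four-species", arms)


FULL_2CPT_SPEC = dict(
    free=["k_elim_mrna", "alpha_k_elim", "k_translate", "alpha_k_translate",
          "cl_ab", "alpha_cl", "q_ab", "alpha_q"],
    fixed={"v1": 40.1, "alpha_v1": 1.0, "v2": 45.6, "alpha_v2": 1.0},
)


@pytest.fixture(scope="session")
def ribomab01_recovery():
    """Generate-then-refit at study conditions: four species, 12 subjects
    each, single bolus, rich sampling, proportional residual CV 15%."""
    truth = dataclasses.replace(RIBOMAB01_PARAMS, sigma_prop=0.15)
    ds = mp.generate_study(four_species_design(), truth, seed=101)
    res = mp.fit_translational(ds, mp.FitSpec(**FULL_2CPT_SPEC), seed=202)
    return truth, res
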