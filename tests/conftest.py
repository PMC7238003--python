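import numpy as np
import pytest

import segflow as sf


@pytest.fixture(scope="session")
def worked():
    """The hand-derived closed-form example parameter set.

    With f_q = 0.1, Q_PV = 0.75: F_I = 0.075/0.3545, F_H = 2.5/3.5,
    F_sys = 0.8 * F_I * F_H (independent arithmetic, frozen).
    """
    drug = sf.DrugParams(
        f_a=0.8, fu_b=1.0, cl_d1_i=1.0, cl_d2_i=1.0,
        cl_int_met1_i=0.2, cl_int_met2_i=0.0, cl_int_sec_i=0.3,
        cl_d1_h=2.0, cl_d2_h=2.0, cl_int_met_h=0.5,
    )
    phys = sf.Physiology(q_pv=0.75, q_ha=0.25)
    spec = sf.FlowModelSpec(variant="SFM", f_q=0.1)
    return drug, phys, spec


@pytest.fixture(scope="session")
def fixtures():
    return sf.reference_fixtures()


def random_bundle(rng, variant="SFM", f_q=None):
    """A random valid parameter set with material disposition in both organs."""
    if f_q is None:
        f_q = rng.uniform(0.05, 1.0)
    drug = sf.DrugParams(
        f_a=rng.uniform(0.3, 1.0),
        k_a=rng.uniform(0.5, 5.0),
        fu_b=rng.uniform(0.2, 1.0),
        cl_d1_i=10 ** rng.uniform(-1, 1.5),
        cl_d2_i=10 ** rng.uniform(-1, 1.5),
        cl_int_met1_i=10 ** rng.uniform(-1.5, 0.7),
        cl_int_met2_i=10 ** rng.uniform(-2, 0.0),
        cl_int_sec_i=10 ** rng.uniform(-2, 0.3),
        cl_d1_h=10 ** rng.uniform(-1, 1.5),
        cl_d2_h=10 ** rng.uniform(-1, 1.5),
        cl_int_met_h=10 ** rng.uniform(-1.5, 0.7),
        cl_int_sec_h=10 ** rng.uniform(-2, 0.3),
        cl_r=rng.uniform(0.0, 0.2),
        p_bile=rng.uniform(0.0, 1.0),
    )
    phys = sf.Physiology(q_pv=0.75, q_ha=0.25)
    spec = sf.FlowModelSpec(variant=variant, f_q=f_q)
    return drug, phys, spec
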