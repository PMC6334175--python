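import logging

import numpy as np
import pytest

from mbverse import (
    GradientWaveform,
    HardwareLimits,
    SLRFilterSpec,
    design_sb_refocusing,
    make_modulation_spec,
)
logging.getLogger("mbverse").setLevel(logging.ERROR)

#: hardware limits used throughout the study
LIMITS = HardwareLimits(b1_max=13.0, g_max=40.0, slew_max=200.0)


@pytest.fixture(scope="session")
def lim():
    return LIMITS


@pytest.fixture(scope="session")
def sb4():
    """Linear-phase TBP=4 singleband 180° on its 2048-sample playout grid."""
    rf, g = design_sb_refocusing(SLRFilterSpec(n_samples=512, tbp=4.0),
                                 thickness=2.0, n_play=2048)
    return rf, g


@pytest.fixture(scope="session")
def mod3():
    """Phase-optimized 3-slice modulation at 28 mm separation."""
    return make_modulation_spec(np.array([-28.0, 0.0, 28.0]))


@pytest.fixture(scope="session")
def mb3(sb4, mod3):
    """Constant-gradient phase-optimized MB3 pulse (TBP=4, 28 mm)."""
    from mbverse import modulate_constant

    sb, g = sb4
    mb = modulate_constant(sb, mod3, g.samples[0])
    return mb, GradientWaveform.constant(g.samples[0], mb.n, mb.dt)


def bloch_matrix_mz(rf, g, z, df=0.0):
    """Independent 3x3 rotation-matrix Bloch integrator (test oracle)."""
    from mbverse.waveforms import GAMMA

    m = np.array([0.0, 0.0, 1.0])
    dt = rf.dt
    for b1, gg in zip(rf.samples, g.samples):
        psi = (GAMMA * gg * z + 2 * np.pi * df * 1e-3) * dt
        c, s = np.cos(psi), np.sin(psi)
        rz = np.array([[c, s, 0], [-s, c, 0], [0, 0, 1]])
        m = rz @ m
        th = GAMMA * abs(b1) * dt
        ph = np.angle(b1)
        ux, uy = np.cos(ph), np.sin(ph)
        k = np.array([[0, 0, uy], [0, 0, -ux], [-uy, ux, 0]])
        rot = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
        m = rot @ m
    return m[2]
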