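"""Shared fixtures: small synthetic streams and analytic oracles."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import pulsekit as pk


def bigaussian_deriv(t, A, sigma, delta, t0):
    """Closed-form derivative of the bipolar Gaussian pulse (oracle)."""
    u = np.asarray(t, dtype=float) - t0
    s2 = 2.0 * sigma**2
    gp = np.exp(-((u + delta / 2.0) ** 2) / s2) * (-(u + delta / 2.0) / sigma**2)
    gm = np.exp(-((u - delta / 2.0) ** 2) / s2) * (-(u - delta / 2.0) / sigma**2)
    return A * (gp - gm)


def analytic_extrema(A, sigma, delta, t0):
    """Exact positive/negative peak times of the bipolar pulse, by root
    finding on the closed-form derivative (independent of the package's
    detection path)."""
    f = lambda t: bigaussian_deriv(t, A, sigma, delta, t0)
    t_pos = brentq(f, t0 - delta / 2.0 - 3 * sigma, t0 - 1e-12 * sigma)
    t_neg = brentq(f, t0 + 1e-12 * sigma, t0 + delta / 2.0 + 3 * sigma)
    return t_pos, t_neg


@pytest.fixture(scope="session")
def default_config():
    return pk.SimulationConfig()


@pytest.fixture(scope="session")
def default_kinematics(default_config):
    return pk.derive_kinematics(default_config)


@pytest.fixture(scope="session")
def short_stream():
    """A 2 s stream at standard settings (2 um, challenging SNR)."""
    cfg = pk.SimulationConfig(duration_s=2.0, seed=42)
    return pk.synthesize_stream(cfg)


@pytest.fixture(scope="session")
def clean_single_pulse(default_kinematics):
    """One noiseless rendered bipolar pulse (A = 10 uV, standard timing)."""
    kin = default_kinematics
    fs = 115_100.0
    ev = pk.TrueEvent(
        t0_s=0.05, d_um=2.0, A_V=10e-6, delta_s=kin.delta_s,
        sigma_s=kin.sigma_s, t_pos_s=0.05 - kin.delta_s / 2,
        t_neg_s=0.05 + kin.delta_s / 2, label="2um",
    )
    grid = pk.TimeGrid(int(0.1 * fs), fs, 0.0)
    return ev, pk.render_event(ev, grid)
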