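import numpy as np
import pytest

import vanthoff as vh


@pytest.fixture
def study_grid():
    """21 temperatures over the physiological range used across the suite."""
    return np.linspace(283.0, 323.0, 21)


@pytest.fixture
def constant_dh_spec():
    """Two-state truth with temperature-independent enthalpy and entropy."""
    return vh.TwoStateModelSpec(T0=300.0, dH0=1e5, dS0=300.0, dCp=0.0, sigma_y=0.05)


@pytest.fixture
def strong_dcp_spec():
    """Two-state truth with a large negative heat-capacity difference.

    dH crosses zero at 310 K, producing a strongly curved van 't Hoff plot
    with a ln(Keq) maximum inside the measured range.
    """
    return vh.TwoStateModelSpec(T0=310.0, dH0=0.0, dS0=0.0, dCp=-1e4, sigma_y=0.05)


@pytest.fixture
def fitted_line_reciprocal():
    """An N=1 reciprocal fit of noiseless straight-line van 't Hoff data."""
    spec = vh.TwoStateModelSpec(T0=300.0, dH0=1e5, dS0=300.0, dCp=0.0)
    series = vh.simulate_lnkeq_series(spec, np.linspace(280, 320, 21), seed=0)
    return vh.fit_free_knot_spline(series, 1, "reciprocal")


def random_knotset(rng, n_intervals, lo=0.0, hi=1.0, value_scale=1.0):
    """A valid random KnotSet with comfortably separated positions."""
    while True:
        inner = np.sort(rng.uniform(lo, hi, size=n_intervals - 1))
        pos = np.concatenate([[lo], inner, [hi]])
        if n_intervals == 1 or np.min(np.diff(pos)) > 0.02 * (hi - lo):
            break
    vals = rng.normal(0.0, value_scale, size=n_intervals + 1)
    return vh.KnotSet(pos, vals)
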