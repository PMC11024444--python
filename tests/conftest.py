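"""Shared fixtures: analytic curve builders and small synthetic cohorts."""

import numpy as np
import pytest

from tlbkit.grid import TEMP_GRID
from tlbkit.io import RawScan, Thermogram


def gaussian(temps, center, sigma, amplitude):
    return amplitude * np.exp(-((temps - center) ** 2) / (2.0 * sigma ** 2))


def make_thermogram(components, sample_id="tg"):
    """Thermogram from a list of (center, sigma, amplitude) Gaussians."""
    cp = np.zeros_like(TEMP_GRID)
    for c, s, a in components:
        cp = cp + gaussian(TEMP_GRID, c, s, a)
    return Thermogram(sample_id, cp)


def make_scan(temps, signal, sample_id="scan", role="sample"):
    return RawScan(sample_id, np.asarray(temps, float), np.asarray(signal, float),
                   role=role)


@pytest.fixture
def unit_gaussian_tg():
    """Single Gaussian: center 63 degC, sigma 2, amplitude 1."""
    return make_thermogram([(63.0, 2.0, 1.0)], "gauss63")


@pytest.fixture
def trimodal_tg():
    """A quiescent-like three-transition profile."""
    return make_thermogram([(63.0, 1.8, 0.15), (70.0, 2.0, 0.095),
                            (77.0, 2.2, 0.04)], "trimodal")


def random_three_gaussian(rng):
    """Random three-transition profile with each component centered well
    inside its canonical window.

    Draws are rejected until each peak window's maximum is a genuine interior
    local maximum (a component can otherwise be swamped by its neighbour's
    tail, leaving only a window-edge supremum and no real valley) — and stays
    one under whole-profile shifts of up to +-0.5 degC, so shift-equivariance
    properties are well posed.
    """
    t = np.arange(45.0, 90.0, 0.01)
    while True:
        comps = []
        for (lo, hi), amp_range in (((61.0, 65.0), (0.06, 0.20)),
                                    ((68.0, 72.0), (0.04, 0.14)),
                                    ((74.5, 79.0), (0.02, 0.10))):
            comps.append((rng.uniform(lo, hi), rng.uniform(1.0, 2.0),
                          rng.uniform(*amp_range)))
        ok = True
        for delta in (-0.5, 0.0, 0.5):
            cp = sum(gaussian(t, c + delta, s, a) for c, s, a in comps)
            for lo, hi in ((60.0, 66.0), (67.0, 73.0), (73.0, 81.0)):
                m = (t >= lo) & (t < hi)
                i = np.argmax(cp[m])
                tm = t[m][i]
                interior = (lo + 0.3 <= tm <= hi - 0.3
                            and cp[m][i] > cp[m][0] and cp[m][i] > cp[m][-1])
                if not interior:
                    ok = False
        if ok:
            return comps
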