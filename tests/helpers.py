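"""Shared construction helpers for the test suite."""

import numpy as np

from mreitaw.adaptive_filter import filter_params
from mreitaw.forward_model import NoiseStdMap


def make_noise_map(grid, sd, tc=0.01):
    sd = np.broadcast_to(np.asarray(sd, dtype=float), grid.shape).copy()
    return NoiseStdMap(sd, np.zeros(grid.shape, bool), grid, tc)


def uniform_params(grid, eta, h, eta_max=None):
    """Filter parameter maps with constant eta and h (direct construction)."""
    sd = np.full(grid.shape, 1.0)
    pm = filter_params(make_noise_map(grid, sd), c_h=1.0, c_eta=1.0,
                       eta_max=max(eta, 1), h_floor=1e-6, sd_ref=1.0,
                       sd_quiet=0.0)
    pm.eta = np.full(grid.shape, int(eta))
    pm.h = np.full(grid.shape, float(h))
    return pm
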