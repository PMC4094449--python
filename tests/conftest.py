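import numpy as np
import pytest

from mreitaw import (
    Grid,
    Inclusion,
    current_density,
    make_disc_phantom,
    make_electrodes,
    solve_voltage,
)


@pytest.fixture(scope="session")
def small_phantom():
    """48x48 disc phantom with one inclusion, plus both electrode pairs."""
    grid = Grid.from_fov(48, 0.24)
    rd = 0.096
    ph = make_disc_phantom(
        grid,
        0.4,
        (Inclusion("A", (0.0, 0.02), 0.03, 1.0, 4.0),),
        disc_radius=rd,
        magnitude_background=30.0,
    )
    els = [
        make_electrodes(grid, pair, 0.01, ph.support, width=0.08, thickness=0.004)
        for pair in ("horizontal", "vertical")
    ]
    return ph, els


@pytest.fixture(scope="session")
def solved_small(small_phantom):
    """Voltage and current density of the small phantom (injection 1)."""
    ph, els = small_phantom
    u = solve_voltage(ph.sigma, els[0])
    j = current_density(ph.sigma, u)
    return ph, els, u, j
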