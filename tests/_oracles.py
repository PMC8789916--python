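"""Independent numerical oracles shared by the test modules."""

import numpy as np


def finite_difference_profile(column, t_final, dz=2.0):
    """Explicit FTCS solver of dC/dt = (D/theta^2) d2C/dz2 on the column
    below the zero-concentration boundary, with C(0) = 0 and a no-flux
    bottom, from a uniform initial condition.

    Independent numerical oracle for the closed-form half-space solution.
    """
    d_eff = column.diffusion_coefficient / column.tortuosity2
    z = np.arange(0.0, column.bottom_depth - column.boundary_depth + dz, dz)
    c = np.ones_like(z)
    c[0] = 0.0
    dt = 0.4 * dz**2 / d_eff
    steps = int(np.ceil(t_final / dt))
    dt = t_final / steps
    lam = d_eff * dt / dz**2
    for _ in range(steps):
        interior = c[1:-1] + lam * (c[2:] - 2 * c[1:-1] + c[:-2])
        c[-1] += lam * 2 * (c[-2] - c[-1])  # ghost-node no-flux bottom
        c[1:-1] = interior
        c[0] = 0.0
    return z, c
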