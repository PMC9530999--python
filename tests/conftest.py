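import numpy as np
import pytest

from hjdimer.dipole_geometry import DipoleGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def random_dipole_pair(rng, min_gap=0.05):
    """A random, non-degenerate dipole pair (end positions in nm)."""
    while True:
        pts = rng.uniform(-3.0, 3.0, size=(4, 3))
        r_m, s_m, r_n, s_n = pts
        cross = [
            np.linalg.norm(a - b)
            for a in (r_m, s_m)
            for b in (r_n, s_n)
        ]
        if (
            np.linalg.norm(r_m - s_m) > min_gap
            and np.linalg.norm(r_n - s_n) > min_gap
            and min(cross) > min_gap
            and np.linalg.norm((r_m + s_m) / 2 - (r_n + s_n) / 2) > min_gap
        ):
            return (
                DipoleGeometry(r=r_m, s=s_m),
                DipoleGeometry(r=r_n, s=s_n),
            )


def random_rotation(rng):
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def coulomb_sum_oracle(m, n, mu_m, mu_n, refractive_index=1.33):
    """Independent four-point-charge Coulomb oracle for the extended-dipole
    coupling: charges +/- mu_i/l_i at the dye ends, interaction screened by
    n^2, energy converted to meV.  Pure SI arithmetic, no shared code with
    the implementation under test."""
    from scipy.constants import c, e, epsilon_0, pi

    debye = 1e-21 / c
    l_m = np.linalg.norm(m.r - m.s)
    l_n = np.linalg.norm(n.r - n.s)
    q_m = mu_m * debye / (l_m * 1e-9)
    q_n = mu_n * debye / (l_n * 1e-9)
    energy = 0.0
    for pm, sgn_m in ((m.r, +1), (m.s, -1)):
        for pn, sgn_n in ((n.r, +1), (n.s, -1)):
            d = np.linalg.norm(pm - pn) * 1e-9
            energy += sgn_m * sgn_n * q_m * q_n / (
                4 * pi * epsilon_0 * refractive_index**2 * d
            )
    return energy / (e * 1e-3)
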