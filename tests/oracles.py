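"""Independent closed-form oracles shared across test modules."""

from scipy.integrate import quad


def axisymmetric_mean_stress_oracle(t_r, R, nu=0.5, E=1.0):
    """Closed-form radial integration of plane-stress equilibrium.

    For an axisymmetric in-plane body force t_r(r) on a free disk of radius
    R, the Navier equation reduces to d/dr[(1/r)d(ru)/dr] = -t_r/E', whose
    double quadrature gives mean stress (σ_rr+σ_θθ)/2 = E/(2(1-ν))·(A - g(r))
    with g(r) = (1/E')∫₀ʳ t_r ds and A fixed by σ_rr(R) = 0.
    """
    Ep = E / (1 - nu ** 2)
    g = lambda r: quad(t_r, 0, r)[0] / Ep
    h = lambda r: quad(lambda s: s * g(s), 0, r)[0] / r ** 2
    A = 2.0 / (1 + nu) * (g(R) - (1 - nu) * h(R))
    return lambda r: E / (2 * (1 - nu)) * (A - g(r))
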