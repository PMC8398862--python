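import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import beta as beta_fn

import polytrait as pt
from polytrait.diffusion import _e_p2q_closure

REF_PARAMS = dict(alpha=4000.0, beta=0.4, gamma=0.0107, delta_c1_tilde=-0.0022)


def test_density_normalizes_and_matches_quad():
    d = pt.stationary_density(pt.DiffusionParams(**REF_PARAMS))
    val, err = quad(d.pdf, 0.0, 1.0, points=[0.5], limit=300)
    assert val == pytest.approx(1.0, abs=1e-6)
    # moments against adaptive quadrature
    m_quad, _ = quad(lambda p: p * d.pdf(p), 0.0, 1.0, limit=300)
    assert d.mean() == pytest.approx(m_quad, abs=1e-8)
    assert d.bin_probabilities(np.linspace(0, 1, 21)).sum() == pytest.approx(
        1.0, abs=1e-6)


def test_neutral_limit_is_symmetric_beta():
    """gamma -> 0 reduces the density to Beta(2*beta, 2*beta)."""
    d = pt.stationary_density(pt.DiffusionParams(alpha=4000.0, beta=0.4,
                                                 gamma=1e-12))
    p = np.array([0.05, 0.3, 0.5, 0.9])
    expected = p**-0.2 * (1 - p) ** -0.2 / beta_fn(0.8, 0.8)
    assert d.pdf(p) == pytest.approx(expected, rel=1e-8)
    assert d.mean() == pytest.approx(0.5, abs=1e-10)


def test_symmetry_when_deviation_zero():
    d = pt.stationary_density(pt.DiffusionParams(alpha=4000.0, beta=0.4,
                                                 gamma=0.0107))
    p = np.linspace(0.01, 0.49, 20)
    assert d.pdf(p) == pytest.approx(d.pdf(1.0 - p), rel=1e-12)


@pytest.mark.parametrize("beta, shape", [(0.2, "U"), (0.4, "U"), (0.6, "bell"),
                                         (2.0, "bell")])
def test_u_versus_bell_shape(beta, shape):
    d = pt.stationary_density(pt.DiffusionParams(alpha=400.0, beta=beta,
                                                 gamma=0.01))
    assert d.shape == shape
    if shape == "U":
        assert d.pdf(1e-3) > d.pdf(0.5)
    else:
        assert d.pdf(1e-3) < d.pdf(0.5)


def test_deviation_sign_tilts_the_mean():
    up = pt.stationary_density(pt.DiffusionParams(4000.0, 0.4, 0.0107, -0.01))
    down = pt.stationary_density(pt.DiffusionParams(4000.0, 0.4, 0.0107, 0.01))
    assert up.mean() > 0.5 > down.mean()


def test_normalization_approximation():
    par = pt.DiffusionParams(**REF_PARAMS)
    exact = pt.stationary_density(par).normalization
    approx = pt.normalization_approx(par)
    assert approx == pytest.approx(exact, rel=0.05)
    # neutral limit: C^-1 = B(2 beta, 2 beta)
    neutral = pt.DiffusionParams(alpha=4000.0, beta=0.4, gamma=0.0)
    assert pt.normalization_approx(neutral) == pytest.approx(
        1.0 / beta_fn(0.8, 0.8), rel=1e-12)
    # out of validity: bracket <= 0 must raise
    with pytest.raises(ValueError, match="bracket"):
        pt.normalization_approx(pt.DiffusionParams(4000.0, 0.4, 0.2))


def test_equilibrium_variance_formula():
    ev = pt.equilibrium_variance
    assert ev(200, 0.01, 0.0) == 0.0
    assert ev(200, 0.01, 0.4) == pytest.approx(0.0123077, rel=1e-5)
    assert ev(200, 0.01, 1e6) == pytest.approx(0.02, rel=1e-5)
    assert ev(200, 0.01, np.inf) == 0.02


def test_moment_dynamics_neutral_decay():
    # s = 0: mean frozen, heterozygosity decays at exactly 1/2N
    m = (0.3, 0.11, 0.19)
    d = pt.moment_dynamics(m, gamma=0.01, s=0.0, N=100.0, delta_c1=-0.2)
    assert d[0] == 0.0
    assert d[2] == pytest.approx(-0.19 / 200.0, rel=1e-12)
    # delta_c1 = 0: drift alone erodes variance
    d0 = pt.moment_dynamics(m, gamma=0.01, s=0.1, N=100.0, delta_c1=0.0)
    assert d0[2] < 0
    with pytest.raises(ValueError, match="inconsistent"):
        pt.moment_dynamics((0.3, 0.11, 0.5), 0.01, 0.1, 100.0, 0.0)
    # alternative closure is selectable and only affects selection terms
    alt = pt.moment_dynamics(m, gamma=0.01, s=0.1, N=100.0, delta_c1=-0.2,
                             closure="independent")
    ref = pt.moment_dynamics(m, gamma=0.01, s=0.1, N=100.0, delta_c1=-0.2)
    assert alt[0] == ref[0] and alt[1] != ref[1]
    with pytest.raises(ValueError, match="closure"):
        pt.moment_dynamics(m, 0.01, 0.1, 100.0, 0.0, closure="bogus")


def test_moment_closure_exact_for_beta_distribution():
    a, b = 1.7, 3.1
    m1 = a / (a + b)
    m2 = a * (a + 1) / ((a + b) * (a + b + 1))
    m3 = m2 * (a + 2) / (a + b + 2)
    assert _e_p2q_closure(m1, m2) == pytest.approx(m2 - m3, rel=1e-12)
    # degenerate guards
    assert _e_p2q_closure(1.0, 1.0) == 0.0
    assert _e_p2q_closure(0.4, 0.16) == pytest.approx(0.16 * 0.6)


def test_moment_ode_tracks_wf_ensemble():
    """Drift-only moment ODEs track a neutral WF ensemble of one locus."""
    N, p0, T, R = 100, 0.3, 150, 4000
    rng = np.random.default_rng(77)
    arch = pt.TraitArchitecture(np.array([1e-9]), mutation_rate=0.0)
    reg = pt.SelectionRegime(s=1e-9, optimum_before=0.0)
    res = pt.simulate(arch, reg, pt.DemographySchedule.constant(N),
                      np.full((R, 1), p0), T, rng, thin=T,
                      record_loci=np.array([0]))
    e_pq_sim = float(
        (res.freq_samples[:, -1, 0] * (1 - res.freq_samples[:, -1, 0])).mean())
    t, mom = pt.integrate_moments((p0, p0 * p0 + 0.0, p0 * (1 - p0)),
                                  gamma=1e-9, s=0.0, N=N, delta_c1_fn=0.0,
                                  t_max=T)
    assert mom[-1, 2] == pytest.approx(p0 * (1 - p0) * np.exp(-T / (2 * N)),
                                       rel=1e-3)
    assert e_pq_sim == pytest.approx(mom[-1, 2], rel=0.05)


def test_density_moments_match_wf_time_average():
    """Stationary-density mean/variance vs a long neutral-ish WF run.

    Small population and high mutation rate keep the mixing time short so
    the time average converges quickly.
    """
    N, mu, s, gamma = 500, 2.5e-4, 0.01, 0.02
    beta = 2 * N * mu
    rng = np.random.default_rng(5)
    n = 64
    arch = pt.TraitArchitecture(np.full(n, gamma), mutation_rate=mu)
    reg = pt.SelectionRegime(s=s, optimum_before=0.0)
    res = pt.simulate(arch, reg, pt.DemographySchedule.constant(N),
                      np.full((8, n), 0.5), 30000, rng, thin=100,
                      record_loci=np.arange(n))
    w = res.times >= 5000
    samples = res.freq_samples[:, w, :].ravel()
    d = pt.stationary_density(
        pt.DiffusionParams(alpha=2 * N * s, beta=beta, gamma=gamma))
    assert samples.mean() == pytest.approx(d.mean(), abs=0.02)
    assert samples.var() == pytest.approx(d.variance(), rel=0.08)


def test_invalid_diffusion_params():
    with pytest.raises(ValueError):
        pt.DiffusionParams(alpha=-1.0, beta=0.4, gamma=0.01)
    with pytest.raises(ValueError):
        pt.stationary_density(pt.DiffusionParams(alpha=100.0, beta=0.0,
                                                 gamma=0.01))
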