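import numpy as np
import pytest

import polytrait as pt
from polytrait.deterministic import SHIFT, SWEEP, fit_decay_rate


def euler_oracle(arch, regime, p0, t_max, dt=1e-3):
    """Brute-force fixed-step Euler integration of the coupled system."""
    p = np.asarray(p0, dtype=float).copy()
    steps = int(round(t_max / dt))
    for k in range(steps):
        p = p + dt * pt.ode_rhs(p, arch, regime, k * dt)
    return p


def test_rhs_hand_value():
    """Single locus, gamma=0.01, p=0.3, s=0.1, mu=1e-5, optimum 0.2."""
    arch = pt.TraitArchitecture(np.array([0.01]), mutation_rate=1e-5)
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.2)
    dp = pt.ode_rhs(np.array([0.3]), arch, reg)
    assert dp[0] == pytest.approx(4.642e-5, rel=1e-10)


def test_rhs_fixed_points(ref_arch):
    # all p = 1/2 with the optimum at the (zero) trait mean: every term vanishes
    reg0 = pt.SelectionRegime(s=0.1, optimum_before=0.0)
    p_half = np.full(ref_arch.n_loci, 0.5)
    assert np.allclose(pt.ode_rhs(p_half, ref_arch, reg0), 0.0)
    # absorbing boundaries without mutation
    arch0 = pt.TraitArchitecture(ref_arch.effects, mutation_rate=0.0)
    p_fix = np.tile([0.0, 1.0], ref_arch.n_loci // 2)
    assert np.allclose(pt.ode_rhs(p_fix, arch0, reg0), 0.0)


def test_integrate_matches_euler_oracle():
    arch = pt.sample_architecture(5, 0.02, 1e-5, seed=5)
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.06)
    p0 = np.array([0.3, 0.5, 0.7, 0.4, 0.6])
    traj = pt.integrate(arch, reg, p0, 100.0, n_points=11)
    oracle = euler_oracle(arch, reg, p0, 100.0)
    assert traj.freqs[-1] == pytest.approx(oracle, rel=1e-4)


def test_equilibrium_is_fixed_point(ref_regime):
    arch = pt.sample_architecture(30, 0.01, 1e-5, seed=9)
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.05)
    eq = pt.find_equilibrium(arch, reg)
    traj = pt.integrate(arch, reg, eq, 5000.0, fit_rate=False)
    assert np.max(np.abs(traj.freqs - eq)) < 1e-6


def test_frequencies_stay_in_unit_interval():
    arch = pt.sample_architecture(50, 0.02, 1e-5, seed=11)
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.3, optimum_after=0.8,
                             shift_time=500.0)
    traj = pt.integrate(arch, reg, np.full(50, 0.5), 4000.0)
    assert traj.freqs.min() >= 0.0 and traj.freqs.max() <= 1.0


def all_minor_arch(n=200, gamma_bar=0.01, seed=2):
    """Exponential sample in which essentially every locus is minor:
    mu = 1.25e-4, s = 0.1 puts the threshold at 10*gamma_bar."""
    return pt.sample_architecture(n, gamma_bar, 1.25e-4, seed=seed)


def test_decay_rate_matches_s_n_gamma2():
    """|Delta_c1| decays exponentially at ~ s*n*gamma_bar^2 (small effects)."""
    arch = all_minor_arch()
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.4)
    traj = pt.integrate(arch, reg, np.full(200, 0.5), 3000.0, n_points=600)
    theory = pt.short_term_rate(
        arch, pt.SelectionRegime(s=0.1, optimum_before=0.2, optimum_after=0.4),
        "small_effects")
    assert theory == pytest.approx(0.1 * 200 * 0.01**2, rel=1e-12)
    assert traj.rate_estimate == pytest.approx(theory, rel=0.25)


def test_rate_doubles_with_locus_number():
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.2, optimum_after=0.4)
    r1 = pt.short_term_rate(all_minor_arch(n=200), reg, "small_effects")
    r2 = pt.short_term_rate(all_minor_arch(n=400), reg, "small_effects")
    assert r2 == pytest.approx(2 * r1, rel=1e-12)
    # and the fitted rates behave the same way
    arch2 = all_minor_arch(n=400)
    reg_f = pt.SelectionRegime(s=0.1, optimum_before=0.4)
    t1 = pt.integrate(all_minor_arch(n=200), reg_f, np.full(200, 0.5), 3000.0,
                      n_points=600)
    t2 = pt.integrate(arch2, reg_f, np.full(400, 0.5), 1500.0, n_points=600)
    assert t2.rate_estimate / t1.rate_estimate == pytest.approx(2.0, rel=0.25)


def test_directional_approximation_tracks_full_system():
    """Short-term: the directional-only system matches the full one on
    Delta_c1(t) to within 5% of the initial deviation."""
    arch = all_minor_arch()
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.4)
    p0 = np.full(200, 0.5)
    t_star = 1.0 / (0.1 * pt.compute_cumulants(arch, p0, 0.4).c2)
    full = pt.integrate(arch, reg, p0, t_star, n_points=100, fit_rate=False)
    approx = pt.integrate(arch, reg, p0, t_star, n_points=100,
                          directional_only=True, fit_rate=False)
    dev0 = abs(full.delta_c1[0])
    assert np.max(np.abs(full.delta_c1 - approx.delta_c1)) < 0.05 * dev0


def test_quasi_equilibrium_deviation_values():
    qed = pt.quasi_equilibrium_deviation
    assert qed(0.01, 0.0, 1e-5, 0.1, 0.0) == 0.0
    assert qed(0.0123, 0.0, 1e-5, 0.1, 0.2) == pytest.approx(-0.0032, rel=1e-3)
    # mu = 0 limit
    assert qed(0.01, 2e-4, 0.0, 0.1, 0.2) == pytest.approx(-2e-4 / (2 * 0.01))
    with pytest.raises(ZeroDivisionError):
        qed(0.0, 0.0, 0.0, 0.1, 0.2)


def test_predict_shifts_values_and_signs(ref_arch):
    arch = pt.TraitArchitecture(np.array([0.01]), mutation_rate=1e-5)
    pred = pt.predict_shifts(arch, np.array([0.5]), delta_c1_0=-0.2, c2_0=0.02)
    assert pred.delta_p[0] == pytest.approx(
        0.01 * 0.25 * 0.2 * (1 - np.exp(-1)) / 0.02, rel=1e-12)
    assert pred.aligned[0]
    # zero deviation and boundary loci give zero shift
    z = pt.predict_shifts(ref_arch, np.full(200, 0.5), 0.0, 0.01)
    assert np.all(z.delta_p == 0.0)
    b = pt.predict_shifts(arch, np.array([1.0]), -0.2, 0.02)
    assert b.delta_p[0] == 0.0
    with pytest.raises(ZeroDivisionError):
        pt.predict_shifts(arch, np.array([0.5]), -0.2, 0.0)


def test_shift_prediction_matches_ode():
    """The closed-form shift prediction agrees with the integrated system
    within 10% for effects below half the minor/major threshold."""
    arch = all_minor_arch(seed=21)
    ghat = pt.effect_threshold(1.25e-4, 0.1)
    small = arch.effects < ghat / 2
    assert small.sum() > 150
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.4)
    p0 = np.full(200, 0.5)
    c2_0 = pt.compute_cumulants(arch, p0, 0.4).c2
    delta0 = pt.compute_cumulants(arch, p0, 0.4).delta_c1
    t_star = 1.0 / (0.1 * c2_0)
    traj = pt.integrate(arch, reg, p0, t_star, n_points=50, fit_rate=False)
    dp_ode = traj.freqs[-1] - p0
    pred = pt.predict_shifts(arch, p0, delta0, c2_0)
    rel = np.abs(pred.delta_p[small] - dp_ode[small]) / np.abs(dp_ode[small])
    assert np.max(rel) < 0.10


def test_sweep_classification():
    # all-minor, tiny effects: no sweep candidates
    arch = all_minor_arch()
    reg = pt.SelectionRegime(s=0.1, optimum_before=0.2, optimum_after=0.4)
    p0 = np.full(200, 0.5)
    labels = pt.classify_sweep_candidates(arch, reg, p0)
    c2_0 = pt.compute_cumulants(arch, p0, 0.2).c2
    if np.all(arch.effects < c2_0):
        assert np.all(labels == SHIFT)
    # single large-effect locus sweeps
    big = pt.TraitArchitecture(np.array([0.5]), mutation_rate=1e-5)
    assert pt.classify_sweep_candidates(big, reg, np.array([0.1]))[0] == SWEEP
    # monotone in effect size within one architecture
    mixed = pt.sample_architecture(100, 0.05, 1e-5, seed=13)
    lab = pt.classify_sweep_candidates(mixed, reg, np.full(100, 0.5))
    if (lab == SWEEP).any() and (lab == SHIFT).any():
        assert mixed.effects[lab == SWEEP].min() > mixed.effects[lab == SHIFT].max()


def test_fit_decay_rate_recovers_synthetic_exponential():
    t = np.linspace(0, 2000, 300)
    rate = 0.002
    delta = -0.2 * np.exp(-rate * t) - 0.003
    assert fit_decay_rate(t, delta) == pytest.approx(rate, rel=0.02)
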