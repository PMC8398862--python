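"""Diffusion-approximation theory for a locus under stabilizing selection.

With scaled selection ``alpha = 2 N s`` and scaled mutation ``beta = 2 N mu``,
the stationary density of the "+"-allele frequency at a locus of effect
``gamma``, given a constant quasi-equilibrium mean deviation
``delta_c1_tilde``, is

    f(p) = C p^{2 beta - 1} q^{2 beta - 1}
             exp(-2 alpha gamma delta_c1_tilde p - alpha gamma^2 p q).

The density is U-shaped (mass piling up at the frequency boundaries) when
``2 beta < 1`` and bell-shaped when ``beta > 0.5``.  The normalization C is
computed by Gauss–Jacobi quadrature (authoritative); the closed-form
approximation

    C^{-1} ≈ B(2 beta, 2 beta) [1 - alpha gamma delta_c1_tilde
                                  - alpha gamma^2 beta / (4 beta + 1)]

is exposed as a diagnostic.  Averaged over exponential effect sizes with
mean ``gamma_bar``, the stationary genetic variance of the trait is
approximately ``(4 beta / (4 beta + 1)) n gamma_bar^2`` (the deterministic
value ``n gamma_bar^2`` is recovered as ``beta -> inf``).

During the adaptive phase the lowest-order frequency moments obey
(directional selection + drift only)

    d/dt E{p}  = -s gamma E{pq} Delta_c1(t)
    d/dt E{p2} = -2 s gamma E{p2 q} Delta_c1(t) + E{pq} / (2N)
    d/dt E{pq} = -s gamma E{pq} Delta_c1 + 2 s gamma E{p2 q} Delta_c1
                 - E{pq} / (2N),

closed for E{p2 q} with a beta-distribution ansatz matched to the current
mean and variance.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import integrate as sp_integrate
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import beta as beta_fn
from scipy.special import roots_jacobi

from .architecture import TraitArchitecture
from .deterministic import quasi_equilibrium_deviation

__all__ = [
    "DiffusionParams",
    "EquilibriumDensity",
    "stationary_density",
    "normalization_approx",
    "equilibrium_variance",
    "moment_dynamics",
    "integrate_moments",
    "self_consistent_deviation",
]


@dataclasses.dataclass(frozen=True)
class DiffusionParams:
    """Scaled parameters of the per-locus diffusion."""

    alpha: float  # 2 N s
    beta: float  # 2 N mu
    gamma: float  # locus effect size (trait units)
    delta_c1_tilde: float = 0.0  # quasi-equilibrium mean deviation

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @classmethod
    def from_population(
        cls, N: float, s: float, mu: float, gamma: float, delta_c1_tilde: float = 0.0
    ) -> "DiffusionParams":
        return cls(alpha=2.0 * N * s, beta=2.0 * N * mu, gamma=gamma,
                   delta_c1_tilde=delta_c1_tilde)


class EquilibriumDensity:
    """Stationary allele-frequency density with quadrature normalization.

    Expectations of smooth functions are computed with Gauss–Jacobi
    quadrature that absorbs the ``(pq)^{2 beta - 1}`` endpoint behaviour
    exactly, so integrable boundary singularities (``beta < 0.5``) cost
    nothing.
    """

    def __init__(self, params: DiffusionParams, n_nodes: int = 160):
        if params.beta <= 0:
            raise ValueError("beta must be > 0 for an integrable density")
        self.params = params
        a = 2.0 * params.beta  # beta-weight exponent
        x, w = roots_jacobi(n_nodes, a - 1.0, a - 1.0)
        self._nodes = (x + 1.0) / 2.0
        self._weights = w * 0.5 ** (2.0 * a - 1.0)
        z = self._weights @ self._exp_factor(self._nodes)
        if not np.isfinite(z) or z <= 0:
            raise RuntimeError("quadrature normalization failed")
        self.normalization = float(1.0 / z)  # C_i

    def _exp_factor(self, p: np.ndarray) -> np.ndarray:
        pr = self.params
        p = np.asarray(p, dtype=float)
        return np.exp(-2.0 * pr.alpha * pr.gamma * pr.delta_c1_tilde * p
                      - pr.alpha * pr.gamma**2 * p * (1.0 - p))

    @property
    def shape(self) -> str:
        """"U" when 2*beta < 1 (boundary-divergent), else "bell"."""
        return "U" if 2.0 * self.params.beta < 1.0 else "bell"

    def pdf(self, p: np.ndarray | float) -> np.ndarray | float:
        p_arr = np.asarray(p, dtype=float)
        a = 2.0 * self.params.beta
        with np.errstate(divide="ignore"):
            val = (self.normalization
                   * p_arr ** (a - 1.0) * (1.0 - p_arr) ** (a - 1.0)
                   * self._exp_factor(p_arr))
        return float(val) if np.ndim(p) == 0 else val

    def expectation(self, h) -> float:
        """E[h(p)] for a smooth function h, by Gauss–Jacobi quadrature."""
        vals = h(self._nodes) * self._exp_factor(self._nodes)
        return float(self.normalization * (self._weights @ vals))

    def mean(self) -> float:
        return self.expectation(lambda p: p)

    def variance(self) -> float:
        m = self.mean()
        return self.expectation(lambda p: (p - m) ** 2)

    def e_pq(self) -> float:
        return self.expectation(lambda p: p * (1.0 - p))

    def e_pq_qmp(self) -> float:
        """E[p q (q - p)], the per-locus skew moment."""
        return self.expectation(lambda p: p * (1.0 - p) * (1.0 - 2.0 * p))

    def bin_probabilities(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass of the density in each bin of a partition of [0,1].

        Outer bins use an adaptive quadrature with the algebraic endpoint
        weight so boundary singularities are integrated accurately.
        """
        edges = np.asarray(edges, dtype=float)
        a = 2.0 * self.params.beta
        C = self.normalization
        probs = np.empty(edges.size - 1)
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            if lo <= 0.0:
                val, _ = sp_integrate.quad(
                    lambda p: C * (1.0 - p) ** (a - 1.0) * self._exp_factor(p),
                    0.0, hi, weight="alg", wvar=(a - 1.0, 0.0))
            elif hi >= 1.0:
                val, _ = sp_integrate.quad(
                    lambda p: C * p ** (a - 1.0) * self._exp_factor(p),
                    lo, 1.0, weight="alg", wvar=(0.0, a - 1.0))
            else:
                val, _ = sp_integrate.quad(self.pdf, lo, hi, limit=200)
            probs[k] = val
        return probs


def stationary_density(params: DiffusionParams, n_nodes: int = 160) -> EquilibriumDensity:
    """Stationary density with quadrature normalization (authoritative)."""
    return EquilibriumDensity(params, n_nodes=n_nodes)


def normalization_approx(params: DiffusionParams) -> float:
    """Closed-form approximation to the normalization constant C.

    Valid while the bracket ``1 - alpha gamma Delta - alpha gamma^2 beta /
    (4 beta + 1)`` stays positive; outside that range a ValueError signals
    that the quadrature normalization must be used instead.
    """
    pr = params
    bracket = (1.0 - pr.alpha * pr.gamma * pr.delta_c1_tilde
               - pr.alpha * pr.gamma**2 * pr.beta / (4.0 * pr.beta + 1.0))
    if bracket <= 0:
        raise ValueError(
            f"normalization bracket = {bracket:g} <= 0: approximation outside its "
            "validity range; use the quadrature normalization")
    return float(1.0 / (beta_fn(2.0 * pr.beta, 2.0 * pr.beta) * bracket))


def equilibrium_variance(n: int, mean_effect: float, beta: float) -> float:
    """Stationary genetic variance ``(4 beta / (4 beta + 1)) n gamma_bar^2``.

    Holds for exponentially distributed effect sizes with mean
    ``gamma_bar`` in the minor-allele regime; ``beta = inf`` returns the
    deterministic value ``n gamma_bar^2`` and ``beta = 0`` returns 0 (drift
    fixes every locus without mutation).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if math.isinf(beta):
        return n * mean_effect**2
    return (4.0 * beta / (4.0 * beta + 1.0)) * n * mean_effect**2


def _e_p2q_closure(m1: float, m2: float) -> float:
    """Closure for E{p^2 (1-p)} from (E{p}, E{p^2}) via a beta ansatz.

    Fits Beta(a, b) to the mean and variance and returns its exact third
    moment combination.  Degenerate states (zero or maximal variance) fall
    back to the corresponding point-mass limits.
    """
    var = m2 - m1 * m1
    vmax = m1 * (1.0 - m1)
    if vmax <= 0.0:  # fixed at 0 or 1
        return 0.0
    if var <= 0.0:  # point mass at m1
        return m1 * m1 * (1.0 - m1)
    if var >= vmax:  # two-point mass at the boundaries
        return 0.0
    s = vmax / var - 1.0  # a + b
    a = m1 * s
    e_p3 = m2 * (a + 2.0) / (s + 2.0)  # Beta: E[p^3] = E[p^2] (a+2)/(a+b+2)
    return m2 - e_p3


def moment_dynamics(
    moments: tuple[float, float, float],
    gamma: float,
    s: float,
    N: float,
    delta_c1: float,
    closure: str = "beta",
) -> np.ndarray:
    """Time derivatives of (E{p}, E{p^2}, E{pq}) during the adaptive phase.

    ``moments`` must be internally consistent: E{pq} = E{p} - E{p^2} and
    E{p^2} <= E{p}.  ``closure`` selects the approximation for the unclosed
    third moment E{p^2 q}: ``"beta"`` (beta-distribution ansatz, default)
    or ``"independent"`` (the cruder factorisation E{p^2} E{q}).
    """
    e_p, e_p2, e_pq = (float(m) for m in moments)
    if e_p2 > e_p + 1e-12 or abs(e_pq - (e_p - e_p2)) > 1e-9:
        raise ValueError("inconsistent moments: need E{pq} = E{p} - E{p^2} <= E{p}")
    if closure == "beta":
        e_p2q = _e_p2q_closure(e_p, e_p2)
    elif closure == "independent":
        e_p2q = e_p2 * (1.0 - e_p)
    else:
        raise ValueError("closure must be 'beta' or 'independent'")
    drift = e_pq / (2.0 * N)
    d_p = -s * gamma * e_pq * delta_c1
    d_p2 = -2.0 * s * gamma * e_p2q * delta_c1 + drift
    d_pq = -s * gamma * e_pq * delta_c1 + 2.0 * s * gamma * e_p2q * delta_c1 - drift
    return np.array([d_p, d_p2, d_pq])


def integrate_moments(
    m0: tuple[float, float, float],
    gamma: float,
    s: float,
    N: float,
    delta_c1_fn,
    t_max: float,
    n_points: int = 200,
    closure: str = "beta",
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the moment ODEs; ``delta_c1_fn`` maps t -> Delta_c1(t).

    A constant may be passed for ``delta_c1_fn``.  Returns (times, moments)
    with moments of shape (T, 3).
    """
    if not callable(delta_c1_fn):
        const = float(delta_c1_fn)
        delta_c1_fn = lambda t: const  # noqa: E731

    def rhs(t, y):
        # re-impose consistency: integrate (E{p}, E{p^2}), derive E{pq}
        e_p, e_p2 = y
        d = moment_dynamics((e_p, e_p2, e_p - e_p2), gamma, s, N,
                            delta_c1_fn(t), closure=closure)
        return d[:2]

    t_eval = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(rhs, (0.0, t_max), list(m0[:2]), t_eval=t_eval, rtol=1e-8,
                    atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"moment integration failed: {sol.message}")
    e_p, e_p2 = sol.y
    out = np.column_stack([e_p, e_p2, e_p - e_p2])
    return sol.t, out


def _cumulants_given_deviation(
    arch: TraitArchitecture, N: float, s: float, delta: float, n_nodes: int
) -> tuple[float, float, float]:
    """Stationary (c1, c2, c3) implied by the per-locus densities at deviation delta."""
    alpha = 2.0 * N * s
    beta = 2.0 * N * arch.mutation_rate
    c1 = c2 = c3 = 0.0
    for g in arch.effects:
        dens = EquilibriumDensity(
            DiffusionParams(alpha, beta, float(g), delta), n_nodes=n_nodes)
        c1 += g * (2.0 * dens.mean() - 1.0)
        c2 += 2.0 * g * g * dens.e_pq()
        c3 += 2.0 * g**3 * dens.e_pq_qmp()
    return c1, c2, c3


def self_consistent_deviation(
    arch: TraitArchitecture,
    N: float,
    s: float,
    z0: float,
    mode: str = "eq9",
    tol: float = 1e-10,
    max_iter: int = 200,
    n_nodes: int = 96,
) -> float:
    """Self-consistent quasi-equilibrium deviation Delta_c1~ from theory alone.

    mode "eq9": iterate — given Delta, compute stationary cumulants from the
    per-locus densities, then update Delta from the quasi-equilibrium
    relation.  mode "mean": solve the mean-balance condition
    ``c1(Delta) = z0 + Delta`` directly.  Both are diffusion-level
    predictions of the quantity the simulator measures as a time average.
    """
    mu = arch.mutation_rate
    if mode == "eq9":
        delta = 0.0
        for _ in range(max_iter):
            _, c2, c3 = _cumulants_given_deviation(arch, N, s, delta, n_nodes)
            new = quasi_equilibrium_deviation(c2, c3, mu, s, z0)
            if abs(new - delta) < tol:
                return float(new)
            delta = 0.5 * (delta + new)
        raise RuntimeError("self-consistent iteration did not converge")
    if mode == "mean":
        def residual(delta):
            c1, _, _ = _cumulants_given_deviation(arch, N, s, delta, n_nodes)
            return c1 - z0 - delta
        return float(brentq(residual, -0.2, 0.2, xtol=tol))
    raise ValueError("mode must be 'eq9' or 'mean'")
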