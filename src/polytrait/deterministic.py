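"""Deterministic (infinite-population) allele-frequency dynamics.

The frequency of the trait-increasing allele at locus *i* obeys the coupled
system

    dp_i/dt = -s gamma_i p_i q_i Delta_c1
              - (s gamma_i^2 / 2) p_i q_i (q_i - p_i)
              + mu (q_i - p_i),

where ``Delta_c1 = c1 - z_opt`` couples the loci through the trait mean.
The three terms are directional selection toward the optimum, stabilizing
selection around it, and symmetric mutation.

During the *short-term phase* after an optimum shift (the time until the
trait mean first closely approaches the new optimum, operationally one time
constant ``t* = 1/(s c2(0))``), the directional term dominates and the mean
deviation decays approximately exponentially:

* small-effects case (all loci minor): rate ``s n gamma_bar^2``
  (= ``s c2(0)`` with intermediate starting frequencies), with ``n`` the
  number of minor loci;
* large-effects case: rate proportional to ``s zf gamma_bar`` (the
  proportionality constant is not pinned down here and is exposed as 1).

The per-locus frequency shift accumulated over the short-term phase is,
for sufficiently small effects,

    delta_p_i ≈ -gamma_i p_i(0) q_i(0) Delta_c1(0) (1 - e^{-1}) / c2(0).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit

from .architecture import (
    CumulantSet,
    SelectionRegime,
    TraitArchitecture,
    cumulant_arrays,
    effect_threshold,
)

__all__ = [
    "DeterministicTrajectory",
    "ShiftPrediction",
    "ode_rhs",
    "integrate",
    "find_equilibrium",
    "equilibrium_initial_freqs",
    "fit_decay_rate",
    "short_term_rate",
    "quasi_equilibrium_deviation",
    "predict_shifts",
    "classify_sweep_candidates",
]

SWEEP = "sweep_expected"
SHIFT = "shift_expected"


def ode_rhs(
    freqs: np.ndarray,
    arch: TraitArchitecture,
    regime: SelectionRegime,
    t: float = 0.0,
    directional_only: bool = False,
) -> np.ndarray:
    """Right-hand side dp_i/dt of the coupled deterministic system.

    ``Delta_c1`` is evaluated from the full current frequency vector.  With
    ``directional_only=True`` only the directional-selection term is kept
    (the classical short-term approximation).
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    g = arch.effects
    c1 = (2.0 * p - 1.0) @ g
    delta_c1 = c1 - regime.optimum_at(t)
    pq = p * q
    dp = -regime.s * g * pq * delta_c1
    if not directional_only:
        dp = dp - (regime.s * g * g / 2.0) * pq * (q - p) + arch.mutation_rate * (q - p)
    return dp


@dataclasses.dataclass
class DeterministicTrajectory:
    """Integrated trajectory with cumulants at every output time."""

    times: np.ndarray
    freqs: np.ndarray  # (T, n)
    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    delta_c1: np.ndarray
    rate_estimate: float | None = None

    def cumulants_at(self, idx: int, optimum: float | None = None) -> CumulantSet:
        d = self.delta_c1[idx] if optimum is None else self.c1[idx] - optimum
        return CumulantSet(
            float(self.c1[idx]), float(self.c2[idx]), float(self.c3[idx]), float(d)
        )

    def to_frame(self, include_freqs: bool = False) -> pd.DataFrame:
        data = {
            "generation": self.times,
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "delta_c1": self.delta_c1,
        }
        df = pd.DataFrame(data)
        if include_freqs:
            for i in range(self.freqs.shape[1]):
                df[f"p_{i + 1}"] = self.freqs[:, i]
        return df

    def save_tsv(self, path: str | Path, include_freqs: bool = False) -> None:
        self.to_frame(include_freqs).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass(frozen=True)
class ShiftPrediction:
    """Predicted per-locus frequency shifts over the short-term phase."""

    delta_p: np.ndarray
    aligned: np.ndarray  # delta_p > 0, i.e. toward an upward optimum shift


def integrate(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    p0: np.ndarray,
    t_max: float,
    n_points: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    directional_only: bool = False,
    fit_rate: bool = True,
) -> DeterministicTrajectory:
    """Adaptive-step integration of the coupled ODE system.

    Integrates piecewise around an optimum shift inside ``(0, t_max)`` so
    the discontinuous forcing never sits inside an integrator step.
    Frequencies are clipped only for round-off-scale overshoots (< 1e-9);
    anything larger raises.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (arch.n_loci,):
        raise ValueError("p0 has wrong length for this architecture")
    if np.any(p0 < 0) or np.any(p0 > 1):
        raise ValueError("initial frequencies must lie in [0, 1]")

    breaks = [0.0, float(t_max)]
    if regime.has_shift and 0.0 < regime.shift_time < t_max:
        breaks.insert(1, float(regime.shift_time))
    times = np.linspace(0.0, float(t_max), n_points)

    def rhs(t, p):
        return ode_rhs(p, arch, regime, t, directional_only=directional_only)

    all_t, all_p = [], []
    y = p0
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_t = times[(times >= a) & (times <= b)]
        t_eval = np.unique(np.concatenate([[a], seg_t, [b]]))
        sol = solve_ivp(
            rhs, (a, b), y, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
        all_t.append(sol.t)
        all_p.append(sol.y.T)
    t_out = np.concatenate(all_t)
    p_out = np.concatenate(all_p, axis=0)
    t_out, keep = np.unique(t_out, return_index=True)
    p_out = p_out[keep]

    over = max(float(-p_out.min(initial=0.0)), float(p_out.max(initial=1.0) - 1.0))
    if over > 1e-9:
        raise RuntimeError(f"integrator left [0,1] by {over:g}; tighten tolerances")
    p_out = np.clip(p_out, 0.0, 1.0)

    c1, c2, c3 = cumulant_arrays(arch.effects, p_out)
    opt = np.array([regime.optimum_at(t) for t in t_out])
    traj = DeterministicTrajectory(t_out, p_out, c1, c2, c3, c1 - opt)
    if fit_rate:
        try:
            traj.rate_estimate = fit_decay_rate(t_out, traj.delta_c1)
        except ValueError:
            traj.rate_estimate = None
    return traj


def fit_decay_rate(times: np.ndarray, delta_c1: np.ndarray) -> float:
    """Fitted exponential decay rate of |Delta_c1(t)| (1/generations).

    The deviation decays toward a small quasi-equilibrium level, not to
    zero, so a three-parameter exponential ``A exp(-r t) + B`` is fitted;
    the log-linear slope of the asymptote-corrected deviation seeds the
    nonlinear fit.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(delta_c1, dtype=float)
    a0, b0 = d[0] - d[-1], d[-1]
    if a0 == 0.0:
        raise ValueError("no initial deviation to fit")
    y = np.abs(d - b0)
    mask = (y > 0.05 * abs(a0)) & (y < 0.80 * abs(a0))
    if mask.sum() >= 3:
        r0 = max(float(-np.polyfit(t[mask], np.log(y[mask]), 1)[0]), 1e-12)
    else:
        r0 = 1.0 / max(t[-1] - t[0], 1.0)
    popt, _ = curve_fit(
        lambda tt, a, r, b: a * np.exp(-r * tt) + b,
        t, d, p0=[a0, r0, b0], maxfev=20000,
    )
    return float(popt[1])


def short_term_rate(
    arch: TraitArchitecture, regime: SelectionRegime, case: str
) -> float:
    """Analytic short-term approach rate for the two extreme regimes.

    ``case="small_effects"`` returns ``s * n_minor * gamma_bar^2`` exactly.
    ``case="large_effects"`` returns ``s * zf * gamma_bar`` — a
    proportionality only (constant set to 1; the exact prefactor is not
    fixed by the theory exposed here).
    """
    if case == "small_effects":
        return regime.s * arch.n_minor(regime.s) * arch.mean_effect**2
    if case == "large_effects":
        zf = regime.optimum_after if regime.optimum_after is not None else regime.optimum_before
        return regime.s * zf * arch.mean_effect
    raise ValueError("case must be 'small_effects' or 'large_effects'")


def quasi_equilibrium_deviation(
    c2_eq: float, c3_eq: float, mu: float, s: float, z0: float
) -> float:
    """Quasi-equilibrium deviation of the trait mean from the optimum.

    Setting d(Delta_c1)/dt = 0 in the cumulant dynamics gives

        Delta_c1~ = -((s/2) c3~ + 2 mu z0) / (s c2~ + 2 mu).
    """
    denom = s * c2_eq + 2.0 * mu
    if denom <= 0:
        raise ZeroDivisionError("s*c2 + 2*mu must be > 0")
    return -((s / 2.0) * c3_eq + 2.0 * mu * z0) / denom


def predict_shifts(
    arch: TraitArchitecture,
    p0: np.ndarray,
    delta_c1_0: float,
    c2_0: float,
) -> ShiftPrediction:
    """Per-locus frequency shifts over the short-term phase (small effects).

    ``delta_p_i = -gamma_i p_i(0) q_i(0) Delta_c1(0) (1-e^{-1}) / c2(0)``.
    All shifts share the sign of ``-Delta_c1(0)``: after an upward optimum
    shift the "+"-allele frequencies move coherently upward.
    """
    if c2_0 <= 0:
        raise ZeroDivisionError("initial genetic variance must be > 0")
    p0 = np.asarray(p0, dtype=float)
    dp = -arch.effects * p0 * (1.0 - p0) * delta_c1_0 * (1.0 - np.exp(-1.0)) / c2_0
    return ShiftPrediction(delta_p=dp, aligned=dp > 0)


def classify_sweep_candidates(
    arch: TraitArchitecture, regime: SelectionRegime, p0: np.ndarray
) -> np.ndarray:
    """Label each locus ``sweep_expected`` or ``shift_expected``.

    In a large-effects-dominated architecture (majority of loci major),
    loci with effects at least the mean effect ``gamma_bar`` are sweep
    candidates; in a small-effects-dominated one, a large frequency change
    needs ``gamma_i > c2(0)``, the initial genetic variance.
    """
    gamma_hat = effect_threshold(arch.mutation_rate, regime.s)
    major_dominated = np.mean(arch.effects > gamma_hat) > 0.5
    if major_dominated:
        labels = np.where(arch.effects >= arch.mean_effect, SWEEP, SHIFT)
    else:
        _, c2_0, _ = cumulant_arrays(arch.effects, np.asarray(p0, dtype=float))
        labels = np.where(arch.effects > float(c2_0), SWEEP, SHIFT)
    return labels


def _major_boundary_freq(gamma: float, mu: float, s: float, high: bool) -> float:
    """Mutation–selection boundary equilibrium of an isolated major locus.

    Solves the single-locus ``dp/dt = 0`` (with the mean at the optimum,
    Delta_c1 = 0) numerically on the requested side of 1/2.
    """

    def g(p):
        q = 1.0 - p
        return -(s * gamma * gamma / 2.0) * p * q * (q - p) + mu * (q - p)

    if mu == 0.0:
        return 1.0 - 1e-12 if high else 1e-12
    lo, hi = (0.5 + 1e-9, 1.0 - 1e-15) if high else (1e-15, 0.5 - 1e-9)
    if g(lo) * g(hi) > 0:  # no boundary root: locus is effectively minor
        return 0.5
    return float(brentq(g, lo, hi, xtol=1e-15))


def equilibrium_initial_freqs(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    major_side: str = "low",
) -> np.ndarray:
    """Rough deterministic equilibrium: minor loci at 1/2, major at boundary.

    Major loci are placed at the mutation–selection boundary equilibrium on
    the low-frequency side by default ("high" puts them near fixation).
    This is the textbook starting point; :func:`find_equilibrium` relaxes
    it to the exact coupled equilibrium.
    """
    minor = arch.minor_mask(regime.s)
    p = np.full(arch.n_loci, 0.5)
    for i in np.where(~minor)[0]:
        p[i] = _major_boundary_freq(
            float(arch.effects[i]), arch.mutation_rate, regime.s, high=(major_side == "high")
        )
    return p


def find_equilibrium(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    p0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_time: float = 4e6,
) -> np.ndarray:
    """Relax the ODE system to its stable equilibrium under the z0 optimum.

    Integrates with the optimum fixed at ``optimum_before``, doubling the
    horizon until ``max |dp/dt| < tol``.
    """
    frozen = SelectionRegime(s=regime.s, optimum_before=regime.optimum_before)
    if p0 is None:
        p0 = equilibrium_initial_freqs(arch, regime)
    p = np.asarray(p0, dtype=float)
    t_horizon = 2000.0
    while t_horizon <= max_time:
        traj = integrate(arch, frozen, p, t_horizon, n_points=5, fit_rate=False)
        p = traj.freqs[-1]
        if np.max(np.abs(ode_rhs(p, arch, frozen))) < tol:
            return p
        t_horizon *= 4.0
    warnings.warn("equilibrium relaxation did not reach tolerance", stacklevel=2)
    return p
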