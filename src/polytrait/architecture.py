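"""Genetic architecture of an additive quantitative trait.

A trait is controlled additively (no dominance, no epistasis) by ``n``
unlinked diallelic loci.  The trait-increasing ("+") allele at locus *i*
contributes ``+gamma_i / 2`` to the phenotype and the "−" allele
``-gamma_i / 2``, so with "+"-allele frequency ``p_i`` (and ``q_i = 1 - p_i``)
the first three cumulants of the trait distribution are

    c1 = sum_i gamma_i (p_i - q_i)          (mean)
    c2 = 2 sum_i gamma_i^2 p_i q_i          (genetic variance)
    c3 = 2 sum_i gamma_i^3 p_i q_i (q_i - p_i)   (skewness)

Fitness is Gaussian (stabilizing) around an optimum ``z_opt``:
``w(z) = exp(-(s/2) (z - z_opt)^2)``, with ``1/s`` large compared to the
phenotypic variance (weak selection on the trait scale).

Loci are classified by the stability threshold ``gamma_hat = 2 sqrt(2 mu / s)``:
*minor* loci (``gamma < gamma_hat``) equilibrate at intermediate frequencies
near 1/2, *major* loci sit in mutation–selection balance near the frequency
boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraitArchitecture",
    "SelectionRegime",
    "CumulantSet",
    "compute_cumulants",
    "cumulant_arrays",
    "fitness",
    "effect_threshold",
    "sample_architecture",
    "save_architecture",
    "load_architecture",
]


@dataclasses.dataclass(frozen=True)
class TraitArchitecture:
    """Fixed per-locus effect sizes plus the symmetric mutation rate.

    Parameters
    ----------
    effects
        Length-``n`` vector of per-locus effect sizes ``gamma_i > 0``
        (trait units).  Effect sizes are fixed at construction.
    mutation_rate
        Symmetric per-locus, per-generation mutation rate ``mu >= 0``
        between the "+" and "−" alleles.
    mean_effect
        Mean ``gamma_bar`` of the effect-size *distribution* (trait units).
        Defaults to the sample mean of ``effects``; the built-in sampler
        stores the distribution mean it was asked for.
    seed
        Optional seed recorded for provenance when the architecture was
        sampled.
    """

    effects: np.ndarray
    mutation_rate: float
    mean_effect: float = None  # type: ignore[assignment]
    seed: int | None = None

    def __post_init__(self) -> None:
        eff = np.array(self.effects, dtype=float, copy=True)
        if eff.ndim != 1 or eff.size < 1:
            raise ValueError("effects must be a non-empty 1-D vector")
        if not np.all(np.isfinite(eff)) or np.any(eff <= 0):
            raise ValueError("all effect sizes must be finite and > 0")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        eff.setflags(write=False)
        object.__setattr__(self, "effects", eff)
        if self.mean_effect is None:
            object.__setattr__(self, "mean_effect", float(eff.mean()))
        elif self.mean_effect <= 0:
            raise ValueError("mean_effect must be > 0")

    @property
    def n_loci(self) -> int:
        return self.effects.size

    @property
    def trait_range(self) -> float:
        """Maximum attainable |trait mean|, ``sum_i gamma_i``."""
        return float(self.effects.sum())

    def minor_mask(self, s: float) -> np.ndarray:
        """Boolean mask of *minor* loci (``gamma_i < gamma_hat``)."""
        return self.effects < effect_threshold(self.mutation_rate, s)

    def n_minor(self, s: float) -> int:
        return int(self.minor_mask(s).sum())


@dataclasses.dataclass(frozen=True)
class SelectionRegime:
    """Gaussian stabilizing selection with a (possibly shifting) optimum.

    The optimum sits at ``optimum_before`` (z0) for generations
    ``t < shift_time`` and at ``optimum_after`` (zf) from ``shift_time`` on.
    A regime without a shift leaves ``optimum_after`` as ``None``.
    """

    s: float
    optimum_before: float
    optimum_after: float | None = None
    shift_time: float = 0.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("selection strength s must be > 0")

    def optimum_at(self, t: float) -> float:
        if self.optimum_after is None or t < self.shift_time:
            return self.optimum_before
        return self.optimum_after

    @property
    def has_shift(self) -> bool:
        return self.optimum_after is not None and self.optimum_after != self.optimum_before

    def validate(self, arch: TraitArchitecture) -> None:
        """Warn about optimum placements outside the model's assumptions.

        A reachable stationary state near the optimum needs
        ``0 < z0 < n*gamma_bar`` (and ``z0 < zf < n*gamma_bar`` for a shift).
        Violations warn rather than error: exploratory runs may want
        unreachable optima.
        """
        zmax = arch.n_loci * arch.mean_effect
        if not (0.0 < self.optimum_before < zmax):
            warnings.warn(
                f"optimum_before={self.optimum_before} outside (0, n*gamma_bar={zmax:g}); "
                "the trait mean may not reach a stationary state near the optimum",
                stacklevel=2,
            )
        if self.optimum_after is not None:
            if not (self.optimum_before < self.optimum_after):
                warnings.warn("optimum_after <= optimum_before", stacklevel=2)
            if self.optimum_after >= zmax:
                warnings.warn(
                    f"optimum_after={self.optimum_after} >= n*gamma_bar={zmax:g}; "
                    "new optimum is unreachable",
                    stacklevel=2,
                )

    def check_weak_selection(self, c2: float) -> None:
        """Warn when s*c2 > 0.1 (selection not weak relative to 1/s)."""
        if self.s * c2 > 0.1:
            warnings.warn(
                f"s*c2 = {self.s * c2:.3g} > 0.1: selection is not weak relative to "
                "the phenotypic variance; model approximations degrade",
                stacklevel=2,
            )


@dataclasses.dataclass(frozen=True)
class CumulantSet:
    """Trait mean, genetic variance, skewness, and mean-optimum deviation."""

    c1: float
    c2: float
    c3: float
    delta_c1: float


def cumulant_arrays(
    effects: np.ndarray, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized cumulants for a batch of frequency vectors.

    ``freqs`` has shape ``(..., n)``; returns ``(c1, c2, c3)`` with the
    leading shape of ``freqs``.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    g = np.asarray(effects, dtype=float)
    pq = p * q
    c1 = (2.0 * p - 1.0) @ g
    c2 = 2.0 * (pq @ (g * g))
    c3 = 2.0 * ((pq * (q - p)) @ (g * g * g))
    return c1, c2, c3


def compute_cumulants(
    arch: TraitArchitecture, freqs: np.ndarray, optimum: float = 0.0
) -> CumulantSet:
    """Cumulants of the trait distribution at the given allele frequencies.

    Raises on a length mismatch or a frequency outside [0, 1].
    """
    p = np.asarray(freqs, dtype=float)
    if p.shape != (arch.n_loci,):
        raise ValueError(
            f"freqs has shape {p.shape}, expected ({arch.n_loci},) for this architecture"
        )
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    c1, c2, c3 = cumulant_arrays(arch.effects, p)
    return CumulantSet(float(c1), float(c2), float(c3), float(c1 - optimum))


def fitness(z: float | np.ndarray, regime: SelectionRegime, t: float = 0.0):
    """Gaussian fitness ``w(z) = exp(-(s/2) (z - z_opt(t))^2)``."""
    dz = np.asarray(z, dtype=float) - regime.optimum_at(t)
    w = np.exp(-0.5 * regime.s * dz * dz)
    return float(w) if np.isscalar(z) or np.ndim(z) == 0 else w


def effect_threshold(mu: float, s: float) -> float:
    """Minor/major stability threshold ``gamma_hat = 2 sqrt(2 mu / s)``.

    Loci with ``gamma < gamma_hat`` ("minor") have a stable interior
    equilibrium near 1/2; larger effects ("major") equilibrate in
    mutation–selection balance near 0 or 1.  ``mu = 0`` gives 0 (all loci
    major).
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return 2.0 * math.sqrt(2.0 * mu / s)


def sample_architecture(
    n: int,
    mean_effect: float,
    mutation_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TraitArchitecture:
    """Sample i.i.d. exponential effect sizes with mean ``mean_effect``.

    Deterministic given ``seed``.  Passing an explicit ``rng`` overrides
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_effect <= 0:
        raise ValueError("mean_effect must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    effects = rng.exponential(scale=mean_effect, size=n)
    # an exact zero draw is measure-zero but would violate gamma_i > 0
    effects = np.maximum(effects, np.finfo(float).tiny)
    return TraitArchitecture(
        effects=effects, mutation_rate=mutation_rate, mean_effect=mean_effect, seed=seed
    )


def save_architecture(arch: TraitArchitecture, tsv_path: str | Path) -> None:
    """Write effects as two-column TSV plus a JSON sidecar of parameters.

    The sidecar ``<tsv_path>.json`` records (n, gamma_bar, mu, seed) so a
    run can be reproduced bit-for-bit.
    """
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(
        {"locus_id": np.arange(arch.n_loci), "effect_size": arch.effects}
    )
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "n_loci": arch.n_loci,
        "mean_effect": arch.mean_effect,
        "mutation_rate": arch.mutation_rate,
        "seed": arch.seed,
    }
    Path(str(tsv_path) + ".json").write_text(json.dumps(meta, indent=1))


def load_architecture(tsv_path: str | Path) -> TraitArchitecture:
    """Inverse of :func:`save_architecture`."""
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    meta = json.loads(Path(str(tsv_path) + ".json").read_text())
    arch = TraitArchitecture(
        effects=df["effect_size"].to_numpy(),
        mutation_rate=float(meta["mutation_rate"]),
        mean_effect=float(meta["mean_effect"]),
        seed=meta.get("seed"),
    )
    if arch.n_loci != int(meta["n_loci"]):
        raise ValueError("TSV row count disagrees with sidecar n_loci")
    return arch
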