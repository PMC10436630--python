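"""Synthetic abundance cohorts with the structure the monitor assumes.

The generator works backwards through the preprocessing chain. Healthy
samples live in the transformed-standardized space as a Gaussian factor
model: ``x_norm = A t + e`` with ``t`` standard normal on ``d_true`` latent
dimensions and per-feature loadings scaled so every feature has unit
variance; the share of variance carried by the latent factors (default 0.92)
gives the cohort the low-rank correlation structure of real species tables.
Each feature is then mapped to percent-scale relative abundances through the
inverse of the monitoring transform, with per-species baseline abundances
drawn log-uniformly over 1e-3..10 percent, and sparsified by zeroing the
smallest abundances to a target zero fraction. Unhealthy samples add a
planted shift (``fault_magnitude``, in transformed-standardized units) along
known species before back-mapping; multi-pattern healthy cohorts add
separated pattern means in a 2-D latent subspace that carries no extra
variance in the paired background cohort, so contrastive (not plain) PCA is
required to resolve them.

Every generated table ships with a ground-truth record (loadings, fault
list, labels, pattern assignments and the generating population itself)
sufficient to compute any recovery metric without re-deriving hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable
from .preprocess import DEFAULT_SIGMA, inverse_log_transform, log_transform

#: reference draw used to freeze the sparsity cutoff of a population
_CUTOFF_REFERENCE_N = 2000


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``fault_magnitude`` and ``pattern_separation`` are expressed in
    transformed-standardized units (the space the monitor sees);
    ``zero_fraction`` is the target fraction of zero cells in the emitted
    table.
    """

    D: int = 120
    d_true: int = 8
    n_healthy: int = 2000
    n_unhealthy: int = 1000
    zero_fraction: float = 0.30
    fault_species: Sequence[int] = ()
    fault_magnitude: float = 6.0
    n_patterns: int = 1
    pattern_separation: float = 0.0
    signal_fraction: float = 0.92
    abundance_decades: tuple[float, float] = (-3.0, 1.0)
    sd_range: tuple[float, float] = (0.5, 1.5)
    sigma: float = DEFAULT_SIGMA
    phenotype: str = "disease"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_fraction < 1:
            raise ValueError(f"zero_fraction must be in [0, 1), got {self.zero_fraction}")
        if self.n_healthy < 1 or self.n_unhealthy < 0:
            raise ValueError("cohort sizes must be >= 1 (unhealthy may be 0)")
        if not 1 <= self.d_true < self.D:
            raise ValueError(f"d_true must be in [1, D), got {self.d_true}")
        if not 0 < self.signal_fraction < 1:
            raise ValueError("signal_fraction must be in (0, 1)")
        bad = [i for i in self.fault_species if not 0 <= int(i) < self.D]
        if bad:
            raise ValueError(f"fault species indices out of range [0, {self.D}): {bad}")
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")
        if self.n_patterns > 1 and self.pattern_separation <= 0:
            raise ValueError("pattern_separation must be > 0 when n_patterns > 1")


def _pattern_layout(n_patterns: int, separation: float) -> np.ndarray:
    """2-D pattern means: vertices of a regular polygon with adjacent
    distance = separation, centred at the origin."""
    if n_patterns == 1:
        return np.zeros((1, 2))
    if n_patterns == 2:
        return np.array([[-separation / 2, 0.0], [separation / 2, 0.0]])
    r = separation / (2.0 * np.sin(np.pi / n_patterns))
    angles = 2.0 * np.pi * np.arange(n_patterns) / n_patterns
    return np.column_stack([r * np.cos(angles), r * np.sin(angles)])


class CohortPopulation:
    """Frozen generating population for one :class:`SyntheticSpec`.

    All structural randomness (loadings, baselines, sparsity cutoff) is
    derived once from ``spec.seed``; sampling methods take their own
    generator so that fresh, identically-distributed cohorts can be drawn.
    """

    def __init__(self, spec: SyntheticSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        D, d = spec.D, spec.d_true
        basis, _ = np.linalg.qr(rng.normal(size=(D, d + 2)))
        s2 = spec.signal_fraction * D / ((1.0 - spec.signal_fraction) * d)
        A_raw = np.sqrt(s2) * basis[:, :d]
        feat_var = np.sum(A_raw * A_raw, axis=1) + 1.0
        scale = 1.0 / np.sqrt(feat_var)
        #: (D, d_true) latent loadings; features have unit variance
        self.loadings = A_raw * scale[:, None]
        #: per-feature sd of the isotropic noise after scaling
        self.noise_sd = scale
        # pattern subspace: orthonormal in the unscaled basis, rescaled and
        # re-orthonormalized in feature space
        W = basis[:, d : d + 2] * scale[:, None]
        self.pattern_directions, _ = np.linalg.qr(W)
        lo, hi = spec.abundance_decades
        baseline = 10.0 ** rng.uniform(lo, hi, size=D)
        #: per-feature mean and sd on the transformed scale
        self.mu = log_transform(baseline, spec.sigma)
        self.sd = rng.uniform(*spec.sd_range, size=D)
        self.pattern_means = _pattern_layout(spec.n_patterns, spec.pattern_separation)
        self.species_ids = [f"sp_{j + 1:04d}" for j in range(D)]
        # freeze the sparsity cutoff on a reference healthy draw so that
        # every cohort sampled from this population is identically distributed
        if spec.zero_fraction > 0:
            ref = self._abundance(self._normalized_healthy(_CUTOFF_REFERENCE_N, rng))
            self.cutoff = float(np.quantile(ref, spec.zero_fraction))
        else:
            self.cutoff = 0.0

    # -- normalized-space sampling ------------------------------------------

    def _normalized_healthy(
        self, n: int, rng: np.random.Generator, pattern_ids: Optional[np.ndarray] = None
    ) -> np.ndarray:
        t = rng.standard_normal((n, self.spec.d_true))
        eps = rng.standard_normal((n, self.spec.D)) * self.noise_sd
        x = t @ self.loadings.T + eps
        if pattern_ids is not None and self.spec.n_patterns > 1:
            # unit within-pattern spread along the pattern axes, so the
            # separation parameter is in within-pattern sd units; the
            # background cohort carries none of this extra variance
            coords = self.pattern_means[pattern_ids] + rng.standard_normal((n, 2))
            x = x + coords @ self.pattern_directions.T
        return x

    def _normalized_unhealthy(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = self._normalized_healthy(n, rng)
        idx = np.asarray(list(self.spec.fault_species), dtype=int)
        if idx.size:
            x[:, idx] += self.spec.fault_magnitude
        return x

    # -- back-mapping to abundances -----------------------------------------

    def _abundance(self, x_norm: np.ndarray) -> np.ndarray:
        y = self.mu + self.sd * x_norm
        return inverse_log_transform(y, self.spec.sigma)

    def _sparsify(self, values: np.ndarray) -> np.ndarray:
        if self.cutoff > 0:
            values = np.where(values <= self.cutoff, 0.0, values)
        return values

    def sample_healthy(
        self, n: int, rng: np.random.Generator, pattern_ids: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Fresh healthy abundance rows (sparsity applied)."""
        return self._sparsify(self._abundance(self._normalized_healthy(n, rng, pattern_ids)))

    def sample_unhealthy(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._sparsify(self._abundance(self._normalized_unhealthy(n, rng)))

    def assign_patterns(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Balanced, shuffled pattern assignment for n healthy samples."""
        ids = np.resize(np.arange(self.spec.n_patterns), n)
        rng.shuffle(ids)
        return ids


@dataclass
class GroundTruth:
    """Everything needed to score recovery against a generated cohort."""

    spec: SyntheticSpec
    population: CohortPopulation = field(repr=False)
    labels: pd.Series = field(repr=False)
    pattern_ids: Optional[pd.Series] = field(repr=False, default=None)

    @property
    def fault_species_ids(self) -> list[str]:
        return [self.population.species_ids[int(i)] for i in self.spec.fault_species]

    @property
    def pattern_directions(self) -> np.ndarray:
        return self.population.pattern_directions


def generate_cohort(spec: SyntheticSpec) -> tuple[AbundanceTable, GroundTruth]:
    """Healthy + unhealthy abundance table with metadata and ground truth.

    Deterministic given ``spec.seed``. Raises if sparsification silences a
    fault species entirely in the unhealthy arm.
    """
    pop = CohortPopulation(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    pattern_ids = (
        pop.assign_patterns(spec.n_healthy, rng) if spec.n_patterns > 1 else None
    )
    healthy = pop.sample_healthy(spec.n_healthy, rng, pattern_ids)
    unhealthy = pop.sample_unhealthy(spec.n_unhealthy, rng)
    if spec.fault_species and spec.n_unhealthy > 0:
        idx = np.asarray(list(spec.fault_species), dtype=int)
        silenced = (unhealthy[:, idx] == 0).all(axis=0)
        if silenced.any():
            dead = [pop.species_ids[int(i)] for i in idx[silenced]]
            raise ValueError(
                f"zero_fraction {spec.zero_fraction} zeroes fault species {dead} "
                "entirely; lower it or raise the fault magnitude"
            )
    sample_ids = [f"H{i + 1:05d}" for i in range(spec.n_healthy)] + [
        f"U{i + 1:05d}" for i in range(spec.n_unhealthy)
    ]
    values = np.vstack([healthy, unhealthy]) if spec.n_unhealthy else healthy
    data = pd.DataFrame(values, index=sample_ids, columns=pop.species_ids)
    labels = pd.Series(
        ["healthy"] * spec.n_healthy + ["unhealthy"] * spec.n_unhealthy,
        index=sample_ids,
        name="label",
    )
    phenotype = pd.Series(
        ["healthy"] * spec.n_healthy + [spec.phenotype] * spec.n_unhealthy,
        index=sample_ids,
        name="phenotype",
    )
    metadata = pd.DataFrame({"label": labels, "phenotype": phenotype})
    table = AbundanceTable(data, metadata)
    truth = GroundTruth(
        spec=spec,
        population=pop,
        labels=labels,
        pattern_ids=(
            pd.Series(pattern_ids, index=sample_ids[: spec.n_healthy], name="pattern")
            if pattern_ids is not None
            else None
        ),
    )
    return table, truth


@dataclass
class PatternedCohort:
    """Healthy multi-pattern target cohort with its paired background."""

    healthy: AbundanceTable
    background: AbundanceTable
    pattern_ids: pd.Series
    truth: GroundTruth


def generate_patterned_healthy(spec: SyntheticSpec) -> PatternedCohort:
    """Multi-pattern healthy cohort plus a pattern-free background cohort.

    The pattern means live in a latent 2-D subspace that has only baseline
    variance in the background cohort, so the patterns are target-specific.
    With ``n_patterns = 1`` this reduces to the plain healthy arm of
    :func:`generate_cohort`.
    """
    table, truth = generate_cohort(spec)
    healthy = table.subset("healthy")
    background = table.subset("unhealthy")
    n_h = spec.n_healthy
    pattern_ids = (
        truth.pattern_ids
        if truth.pattern_ids is not None
        else pd.Series(np.zeros(n_h, dtype=int), index=healthy.sample_ids, name="pattern")
    )
    return PatternedCohort(
        healthy=healthy, background=background, pattern_ids=pattern_ids, truth=truth
    )
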