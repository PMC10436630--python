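"""Feature selection and abundance preprocessing.

Three stages prepare a relative-abundance table for monitoring:

1. Kolmogorov-Smirnov screening splits species into health-prevalent (H+,
   stochastically more abundant in healthy samples) and health-scarce (H-,
   more abundant in unhealthy samples) panels via one-sided two-sample tests.
2. A piecewise logarithmic transform compresses the percent-scale
   abundances: ``lt(x) = log2(2x + sigma)`` for ``x <= 1`` and
   ``lt(x) = sqrt(x)`` for ``x > 1``. The two branches nearly meet at
   ``x = 1`` and the small offset ``sigma`` keeps zeros finite
   (``lt(0) = log2(sigma)``).
3. Z-score normalization with mean/sd estimated on the healthy training
   cohort only and frozen thereafter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_SIGMA = 1e-5

#: sample size above which scipy switches the KS p-value to the asymptotic form
KS_ASYMPTOTIC_N = 100


@dataclass
class FeatureSelectionResult:
    """Outcome of KS-based H+/H- species screening.

    ``p_minus[s]`` is the one-sided P-value for species ``s`` being
    stochastically larger in the unhealthy group (H- direction); ``p_plus``
    mirrors it for the healthy group. A species enters ``h_minus`` /
    ``h_plus`` iff its direction P-value is <= the list's threshold; the two
    lists may overlap.
    """

    h_plus: list[str]
    h_minus: list[str]
    p_plus: pd.Series
    p_minus: pd.Series
    p_thresh_plus: float
    p_thresh_minus: float
    method: str = "auto"


def ks_select(
    healthy: pd.DataFrame,
    unhealthy: pd.DataFrame,
    p_thresh_minus: float = 1e-3,
    p_thresh_plus: float = 1e-3,
    method: str = "auto",
) -> FeatureSelectionResult:
    """Screen species by one-sided two-sample Kolmogorov-Smirnov tests.

    Parameters
    ----------
    healthy, unhealthy : DataFrame
        Samples x species abundance matrices sharing the species axis. The
        KS statistic is invariant under monotone transforms, so raw percent
        abundances are tested directly.
    p_thresh_minus, p_thresh_plus : float
        Independent inclusion thresholds for the H- and H+ lists, supporting
        threshold scans.
    method : str
        Passed to :func:`scipy.stats.ks_2samp` (``auto`` uses the exact
        p-value for small groups and the asymptotic one above ~100 samples).
    """
    if healthy.shape[0] == 0 or unhealthy.shape[0] == 0:
        raise ValueError("both healthy and unhealthy groups must be non-empty")
    if list(healthy.columns) != list(unhealthy.columns):
        missing = set(healthy.columns) ^ set(unhealthy.columns)
        raise ValueError(f"groups do not share the species axis: {sorted(missing)}")
    if healthy.shape[0] < 2 or unhealthy.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples per species")

    h = healthy.to_numpy(dtype=float)
    u = unhealthy.to_numpy(dtype=float)
    p_minus = np.empty(h.shape[1])
    p_plus = np.empty(h.shape[1])
    for j in range(h.shape[1]):
        # H-: unhealthy stochastically larger <=> F_healthy lies above
        p_minus[j] = stats.ks_2samp(h[:, j], u[:, j], alternative="greater", method=method).pvalue
        p_plus[j] = stats.ks_2samp(h[:, j], u[:, j], alternative="less", method=method).pvalue
    species = list(healthy.columns)
    p_minus = pd.Series(p_minus, index=species, name="p_minus")
    p_plus = pd.Series(p_plus, index=species, name="p_plus")
    used = method
    if method == "auto":
        n_eff = min(h.shape[0], u.shape[0])
        used = "asymp" if n_eff > KS_ASYMPTOTIC_N else "exact"
    return FeatureSelectionResult(
        h_plus=[s for s in species if p_plus[s] <= p_thresh_plus],
        h_minus=[s for s in species if p_minus[s] <= p_thresh_minus],
        p_plus=p_plus,
        p_minus=p_minus,
        p_thresh_plus=p_thresh_plus,
        p_thresh_minus=p_thresh_minus,
        method=used,
    )


def log_transform(values, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Piecewise logarithmic abundance transform.

    ``lt(x) = log2(2x + sigma)`` for ``x <= 1``; ``lt(x) = sqrt(x)`` for
    ``x > 1``. Strictly increasing, finite at 0 (= ``log2(sigma)``).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    return np.where(x <= 1.0, np.log2(2.0 * x + sigma), np.sqrt(np.maximum(x, 1.0)))


def inverse_log_transform(y, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Inverse of :func:`log_transform`; negative back-mapped values clip to 0."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    y = np.asarray(y, dtype=float)
    cut = np.log2(2.0 + sigma)  # = lt(1)
    low = (np.exp2(y) - sigma) / 2.0
    return np.where(y <= cut, np.maximum(low, 0.0), np.square(y))


@dataclass
class TransformParams:
    """Frozen preprocessing parameters (offset, per-feature mean and sd).

    Fitted on the healthy training cohort and never refit at predict time.
    Features with zero training variance are dropped and recorded in
    ``dropped``.
    """

    sigma: float
    mu: np.ndarray
    sd: np.ndarray
    features: list[str]
    dropped: list[str] = field(default_factory=list)


def zscore_fit(
    transformed: pd.DataFrame, sigma: float = DEFAULT_SIGMA, sd_tol: float = 1e-12
) -> TransformParams:
    """Estimate per-feature mean and sd (ddof=1) on the transformed training set.

    Zero-variance features are dropped from the model feature list with a
    logged warning.
    """
    mu = transformed.mean(axis=0)
    sd = transformed.std(axis=0, ddof=1)
    keep = sd > sd_tol
    dropped = [f for f, k in zip(transformed.columns, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
    features = [f for f, k in zip(transformed.columns, keep) if k]
    return TransformParams(
        sigma=sigma,
        mu=mu[features].to_numpy(),
        sd=sd[features].to_numpy(),
        features=features,
        dropped=dropped,
    )


def zscore_apply(transformed: pd.DataFrame, params: TransformParams) -> pd.DataFrame:
    """Normalize with frozen parameters; columns follow the model feature list."""
    missing = [f for f in params.features if f not in transformed.columns]
    if missing:
        raise ValueError(f"matrix missing model features: {missing}")
    x = transformed[params.features].to_numpy(dtype=float)
    return pd.DataFrame(
        (x - params.mu) / params.sd, index=transformed.index, columns=params.features
    )


def prepare(
    abundances: pd.DataFrame,
    params: TransformParams,
    fill_missing_features: bool = False,
) -> pd.DataFrame:
    """Raw percent abundances -> transformed, normalized model matrix.

    With ``fill_missing_features`` a feature absent from the input is imputed
    as abundance 0 before the transform; otherwise a missing feature is an
    error.
    """
    df = abundances
    missing = [f for f in params.features if f not in df.columns]
    if missing:
        if not fill_missing_features:
            raise ValueError(
                f"samples are missing model features {missing}; "
                "enable fill_missing_features to impute them as absent (0)"
            )
        df = df.copy()
        for f in missing:
            df[f] = 0.0
    transformed = pd.DataFrame(
        log_transform(df[params.features].to_numpy(dtype=float), params.sigma),
        index=df.index,
        columns=params.features,
    )
    return zscore_apply(transformed, params)
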