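"""Reconstruction-based contribution diagnosis (BHC).

When a sample alarms, the responsible species are found by reconstruction:
move the sample along a candidate direction ``xi`` by the magnitude ``f``
that minimizes the monitoring index ``Ind(x - xi f) = (x - xi f)' M (x - xi f)``.
The index reduction achieved,

    BHC_i = x' M Xi (Xi' M Xi)^+ Xi' M x,

is the bacteria-to-health-index contribution of that direction. Directions
default to the coordinate axes (one species each) but may be multi-column
blocks when several species are jointly disordered.

Population-averaged BHC spectra per phenotype, the accumulated-contribution
rule for high-contributor species, cross-disease intersections
(broad-spectrum species), and hierarchical clustering of disease spectra
live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

PINV_RTOL = 1e-10


def reconstruction_contribution(
    M: np.ndarray, X: np.ndarray, directions: Optional[np.ndarray] = None
) -> np.ndarray:
    """Contribution of a direction block to the quadratic index x'Mx.

    Parameters
    ----------
    M : (D, D) ndarray
        Positive semi-definite index matrix.
    X : (n, D) ndarray
        Sample rows (already normalized).
    directions : (D, k) ndarray, optional
        Direction block Xi. ``None`` computes all single-species
        contributions at once (Xi = e_i for every i), returning (n, D).

    Returns
    -------
    ndarray
        (n,) block contributions, or (n, D) per-species contributions.
    """
    M = np.asarray(M, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if directions is None:
        # Xi = e_i: BHC_i = (Mx)_i^2 / M_ii, vectorized over species
        mx = X @ M
        diag = np.diag(M).copy()
        zero = diag <= PINV_RTOL * max(diag.max(initial=0.0), 1.0)
        safe = np.where(zero, 1.0, diag)
        out = mx * mx / safe
        out[:, zero] = 0.0
        return out
    Xi = np.asarray(directions, dtype=float)
    if Xi.ndim == 1:
        Xi = Xi[:, None]
    core = Xi.T @ M @ Xi
    core_pinv = np.linalg.pinv(core, rcond=PINV_RTOL, hermitian=True)
    if core.shape[0] > 0:
        rank = np.linalg.matrix_rank(core, tol=PINV_RTOL * max(np.abs(core).max(), 1.0))
        if rank < core.shape[0]:
            logger.warning(
                "direction block Xi'MXi is rank deficient (rank %d of %d); "
                "pseudo-inverse used",
                rank,
                core.shape[0],
            )
    proj = X @ M @ Xi  # (n, k)
    return np.einsum("nk,kl,nl->n", proj, core_pinv, proj)


def bhc_table(
    results,
    abundances: pd.DataFrame,
    index: str = "phi",
    directions: Optional[np.ndarray] = None,
    fill_missing_features: bool = False,
) -> pd.DataFrame:
    """Per-sample BHC table on raw abundances through a fitted model.

    With default directions the result is samples x species; a custom block
    yields a single ``contribution`` column.
    """
    M = results.index_matrix(index)
    X = results.prepare(abundances, fill_missing_features).to_numpy()
    contrib = reconstruction_contribution(M, X, directions)
    if directions is None:
        return pd.DataFrame(contrib, index=abundances.index, columns=results.features)
    return pd.DataFrame({"contribution": contrib}, index=abundances.index)


def population_bhc(
    results,
    abundances: pd.DataFrame,
    index: str = "phi",
    groups: Optional[pd.Series] = None,
    fill_missing_features: bool = False,
) -> pd.DataFrame:
    """Population-averaged per-species BHC, optionally per phenotype group.

    Returns a DataFrame with one row per group (a single ``all`` row when
    ``groups`` is None) and one column per species.
    """
    if abundances.shape[0] == 0:
        raise ValueError("empty sample group")
    per_sample = bhc_table(
        results, abundances, index=index, fill_missing_features=fill_missing_features
    )
    if groups is None:
        return pd.DataFrame([per_sample.mean(axis=0)], index=["all"])
    groups = groups.loc[per_sample.index]
    return per_sample.groupby(groups, observed=True).mean()


@dataclass
class BroadSpectrumResult:
    """High-contributor species per disease and their intersection."""

    per_disease: dict[str, list[str]]
    intersection: list[str]
    ratio: float


def high_contributors(contributions: pd.Series, ratio: float) -> list[str]:
    """Minimal descending-BHC prefix whose accumulated share exceeds ``ratio``.

    Species are sorted by contribution (descending, stable) and accumulated
    until the accumulated/total share strictly exceeds the target.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    total = float(contributions.sum())
    if total <= 0:
        raise ValueError("all-zero contribution vector")
    ordered = contributions.sort_values(ascending=False, kind="stable")
    cum = ordered.cumsum() / total
    k = int(np.searchsorted(cum.to_numpy(), ratio, side="right") + 1)
    k = min(k, ordered.size)
    return list(ordered.index[:k])


def broad_spectrum(
    avg_contributions: pd.DataFrame | Mapping[str, pd.Series],
    ratio: float = 0.8,
) -> BroadSpectrumResult:
    """Per-disease high-contributor sets and their cross-disease intersection.

    ``avg_contributions`` maps disease -> population-averaged BHC vector
    (rows of a DataFrame). Species shared by every disease's set are the
    broad-spectrum contributors.
    """
    if isinstance(avg_contributions, pd.DataFrame):
        items = {str(k): avg_contributions.loc[k] for k in avg_contributions.index}
    else:
        items = {str(k): pd.Series(v) for k, v in avg_contributions.items()}
    if not items:
        raise ValueError("no disease contribution vectors supplied")
    per_disease = {name: high_contributors(vec, ratio) for name, vec in items.items()}
    sets = [set(v) for v in per_disease.values()]
    shared = set.intersection(*sets)
    first = next(iter(per_disease.values()))
    intersection = [s for s in first if s in shared]
    return BroadSpectrumResult(per_disease, intersection, ratio)


def spectrum_cluster(
    avg_contributions: pd.DataFrame,
    metric: str = "correlation",
    method: str = "average",
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of disease contribution spectra.

    Parameters
    ----------
    avg_contributions : DataFrame
        Diseases x species averaged BHC profiles.
    metric : str
        ``correlation`` (default) or any :func:`scipy.spatial.distance.pdist`
        metric. Constant profiles make correlation distance undefined.
    method : str
        Linkage method (default average).
    standardize : bool
        Z-score each profile before clustering.

    Returns
    -------
    (linkage, distances)
        The scipy linkage matrix and the condensed distance vector.
    """
    if avg_contributions.shape[0] < 2:
        raise ValueError("need at least 2 disease profiles to cluster")
    X = avg_contributions.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=1, keepdims=True, ddof=0)
        if (sd == 0).any():
            raise ValueError("constant profile cannot be standardized")
        X = (X - X.mean(axis=1, keepdims=True)) / sd
    if metric == "correlation" and (X.std(axis=1) == 0).any():
        raise ValueError(
            "constant contribution profile: correlation distance undefined; "
            "use metric='euclidean'"
        )
    dist = pdist(X, metric=metric)
    # correlation distance can dip microscopically below 0 in floating point
    dist = np.clip(dist, 0.0, None)
    Z = hierarchy.linkage(dist, method=method)
    return Z, dist
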