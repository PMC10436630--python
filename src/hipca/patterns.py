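"""Contrastive PCA and Gaussian-mixture pattern discovery.

Healthy sub-patterns are resolved against the unhealthy background by
eigen-decomposing the covariance contrast ``S_h - alpha * S_uh``: directions
with high healthy variance but low unhealthy variance surface structure that
ordinary PCA of the healthy cohort alone would bury under shared variation
(the Anna Karenina assumption: unhealthy microbiomes vary more, and along
directions common to both cohorts). Projections onto the leading contrastive
directions are then clustered with a Gaussian mixture, the number of
patterns selected by AIC (default) or BIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from ._linalg import eig_descending

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 2
DEFAULT_GMM_RESTARTS = 10


def default_alpha_grid() -> np.ndarray:
    """0 plus 20 log-spaced contrast values in [1e-1, 1e3]."""
    return np.concatenate([[0.0], np.logspace(-1, 3, 20)])


def _covariance(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=0, keepdims=True)
    return centered.T @ centered / (X.shape[0] - 1)


@dataclass
class ContrastiveModel:
    """Fitted contrastive directions and target projections."""

    alpha: float
    directions: np.ndarray  # (D, k), orthonormal columns
    eigvals: np.ndarray  # top-k eigenvalues of S_h - alpha S_uh, descending
    projections: np.ndarray  # target samples x k
    S_h: np.ndarray = field(repr=False, default=None)
    S_uh: np.ndarray = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.directions


def contrastive_pca(
    target: np.ndarray,
    background: np.ndarray,
    alpha: float = 1.0,
    k: int = DEFAULT_N_COMPONENTS,
) -> ContrastiveModel:
    """Top-k eigenvectors of the covariance contrast ``S_h - alpha S_uh``.

    Parameters
    ----------
    target : (n_h, D) array
        Healthy (foreground) samples, already transformed + normalized on
        the same feature axis as the background.
    background : (n_uh, D) array
        Unhealthy samples whose variance is to be suppressed.
    alpha : float
        Contrast parameter >= 0; ``alpha = 0`` reduces to ordinary PCA of
        the target.
    k : int
        Number of contrastive components.
    """
    target = np.asarray(target, dtype=float)
    background = np.asarray(background, dtype=float)
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if target.shape[1] != background.shape[1]:
        raise ValueError("target and background must share the feature axis")
    D = target.shape[1]
    if not 1 <= k <= D:
        raise ValueError(f"k must be in [1, {D}], got {k}")
    S_h = _covariance(target)
    S_uh = _covariance(background)
    contrast = S_h - alpha * S_uh
    eigvals, eigvecs = eig_descending(contrast)
    scale = max(np.abs(eigvals).max(initial=0.0), 1.0)
    if np.abs(eigvals).max(initial=0.0) < 1e-10 * max(np.abs(S_h).max(initial=0.0), 1.0):
        warnings.warn(
            "contrast matrix is numerically zero: degenerate spectrum, "
            "directions are arbitrary"
        )
    elif eigvals.size > k and abs(eigvals[k - 1] - eigvals[k]) < 1e-10 * scale:
        warnings.warn("degenerate spectrum at the retained cut; directions not unique")
    directions = eigvecs[:, :k]
    return ContrastiveModel(
        alpha=float(alpha),
        directions=directions,
        eigvals=eigvals[:k],
        projections=target @ directions,
        S_h=S_h,
        S_uh=S_uh,
    )


@dataclass
class PatternAssignment:
    """GMM clustering outcome over a range of component counts."""

    k_selected: int
    labels: np.ndarray
    aic_trace: pd.Series
    bic_trace: pd.Series
    criterion: str
    seed: int
    model: GaussianMixture = field(repr=False, default=None)


def gmm_patterns(
    projections: np.ndarray,
    k_range: Sequence[int] = range(1, 8),
    criterion: str = "aic",
    seed: int = 0,
    n_init: int = DEFAULT_GMM_RESTARTS,
) -> PatternAssignment:
    """Fit full-covariance Gaussian mixtures over ``k_range``; pick by AIC/BIC.

    Every candidate k is fitted with ``n_init`` restarts at a fixed seed, the
    AIC and BIC traces are recorded, and the selected k minimizes the chosen
    criterion.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    X = np.atleast_2d(np.asarray(projections, dtype=float))
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("k_range is empty")
    if ks[0] < 1 or ks[-1] >= X.shape[0]:
        raise ValueError(
            f"k_range must lie in [1, n_samples={X.shape[0]}), got {ks[0]}..{ks[-1]}"
        )
    fits, aic, bic = {}, {}, {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
        ).fit(X)
        fits[k] = gm
        aic[k] = gm.aic(X)
        bic[k] = gm.bic(X)
    aic = pd.Series(aic, name="aic")
    bic = pd.Series(bic, name="bic")
    trace = aic if criterion == "aic" else bic
    k_selected = int(trace.idxmin())
    best = fits[k_selected]
    return PatternAssignment(
        k_selected=k_selected,
        labels=best.predict(X),
        aic_trace=aic,
        bic_trace=bic,
        criterion=criterion,
        seed=seed,
        model=best,
    )


@dataclass
class AlphaSelection:
    """Chosen contrast parameter with per-alpha diagnostics."""

    alpha: float
    model: ContrastiveModel
    patterns: PatternAssignment
    diagnostics: pd.DataFrame


def select_alpha(
    target: np.ndarray,
    background: np.ndarray,
    alpha_grid: Optional[Sequence[float]] = None,
    k: int = DEFAULT_N_COMPONENTS,
    k_range: Sequence[int] = range(1, 8),
    criterion: str = "aic",
    seed: int = 0,
) -> AlphaSelection:
    """Pick the contrast parameter maximizing clustering quality.

    For each alpha in the grid, contrastive directions are fitted, target
    projections clustered by GMM, and the mean silhouette of the resulting
    partition scored (single-cluster partitions score -1, silhouette's
    minimum). Ties keep the smallest alpha; the full diagnostic table is
    returned so callers can override.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alphas = sorted(float(a) for a in alpha_grid)
    if not alphas:
        raise ValueError("alpha grid is empty")
    rows = []
    best = None
    for alpha in alphas:
        cm = contrastive_pca(target, background, alpha=alpha, k=k)
        pa = gmm_patterns(cm.projections, k_range=k_range, criterion=criterion, seed=seed)
        if pa.k_selected > 1 and len(np.unique(pa.labels)) > 1:
            score = float(silhouette_score(cm.projections, pa.labels))
        else:
            score = -1.0
        rows.append({"alpha": alpha, "k_selected": pa.k_selected, "silhouette": score})
        if best is None or score > best[0]:
            best = (score, alpha, cm, pa)
    _, alpha, cm, pa = best
    return AlphaSelection(
        alpha=alpha, model=cm, patterns=pa, diagnostics=pd.DataFrame(rows)
    )
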