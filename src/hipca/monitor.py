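"""Core hiPCA monitoring model.

A PCA model is fitted to the preprocessed healthy cohort and each sample is
scored by three statistical-process-control charts:

* Hotelling's ``T2(x) = x' P L^-1 P' x`` monitors the principal-component
  subspace, with control limit ``tau2 = chi2_alpha(d)``;
* ``Q(x) = x' (I - P P') x`` monitors the residual subspace, with the
  Box-approximation limit ``delta2 = (theta2/theta1) chi2_alpha(theta1^2/theta2)``,
  ``theta_k = sum_{i>d} lambda_i^k``;
* the combined health index ``phi(x) = T2/tau2 + Q/delta2`` with limit
  ``zeta2 = g chi2_alpha(h)`` where
  ``g = (d/tau2^2 + theta2/delta2^2) / (d/tau2 + theta1/delta2)`` and
  ``h = (d/tau2 + theta1/delta2)^2 / (d/tau2^2 + theta2/delta2^2)``.

``chi2_alpha(v)`` denotes the upper-alpha chi-square quantile at confidence
``(1 - alpha)``, evaluated by the continuous quantile function so that the
non-integer degrees of freedom of the approximations are exact.

The user-facing API follows the fitted-model convention: :class:`HiPCA` is
constructed from a healthy abundance table and ``fit()`` returns a
:class:`HiPCAResults` that scores, predicts, diagnoses and serializes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import eig_descending, floor_eigvals
from .preprocess import (
    DEFAULT_SIGMA,
    TransformParams,
    log_transform,
    prepare,
    zscore_fit,
    zscore_apply,
)

RULES = ("combined", "majority", "any")


def chi2_upper(confidence: float, dof: float) -> float:
    """Upper-alpha chi-square quantile at confidence (1 - alpha), real dof."""
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    return float(stats.chi2.ppf(confidence, dof))


@dataclass
class HiPCAResults:
    """Fitted hiPCA monitoring model.

    Holds the loading matrix ``P`` (orthonormal columns), retained and
    residual eigenvalues, the frozen preprocessing parameters, and -- after
    control limits are computed -- the thresholds ``tau2``, ``delta2``,
    ``zeta2`` at the stored confidence.
    """

    P: np.ndarray
    eigvals: np.ndarray
    eigvals_res: np.ndarray
    d: int
    features: list[str]
    transform: TransformParams
    pve: Optional[float] = None
    confidence: Optional[float] = None
    tau2: Optional[float] = None
    delta2: Optional[float] = None
    zeta2: Optional[float] = None
    n_train: int = 0
    model: Optional["HiPCA"] = field(default=None, repr=False)

    # -- derived matrices ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.P.shape[0]

    @property
    def theta1(self) -> float:
        return float(np.sum(self.eigvals_res))

    @property
    def theta2(self) -> float:
        return float(np.sum(np.square(self.eigvals_res)))

    @property
    def has_residual_subspace(self) -> bool:
        return self.theta1 > 0.0

    @property
    def D_mat(self) -> np.ndarray:
        """T2 index matrix ``P L^-1 P'``."""
        return (self.P / self.eigvals) @ self.P.T

    @property
    def C(self) -> np.ndarray:
        """Projector onto the principal-component subspace."""
        return self.P @ self.P.T

    @property
    def C_tilde(self) -> np.ndarray:
        """Projector onto the residual subspace, ``I - P P'``."""
        return np.eye(self.n_features) - self.C

    @property
    def Phi(self) -> np.ndarray:
        """Combined-index matrix ``C_tilde/delta2 + D/tau2``."""
        self._require_limits()
        return self.C_tilde / self.delta2 + self.D_mat / self.tau2

    def index_matrix(self, index: str) -> np.ndarray:
        """Quadratic-form matrix M with Ind(x) = x' M x for a chart."""
        if index in ("t2", "T2"):
            return self.D_mat
        if index in ("q", "Q"):
            return self.C_tilde
        if index == "phi":
            return self.Phi
        raise ValueError(f"unknown index {index!r}; expected t2, q or phi")

    def limit(self, index: str) -> float:
        self._require_limits()
        return {"t2": self.tau2, "q": self.delta2, "phi": self.zeta2}[index.lower()]

    def _require_limits(self) -> None:
        if self.tau2 is None:
            raise ValueError("control limits not computed; call compute_limits()")
        if self.delta2 is None:
            raise ValueError(
                "model has no residual subspace (theta1 = 0); "
                "only T2 monitoring is available"
            )

    # -- index evaluation ---------------------------------------------------

    def _check_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return X

    def t2(self, X: np.ndarray) -> np.ndarray:
        """Hotelling T2 of normalized sample rows."""
        X = self._check_matrix(X)
        scores = X @ self.P
        return np.sum(scores * scores / self.eigvals, axis=1)

    def q(self, X: np.ndarray) -> np.ndarray:
        """Squared residual norm (SPE) of normalized sample rows."""
        if not self.has_residual_subspace:
            raise ValueError(
                "model has no residual subspace; use a T2-only rule"
            )
        X = self._check_matrix(X)
        resid = X - (X @ self.P) @ self.P.T
        return np.sum(resid * resid, axis=1)

    def phi(self, X: np.ndarray) -> np.ndarray:
        """Combined health index ``T2/tau2 + Q/delta2`` (lower is healthier)."""
        self._require_limits()
        return self.t2(X) / self.tau2 + self.q(X) / self.delta2

    # -- limits -------------------------------------------------------------

    def compute_limits(self, confidence: float = 0.9) -> "HiPCAResults":
        """Chi-square control limits at confidence ``(1 - alpha)``, in place."""
        tau2 = chi2_upper(confidence, self.d)
        th1, th2 = self.theta1, self.theta2
        if th1 > 0.0:
            delta2 = (th2 / th1) * chi2_upper(confidence, th1 * th1 / th2)
            a = self.d / tau2**2 + th2 / delta2**2
            b = self.d / tau2 + th1 / delta2
            zeta2 = (a / b) * chi2_upper(confidence, b * b / a)
        else:
            delta2 = zeta2 = None
        self.confidence = confidence
        self.tau2, self.delta2, self.zeta2 = tau2, delta2, zeta2
        return self

    # -- prediction ---------------------------------------------------------

    def prepare(self, abundances: pd.DataFrame, fill_missing_features: bool = False) -> pd.DataFrame:
        """Raw percent abundances -> normalized model matrix (frozen params)."""
        return prepare(abundances, self.transform, fill_missing_features)

    def score(
        self,
        abundances: pd.DataFrame,
        rule: str = "combined",
        fill_missing_features: bool = False,
    ) -> pd.DataFrame:
        """Score samples and apply an alarm rule.

        Returns a DataFrame with columns ``T2, Q, phi, flag_T2, flag_Q,
        flag_phi, decision`` indexed by sample id. Rules: ``combined``
        (unhealthy iff phi exceeds zeta2), ``majority`` (at least two of the
        three charts exceed), ``any`` (at least one exceeds).
        """
        if rule not in RULES:
            raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
        self._require_limits()
        X = self.prepare(abundances, fill_missing_features).to_numpy()
        t2 = self.t2(X)
        q = self.q(X)
        phi = t2 / self.tau2 + q / self.delta2
        flag_t2 = t2 > self.tau2
        flag_q = q > self.delta2
        flag_phi = phi > self.zeta2
        n_exceed = flag_t2.astype(int) + flag_q.astype(int) + flag_phi.astype(int)
        if rule == "combined":
            unhealthy = flag_phi
        elif rule == "majority":
            unhealthy = n_exceed >= 2
        else:
            unhealthy = n_exceed >= 1
        return pd.DataFrame(
            {
                "T2": t2,
                "Q": q,
                "phi": phi,
                "flag_T2": flag_t2,
                "flag_Q": flag_q,
                "flag_phi": flag_phi,
                "decision": np.where(unhealthy, "unhealthy", "healthy"),
            },
            index=abundances.index,
        )

    predict = score

    def contributions(
        self,
        abundances: pd.DataFrame,
        index: str = "phi",
        fill_missing_features: bool = False,
    ) -> pd.DataFrame:
        """Per-sample, per-species health-index contributions (BHC)."""
        from .diagnose import bhc_table

        return bhc_table(self, abundances, index=index, fill_missing_features=fill_missing_features)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text model summary."""
        total = float(np.sum(self.eigvals) + self.theta1)
        explained = float(np.sum(self.eigvals)) / total if total > 0 else float("nan")
        lines = [
            "hiPCA monitoring model",
            "=" * 46,
            f"features (species):          {self.n_features}",
            f"training samples:            {self.n_train}",
            f"retained components d:       {self.d}",
            f"explained variance:          {explained:.4f}"
            + (f" (target {self.pve})" if self.pve is not None else ""),
            f"theta1, theta2:              {self.theta1:.4f}, {self.theta2:.4f}",
        ]
        if self.tau2 is not None:
            lines += [
                f"confidence (1 - alpha):      {self.confidence}",
                f"T2 limit tau2:               {self.tau2:.4f}",
                f"Q limit delta2:              "
                + (f"{self.delta2:.4f}" if self.delta2 is not None else "undefined"),
                f"phi limit zeta2:             "
                + (f"{self.zeta2:.4f}" if self.zeta2 is not None else "undefined"),
            ]
        else:
            lines.append("control limits:              not computed")
        if self.transform.dropped:
            lines.append(f"dropped features:            {self.transform.dropped}")
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import write_model

        write_model(self, path)

    @staticmethod
    def load(path) -> "HiPCAResults":
        from .io import read_model

        return read_model(path)


def fit_pca(
    normalized: np.ndarray,
    pve: float = 0.9,
    d: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigen-decompose the sample covariance and pick the retained dimension.

    ``S = X'X / (N - 1)`` (the matrix is already centered by the z-score
    step). ``d`` is the smallest k whose cumulative percentage of explained
    variance reaches ``pve``, unless fixed by the caller. Returns
    ``(eigvals, eigvecs, d)`` with eigenvalues floored at numerical zero.
    """
    X = np.asarray(normalized, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if d is None and not 0 < pve <= 1:
        raise ValueError(f"pve must be in (0, 1], got {pve}")
    S = X.T @ X / (n - 1)
    eigvals, eigvecs = eig_descending(S)
    eigvals = floor_eigvals(eigvals)
    rank = int(np.count_nonzero(eigvals))
    if d is None:
        cum = np.cumsum(eigvals) / np.sum(eigvals)
        d = int(np.searchsorted(cum, pve - 1e-12) + 1)
        d = min(d, rank)
    else:
        if not 1 <= d <= eigvals.size:
            raise ValueError(f"d must be in [1, {eigvals.size}], got {d}")
        if d > rank:
            raise ValueError(f"d={d} exceeds the numerical rank {rank}")
    return eigvals, eigvecs, d


class HiPCA:
    """Health-index PCA model specification.

    Parameters
    ----------
    healthy : pandas.DataFrame
        Healthy training cohort, samples x species, percent-scale relative
        abundances (the model is fitted to healthy samples only).
    features : sequence of str, optional
        Species panel to model (e.g., the KS-selected H- species). Defaults
        to every column.
    sigma : float
        Offset of the logarithmic transform.

    Examples
    --------
    >>> model = HiPCA(healthy_df, features=selection.h_minus)
    >>> results = model.fit(pve=0.9, confidence=0.9)
    >>> scores = results.predict(test_df)
    """

    def __init__(
        self,
        healthy: pd.DataFrame,
        features: Optional[Sequence[str]] = None,
        sigma: float = DEFAULT_SIGMA,
    ) -> None:
        if features is not None:
            features = list(features)
            missing = [f for f in features if f not in healthy.columns]
            if missing:
                raise ValueError(f"features not in table: {missing}")
            healthy = healthy[features]
        if healthy.shape[0] < 2:
            raise ValueError("need at least 2 healthy training samples")
        self.healthy = healthy
        self.sigma = sigma

    @classmethod
    def from_abundance(
        cls,
        table,
        features: Optional[Sequence[str]] = None,
        sigma: float = DEFAULT_SIGMA,
    ) -> "HiPCA":
        """Build from an :class:`~hipca.io.AbundanceTable` with metadata:
        the healthy-labelled samples become the training cohort."""
        return cls(table.subset("healthy").data, features=features, sigma=sigma)

    def fit(
        self,
        pve: float = 0.9,
        confidence: float = 0.9,
        d: Optional[int] = None,
    ) -> HiPCAResults:
        """Fit the monitoring model and compute control limits.

        ``pve`` sets the cumulative explained-variance target that fixes the
        retained dimension (or pass ``d`` directly); ``confidence`` is the
        ``(1 - alpha)`` level of all three control limits.
        """
        transformed = pd.DataFrame(
            log_transform(self.healthy.to_numpy(dtype=float), self.sigma),
            index=self.healthy.index,
            columns=self.healthy.columns,
        )
        params = zscore_fit(transformed, sigma=self.sigma)
        if not params.features:
            raise ValueError("no features left after dropping zero-variance columns")
        X = zscore_apply(transformed, params).to_numpy()
        eigvals, eigvecs, d_sel = fit_pca(X, pve=pve, d=d)
        results = HiPCAResults(
            P=eigvecs[:, :d_sel],
            eigvals=eigvals[:d_sel],
            eigvals_res=eigvals[d_sel:],
            d=d_sel,
            features=params.features,
            transform=params,
            pve=pve,
            n_train=X.shape[0],
            model=self,
        )
        results.compute_limits(confidence)
        return results


@dataclass
class TuneResult:
    """Outcome of a (pve, confidence) grid search."""

    pve: float
    confidence: float
    pi: float
    results: HiPCAResults
    grid: pd.DataFrame


def tune_thresholds(
    model: HiPCA,
    abundances: pd.DataFrame,
    labels: pd.Series,
    pve_grid: Sequence[float],
    confidence_grid: Sequence[float],
    w: float = 0.5,
    rule: str = "combined",
    mode: str = "tn",
) -> TuneResult:
    """Grid-search (pve, confidence) maximizing the prediction index PI.

    ``PI = w * upsilon + (1 - w) * eta`` where ``eta`` is the true-positive
    (unhealthy-detection) rate. By default ``upsilon`` is the true-negative
    rate, so ``PI(w=0.5)`` equals balanced accuracy; ``mode="fp"`` uses the
    false-positive rate instead. The model is refitted per pve and the
    limits recomputed per confidence.
    """
    from .evaluate import evaluate_predictions

    if len(pve_grid) == 0 or len(confidence_grid) == 0:
        raise ValueError("pve and confidence grids must be non-empty")
    labels = labels.loc[abundances.index]
    classes = set(labels)
    if not {"healthy", "unhealthy"} <= classes:
        raise ValueError(
            f"labeled set must contain both classes, got {sorted(classes)}"
        )
    rows = []
    best = None
    for pve in pve_grid:
        fitted = model.fit(pve=pve, confidence=confidence_grid[0])
        for conf in confidence_grid:
            fitted = replace(fitted).compute_limits(conf)
            scores = fitted.score(abundances, rule=rule)
            report = evaluate_predictions(scores["decision"], labels)
            pi = report.pi(w, mode=mode)
            rows.append(
                {
                    "pve": pve,
                    "confidence": conf,
                    "d": fitted.d,
                    "tp_rate": report.tp_rate,
                    "tn_rate": report.tn_rate,
                    "balanced_accuracy": report.balanced_accuracy,
                    "pi": pi,
                }
            )
            if best is None or pi > best.pi:
                best = TuneResult(pve, conf, pi, fitted, grid=None)
    best.grid = pd.DataFrame(rows)
    return best


def grid(*seqs) -> list[tuple]:
    return list(itertools.product(*seqs))
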