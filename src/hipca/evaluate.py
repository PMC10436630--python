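"""Prediction-performance and community-ecology metrics.

Unhealthy is the positive class throughout: ``eta`` (true-positive rate) is
the fraction of unhealthy samples alarmed, the true-negative rate the
fraction of healthy samples passed, and balanced accuracy their mean. The
weighted prediction index ``PI = w * upsilon + (1 - w) * eta`` trades the
two off; by default ``upsilon`` is the true-negative rate (so PI at w = 0.5
is balanced accuracy), with a strict false-positive reading available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EvalReport:
    """Confusion rates and per-phenotype detection table."""

    tp_rate: float
    tn_rate: float
    fp_rate: float
    fn_rate: float
    balanced_accuracy: float
    n_healthy: int
    n_unhealthy: int
    per_phenotype: Optional[pd.DataFrame] = None

    def pi(self, w: float = 0.5, mode: str = "tn") -> float:
        """Weighted prediction index ``w * upsilon + (1 - w) * eta``.

        ``mode="tn"`` (default) takes upsilon as the true-negative rate;
        ``mode="fp"`` as the false-positive rate.
        """
        if mode == "tn":
            upsilon = self.tn_rate
        elif mode == "fp":
            upsilon = self.fp_rate
        else:
            raise ValueError(f"mode must be 'tn' or 'fp', got {mode!r}")
        return w * upsilon + (1.0 - w) * self.tp_rate


def evaluate_predictions(
    decisions: pd.Series,
    labels: pd.Series,
    phenotypes: Optional[pd.Series] = None,
) -> EvalReport:
    """Confusion rates of healthy/unhealthy decisions against true labels.

    The per-phenotype table reports, for each unhealthy phenotype, the
    fraction of its samples called unhealthy; for the healthy phenotype, the
    fraction called healthy.
    """
    decisions = pd.Series(decisions)
    labels = pd.Series(labels)
    if len(decisions) != len(labels):
        raise ValueError(
            f"decision/label length mismatch: {len(decisions)} vs {len(labels)}"
        )
    dec = np.asarray(decisions) == "unhealthy"
    lab = np.asarray(labels) == "unhealthy"
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    tp = float((dec & lab).sum() / n_pos) if n_pos else float("nan")
    tn = float((~dec & ~lab).sum() / n_neg) if n_neg else float("nan")
    report = EvalReport(
        tp_rate=tp,
        tn_rate=tn,
        fp_rate=1.0 - tn if n_neg else float("nan"),
        fn_rate=1.0 - tp if n_pos else float("nan"),
        balanced_accuracy=(tp + tn) / 2.0,
        n_healthy=n_neg,
        n_unhealthy=n_pos,
    )
    if phenotypes is not None:
        phenotypes = pd.Series(phenotypes)
        rows = []
        for phen in pd.unique(phenotypes):
            mask = np.asarray(phenotypes) == phen
            is_healthy_phen = (~lab[mask]).all()
            if is_healthy_phen:
                rate = float((~dec[mask]).sum() / mask.sum())
            else:
                rate = float(dec[mask].sum() / mask.sum())
            rows.append(
                {"phenotype": phen, "n": int(mask.sum()), "detection_rate": rate}
            )
        report.per_phenotype = pd.DataFrame(rows).set_index("phenotype")
    return report


def shannon_richness(abundances) -> tuple[float, int]:
    """Shannon diversity (natural log) and richness of one abundance row.

    Richness counts strictly positive entries; Shannon is ``-sum p ln p``
    over the renormalized positive entries.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("all-zero sample: diversity undefined")
    p = pos / pos.sum()
    shannon = float(-np.sum(p * np.log(p)))
    return shannon, int(pos.size)


def rank_correlate(index_values, covariate) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with two-sided P."""
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def h_minus_richness(abundances: pd.DataFrame, h_minus: list[str]) -> pd.Series:
    """Per-sample count of strictly positive health-scarce (H-) species."""
    unknown = [s for s in h_minus if s not in abundances.columns]
    if unknown:
        raise ValueError(f"species not in table: {unknown}")
    if not h_minus:
        return pd.Series(0, index=abundances.index, name="h_minus_richness")
    counts = (abundances[h_minus].to_numpy(dtype=float) > 0).sum(axis=1)
    return pd.Series(counts, index=abundances.index, name="h_minus_richness")


def iqr_fence(values, k: float = 1.5) -> np.ndarray:
    """Boolean mask of values inside the Tukey fence [Q1 - k*IQR, Q3 + k*IQR].

    Helper for caller-side covariate outlier filtering ahead of
    :func:`rank_correlate`.
    """
    x = np.asarray(values, dtype=float)
    q1, q3 = np.nanpercentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - k * iqr) & (x <= q3 + k * iqr)
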