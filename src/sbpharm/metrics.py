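"""Consensus scoring, enrichment statistics, ligand-efficiency metrics,
Spearman correlation and bit-vector Tanimoto similarity."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONSENSUS_COLUMNS = ("chemplp", "goldscore", "fit")

DEFAULT_RIE_ALPHA = 20.0


# ---------------------------------------------------------------------------
# consensus scoring
# ---------------------------------------------------------------------------


def consensus_score(records: pd.DataFrame, columns: Sequence[str] = CONSENSUS_COLUMNS) -> pd.DataFrame:
    """Sum of per-column min-max normalizations over the supplied population.

    Each score column is rescaled to [0, 1] using its own min/max across the
    records; a degenerate column (max == min) contributes a neutral 0.5 to
    every record.  The result lies in [0, 3] for three columns.
    """
    if len(records) == 0:
        raise ValueError("consensus_score requires at least one record")
    out = records.copy()
    total = np.zeros(len(records))
    for col in columns:
        vals = records[col].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            total += (vals - lo) / (hi - lo)
        else:
            total += 0.5
    out["consensus"] = total
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    auc: float
    rie: float
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR)


def roc_auc(active_scores, decoy_scores, higher_is_better: bool = True) -> float:
    """Rank-sum AUC with half credit for ties."""
    a = np.asarray(active_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if a.size == 0 or d.size == 0:
        raise ValueError("both score sets must be non-empty")
    if not higher_is_better:
        a, d = -a, -d
    ranks = stats.rankdata(np.concatenate([a, d]))
    rank_sum = ranks[: a.size].sum()
    return float((rank_sum - a.size * (a.size + 1) / 2.0) / (a.size * d.size))


def roc_curve(active_scores, decoy_scores, higher_is_better: bool = True) -> np.ndarray:
    a = np.asarray(active_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if not higher_is_better:
        a, d = -a, -d
    scores = np.concatenate([a, d])
    labels = np.concatenate([np.ones(a.size), np.zeros(d.size)])
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(labels) / a.size])
    fpr = np.concatenate([[0.0], np.cumsum(1 - labels) / d.size])
    return np.column_stack([fpr, tpr])


def rie(ranked_labels, alpha: float = DEFAULT_RIE_ALPHA) -> float:
    """Robust initial enhancement of a ranked binary label list.

    Mean exponential rank weight of the actives divided by its expectation
    under uniform random ranking: (1/N) (1 - e^-alpha) / (e^(alpha/N) - 1).
    """
    labels = np.asarray(ranked_labels, dtype=bool)
    N = labels.size
    n = int(labels.sum())
    if n == 0 or n == N:
        raise ValueError("ranking must contain both actives and inactives")
    ranks = np.nonzero(labels)[0] + 1  # 1-based ranks of actives
    observed = np.mean(np.exp(-alpha * ranks / N))
    expected = (1.0 / N) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)
    return float(observed / expected)


def enrichment(active_scores, decoy_scores, alpha: float = DEFAULT_RIE_ALPHA, higher_is_better: bool = True) -> EnrichmentResult:
    a = np.asarray(active_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    auc = roc_auc(a, d, higher_is_better)
    scores = np.concatenate([a, d]) * (1 if higher_is_better else -1)
    labels = np.concatenate([np.ones(a.size, dtype=bool), np.zeros(d.size, dtype=bool)])
    order = np.argsort(-scores, kind="stable")
    return EnrichmentResult(auc=auc, rie=rie(labels[order], alpha), roc_points=roc_curve(a, d, higher_is_better))


# ---------------------------------------------------------------------------
# ligand efficiency metrics
# ---------------------------------------------------------------------------


def le_scale(hac: int) -> float:
    """Size-dependent maximal ligand-efficiency scale (Reynolds fit)."""
    if hac <= 0:
        raise ValueError("HAC must be >= 1")
    return 0.0715 + 7.5328 / hac + 25.7079 / hac**2 - 361.4722 / hac**3


def ligand_efficiency(pic50: float, hac: int) -> float:
    """LE = pIC50 / heavy atom count."""
    if hac <= 0:
        raise ValueError("HAC must be >= 1")
    return pic50 / hac


def lle(pic50: float, logp: float) -> float:
    """Lipophilic ligand efficiency: pIC50 - logP."""
    return pic50 - logp


def fit_quality(pic50: float, hac: int) -> float:
    """FQ = (unrounded) LE normalized by the size-dependent LE scale."""
    return ligand_efficiency(pic50, hac) / le_scale(hac)


def efficiency_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add LE/LLE/FQ columns to a (ligand_id, pIC50, logP, HAC) table."""
    out = table.copy()
    out["LE"] = [ligand_efficiency(p, h) for p, h in zip(out["pIC50"], out["HAC"])]
    out["LLE"] = [lle(p, lp) for p, lp in zip(out["pIC50"], out["logP"])]
    out["FQ"] = [fit_quality(p, h) for p, h in zip(out["pIC50"], out["HAC"])]
    return out


# ---------------------------------------------------------------------------
# rank correlation and similarity
# ---------------------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def tanimoto(bits_a, bits_b) -> float:
    """|a AND b| / |a OR b| on equal-length bit vectors; 1.0 when both empty."""
    a = np.asarray(bits_a, dtype=bool)
    b = np.asarray(bits_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("bit vectors must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
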