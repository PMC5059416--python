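"""Target-decoy confidence estimation.

The same machinery serves PSMs, peptides and protein groups: each entity
is an (id, score, label) triple, and decoy matches stand in for the
incorrect-target score distribution.  Provided here are

* q-values from target-decoy counts with the conservative ``+1``
  pseudo-count and no pi0 correction,
* posterior error probabilities from a binned decoy/target ratio made
  monotone by isotonic regression,
* empirical p-values against the decoy score distribution, and
* Fisher's method for combining independent p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "ScoredEntity",
    "target_decoy_qvalues",
    "qvalues_from_target_decoy",
    "pep_estimates",
    "estimate_peps",
    "empirical_pvalue",
    "empirical_pvalues",
    "fisher_combine",
    "confidence_table",
]

TARGET = "target"
DECOY = "decoy"


@dataclass(frozen=True)
class ScoredEntity:
    """Generic scored match: a PSM, a peptide, or a protein group."""

    id: str
    score: float
    label: str  # "target" or "decoy"

    def __post_init__(self) -> None:
        if self.label not in (TARGET, DECOY):
            raise ValueError(f"label must be 'target' or 'decoy', got {self.label!r}")
        if not np.isfinite(self.score):
            raise ValueError(f"score for {self.id!r} is not finite")


def _as_arrays(entities: Sequence[ScoredEntity]):
    scores = np.array([e.score for e in entities], dtype=float)
    is_target = np.array([e.label == TARGET for e in entities], dtype=bool)
    ids = [e.id for e in entities]
    return ids, scores, is_target


def target_decoy_qvalues(scores: np.ndarray, is_target: np.ndarray) -> np.ndarray:
    """q-values for every entity from target-decoy competition counts.

    At each target-score threshold ``t`` the FDR estimate is
    ``(1 + #{decoys >= t}) / #{targets >= t}``; the q-value of a score
    ``s`` is the minimum FDR over thresholds ``t <= s``, capped at 1.
    Entities tied in score share a q-value (threshold semantics use
    ``>=``).  Decoys receive the q-value of the nearest target threshold
    at or below their score, for reporting only.
    """
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_targets = int(is_target.sum())
    if n_targets == 0:
        raise ValueError("q-value estimation requires at least one target")
    t_sorted = np.sort(scores[is_target])
    d_sorted = np.sort(scores[~is_target])
    thresholds = np.unique(t_sorted)  # ascending
    n_t_ge = n_targets - np.searchsorted(t_sorted, thresholds, side="left")
    n_d_ge = d_sorted.size - np.searchsorted(d_sorted, thresholds, side="left")
    fdr = (n_d_ge + 1.0) / n_t_ge
    q_at_threshold = np.minimum(np.minimum.accumulate(fdr), 1.0)
    idx = np.searchsorted(thresholds, scores, side="right") - 1
    idx = np.maximum(idx, 0)  # scores below every target take the loosest threshold
    return q_at_threshold[idx]


def qvalues_from_target_decoy(entities: Sequence[ScoredEntity]) -> pd.DataFrame:
    """Confidence table with q-values, sorted by descending score."""
    ids, scores, is_target = _as_arrays(entities)
    q = target_decoy_qvalues(scores, is_target)
    df = pd.DataFrame(
        {
            "id": ids,
            "label": np.where(is_target, TARGET, DECOY),
            "score": scores,
            "q_value": q,
        }
    )
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)


def pep_estimates(
    scores: np.ndarray, is_target: np.ndarray, n_bins: int | None = None
) -> np.ndarray:
    """Posterior error probabilities via a binned decoy/target ratio.

    Entities are sorted by score into equal-count bins; the raw PEP of a
    bin is ``min(1, #decoys / #targets)`` within it, and isotonic
    (pool-adjacent-violators) regression enforces a PEP that is
    non-increasing with score.  Below 20 targets or 20 decoys a single
    global bin is used.
    """
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    n = scores.size
    n_t = int(is_target.sum())
    n_d = n - n_t
    if n_bins is None:
        n_bins = max(20, n // 500)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_t < 20 or n_d < 20:
        return np.full(n, min(1.0, n_d / max(n_t, 1)))
    order = np.argsort(scores, kind="mergesort")  # ascending
    chunks = [c for c in np.array_split(order, n_bins) if c.size]
    x, raw, w = [], [], []
    for c in chunks:
        t = int(is_target[c].sum())
        d = c.size - t
        raw.append(min(1.0, d / t) if t else 1.0)
        x.append(float(scores[c].mean()))
        w.append(float(c.size))
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0, out_of_bounds="clip")
    fitted = iso.fit_transform(np.asarray(x), np.asarray(raw), sample_weight=np.asarray(w))
    pep = np.empty(n)
    for c, value in zip(chunks, fitted):
        pep[c] = value
    return pep


def estimate_peps(
    entities: Sequence[ScoredEntity], n_bins: int | None = None
) -> pd.DataFrame:
    """Confidence table with PEPs, sorted by descending score."""
    ids, scores, is_target = _as_arrays(entities)
    pep = pep_estimates(scores, is_target, n_bins)
    df = pd.DataFrame(
        {
            "id": ids,
            "label": np.where(is_target, TARGET, DECOY),
            "score": scores,
            "pep": pep,
        }
    )
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)


def empirical_pvalues(scores: np.ndarray, decoy_scores: np.ndarray) -> np.ndarray:
    """Empirical p-values against the decoy score distribution.

    ``p = (1 + #{decoys >= score}) / (1 + #decoys)`` — the add-one
    smoothing keeps every p strictly positive, as Fisher's method
    requires.
    """
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    if decoy_scores.size == 0:
        raise ValueError("empirical p-values require at least one decoy score")
    d_sorted = np.sort(decoy_scores)
    n_ge = d_sorted.size - np.searchsorted(d_sorted, np.asarray(scores, dtype=float), side="left")
    return (1.0 + n_ge) / (1.0 + d_sorted.size)


def empirical_pvalue(score: float, decoy_scores: Sequence[float]) -> float:
    """Scalar convenience wrapper around :func:`empirical_pvalues`."""
    return float(empirical_pvalues(np.array([score]), np.asarray(decoy_scores))[0])


def fisher_combine(p_values: Iterable[float]) -> float:
    """Combine independent p-values with Fisher's method.

    ``X = -2 * sum(ln p_i)`` follows a chi-square distribution with
    ``2k`` degrees of freedom under the global null; the survival
    probability at ``X`` is returned.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(chi2.sf(stat, 2 * p.size))


def confidence_table(
    entities: Sequence[ScoredEntity],
    n_bins: int | None = None,
    with_pvalues: bool = False,
) -> pd.DataFrame:
    """Full confidence table: q-values, PEPs, and optional p-values."""
    ids, scores, is_target = _as_arrays(entities)
    df = pd.DataFrame(
        {
            "id": ids,
            "label": np.where(is_target, TARGET, DECOY),
            "score": scores,
            "q_value": target_decoy_qvalues(scores, is_target),
            "pep": pep_estimates(scores, is_target, n_bins),
        }
    )
    if with_pvalues:
        decoy_scores = scores[~is_target]
        df["p_value"] = empirical_pvalues(scores, decoy_scores)
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
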