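"""The two antenatal-care dimensions and the scale-reliability coefficient.

Dimension 1 (independent of the health system): an indicator of three or
more ANC visits.  Dimension 2 (dependent on the health system): women are
scored on the first principal component of the eight binary service items,
cut into L equal-probability levels, and flagged when they reach the
highest level.  Internal consistency of the item set is summarized by
Cronbach's alpha.

PCA is covariance-based on the raw 0/1 items — the same convention the DHS
wealth index uses — rather than tetrachoric.  The first component is
sign-oriented so that receiving every service scores highest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, DegenerateInputError


@dataclass
class CareScore:
    """First-principal-component scoring of the service items."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: float


@dataclass
class ReliabilityResult:
    """Cronbach's alpha and its ingredients."""

    alpha: float
    k: int
    item_variances: np.ndarray
    total_variance: float


@dataclass
class AncDimensions:
    """Per-woman values of both ANC dimensions."""

    d1: np.ndarray
    care_score: np.ndarray
    care_level: np.ndarray
    d2: np.ndarray
    levels: int
    pca: CareScore
    reliability: ReliabilityResult


def compute_visit_dimension(anc_visits) -> np.ndarray:
    """Indicator of three or more ANC visits (D1)."""
    visits = np.asarray(anc_visits)
    if visits.size and visits.min() < 0:
        raise DataError("ANC visit counts must be non-negative")
    return (visits >= 3).astype(np.int64)


def _as_item_matrix(items) -> np.ndarray:
    X = items.to_numpy(dtype=float) if isinstance(items, pd.DataFrame) else np.asarray(items, dtype=float)
    if X.ndim != 2:
        raise DataError("items must be a 2-D table (rows = women, columns = items)")
    if np.isnan(X).any():
        raise DataError("items contain missing values; drop incomplete rows upstream")
    return X


def care_pca(items) -> CareScore:
    """PCA of the item covariance matrix, keeping the first component.

    Scores are centered at zero.  The component is oriented so the loading
    sum is positive, making "all services received" the highest-scoring
    pattern whenever loadings share a sign.
    """
    X = _as_item_matrix(items)
    n = X.shape[0]
    if n < 2:
        raise DegenerateInputError("PCA needs at least 2 rows")
    centered = X - X.mean(axis=0)
    if not np.any(centered):
        raise DegenerateInputError("all rows identical: item covariance is zero")
    cov = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, -1]
    if v.sum() < 0 or (v.sum() == 0 and v[np.argmax(np.abs(v))] < 0):
        v = -v
    scores = centered @ v
    ratio = float(eigvals[-1] / eigvals.sum())
    return CareScore(scores=scores, loadings=v, explained_variance_ratio=ratio)


def compute_care_score(items) -> np.ndarray:
    """First-principal-component care-intensity score (centered)."""
    return care_pca(items).scores


def classify_care_level(care_score, levels: int) -> np.ndarray:
    """Quantile cut of the care score into ``levels`` equal-probability levels.

    Tertiles for L=3, median split for L=2.  A tied block straddling a cut
    is assigned wholly to the lower level, so level sizes can differ by the
    size of the tie block.  Level L is the highest intensity of care.
    """
    if levels not in (2, 3):
        raise DataError(f"levels must be 2 or 3, got {levels}")
    scores = np.asarray(care_score, dtype=float)
    n = scores.size
    if n == 0 or np.ptp(scores) == 0:
        raise DegenerateInputError("care scores have no variation; cannot cut levels")
    s = np.sort(scores)
    cuts = [s[int(np.ceil(n * k / levels)) - 1] for k in range(1, levels)]
    return 1 + (scores[:, None] > np.asarray(cuts)[None, :]).sum(axis=1)


def compute_care_dimension(care_level, levels: int) -> np.ndarray:
    """Indicator of the highest care level (D2)."""
    level = np.asarray(care_level)
    if level.size and (level.min() < 1 or level.max() > levels):
        raise DataError(f"care levels must lie in 1..{levels}")
    return (level == levels).astype(np.int64)


def cronbach_alpha(items) -> ReliabilityResult:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item variances)/total variance)."""
    X = _as_item_matrix(items)
    n, k = X.shape
    if k < 2:
        raise DataError("alpha needs at least 2 items")
    if n < 2:
        raise DataError("alpha needs at least 2 rows")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateInputError("total score has zero variance")
    alpha = (k / (k - 1)) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(alpha=float(alpha), k=k, item_variances=item_var,
                             total_variance=float(total_var))


def compute_dimensions(anc_visits, items, levels: int = 3) -> AncDimensions:
    """Both dimensions plus scoring metadata for one microdata table."""
    d1 = compute_visit_dimension(anc_visits)
    pca = care_pca(items)
    level = classify_care_level(pca.scores, levels)
    d2 = compute_care_dimension(level, levels)
    rel = cronbach_alpha(items)
    return AncDimensions(d1=d1, care_score=pca.scores, care_level=level, d2=d2,
                         levels=levels, pca=pca, reliability=rel)
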