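"""Variable-importance and model-evaluation statistics.

Covers the quantities used to screen predictors and compare fitted models:
rank-based AUC, permutation importance (the sole importance indicator used
for screening), small-sample-corrected AIC, and the Schoener's D / Warren's
I niche-overlap statistics between suitability surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent_engine import MaxentModel, predict

__all__ = [
    "OverlapPair", "auc", "permutation_importance", "aicc",
    "aicc_from_loglik", "niche_overlap", "similarity_matrix",
]


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC of presence vs background scores.

    Ties count one half; identical constant scores give exactly 0.5.
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("scores must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    r1 = ranks[:p.size].sum()
    u = r1 - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def permutation_importance(model: MaxentModel,
                           presence_X: pd.DataFrame | np.ndarray,
                           background_X: pd.DataFrame | np.ndarray,
                           seed: int = 0, n_permutations: int = 1) -> pd.Series:
    """Per-variable permutation importance, as percentages summing to 100.

    For each variable in the data, its values are permuted jointly across
    the stacked presence+background rows, the training AUC is recomputed,
    and the drop from the baseline AUC (floored at 0) is recorded, averaged
    over ``n_permutations``. Drops are normalized to percentages. Variables
    present in the data but not in the model score 0.
    """
    if len(model.variable_names) == 0:
        raise ValueError("model has no variables; importance undefined")
    P = _as_frame(presence_X, model.variable_names)
    B = _as_frame(background_X, model.variable_names)
    rng = np.random.default_rng(seed)
    base = auc(predict(model, P, "raw"), predict(model, B, "raw"))
    m = len(P)
    drops = {}
    for name in P.columns:
        if name not in model.variable_names:
            drops[name] = 0.0
            continue
        acc = 0.0
        for _ in range(n_permutations):
            combined = np.concatenate([P[name].to_numpy(), B[name].to_numpy()])
            rng.shuffle(combined)
            Pp, Bp = P.copy(), B.copy()
            Pp[name] = combined[:m]
            Bp[name] = combined[m:]
            acc += max(0.0, base - auc(predict(model, Pp, "raw"),
                                       predict(model, Bp, "raw")))
        drops[name] = acc / n_permutations
    out = pd.Series(drops, dtype=float)
    total = out.sum()
    return out * (100.0 / total) if total > 0 else out


def _as_frame(X, names: Sequence[str]) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.copy()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return pd.DataFrame(X, columns=list(names))


def aicc_from_loglik(loglik: float, K: int, n: int) -> float:
    """AICc = 2K − 2 lnL + 2K(K+1)/(n − K − 1); NaN when n ≤ K + 1."""
    if n <= K + 1:
        warnings.warn(f"AICc undefined for n={n}, K={K}", stacklevel=2)
        return float("nan")
    return 2 * K - 2 * loglik + 2 * K * (K + 1) / (n - K - 1)


def aicc(model: MaxentModel, presence_X, background_X=None) -> float:
    """Small-sample-corrected AIC of a fitted model at its presences.

    The likelihood of each presence is the model's raw output renormalized
    to sum 1 over the evaluation extent — the presence plus background rows
    when ``background_X`` is given (the usual convention in niche-model
    selection), or the presence rows alone otherwise. K counts nonzero
    coefficients.
    """
    from scipy.special import logsumexp

    P = _as_frame(presence_X, model.variable_names)
    scores_p = model.linear_score(P)
    all_scores = scores_p
    if background_X is not None:
        B = _as_frame(background_X, model.variable_names)
        all_scores = np.concatenate([scores_p, model.linear_score(B)])
    # log of raw renormalized over the evaluation extent, in log space
    loglik = float((scores_p - logsumexp(all_scores)).sum())
    return aicc_from_loglik(loglik, model.n_nonzero, len(P))


@dataclass(frozen=True)
class OverlapPair:
    """Niche-overlap statistics between two normalized suitability maps."""

    d: float   # Schoener's D
    i: float   # Warren's I (Hellinger-based)


def _normalize_map(m: np.ndarray) -> np.ndarray:
    v = np.asarray(m, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if (v < 0).any():
        raise ValueError("suitability maps must be non-negative")
    s = v.sum()
    if s <= 0:
        raise ValueError("all-zero map cannot be normalized")
    return v / s


def niche_overlap(map1: np.ndarray, map2: np.ndarray) -> OverlapPair:
    """Schoener's D and Warren's I between two suitability surfaces.

    Maps must share grid and mask (NaN cells are treated as the mask and
    must coincide). Each map is normalized to sum 1 over valid cells;
    D = 1 − ½ Σ|p1 − p2| and I = 1 − ½ Σ(√p1 − √p2)².
    """
    a1, a2 = np.asarray(map1, dtype=float), np.asarray(map2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError("maps must share a grid")
    if not np.array_equal(np.isfinite(a1), np.isfinite(a2)):
        raise ValueError("maps must share a nodata mask")
    p1, p2 = _normalize_map(a1), _normalize_map(a2)
    d = 1.0 - 0.5 * np.abs(p1 - p2).sum()
    i = 1.0 - 0.5 * ((np.sqrt(p1) - np.sqrt(p2)) ** 2).sum()
    return OverlapPair(float(np.clip(d, 0.0, 1.0)), float(np.clip(i, 0.0, 1.0)))


def similarity_matrix(maps: Mapping[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise D and I matrices over named suitability maps.

    Returns two symmetric DataFrames with unit diagonal, ordered as given.
    """
    names = list(maps)
    if len(names) < 2:
        raise ValueError("need at least 2 maps")
    D = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    I = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            pair = niche_overlap(maps[a], maps[b])
            D.loc[a, b] = D.loc[b, a] = pair.d
            I.loc[a, b] = I.loc[b, a] = pair.i
    return D, I
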