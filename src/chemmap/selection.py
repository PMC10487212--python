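"""Availability-constrained wavelength selection.

Two procedures pick up to six wavelengths per composition from the
commercially available candidates:

* **ranking and uncorrelatedness** — RReliefF (regression Relief) ranks the
  candidates, then the top 20 are pruned so no survivor is correlated above
  |r| = 0.8 with an earlier survivor, keeping at most six;
* **subset selection** — correlation-based feature selection (CFS): a
  best-first search over the subset lattice scores subsets by the merit
  ``k * r_cf / sqrt(k + k (k - 1) * r_ff)``, and an oversized winner is
  reduced by enumerating all six-member sub-subsets.

Both are deterministic given the data, configuration and seed.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


# --------------------------------------------------------------------------
# candidate restriction by commercial availability
# --------------------------------------------------------------------------

MODALITIES = ("filter", "light_source")


@dataclass
class CandidateSet:
    """Wavelengths that survive the availability filter, with their column
    indices into the full spectra grid."""

    wavelengths: np.ndarray
    indices: np.ndarray
    modality: str


def filter_available(grid_wavelengths, availability, modality: str) -> CandidateSet:
    """Keep exactly the grid wavelengths flagged available for ``modality``.

    ``modality="filter"`` uses the bandpass-filter flags;
    ``modality="light_source"`` uses the union of the LED and laser flags.
    """
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}; got {modality!r}")
    grid = np.asarray(grid_wavelengths, dtype=float)
    avail_wl = availability["wavelength"].to_numpy(dtype=float)
    if modality == "filter":
        flags = availability["available_filter"].to_numpy(dtype=bool)
    else:
        flags = (availability["available_led"].to_numpy(dtype=bool)
                 | availability["available_laser"].to_numpy(dtype=bool))
    available = set(avail_wl[flags])
    idx = np.array([i for i, w in enumerate(grid) if w in available], dtype=int)
    if idx.size == 0:
        raise ValueError(f"no grid wavelength is commercially available for {modality}")
    return CandidateSet(wavelengths=grid[idx], indices=idx, modality=modality)


# --------------------------------------------------------------------------
# RReliefF (regression Relief) ranking
# --------------------------------------------------------------------------

def rrelieff_weights(X, y, k_neighbors: int = 10, n_iterations: int | None = None,
                     sigma: float = 20.0, seed: int = 0) -> np.ndarray:
    """Feature weights by the regression Relief algorithm.

    For each probed instance, the ``k_neighbors`` nearest neighbours (by
    Manhattan distance on range-normalised features) contribute
    rank-weighted estimates of the probabilities of a changed prediction,
    a changed feature value, and both together; the weight of feature ``f``
    is ``P(dA & dC)/P(dC) - P(dA & ~dC)/P(~dC)``.

    ``n_iterations=None`` probes every instance in order (deterministic and
    sample-order invariant); a smaller count probes a seeded random subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} samples; got {n}")
    y_range = y.max() - y.min()
    if y_range <= 0:
        raise ValueError("target is constant; RReliefF weights are undefined")

    f_range = X.max(axis=0) - X.min(axis=0)
    nonconst = f_range > 0
    Xn = np.zeros_like(X)
    Xn[:, nonconst] = (X[:, nonconst] - X[:, nonconst].min(axis=0)) / f_range[nonconst]
    yn = (y - y.min()) / y_range

    if n_iterations is None or n_iterations >= n:
        probes = np.arange(n)
    else:
        probes = np.sort(np.random.default_rng(seed).choice(n, n_iterations, replace=False))

    rank_w = np.exp(-((np.arange(1, k_neighbors + 1) / sigma) ** 2))
    rank_w = rank_w / rank_w.sum()

    dist = cdist(Xn[probes], Xn, metric="cityblock")
    dist[np.arange(len(probes)), probes] = np.inf  # exclude self

    n_dC = 0.0
    n_dA = np.zeros(d)
    n_dCdA = np.zeros(d)
    for row, i in enumerate(probes):
        nbr = np.argpartition(dist[row], k_neighbors)[:k_neighbors]
        nbr = nbr[np.argsort(dist[row][nbr], kind="stable")]
        d_y = np.abs(yn[i] - yn[nbr])                       # (k,)
        d_f = np.abs(Xn[i] - Xn[nbr])                       # (k, d)
        n_dC += float(d_y @ rank_w)
        n_dA += rank_w @ d_f
        n_dCdA += (d_y * rank_w) @ d_f
    m = float(len(probes))
    if n_dC <= 0 or m - n_dC <= 0:
        return np.zeros(d)
    return n_dCdA / n_dC - (n_dA - n_dCdA) / (m - n_dC)


def prune_correlated(ranked_indices, X, top_n: int = 20, r_threshold: float = 0.8,
                     max_keep: int = 6) -> list[int]:
    """Uncorrelatedness pruning of a ranked candidate list.

    Take the ``top_n`` best-ranked candidates; the rank-1 candidate always
    survives; walk the survivor list dropping any later candidate whose
    |Pearson r| with the current survivor exceeds ``r_threshold``; keep at
    most ``max_keep`` survivors.
    """
    ranked = list(ranked_indices)[:top_n]
    if not ranked:
        raise ValueError("ranked candidate list is empty")
    X = np.asarray(X, dtype=float)
    survivors = ranked.copy()
    pos = 0
    while pos < len(survivors):
        anchor = survivors[pos]
        kept = survivors[: pos + 1]
        for j in survivors[pos + 1:]:
            r = _safe_corr(X[:, anchor], X[:, j])
            if abs(r) <= r_threshold:
                kept.append(j)
        survivors = kept
        pos += 1
    return survivors[:max_keep]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# CFS merit and best-first subset search
# --------------------------------------------------------------------------

class _CfsCorrelations:
    """Precomputed |Pearson r| tables for fast incremental merit evaluation."""

    def __init__(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        sd = X.std(axis=0)
        zero_var = sd == 0
        if zero_var.any():
            warnings.warn(
                f"{int(zero_var.sum())} zero-variance feature(s) excluded from "
                "correlations (treated as uncorrelated)"
            )
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sy = y.std()
        if sy == 0:
            raise ValueError("target is constant; CFS merit is undefined")
        with np.errstate(divide="ignore", invalid="ignore"):
            r_cf = (Xc.T @ yc) / (n * sd * sy)
            cov = (Xc.T @ Xc) / n
            r_ff = cov / np.outer(sd, sd)
        r_cf[zero_var] = 0.0
        r_ff[zero_var, :] = 0.0
        r_ff[:, zero_var] = 0.0
        np.fill_diagonal(r_ff, 1.0)
        self.abs_cf = np.abs(r_cf)
        self.abs_ff = np.abs(r_ff)

    def merit(self, subset) -> float:
        """CFS merit ``k r_cf / sqrt(k + k (k-1) r_ff)`` of a feature subset."""
        idx = np.fromiter(subset, dtype=int)
        k = idx.size
        if k == 0:
            return 0.0
        s_cf = float(self.abs_cf[idx].sum())
        if k == 1:
            return s_cf
        sub = self.abs_ff[np.ix_(idx, idx)]
        s_ff = float((sub.sum() - k) / 2.0)  # sum over unordered distinct pairs
        return s_cf / np.sqrt(k + 2.0 * s_ff)


def cfs_merit(subset, X, y) -> float:
    """CFS merit of ``subset`` (column indices into ``X``) against ``y``."""
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    return _CfsCorrelations(X, y).merit(subset)


def bestfirst_search(candidates, X, y, stale_limit: int = 5,
                     corr: "_CfsCorrelations | None" = None) -> list[int]:
    """Best-first search over the subset lattice, scored by CFS merit.

    Starts from the empty set; each expansion toggles one candidate (add or
    remove); nodes are expanded in order of decreasing merit; the search
    stops after ``stale_limit`` consecutive expansions that fail to improve
    the best merit seen, and returns that best subset.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate wavelengths to search")
    corr = corr or _CfsCorrelations(X, y)

    start: frozenset = frozenset()
    best_set, best_merit = start, 0.0
    open_heap = [(-0.0, tuple())]         # (-merit, sorted member tuple)
    seen = {start}
    stale = 0
    while open_heap and stale <= stale_limit:
        _, members = heapq.heappop(open_heap)
        node = frozenset(members)
        improved = False
        for c in candidates:
            child = node | {c} if c not in node else node - {c}
            if not child or child in seen:
                continue
            seen.add(child)
            m = corr.merit(child)
            if m > best_merit + 1e-12:
                best_set, best_merit = child, m
                improved = True
            heapq.heappush(open_heap, (-m, tuple(sorted(child))))
        stale = 0 if improved else stale + 1
    return sorted(best_set)


def enumerate_six_member(subset, X, y, max_size: int = 6,
                         corr: "_CfsCorrelations | None" = None) -> list[int]:
    """Reduce an oversized subset by enumerating all ``max_size``-member
    sub-subsets and keeping the merit argmax (ties: lexicographically
    smallest index list)."""
    subset = sorted(subset)
    if len(subset) <= max_size:
        return subset
    corr = corr or _CfsCorrelations(X, y)
    best, best_merit = None, -np.inf
    # combinations() is lexicographic, so on merit ties the lexicographically
    # smallest index list is kept automatically
    for sub in combinations(subset, max_size):
        m = corr.merit(sub)
        if m > best_merit + 1e-12:
            best, best_merit = sub, m
    return list(best)


# --------------------------------------------------------------------------
# results container and sklearn-style estimators
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of one selection run for one composition/modality."""

    method: str                              # ranking_uncorrelatedness | subset_selection
    composition: str | None
    modality: str | None
    wavelengths_nm: list[float]
    indices: list[int]                       # columns into the full spectra grid
    per_wavelength_r: list[float]            # Pearson r of reflectance vs target
    merit: float | None = None
    extras: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "composition": self.composition,
            "modality": self.modality,
            "method": self.method,
            "wavelengths_nm": list(map(float, self.wavelengths_nm)),
            "per_wavelength_r": [round(float(r), 6) for r in self.per_wavelength_r],
            "merit": None if self.merit is None else float(self.merit),
        }


class RReliefF(BaseEstimator):
    """Regression Relief feature ranker (sklearn-style).

    Attributes after :meth:`fit`: ``weights_`` (per-feature scores) and
    ``ranking_`` (feature indices, best first).
    """

    def __init__(self, k_neighbors: int = 10, n_iterations: int | None = None,
                 sigma: float = 20.0, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.n_iterations = n_iterations
        self.sigma = sigma
        self.random_state = random_state

    def fit(self, X, y):
        self.weights_ = rrelieff_weights(
            X, y, k_neighbors=self.k_neighbors, n_iterations=self.n_iterations,
            sigma=self.sigma, seed=self.random_state,
        )
        self.ranking_ = np.argsort(-self.weights_, kind="stable")
        return self


class RankUncorrelatedSelector(BaseEstimator, TransformerMixin):
    """Ranking-and-uncorrelatedness wavelength selector.

    RReliefF ranks the candidates; the top ``top_n`` are pruned of
    wavelengths correlated above ``r_threshold`` with a better-ranked
    survivor; at most ``max_keep`` survive.
    """

    def __init__(self, top_n: int = 20, r_threshold: float = 0.8, max_keep: int = 6,
                 k_neighbors: int = 10, n_iterations: int | None = None,
                 sigma: float = 20.0, random_state: int = 0):
        self.top_n = top_n
        self.r_threshold = r_threshold
        self.max_keep = max_keep
        self.k_neighbors = k_neighbors
        self.n_iterations = n_iterations
        self.sigma = sigma
        self.random_state = random_state

    def fit(self, X, y):
        ranker = RReliefF(self.k_neighbors, self.n_iterations, self.sigma,
                          self.random_state).fit(X, y)
        self.weights_ = ranker.weights_
        self.ranking_ = ranker.ranking_
        self.selected_idx_ = prune_correlated(
            self.ranking_, X, top_n=self.top_n, r_threshold=self.r_threshold,
            max_keep=self.max_keep,
        )
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selected_idx_] = True
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        return np.asarray(X)[:, self.selected_idx_]


class CFSSubsetSelector(BaseEstimator, TransformerMixin):
    """CFS subset selector: best-first search, then six-member enumeration."""

    def __init__(self, stale_limit: int = 5, max_size: int = 6):
        self.stale_limit = stale_limit
        self.max_size = max_size

    def fit(self, X, y):
        corr = _CfsCorrelations(X, y)
        raw = bestfirst_search(range(np.asarray(X).shape[1]), X, y,
                               stale_limit=self.stale_limit, corr=corr)
        self.search_subset_ = list(raw)
        self.selected_idx_ = enumerate_six_member(raw, X, y, max_size=self.max_size,
                                                  corr=corr)
        self.merit_ = corr.merit(self.selected_idx_)
        self.support_ = np.zeros(np.asarray(X).shape[1], dtype=bool)
        self.support_[self.selected_idx_] = True
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        return np.asarray(X)[:, self.selected_idx_]


def select_wavelengths(X, y, grid_wavelengths, availability, modality: str,
                       method: str = "ranking_uncorrelatedness",
                       composition: str | None = None,
                       random_state: int = 0, **params) -> SelectionResult:
    """End-to-end selection on the full spectra grid for one composition.

    Restricts the grid to commercially available candidates, runs the
    requested procedure on the candidate columns, and reports selected
    wavelengths with their Pearson correlations against the target.
    """
    cand = filter_available(grid_wavelengths, availability, modality)
    Xc = np.asarray(X, dtype=float)[:, cand.indices]
    y = np.asarray(y, dtype=float)

    if method == "ranking_uncorrelatedness":
        sel = RankUncorrelatedSelector(random_state=random_state, **params).fit(Xc, y)
        merit = None
        extras = {"weights": sel.weights_}
    elif method == "subset_selection":
        sel = CFSSubsetSelector(**params).fit(Xc, y)
        merit = sel.merit_
        extras = {"search_subset": [int(cand.indices[i]) for i in sel.search_subset_]}
    else:
        raise ValueError(f"unknown method {method!r}")

    local = list(sel.selected_idx_)
    grid_idx = [int(cand.indices[i]) for i in local]
    wavelengths = [float(np.asarray(grid_wavelengths)[i]) for i in grid_idx]
    r = [_safe_corr(Xc[:, i], y) for i in local]
    order = np.argsort(wavelengths)
    return SelectionResult(
        method=method,
        composition=composition,
        modality=modality,
        wavelengths_nm=[wavelengths[i] for i in order],
        indices=[grid_idx[i] for i in order],
        per_wavelength_r=[r[i] for i in order],
        merit=merit,
        extras=extras,
    )
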