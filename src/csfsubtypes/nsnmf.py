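"""Nonsmooth non-negative matrix factorization with consensus clustering.

The decomposition is ``V ≈ W S H`` with ``V`` a nonnegative proteins x
subjects matrix, ``W`` the protein profiles (proteins x k), ``H`` the
subject loadings (k x subjects), and the smoothing matrix
``S = (1 - θ) I + (θ / k) J`` that drives sparseness in ``W`` and ``H``.
Optimisation uses multiplicative updates on the Frobenius objective
``‖V − W S H‖²`` with ``W S`` (resp. ``S H``) treated as the effective
basis (resp. coefficient) matrix, which keeps every update monotone.

Stability of subject classification across stochastic restarts is
summarised by a consensus matrix over ``n_runs`` seeded restarts, its
cophenetic correlation coefficient, and the mean silhouette width of the
consensus dissimilarity.  Rank selection combines a cophenetic plateau
rule, a two-fold fit-gain-over-permuted-data rule, and a silhouette floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class NsnmfConfig:
    theta: float = 0.5
    max_iter: int = 2000
    tol: float = 1e-6  # relative rss change
    n_runs: int = 50
    rank_min: int = 2
    rank_max: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.max_iter < 1 or self.tol < 0:
            raise ValueError("invalid convergence settings")
        if not 1 <= self.rank_min <= self.rank_max:
            raise ValueError("invalid rank range")


@dataclass
class FactorModel:
    """One converged nsNMF decomposition."""

    W: np.ndarray  # proteins x k
    H: np.ndarray  # k x subjects
    S: np.ndarray  # k x k
    theta: float
    rank: int
    rss: float
    rss_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int | None = None


@dataclass
class ConsensusSummary:
    consensus: np.ndarray  # subjects x subjects co-clustering fractions
    cophenetic: float
    silhouette: float
    labels: np.ndarray  # consensus labels, 1-based
    per_run_rss: np.ndarray
    best_model: FactorModel
    rank: int
    n_runs: int
    uninformative: bool = False  # single run: stability trivially perfect


@dataclass
class RankSelection:
    summaries: dict[int, ConsensusSummary]
    real_rss: dict[int, float]
    perm_rss: dict[int, float]
    criteria: dict[int, dict[str, bool]]
    selected: int | None

    @property
    def failed(self) -> bool:
        return self.selected is None


def smoothing_matrix(k: int, theta: float) -> np.ndarray:
    """``S = (1 − θ) I + (θ / k) J``: symmetric and doubly stochastic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    return (1.0 - theta) * np.eye(k) + theta / k * np.ones((k, k))


def _as_array(V) -> np.ndarray:
    if isinstance(V, pd.DataFrame):
        V = V.to_numpy()
    return np.asarray(V, dtype=float)


def factorize(V, k: int, config: NsnmfConfig | None = None, seed: int | None = None) -> FactorModel:
    """Fit ``V ≈ W S H`` by multiplicative updates from a seeded uniform init.

    ``V`` must be nonnegative with no missing values (use
    :func:`csfsubtypes.preprocess.nonneg_shift` first).  The residual sum of
    squares is recorded after every iteration and is non-increasing.
    """
    config = config or NsnmfConfig()
    config.validate()
    V = _as_array(V)
    if np.isnan(V).any():
        raise ValueError("V contains missing values")
    if (V < 0).any():
        raise ValueError("V has negative entries; apply nonneg_shift before factorization")
    p, n = V.shape
    if not 1 <= k < min(p, n):
        raise ValueError(f"rank k={k} must satisfy 1 <= k < min{V.shape}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    S = smoothing_matrix(k, config.theta)
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(p, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale

    trace = []
    rss_prev = np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        A = W @ S  # effective basis for the H step
        H *= (A.T @ V) / (A.T @ A @ H + _EPS)
        B = S @ H  # effective coefficients for the W step
        W *= (V @ B.T) / (W @ (B @ B.T) + _EPS)
        rss = float(np.linalg.norm(V - W @ (S @ H)) ** 2)
        trace.append(rss)
        if rss_prev < np.inf and (rss_prev - rss) <= config.tol * max(rss_prev, _EPS):
            converged = True
            break
        rss_prev = rss

    return FactorModel(
        W=W, H=H, S=S, theta=config.theta, rank=k,
        rss=trace[-1], rss_trace=np.asarray(trace), n_iter=it,
        converged=converged, seed=seed,
    )


def predict_subtypes(
    model: FactorModel, V_new=None
) -> tuple[np.ndarray, np.ndarray]:
    """Hard subtype labels (1-based) and per-subject loadings summing to 1.

    Without ``V_new`` the fitted coefficient matrix ``H`` is used directly;
    new subjects are first projected onto the fitted basis ``W S`` by
    nonnegative least squares.  Ties at the argmax resolve to the lowest
    component index and are logged.
    """
    if V_new is None:
        H = model.H
    else:
        V_new = _as_array(V_new)
        if V_new.shape[0] != model.W.shape[0]:
            raise ValueError("V_new must have the same protein rows as the fitted model")
        A = model.W @ model.S
        H = np.column_stack([nnls(A, V_new[:, j])[0] for j in range(V_new.shape[1])])
    labels = H.argmax(axis=0) + 1
    sorted_h = np.sort(H, axis=0)
    ties = np.isclose(sorted_h[-1], sorted_h[-2]) if H.shape[0] > 1 else np.zeros(H.shape[1], bool)
    if ties.any():
        logger.warning("argmax ties for %d subject(s); lowest component kept", int(ties.sum()))
    total = H.sum(axis=0)
    loadings = np.divide(H, np.where(total > 0, total, 1.0), out=np.zeros_like(H))
    return labels, loadings


def silhouette_width(dissimilarity: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width ``s(i) = (b − a) / max(a, b)`` on a
    precomputed dissimilarity matrix.

    Subjects in singleton clusters score 0 by convention.
    """
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = D.shape[0]
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            continue  # singleton: s = 0
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(D[i, labels == other].mean() for other in uniq if other != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def _cophenetic_coefficient(consensus: np.ndarray) -> tuple[float, np.ndarray]:
    """Cophenetic correlation of average-linkage clustering of 1 − C,
    plus the linkage matrix."""
    dist = squareform(1.0 - consensus, checks=False)
    Z = linkage(dist, method="average")
    coph = cophenet(Z)
    if np.allclose(dist, coph, rtol=0.0, atol=1e-12):
        # identical structures (e.g. every run produced the same labels)
        rho = 1.0
    elif np.std(dist) == 0 or np.std(coph) == 0:
        rho = 0.0
    else:
        rho = min(float(np.corrcoef(dist, coph)[0, 1]), 1.0)
    return rho, Z


def run_consensus(V, k: int, config: NsnmfConfig | None = None) -> ConsensusSummary:
    """Consensus clustering over ``n_runs`` seeded nsNMF restarts.

    The consensus matrix ``C`` holds the fraction of runs in which each
    subject pair received the same hard label.  The cophenetic coefficient
    correlates the consensus dissimilarity ``1 − C`` with the cophenetic
    distances of its average-linkage dendrogram; consensus labels are the
    ``k``-cluster cut of that dendrogram, and the silhouette is evaluated on
    ``1 − C`` with those labels.
    """
    config = config or NsnmfConfig()
    config.validate()
    V = _as_array(V)
    n = V.shape[1]
    seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(config.seed).spawn(config.n_runs)]

    counts = np.zeros((n, n))
    per_run_rss = np.empty(config.n_runs)
    best: FactorModel | None = None
    for r, run_seed in enumerate(seeds):
        model = factorize(V, k, config, seed=run_seed)
        labels, _ = predict_subtypes(model)
        if len(np.unique(labels)) < k:
            logger.info("run %d: empty component at k=%d (kept)", r, k)
        counts += labels[:, None] == labels[None, :]
        per_run_rss[r] = model.rss
        if best is None or model.rss < best.rss:
            best = model
    consensus = counts / config.n_runs
    np.fill_diagonal(consensus, 1.0)

    rho, Z = _cophenetic_coefficient(consensus)
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) >= 2:
        sil = silhouette_width(1.0 - consensus, labels)
    else:
        sil = 0.0
        logger.warning("consensus cut produced a single cluster at k=%d", k)
    return ConsensusSummary(
        consensus=consensus,
        cophenetic=rho,
        silhouette=sil,
        labels=labels,
        per_run_rss=per_run_rss,
        best_model=best,
        rank=k,
        n_runs=config.n_runs,
        uninformative=config.n_runs == 1,
    )


def _permute_rows(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each protein's values across subjects."""
    out = np.empty_like(V)
    for i in range(V.shape[0]):
        out[i] = V[i, rng.permutation(V.shape[1])]
    return out


def _best_permuted_rss(V: np.ndarray, k: int, config: NsnmfConfig, seed_seq) -> float:
    """Best rss over n_runs factorizations of per-run row-permuted copies."""
    best = np.inf
    for child in seed_seq.spawn(config.n_runs):
        rng = np.random.default_rng(child)
        model = factorize(_permute_rows(V, rng), k, config, seed=int(child.generate_state(1)[0]))
        best = min(best, model.rss)
    return best


def select_rank(
    V,
    config: NsnmfConfig | None = None,
    cophenetic_window: float = 0.02,
    silhouette_floor: float = 0.5,
) -> RankSelection:
    """Choose the number of subtypes over ``rank_min..rank_max``.

    A rank ``k`` qualifies when (1) its cophenetic coefficient is within
    ``cophenetic_window`` of the maximum over tested ranks, (2) the fit gain
    over rank ``k − 1`` is at least twice the corresponding gain on
    row-permuted data, and (3) the mean silhouette is at least
    ``silhouette_floor``.  The largest qualifying rank is selected; if none
    qualifies the selection is an explicit failure state
    (``selected is None``).
    """
    config = config or NsnmfConfig()
    config.validate()
    if config.rank_max <= config.rank_min:
        raise ValueError("rank range must contain at least 2 ranks")
    V = _as_array(V)

    ranks = list(range(config.rank_min, config.rank_max + 1))
    all_ranks = [config.rank_min - 1] + ranks if config.rank_min >= 2 else ranks
    perm_root = np.random.SeedSequence([config.seed, 0x9E3779B9])

    summaries: dict[int, ConsensusSummary] = {}
    real_rss: dict[int, float] = {}
    perm_rss: dict[int, float] = {}
    perm_children = perm_root.spawn(len(all_ranks))
    for k, child in zip(all_ranks, perm_children):
        if k in ranks:
            summary = run_consensus(V, k, _with_seed(config, np.random.SeedSequence([config.seed, k])))
            summaries[k] = summary
            real_rss[k] = float(summary.per_run_rss.min())
        else:
            rss = min(
                factorize(V, k, config, seed=int(s.generate_state(1)[0])).rss
                for s in np.random.SeedSequence([config.seed, k]).spawn(config.n_runs)
            )
            real_rss[k] = rss
        perm_rss[k] = _best_permuted_rss(V, k, config, child)

    max_rho = max(s.cophenetic for s in summaries.values())
    criteria: dict[int, dict[str, bool]] = {}
    for k in ranks:
        prev = k - 1
        flags = {
            "stability": summaries[k].cophenetic >= max_rho - cophenetic_window,
            "silhouette": summaries[k].silhouette >= silhouette_floor,
        }
        if prev in real_rss:
            gain = real_rss[prev] - real_rss[k]
            perm_gain = perm_rss[prev] - perm_rss[k]
            flags["fit_gain"] = gain >= 2.0 * perm_gain
        else:
            flags["fit_gain"] = True  # no lower-rank reference available
        criteria[k] = flags

    passing = [k for k in ranks if all(criteria[k].values())]
    selected = max(passing) if passing else None
    if selected is None:
        logger.warning("no rank in %s satisfies all selection criteria", ranks)
    return RankSelection(
        summaries=summaries,
        real_rss=real_rss,
        perm_rss=perm_rss,
        criteria=criteria,
        selected=selected,
    )


def _with_seed(config: NsnmfConfig, seq: np.random.SeedSequence) -> NsnmfConfig:
    from dataclasses import replace

    return replace(config, seed=int(seq.generate_state(1)[0]))
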