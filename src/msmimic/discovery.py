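"""Molecular subgroup discovery by NMF consensus clustering.

A β matrix is factorized as X ≈ W·H (non-negative basis "metagenes" and
coefficients) at several ranks k; repeated factorizations over random
initializations and sample subsamples give a sample × sample consensus
matrix of co-assignment frequencies.  The rank whose consensus matrix is
most nearly block-diagonal — highest cophenetic correlation, mean silhouette
width as tie-breaker — is selected, and final assignments come from
hierarchical clustering of that consensus matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .matrix import BetaMatrix

__all__ = [
    "ConsensusResult",
    "nmf_factorize",
    "consensus_cluster",
    "silhouette_widths",
    "match_labels",
]

_EPS = 1e-12


def _nmf_mu(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 200,
    tol: float = 1e-4,
    track_objective: bool = False,
    check_every: int = 10,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF minimising the Frobenius reconstruction error.

    Returns (W, H, objective_history); the history is per-iteration when
    ``track_objective`` else sampled every ``check_every`` iterations.
    """
    n, m = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = scale * rng.random((n, k), dtype=X.dtype) + _EPS
    H = scale * rng.random((k, m), dtype=X.dtype) + _EPS
    history: list[float] = []
    prev = None
    for it in range(max_iter):
        # H update, then W update (Lee–Seung multiplicative rules).
        WtX = W.T @ X
        WtWH = (W.T @ W) @ H
        H *= WtX / np.maximum(WtWH, _EPS)
        XHt = X @ H.T
        WHHt = W @ (H @ H.T)
        W *= XHt / np.maximum(WHHt, _EPS)
        if track_objective or (it + 1) % check_every == 0 or it == max_iter - 1:
            err = float(np.linalg.norm(X - W @ H))
            history.append(err)
            if not track_objective:
                if prev is not None and prev - err < tol * max(prev, _EPS):
                    break
                prev = err
    return W, H, history


def nmf_factorize(
    beta: BetaMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    track_objective: bool = False,
):
    """Factorize a β matrix at rank ``k``.

    Returns ``(basis, coefficients, objective_history)`` where ``basis`` is
    loci × k (the metagenes) and ``coefficients`` k × samples; the sample
    assignment is the argmax coefficient.  Missing values are rejected —
    impute or filter first.
    """
    if k < 1:
        raise ValueError("rank k must be >= 1")
    X = beta.to_numpy() if isinstance(beta, BetaMatrix) else np.asarray(beta, dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "matrix contains missing values; impute (e.g. BetaMatrix.fill_median) "
            "before factorization"
        )
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    rng = np.random.default_rng(seed)
    # Samples × loci in, so W holds per-sample coefficients: transpose to the
    # conventional (loci × k) basis and (k × samples) coefficient layout.
    W, H, history = _nmf_mu(
        X, k, rng, max_iter=max_iter, tol=tol, track_objective=track_objective
    )
    return H.T, W.T, history


@dataclass
class ConsensusResult:
    """Outcome of consensus clustering over a range of ranks."""

    k_selected: int
    assignments: pd.Series
    consensus: dict[int, np.ndarray] = field(repr=False)
    cophenetic: dict[int, float]
    mean_silhouette: dict[int, float]
    basis: pd.DataFrame = field(repr=False)
    coefficients: pd.DataFrame = field(repr=False)
    loci_used: list[str] = field(repr=False, default_factory=list)

    def report(self) -> dict:
        return {
            "k_selected": int(self.k_selected),
            "cophenetic": {int(k): float(v) for k, v in self.cophenetic.items()},
            "mean_silhouette": {int(k): float(v) for k, v in self.mean_silhouette.items()},
            "group_sizes": self.assignments.value_counts().sort_index().to_dict(),
        }


def _consensus_labels(consensus: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Hierarchical clustering of a consensus matrix; returns labels and the
    cophenetic correlation between consensus dissimilarity and tree heights."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    if condensed.std() < 1e-12:
        coph = 0.0  # degenerate: all pairwise dissimilarities equal
    else:
        coph, _ = cophenet(Z, condensed)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, float(coph)


def consensus_cluster(
    beta: BetaMatrix,
    k_range: range | list[int] = range(2, 9),
    n_restarts: int = 50,
    seed: int = 0,
    subsample: float = 0.8,
    top_variable: int | None = 2000,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> ConsensusResult:
    """Consensus NMF clustering with rank selection.

    For each rank the matrix is factorized ``n_restarts`` times on random
    80% sample subsets; co-assignment frequencies form the consensus matrix.
    Before clustering, loci are restricted to the ``top_variable`` most
    variably methylated (missing entries are filled with locus medians).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ValueError("k_range must contain ranks >= 2")
    n = beta.n_samples
    if ks[-1] > n / 3:
        raise ValueError("largest rank exceeds n_samples / 3")
    if n_restarts < 10:
        raise ValueError("n_restarts must be >= 10")

    filled = beta.fill_median()
    loci = (
        filled.top_variable_loci(top_variable)
        if top_variable is not None and top_variable < filled.n_loci
        else filled.locus_ids
    )
    X = filled.subset_loci(loci).to_numpy().astype(np.float32)

    rng = np.random.default_rng(seed)
    n_sub = max(ks[-1] + 1, int(round(subsample * n)))
    consensus: dict[int, np.ndarray] = {}
    cophenetic: dict[int, float] = {}
    mean_sil: dict[int, float] = {}
    labels_at_k: dict[int, np.ndarray] = {}

    for k in ks:
        together = np.zeros((n, n), dtype=np.float64)
        observed = np.zeros((n, n), dtype=np.float64)
        for _ in range(n_restarts):
            idx = rng.choice(n, size=n_sub, replace=False)
            W, _, _ = _nmf_mu(X[idx], k, rng, max_iter=max_iter, tol=tol)
            assign = W.argmax(axis=1)
            same = assign[:, None] == assign[None, :]
            observed[np.ix_(idx, idx)] += 1.0
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            C = np.where(observed > 0, together / np.maximum(observed, 1.0), 0.0)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
        consensus[k] = C
        labels, coph = _consensus_labels(C, k)
        labels_at_k[k] = labels
        cophenetic[k] = coph
        dist = 1.0 - C
        np.fill_diagonal(dist, 0.0)
        if len(np.unique(labels)) >= 2:
            mean_sil[k] = float(np.mean(silhouette_widths(dist, labels)))
        else:
            mean_sil[k] = 0.0

    # Rank selection: highest cophenetic correlation, mean silhouette width
    # as tie-breaker.  Consensus matrices of strongly structured data are all
    # near-perfect, so cophenetic values within `tie_band` of the maximum are
    # treated as tied; the silhouette then discriminates the true rank.
    tie_band = 0.01
    coph_max = max(cophenetic[k] for k in ks)
    tied = [k for k in ks if cophenetic[k] >= coph_max - tie_band]
    k_selected = sorted(tied, key=lambda k: (-round(mean_sil[k], 9), k))[0]

    final_labels = labels_at_k[k_selected]
    basis, coeff, _ = nmf_factorize(
        BetaMatrix(filled.values.loc[:, loci]),
        k_selected,
        seed=int(rng.integers(0, 2**31 - 1)),
        max_iter=200,
    )
    return ConsensusResult(
        k_selected=k_selected,
        assignments=pd.Series(final_labels, index=beta.sample_ids, name="subgroup"),
        consensus=consensus,
        cophenetic=cophenetic,
        mean_silhouette=mean_sil,
        basis=pd.DataFrame(basis, index=loci, columns=range(1, k_selected + 1)),
        coefficients=pd.DataFrame(
            coeff, index=range(1, k_selected + 1), columns=beta.sample_ids
        ),
        loci_used=list(loci),
    )


def silhouette_widths(distance: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Per-sample silhouette widths s(i) = (b(i) − a(i)) / max(a(i), b(i)).

    ``distance`` is a square dissimilarity matrix; singleton clusters get
    width 0 by convention, but a partition of only singletons is rejected.
    """
    distance = np.asarray(distance, dtype=float)
    labels = np.asarray(assignments)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    if (counts == 1).all():
        raise ValueError("silhouette undefined for a singleton-only partition")
    return silhouette_samples(distance, labels, metric="precomputed")


def match_labels(predicted, truth) -> tuple[dict, float]:
    """Optimal one-to-one relabeling of ``predicted`` onto ``truth``.

    Solves the assignment problem on the confusion matrix (Hungarian
    algorithm), padding with empty classes when cardinalities differ.
    Returns ``(mapping predicted-label → truth-label, agreement fraction)``.
    """
    pred = pd.Series(list(predicted))
    true = pd.Series(list(truth))
    if len(pred) != len(true):
        raise ValueError("predicted and truth must have equal length")
    p_labels = sorted(pred.unique(), key=str)
    t_labels = sorted(true.unique(), key=str)
    size = max(len(p_labels), len(t_labels))
    cm = np.zeros((size, size))
    p_index = {l: i for i, l in enumerate(p_labels)}
    t_index = {l: i for i, l in enumerate(t_labels)}
    for p, t in zip(pred, true):
        cm[p_index[p], t_index[t]] += 1
    rows, cols = linear_sum_assignment(-cm)
    mapping = {
        p_labels[r]: t_labels[c]
        for r, c in zip(rows, cols)
        if r < len(p_labels) and c < len(t_labels)
    }
    agreement = cm[rows, cols].sum() / len(pred)
    return mapping, float(agreement)
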