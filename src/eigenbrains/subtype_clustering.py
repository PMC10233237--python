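"""Data-driven subtyping by affinity propagation on component scores.

Pairwise similarity is the negative squared distance between per-column
standardized scores; the shared preference (similarity-matrix diagonal)
is a low quantile of the off-diagonal similarities, which discourages
many small clusters.  Exemplar-based clusters from message passing are
then agglomerated into a full merge hierarchy, and the distance metric
(euclidean, manhattan, or correlation) is chosen by mean silhouette.

The message-passing updates are::

    r(i,k) <- s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
    a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))   (i != k)
    a(k,k) <- sum_{i' != k} max(0, r(i',k))

with damped in-place averaging, exemplars {k : r(k,k) + a(k,k) > 0},
and convergence declared when the exemplar set is stable for
``conv_iter`` consecutive sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SimilarityMatrix",
    "ClusteringResult",
    "METRICS",
    "pairwise_distance",
    "similarity_from_distance",
    "preference_from_quantile",
    "affinity_propagation",
    "agglomerate_exemplars",
    "silhouette",
    "select_metric",
    "standardize_scores",
    "net_similarity",
]

#: documented metric order; ties in metric selection resolve to the first
METRICS = ("euclidean", "manhattan", "correlation")

_SCIPY_METRIC = {"euclidean": "euclidean", "manhattan": "cityblock", "correlation": "correlation"}


@dataclass
class SimilarityMatrix:
    """n x n similarity matrix: off-diagonal -d^2, diagonal = shared preference."""

    values: np.ndarray
    metric: str = "euclidean"
    preference_quantile: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def preference(self) -> float:
        return float(self.values[0, 0])


@dataclass
class ClusteringResult:
    labels: np.ndarray
    exemplars: np.ndarray
    n_iterations: int
    converged: bool
    net_similarity: float
    merge_tree: list[tuple[int, int, float]] = field(default_factory=list)
    silhouette_mean: float = float("nan")
    silhouette_per_subject: np.ndarray | None = None
    metric: str = ""

    @property
    def n_clusters(self) -> int:
        return int(self.exemplars.size)


def standardize_scores(scores: np.ndarray) -> np.ndarray:
    """Z-score each component column (the clustering works on scaled scores)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    sd = scores.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant score column")
    return (scores - scores.mean(axis=0)) / sd


def pairwise_distance(scores: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix between subjects' score rows.

    ``correlation`` is 1 - Pearson r across components and needs K >= 2
    non-constant rows.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if metric not in _SCIPY_METRIC:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "correlation":
        if scores.shape[1] < 2:
            raise ValueError("correlation distance needs at least 2 components")
        if np.any(np.ptp(scores, axis=1) == 0):
            raise ValueError("correlation distance undefined for a constant score profile")
    d = squareform(pdist(scores, metric=_SCIPY_METRIC[metric]))
    np.fill_diagonal(d, 0.0)
    return d


def similarity_from_distance(distances: np.ndarray) -> np.ndarray:
    """s(i,k) = -d(i,k)^2 off-diagonal (diagonal left at 0 until the preference is set)."""
    d = np.asarray(distances, dtype=float)
    s = -(d**2)
    np.fill_diagonal(s, 0.0)
    return s


def preference_from_quantile(similarities: np.ndarray, q: float = 0.1) -> float:
    """The q-quantile of off-diagonal similarities (lower -> fewer clusters)."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    s = np.asarray(similarities, dtype=float)
    off = s[~np.eye(s.shape[0], dtype=bool)]
    return float(np.quantile(off, q))


def build_similarity(scores: np.ndarray, metric: str = "euclidean",
                     preference_quantile: float = 0.1,
                     standardize: bool = True) -> tuple[SimilarityMatrix, np.ndarray]:
    """Distance -> similarity -> preference in one step; returns (S, D)."""
    z = standardize_scores(scores) if standardize else np.atleast_2d(np.asarray(scores, float))
    d = pairwise_distance(z, metric=metric)
    s = similarity_from_distance(d)
    pref = preference_from_quantile(s, preference_quantile)
    np.fill_diagonal(s, pref)
    return SimilarityMatrix(values=s, metric=metric, preference_quantile=preference_quantile), d


def net_similarity(similarities: np.ndarray, labels: np.ndarray, exemplars: np.ndarray) -> float:
    """Sum of member-to-exemplar similarities plus exemplar preferences."""
    s = np.asarray(similarities, dtype=float)
    total = 0.0
    for i, lab in enumerate(labels):
        k = int(exemplars[lab])
        total += s[k, k] if i == k else s[i, k]
    return float(total)


def _assign(s: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    labels = np.argmax(s[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)  # each exemplar labels itself
    return labels


def _exemplar_set_value(s: np.ndarray, exemplars: np.ndarray) -> float:
    """Net similarity of the best assignment to a candidate exemplar set."""
    n = s.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[exemplars] = True
    member_best = s[np.ix_(~mask, exemplars)].max(axis=1).sum() if (~mask).any() else 0.0
    return float(member_best + s[exemplars, exemplars].sum())


def _polish_exemplars(s: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    """Greedy add/remove/swap local search on the exemplar set.

    Message passing can settle near, but not at, the net-similarity
    optimum on small instances; this deterministic polish only ever
    improves the objective and leaves already-optimal solutions alone.
    """
    n = s.shape[0]
    current = np.sort(np.asarray(exemplars))
    value = _exemplar_set_value(s, current)
    # a single far-away exemplar can beat any 2-set reachable by one move;
    # restarting from the best singleton covers that basin as well
    best_single = int(np.argmax(s.sum(axis=0)))
    single_value = _exemplar_set_value(s, np.array([best_single]))
    if single_value > value:
        current, value = np.array([best_single]), single_value
    improved = True
    while improved:
        improved = False
        non_members = np.setdiff1d(np.arange(n), current)
        candidates: list[np.ndarray] = []
        if current.size > 1:
            candidates += [np.delete(current, i) for i in range(current.size)]
        candidates += [np.sort(np.append(current, j)) for j in non_members]
        for i in range(current.size):
            for j in non_members:
                cand = current.copy()
                cand[i] = j
                candidates.append(np.sort(cand))
        for cand in candidates:
            cand_value = _exemplar_set_value(s, cand)
            if cand_value > value + 1e-12:
                current, value, improved = cand, cand_value, True
                break
    return current


def affinity_propagation(similarity: SimilarityMatrix | np.ndarray, damping: float = 0.9,
                         max_iter: int = 2000, conv_iter: int = 200,
                         seed: int = 0, polish: bool = True) -> ClusteringResult:
    """Exemplar-based clustering by responsibility/availability message passing.

    A tiny seeded symmetry-breaking noise (1e-12 of the similarity range)
    is added so degenerate instances resolve deterministically.  After
    convergence each cluster's exemplar is refined to the member that
    maximizes the within-cluster similarity sum, a greedy local search
    polishes the exemplar set (``polish=False`` disables it), and members
    are reassigned to their most similar exemplar.
    """
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must lie in [0.5, 1)")
    s = np.array(similarity.values if isinstance(similarity, SimilarityMatrix) else similarity,
                 dtype=float)
    n = s.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")

    rng = np.random.default_rng(seed)
    spread = float(s.max() - s.min())
    if spread == 0:
        spread = 1.0
    s = s + rng.standard_normal((n, n)) * 1e-12 * spread

    r = np.zeros((n, n))
    a = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    n_iterations = max_iter

    for it in range(1, max_iter + 1):
        # responsibilities
        m = a + s
        first = np.argmax(m, axis=1)
        max1 = m[idx, first]
        m[idx, first] = -np.inf
        max2 = np.max(m, axis=1)
        r_new = s - max1[:, None]
        r_new[idx, first] = s[idx, first] - max2
        r = damping * r + (1.0 - damping) * r_new

        # availabilities
        rp = np.maximum(r, 0.0)
        rp[idx, idx] = r[idx, idx]
        colsum = rp.sum(axis=0)
        a_new = np.minimum(0.0, colsum[None, :] - rp)
        a_new[idx, idx] = colsum - rp[idx, idx]
        a = damping * a + (1.0 - damping) * a_new

        exemplars = np.flatnonzero(np.diag(r) + np.diag(a) > 0)
        if prev_exemplars is not None and exemplars.size and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= conv_iter:
                converged = True
                n_iterations = it
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    if prev_exemplars is None or prev_exemplars.size == 0:
        # fall back to the single best exemplar by net similarity
        warnings.warn("no exemplar emerged from message passing; using best single exemplar",
                      stacklevel=2)
        totals = s.sum(axis=0)
        exemplars = np.array([int(np.argmax(totals))])
        converged = False
    else:
        exemplars = prev_exemplars

    labels = _assign(s, exemplars)
    # refine each exemplar to the member maximizing within-cluster similarity
    refined = exemplars.copy()
    for c in range(exemplars.size):
        members = np.flatnonzero(labels == c)
        if members.size:
            sub = s[np.ix_(members, members)]
            refined[c] = members[int(np.argmax(sub.sum(axis=0)))]
    refined = np.sort(np.unique(refined))
    if polish:
        refined = _polish_exemplars(s, refined)
    labels = _assign(s, refined)

    s_clean = similarity.values if isinstance(similarity, SimilarityMatrix) else np.asarray(similarity, float)
    return ClusteringResult(
        labels=labels,
        exemplars=refined,
        n_iterations=n_iterations,
        converged=converged,
        net_similarity=net_similarity(s_clean, labels, refined),
        metric=similarity.metric if isinstance(similarity, SimilarityMatrix) else "",
    )


def _joint_similarity(s: np.ndarray, members: np.ndarray, preference_diag: bool = False) -> tuple[float, int]:
    """Best-exemplar average similarity for a merged member set."""
    best = -np.inf
    best_e = int(members[0])
    for e in members:
        others = members[members != e]
        score = s[others, e].mean() if others.size else s[e, e]
        if score > best:
            best, best_e = float(score), int(e)
    return best, best_e


def agglomerate_exemplars(similarity: SimilarityMatrix | np.ndarray,
                          result: ClusteringResult) -> list[tuple[int, int, float]]:
    """Merge clusters bottom-up by the joint-cluster criterion.

    At each step the pair of clusters maximizing the joint similarity
    (average similarity of all joint members to the best joint exemplar)
    is merged, until one cluster remains.  Returns an ordered list of
    ``(cluster_a, cluster_b, joint_similarity)`` merges referencing the
    original cluster indices via a linkage-style numbering: merge *m*
    creates cluster ``n_clusters + m``.
    """
    s = np.asarray(similarity.values if isinstance(similarity, SimilarityMatrix) else similarity,
                   dtype=float)
    n_clusters = result.n_clusters
    if n_clusters < 2:
        raise ValueError("agglomeration needs at least 2 clusters")
    members: dict[int, np.ndarray] = {
        c: np.flatnonzero(result.labels == c) for c in range(n_clusters)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n_clusters
    while len(members) > 1:
        keys = sorted(members)
        best = (-np.inf, keys[0], keys[1])
        for ia in range(len(keys)):
            for ib in range(ia + 1, len(keys)):
                ka, kb = keys[ia], keys[ib]
                joint = np.concatenate([members[ka], members[kb]])
                score, _ = _joint_similarity(s, joint)
                if score > best[0]:
                    best = (score, ka, kb)
        score, ka, kb = best
        merges.append((ka, kb, score))
        members[next_id] = np.concatenate([members.pop(ka), members.pop(kb)])
        next_id += 1
    return merges


def cut_merge_tree(merges: list[tuple[int, int, float]], labels: np.ndarray,
                   n_groups: int) -> np.ndarray:
    """Per-subject labels after agglomerating down to ``n_groups`` clusters.

    Replays the merge list until only ``n_groups`` clusters remain; useful
    when message passing over-segments and the hierarchy level of interest
    is known.
    """
    labels = np.asarray(labels)
    n_clusters = int(np.max(labels)) + 1
    if not 1 <= n_groups <= n_clusters:
        raise ValueError(f"n_groups must lie in [1, {n_clusters}]")
    parent = {c: c for c in range(n_clusters)}  # original cluster -> current root
    next_id = n_clusters
    for ka, kb, _score in merges:
        if len(set(parent.values())) <= n_groups:
            break
        for c in parent:
            if parent[c] in (ka, kb):
                parent[c] = next_id
        next_id += 1
    remap = {root: i for i, root in enumerate(sorted(set(parent.values())))}
    return np.array([remap[parent[int(lab)]] for lab in labels])


def merge_tree_linkage(merges: list[tuple[int, int, float]], labels: np.ndarray) -> np.ndarray:
    """Convert a merge list to a scipy-style 4-column linkage table.

    Heights are negated joint similarities, shifted to be nonnegative and
    made weakly monotone so standard dendrogram code accepts them.
    """
    n_clusters = int(np.max(labels)) + 1
    sizes = {c: int(np.sum(labels == c)) for c in range(n_clusters)}
    heights = [-m[2] for m in merges]
    base = min(heights) if heights else 0.0
    link = np.zeros((len(merges), 4))
    running = 0.0
    for i, (ka, kb, _score) in enumerate(merges):
        h = heights[i] - base
        running = max(running, h)
        size = sizes[ka] + sizes[kb]
        sizes[n_clusters + i] = size
        link[i] = (ka, kb, running, size)
    return link


def silhouette(distances: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-subject silhouette values and their mean.

    ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` where *a* is the mean
    intra-cluster distance (excluding self) and *b* the minimum over
    other clusters of the mean distance to that cluster.  Singleton
    clusters score 0; if every a and b is 0 (coincident points) the
    value is 0 with a warning.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = d.shape[0]
    values = np.zeros(n)
    warned = False
    for i in range(n):
        own = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        if own.size == 0:
            values[i] = 0.0  # singleton
            continue
        a = d[i, own].mean()
        b = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        if denom == 0:
            if not warned:
                warnings.warn("coincident points: silhouette set to 0", stacklevel=2)
                warned = True
            values[i] = 0.0
        else:
            values[i] = (b - a) / denom
    return values, float(values.mean())


def cluster_scores(scores: np.ndarray, metric: str = "euclidean",
                   preference_quantile: float = 0.1, damping: float = 0.9,
                   max_iter: int = 2000, conv_iter: int = 200, seed: int = 0,
                   standardize: bool = True) -> ClusteringResult:
    """Full clustering of score rows for one metric, with silhouette and merge tree."""
    sim, d = build_similarity(scores, metric=metric, preference_quantile=preference_quantile,
                              standardize=standardize)
    result = affinity_propagation(sim, damping=damping, max_iter=max_iter,
                                  conv_iter=conv_iter, seed=seed)
    if result.n_clusters >= 2:
        per_subject, mean = silhouette(d, result.labels)
        result.silhouette_per_subject = per_subject
        result.silhouette_mean = mean
        result.merge_tree = agglomerate_exemplars(sim, result)
    return result


def select_metric(scores: np.ndarray, metrics: tuple[str, ...] = METRICS,
                  preference_quantile: float = 0.1, damping: float = 0.9,
                  max_iter: int = 2000, conv_iter: int = 200, seed: int = 0,
                  standardize: bool = True) -> tuple[str, dict[str, ClusteringResult]]:
    """Run the clustering once per metric and pick the best mean silhouette.

    Ties resolve to the first metric in the documented order.  Metrics
    yielding fewer than 2 clusters are recorded but cannot win.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 candidate metrics")
    results: dict[str, ClusteringResult] = {}
    for metric in metrics:
        results[metric] = cluster_scores(
            scores, metric=metric, preference_quantile=preference_quantile,
            damping=damping, max_iter=max_iter, conv_iter=conv_iter, seed=seed,
            standardize=standardize,
        )
    eligible = [m for m in metrics if results[m].n_clusters >= 2]
    if not eligible:
        raise ValueError("no metric produced at least 2 clusters")
    best = max(eligible, key=lambda m: results[m].silhouette_mean)
    return best, results
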