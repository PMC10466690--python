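"""k-means clustering of motif-frequency vectors and centroid analysis.

Vectors from the two differential peak classes are clustered jointly
(k = 8 by default). Clusters composed predominantly of one origin
(purity >= a threshold, default 0.9; 1.0 reproduces a strict
"only one origin" reading) are the group-specific clusters; the largest
coordinates of their centroids name the short motifs that characterize
each group.

The k-means fit is a deterministic Lloyd iteration from a seeded greedy
farthest-point initialization, with restarts; a library k-means would not
expose the per-iteration monotonicity this module asserts, and determinism
across runs is a hard requirement here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .motifs import FrequencyVector, MotifCatalog

from .differential import PEAKS_0_5, PEAKS_2_0


@dataclass
class ClusterModel:
    k: int
    seed: int
    peak_ids: List[str]
    assignments: Dict[str, int]          # peak_id -> cluster index
    centroids: np.ndarray                # (k, n_motifs)
    wcss: float
    labels: np.ndarray = field(default=None, repr=False)  # per-row cluster index


@dataclass
class ClusterComposition:
    counts: Dict[int, Dict[str, int]]        # cluster -> origin -> count
    proportions: Dict[int, Optional[Dict[str, float]]]  # None for empty clusters


@dataclass
class GroupSpecificCluster:
    cluster: int
    dominant_origin: str
    purity: float
    top_motifs: List[int]


def _as_matrix(vectors) -> Tuple[np.ndarray, List[str], List[str]]:
    if isinstance(vectors, np.ndarray):
        X = np.asarray(vectors, dtype=float)
        ids = [f"v{i}" for i in range(len(X))]
        origins = [PEAKS_2_0] * len(X)
    else:
        X = np.vstack([v.values for v in vectors]).astype(float)
        ids = [v.peak_id for v in vectors]
        origins = [v.origin for v in vectors]
    return X, ids, origins


def _nearest(X: np.ndarray, centroids: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    return labels, d2[np.arange(len(X)), labels]


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    first = int(rng.integers(n))
    chosen = [first]
    d2 = ((X - X[first]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d2))  # ties -> lowest index
        chosen.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return X[chosen].copy()


def fit_kmeans(
    vectors,
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
) -> ClusterModel:
    """Lloyd's k-means, deterministic given the seed, best of ``n_restarts``.

    Raises on n < k and on all-identical input vectors (degenerate). The
    within-cluster sum of squares is asserted non-increasing across Lloyd
    iterations, and the returned model satisfies the centroid-mean and
    nearest-centroid invariants exactly (up to floating-point summation).
    """
    X, ids, _ = _as_matrix(vectors)
    n = len(X)
    if n < k:
        raise ValueError(f"need at least k={k} vectors, got {n}")
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("all vectors identical: clustering is degenerate")

    rng = np.random.default_rng(seed)
    best: Optional[Tuple[float, np.ndarray, np.ndarray]] = None
    for _ in range(max(n_restarts, 1)):
        centroids = _farthest_point_init(X, k, rng)
        labels, d2 = _nearest(X, centroids)
        prev_wcss = float(d2.sum())
        for _ in range(max_iter):
            for c in range(k):
                members = X[labels == c]
                if len(members):
                    centroids[c] = members.mean(axis=0)
                else:
                    # re-seed an empty cluster with the point farthest from
                    # its current centroid (deterministic tie-break by index)
                    _, cur_d2 = _nearest(X, centroids)
                    centroids[c] = X[int(np.argmax(cur_d2))]
            new_labels, d2 = _nearest(X, centroids)
            wcss = float(d2.sum())
            if wcss > prev_wcss + 1e-9 * max(prev_wcss, 1.0):
                raise AssertionError("WCSS increased across a Lloyd iteration")
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels, prev_wcss = new_labels, wcss
        # final means so the centroid-mean invariant holds at convergence
        for c in range(k):
            members = X[labels == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
        _, d2 = _nearest(X, centroids)
        wcss = float(d2.sum())
        if best is None or wcss < best[0]:
            best = (wcss, labels.copy(), centroids.copy())

    wcss, labels, centroids = best
    return ClusterModel(
        k=k, seed=seed, peak_ids=ids,
        assignments={pid: int(c) for pid, c in zip(ids, labels)},
        centroids=centroids, wcss=wcss, labels=labels,
    )


def cluster_composition(model: ClusterModel, vectors) -> ClusterComposition:
    """Exact per-cluster counts and proportions of vector origins."""
    _, ids, origins = _as_matrix(vectors)
    origin_of = dict(zip(ids, origins))
    counts: Dict[int, Dict[str, int]] = {
        c: {PEAKS_2_0: 0, PEAKS_0_5: 0} for c in range(model.k)
    }
    for pid, c in model.assignments.items():
        counts[c][origin_of[pid]] += 1
    proportions: Dict[int, Optional[Dict[str, float]]] = {}
    for c, cc in counts.items():
        total = sum(cc.values())
        proportions[c] = (
            {o: v / total for o, v in cc.items()} if total else None  # empty: undefined
        )
    return ClusterComposition(counts, proportions)


def select_group_specific_clusters(
    composition: ClusterComposition,
    model: ClusterModel,
    purity_min: float = 0.9,
    n_top_motifs: int = 5,
) -> List[GroupSpecificCluster]:
    """Clusters dominated (purity >= purity_min) by one peak origin.

    Per selected cluster, motifs are ranked by centroid coordinate
    descending, ties broken by the lower motif id.
    """
    selected = []
    for c in range(model.k):
        props = composition.proportions[c]
        if props is None:
            continue
        dominant = max(props, key=lambda o: props[o])
        purity = props[dominant]
        if purity >= purity_min:
            centroid = model.centroids[c]
            ranked = sorted(range(len(centroid)), key=lambda m: (-centroid[m], m))
            selected.append(
                GroupSpecificCluster(c, dominant, purity, ranked[:n_top_motifs])
            )
    return selected


def embed_2d(vectors, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP layout of the vectors, for display only.

    Deterministic given the seed. The neighborhood size is shrunk (with a
    warning) when there are fewer vectors than requested neighbors.
    Coordinates carry no downstream semantics.
    """
    X, _, _ = _as_matrix(vectors)
    if len(X) < 10:
        raise ValueError("embedding needs at least 10 vectors")
    if n_neighbors >= len(X):
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n={len(X)}; shrinking to {len(X) - 1}"
        )
        n_neighbors = len(X) - 1
    import umap  # deferred: numba-backed import is expensive

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
        return np.asarray(reducer.fit_transform(X), dtype=float)


def plot_embedding(coords: np.ndarray, vectors, model: ClusterModel, path) -> None:
    """Scatter of the 2-D layout colored by cluster, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, ids, _ = _as_matrix(vectors)
    labels = np.array([model.assignments[i] for i in ids])
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=labels, cmap="tab10", s=12)
    fig.colorbar(sc, ax=ax, label="cluster")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_assignments_tsv(model: ClusterModel, vectors, path) -> None:
    _, ids, origins = _as_matrix(vectors)
    origin_of = dict(zip(ids, origins))
    with open(path, "w") as fh:
        fh.write("peak_id\torigin\tcluster\n")
        for pid in model.peak_ids:
            fh.write(f"{pid}\t{origin_of[pid]}\t{model.assignments[pid]}\n")


def write_centroids_tsv(model: ClusterModel, catalog: MotifCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\t" + "\t".join(f"m{m.motif_id}" for m in catalog) + "\n")
        for c in range(model.k):
            vals = "\t".join(f"{x:.10g}" for x in model.centroids[c])
            fh.write(f"{c}\t{vals}\n")


def write_composition_tsv(composition: ClusterComposition, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tn_peaks_2_0\tn_peaks_0_5\tprop_peaks_2_0\tprop_peaks_0_5\n")
        for c in sorted(composition.counts):
            cc = composition.counts[c]
            props = composition.proportions[c]
            if props is None:
                fh.write(f"{c}\t0\t0\tNA\tNA\n")
            else:
                fh.write(
                    f"{c}\t{cc[PEAKS_2_0]}\t{cc[PEAKS_0_5]}\t"
                    f"{props[PEAKS_2_0]:.6g}\t{props[PEAKS_0_5]:.6g}\n"
                )
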