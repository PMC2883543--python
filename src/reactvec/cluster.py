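"""Hierarchical clustering of reaction vectors and cluster-number selection.

The reactome is clustered bottom-up: Euclidean distances between reaction
vectors feed UPGMA (average-linkage agglomeration), giving an ultrametric
dendrogram.  Cutting the tree below its k-1 highest merges yields a k-group
partition, so a whole family of nested classifications is available from one
tree.  The number of clusters is chosen separately by fitting Gaussian
mixtures over a range of k and maximising the Bayesian information
criterion, reported in the mclust convention (larger is better).

Height convention: by default a merge at average linkage distance d is drawn
at height d/2, the molecular-phylogenetics convention under which the
root-to-leaf path is half the cophenetic distance; ``height_convention="full"``
uses the raw linkage distance, as R's hclust does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .reactions import ReactionVector

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Clustering",
    "BicScan",
    "euclidean_distances",
    "upgma",
    "write_newick",
    "cut_tree",
    "select_k_bic",
]


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class Dendrogram:
    """Rooted ultrametric tree wrapping a scipy linkage matrix."""

    ids: tuple[str, ...]
    linkage: np.ndarray = field(repr=False)
    height_convention: str = "half"

    def __post_init__(self) -> None:
        if self.height_convention not in ("half", "full"):
            raise ValueError("height_convention must be 'half' or 'full'")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def node_heights(self) -> np.ndarray:
        """Height of each internal node, in merge order."""
        h = self.linkage[:, 2].copy()
        return h / 2 if self.height_convention == "half" else h

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise cophenetic distances (merge linkage distances)."""
        return squareform(sch.cophenet(self.linkage))


@dataclass
class Clustering:
    """Partition of items into clusters labelled 1..k."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        found = set(self.labels.values())
        if found != set(range(1, self.k + 1)):
            raise ValueError(f"expected labels 1..{self.k}, found {sorted(found)}")

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for item, c in self.labels.items():
            out[c].append(item)
        return out


@dataclass
class BicScan:
    k_values: list[int]
    bic: list[float]
    k_star: int
    status: list[str]


def _vectors_to_matrix(vectors: list[ReactionVector]) -> tuple[tuple[str, ...], np.ndarray]:
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    vocab = vectors[0].vocabulary
    for v in vectors:
        if v.vocabulary.keys != vocab.keys:
            raise ValueError("vectors span different vocabularies")
    ids = tuple(v.reaction_id for v in vectors)
    return ids, np.vstack([np.asarray(v.values, dtype=float) for v in vectors])


def euclidean_distances(vectors: list[ReactionVector]) -> DistanceMatrix:
    ids, X = _vectors_to_matrix(vectors)
    return DistanceMatrix(ids, squareform(pdist(X, metric="euclidean")))


def upgma(dm: DistanceMatrix, height_convention: str = "half") -> Dendrogram:
    """Average-linkage agglomeration of a distance matrix."""
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    Z = sch.linkage(squareform(dm.d, checks=False), method="average")
    return Dendrogram(tuple(dm.ids), Z, height_convention)


# --------------------------------------------------------------------------
# newick export
# --------------------------------------------------------------------------

_NEWICK_RESERVED = set("()[]{}:;,'\" \t\n")


def _newick_label(label: str) -> str:
    if any(c in _NEWICK_RESERVED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_newick(t: Dendrogram) -> str:
    """Newick string with branch lengths = parent height - child height.

    Children are ordered by their smallest contained leaf index, making the
    output deterministic for a given linkage.
    """
    n = t.n_leaves
    heights = t.node_heights()
    Z = t.linkage

    def min_leaf(node: int) -> int:
        while node >= n:
            node = int(min(Z[node - n, 0], Z[node - n, 1]))
        return node

    def render(node: int, parent_h: float) -> str:
        if node < n:
            return f"{_newick_label(t.ids[node])}:{_fmt(parent_h)}"
        h = heights[node - n]
        kids = sorted(
            (int(Z[node - n, 0]), int(Z[node - n, 1])), key=min_leaf
        )
        inner = ",".join(render(c, h) for c in kids)
        return f"({inner}):{_fmt(parent_h - h)}"

    if n == 1:
        return f"{_newick_label(t.ids[0])}:0;"
    root = n + len(Z) - 1
    return render(root, heights[-1]).rsplit(":", 1)[0] + ";"


# --------------------------------------------------------------------------
# tree cutting
# --------------------------------------------------------------------------


def cut_tree(t: Dendrogram, k: int) -> Clustering:
    """Partition into k groups by discarding the k-1 highest merges.

    Linkage rows are height-ordered with ties resolved by merge order, so
    applying only the first n-k merges realises exactly that rule.  Cluster
    numbers follow the order of each cluster's smallest leaf index.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - k):
        a, b = int(t.linkage[i, 0]), int(t.linkage[i, 1])
        # linkage node ids >= n refer to earlier merges; map to any member leaf
        a = a if a < n else _any_leaf(t.linkage, a, n)
        b = b if b < n else _any_leaf(t.linkage, b, n)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[t.ids[leaf]] = roots[r]
    return Clustering(labels, k)


def _any_leaf(Z: np.ndarray, node: int, n: int) -> int:
    while node >= n:
        node = int(Z[node - n, 0])
    return node


# --------------------------------------------------------------------------
# BIC model selection
# --------------------------------------------------------------------------


def select_k_bic(
    vectors: list[ReactionVector] | np.ndarray,
    k_max: int = 100,
    seed: int = 0,
) -> BicScan:
    """Scan Gaussian-mixture fits over k = 1..k_max and pick the BIC optimum.

    BIC is reported in the mclust convention (larger is better, i.e. the
    negative of sklearn's).  Diagonal covariances with a variance floor are
    used: full covariances are ill-conditioned for high-dimensional integer
    vectors containing exactly duplicated points.  Duplicated rows are
    jittered by N(0, 1e-8) before fitting only (distances are never
    jittered).  When fewer than k_max+1 items are given the scan is
    truncated to 1..n-1.  A k whose fit fails is recorded and excluded
    from the argmax.
    """
    from sklearn.mixture import GaussianMixture

    if isinstance(vectors, np.ndarray):
        X = np.asarray(vectors, dtype=float)
    else:
        _, X = _vectors_to_matrix(vectors)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    X = X.copy()
    _, first_idx, inverse = np.unique(X, axis=0, return_index=True, return_inverse=True)
    dup_mask = np.ones(n, dtype=bool)
    dup_mask[first_idx] = False
    if dup_mask.any():
        X[dup_mask] += rng.normal(0.0, 1e-8, size=(dup_mask.sum(), X.shape[1]))

    upper = min(k_max, max(n - 1, 1))
    k_values = list(range(1, upper + 1))
    bics: list[float] = []
    status: list[str] = []
    for k in k_values:
        try:
            gmm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                reg_covar=1e-6,
                n_init=5,
                init_params="k-means++",
                random_state=seed,
            ).fit(X)
            bics.append(-gmm.bic(X))
            status.append("ok")
        except Exception:
            bics.append(float("nan"))
            status.append("failed")
    ok = [i for i, s in enumerate(status) if s == "ok"]
    if not ok:
        raise RuntimeError("every mixture fit failed")
    k_star = k_values[max(ok, key=lambda i: bics[i])]
    return BicScan(k_values, bics, k_star, status)


def gmm_labels(
    vectors: list[ReactionVector] | np.ndarray,
    k: int,
    seed: int = 0,
) -> Clustering:
    """Mixture-responsibility labelling at a fixed k (alternative to cut_tree)."""
    from sklearn.mixture import GaussianMixture

    if isinstance(vectors, np.ndarray):
        ids = tuple(str(i) for i in range(vectors.shape[0]))
        X = np.asarray(vectors, dtype=float)
    else:
        ids, X = _vectors_to_matrix(vectors)
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        reg_covar=1e-6,
        n_init=5,
        init_params="k-means++",
        random_state=seed,
    ).fit(X)
    raw = gmm.predict(X)
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[ids[i]] = remap[r]
    return Clustering(labels, len(remap))


# --------------------------------------------------------------------------
# TSV export
# --------------------------------------------------------------------------


def write_assignments_tsv(c: Clustering) -> str:
    out = ["item_id\tcluster"]
    out.extend(f"{item}\t{lab}" for item, lab in c.labels.items())
    return "\n".join(out) + "\n"


def read_assignments_tsv(text: str) -> Clustering:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    labels = {}
    for ln in lines[1:]:
        item, lab = ln.split("\t")
        labels[item] = int(lab)
    return Clustering(labels, max(labels.values()))


def write_bic_tsv(scan: BicScan) -> str:
    out = ["k\tbic\tstatus"]
    for k, b, s in zip(scan.k_values, scan.bic, scan.status):
        out.append(f"{k}\t{b!r}\t{s}")
    out.append(f"# k_star\t{scan.k_star}")
    return "\n".join(out) + "\n"
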