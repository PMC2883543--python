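"""Association and enrichment statistics between clusterings and keywords.

Given a partition of reactions/enzymes and sets of annotation keywords
(reaction-type terms, sequence motifs, domain signatures, ontology terms --
all treated uniformly as "keywords"), two questions are answered:

* Does the clustering as a whole agree with the keywords?  A cluster-by-
  keyword contingency table of frequencies is scored by a chi-squared test
  with the Yates continuity correction (keywords are often rare, and the
  correction makes the test conservative), and the statistic is mapped to a
  z-score through Fisher's approximation z = sqrt(2*chi2) - sqrt(2*dof - 1)
  with dof = (N-1)(k-1), so that classifications with different table shapes
  become comparable on one scale.  z near 0 means no association; large
  positive z means items clustering together share keywords.

* Which keywords (or triplet components) characterise each cluster?  Each
  feature's frequency inside a cluster is compared against its background
  probability with a hypergeometric upper tail, switching to a Poisson tail
  in the low-frequency regime (n*p < 5 and p < 0.1, n the in-cluster
  frequency and p the background probability).

Multiple keywords per item are counted in every matching column, so the
independence assumption of the chi-squared test is approximate; raw p-values
are reported by default, with Bonferroni/Benjamini-Hochberg available as an
option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import Clustering, Dendrogram, cut_tree

__all__ = [
    "AnnotationSet",
    "ContingencyTable",
    "AssociationResult",
    "EnrichmentResult",
    "contingency",
    "chi_squared_yates",
    "fisher_z",
    "enrichment",
    "background_probabilities",
    "compare_clusterings",
    "cut_to_match",
]


class DegenerateTableError(ValueError):
    """Contingency table with fewer than two rows or columns."""


@dataclass
class AnnotationSet:
    """Keyword assignments from one source (e.g. reaction-type terms)."""

    name: str
    assignments: dict[str, set[str]]

    def __post_init__(self) -> None:
        for item, kws in self.assignments.items():
            if any(not kw for kw in kws):
                raise ValueError(f"{self.name}: empty keyword on item {item!r}")


@dataclass
class ContingencyTable:
    clusters: tuple[int, ...]
    keywords: tuple[str, ...]
    f: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f)
        if self.f.shape != (len(self.clusters), len(self.keywords)):
            raise ValueError("frequency matrix shape mismatch")
        if np.any(self.f < 0):
            raise ValueError("frequencies must be >= 0")


@dataclass
class AssociationResult:
    chi2: float
    dof: int
    z: float


@dataclass
class EnrichmentResult:
    cluster: int
    feature: str
    n: int
    p_background: float
    p_value: float
    law_used: str  # "hypergeometric" | "poisson"


def contingency(c: Clustering, a: AnnotationSet) -> ContingencyTable:
    """Cluster-by-keyword frequency table.

    f[c][w] counts the items of cluster c annotated with keyword w.  Items
    without annotations contribute nothing; keywords with zero total
    frequency over the clustered items are dropped.
    """
    items = set(c.labels) & set(a.assignments)
    if not items:
        raise ValueError(
            f"no overlap between clustered items and annotation set {a.name!r}"
        )
    keywords = sorted({kw for i in items for kw in a.assignments[i]})
    clusters = tuple(range(1, c.k + 1))
    kw_idx = {kw: j for j, kw in enumerate(keywords)}
    f = np.zeros((c.k, len(keywords)), dtype=np.int64)
    for item in items:
        row = c.labels[item] - 1
        for kw in a.assignments[item]:
            f[row, kw_idx[kw]] += 1
    keep = f.sum(axis=0) > 0
    return ContingencyTable(clusters, tuple(np.array(keywords)[keep]), f[:, keep])


def chi_squared_yates(t: ContingencyTable) -> tuple[float, int]:
    """Chi-squared statistic with per-cell Yates continuity correction.

    Each cell contributes max(|O - E| - 0.5, 0)^2 / E; dof = (N-1)(k-1)
    after all-zero rows/columns (which would make expectations zero) are
    dropped with a warning.
    """
    f = t.f.astype(float)
    row_ok, col_ok = f.sum(axis=1) > 0, f.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {int((~row_ok).sum())} all-zero row(s) and "
            f"{int((~col_ok).sum())} all-zero column(s)",
            stacklevel=2,
        )
        f = f[row_ok][:, col_ok]
    n_rows, n_cols = f.shape
    if n_rows < 2 or n_cols < 2:
        raise DegenerateTableError(
            f"contingency table is {n_rows}x{n_cols}; need at least 2x2"
        )
    total = f.sum()
    if total <= 0:
        raise DegenerateTableError("contingency table has zero total count")
    expected = np.outer(f.sum(axis=1), f.sum(axis=0)) / total
    adj = np.maximum(np.abs(f - expected) - 0.5, 0.0)
    chi2 = float(np.sum(adj**2 / expected))
    dof = (n_rows - 1) * (n_cols - 1)
    return chi2, dof


def fisher_z(chi2: float, dof: int) -> float:
    """Fisher's normal approximation: z = sqrt(2*chi2) - sqrt(2*dof - 1)."""
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return math.sqrt(2.0 * chi2) - math.sqrt(2.0 * dof - 1.0)


def association(c: Clustering, a: AnnotationSet) -> AssociationResult:
    """Contingency + Yates chi-squared + Fisher z in one step."""
    chi2, dof = chi_squared_yates(contingency(c, a))
    return AssociationResult(chi2, dof, fisher_z(chi2, dof))


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------


def background_probabilities(
    features: dict[str, set[str]], items: set[str] | None = None
) -> dict[str, float]:
    """Feature probability = carrier count / item count over all clusters."""
    pool = set(features) if items is None else items & set(features)
    n = len(pool)
    if n == 0:
        raise ValueError("no items to compute background from")
    counts: dict[str, int] = {}
    for item in pool:
        for ft in features[item]:
            counts[ft] = counts.get(ft, 0) + 1
    return {ft: c / n for ft, c in counts.items()}


def enrichment(
    c: Clustering,
    features: dict[str, set[str]],
    background: dict[str, float] | None = None,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Per-cluster upper-tail enrichment p-values for every feature.

    Default law: hypergeometric P(X >= n) for drawing the cluster from the
    finite population of clustered items.  Low-frequency switch: when
    n*p < 5 and p < 0.1, the Poisson upper tail with lambda = cluster_size*p
    is used instead.  ``background`` overrides the empirical feature
    probabilities; a feature observed but absent from it is an error.
    ``correction`` may be "bonferroni" or "bh" (off by default; raw
    p-values are the primary output).
    """
    items = set(c.labels)
    pop = items & set(features)
    if not pop:
        raise ValueError("no clustered items carry features")
    N = len(items)
    carrier_counts: dict[str, int] = {}
    for item in pop:
        for ft in features[item]:
            carrier_counts[ft] = carrier_counts.get(ft, 0) + 1
    if background is None:
        background = {ft: k / N for ft, k in carrier_counts.items()}
    else:
        missing = set(carrier_counts) - set(background)
        if missing:
            raise KeyError(f"features absent from background: {sorted(missing)}")
    for ft, p in background.items():
        if not 0 < p <= 1:
            raise ValueError(f"background probability for {ft!r} outside (0, 1]")

    members = c.members()
    results: list[EnrichmentResult] = []
    for cl in range(1, c.k + 1):
        size = len(members[cl])
        in_cluster: dict[str, int] = {ft: 0 for ft in background}
        for item in members[cl]:
            for ft in features.get(item, ()):
                in_cluster[ft] += 1
        for ft, p in sorted(background.items()):
            n = in_cluster[ft]
            if n * p < 5 and p < 0.1:
                law = "poisson"
                p_value = float(sps.poisson.sf(n - 1, size * p))
            else:
                law = "hypergeometric"
                K = carrier_counts.get(ft, int(round(p * N)))
                p_value = float(sps.hypergeom.sf(n - 1, N, K, size))
            results.append(EnrichmentResult(cl, ft, n, p, min(p_value, 1.0), law))

    if correction:
        ps = np.array([r.p_value for r in results])
        if correction == "bonferroni":
            adj = np.minimum(ps * len(ps), 1.0)
        elif correction == "bh":
            order = np.argsort(ps)
            m = len(ps)
            adj = np.empty(m)
            running = 1.0
            for rank_from_top, i in enumerate(order[::-1]):
                rank = m - rank_from_top
                running = min(running, ps[i] * m / rank)
                adj[i] = running
        else:
            raise ValueError(f"unknown correction {correction!r}")
        for r, q in zip(results, adj):
            r.p_value = float(q)
    return results


# --------------------------------------------------------------------------
# clustering comparison
# --------------------------------------------------------------------------


def compare_clusterings(
    clusterings: dict[str, Clustering],
    annotation_sets: list[AnnotationSet],
) -> pd.DataFrame:
    """Fisher z for every (clustering, annotation set) pair.

    Returns a clustering-by-set matrix of z-scores; comparing schemes at
    equal cluster counts (e.g. a tree cut matched to a reference hierarchy
    level, see :func:`cut_to_match`) is the caller's responsibility.
    """
    data = {
        a.name: [association(c, a).z for c in clusterings.values()]
        for a in annotation_sets
    }
    return pd.DataFrame(data, index=list(clusterings.keys()))


def cut_to_match(t: Dendrogram, reference: Clustering) -> Clustering:
    """Cut the tree into as many groups as a reference classification has."""
    return cut_tree(t, reference.k)


# --------------------------------------------------------------------------
# TSV I/O
# --------------------------------------------------------------------------


def read_annotations_tsv(text: str) -> dict[str, AnnotationSet]:
    """Rows of item_id <TAB> source <TAB> keyword; one set per source."""
    sets: dict[str, dict[str, set[str]]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        item, source, kw = ln.split("\t")
        sets.setdefault(source, {}).setdefault(item, set()).add(kw)
    return {name: AnnotationSet(name, assign) for name, assign in sets.items()}


def write_annotations_tsv(sets: list[AnnotationSet]) -> str:
    out = ["item_id\tsource\tkeyword"]
    for a in sets:
        for item in sorted(a.assignments):
            for kw in sorted(a.assignments[item]):
                out.append(f"{item}\t{a.name}\t{kw}")
    return "\n".join(out) + "\n"


def write_enrichment_tsv(results: list[EnrichmentResult]) -> str:
    out = ["cluster\tfeature\tn\tp_background\tlaw\tp_value"]
    for r in results:
        out.append(
            f"{r.cluster}\t{r.feature}\t{r.n}\t{r.p_background!r}\t{r.law_used}\t{r.p_value!r}"
        )
    return "\n".join(out) + "\n"
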