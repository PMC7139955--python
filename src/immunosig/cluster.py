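"""Two-way hierarchical clustering of immunome-restricted expression.

Genes (and separately, samples) are agglomerated using correlation
distance 1 - Pearson r.  For centroid linkage the dissimilarity between
two clusters is the correlation distance between their mean profiles,
recomputed from the original profiles after every merge — centroid
linkage under a non-Euclidean dissimilarity has no exact Lance-Williams
update, so recomputation is the only self-consistent definition.  The
resulting merge heights can occasionally decrease (inversions); such
heights are flattened up to the previous merge height and the event is
logged.

Ties in the minimum inter-cluster distance are broken by the
lexicographically smallest pair of cluster representative labels (the
smallest leaf label in each cluster), which makes the merge sequence
deterministic and invariant to input ordering.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LOG2, ExpressionMatrix

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


# ---------------------------------------------------------------------------
# immunome taxonomy


@dataclass
class ImmunomeModel:
    """Gene -> immune-class taxonomy (LM22-style, ~22 classes).

    Loaded from a GMT where each line is one class; a gene may belong to
    several classes.  The packaged file is a placeholder membership
    meant to be edited for real analyses.
    """

    classes: dict[str, set[str]]  # gene -> class labels

    @property
    def vocabulary(self) -> set[str]:
        out: set[str] = set()
        for labels in self.classes.values():
            out |= labels
        return out

    @property
    def genes(self) -> set[str]:
        return set(self.classes)

    @classmethod
    def from_gmt(cls, path: str) -> "ImmunomeModel":
        from .io import read_gmt

        sets = read_gmt(path)
        classes: dict[str, set[str]] = {}
        for label, rec in sets.items():
            for g in rec["genes"]:
                classes.setdefault(g, set()).add(label)
        return cls(classes)

    @classmethod
    def default(cls) -> "ImmunomeModel":
        from importlib import resources

        path = resources.files("immunosig") / "data" / "immunome_placeholder.gmt"
        return cls.from_gmt(str(path))


# ---------------------------------------------------------------------------
# dendrogram


@dataclass
class Merge:
    left: int
    right: int
    height: float


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over labelled leaves.

    Node ids follow the scipy convention: leaves are ``0..n-1`` in the
    order of ``leaves``; the i-th merge creates node ``n + i``.  Heights
    are non-decreasing (inversions flattened at build time).
    """

    leaves: list[str]
    merges: list[Merge]
    axis: str = "genes"  # genes | samples
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if self.merges and len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cut(self, height: float | None = None, k: int | None = None) -> list[list[str]]:
        """Flat clusters from cutting the tree.

        Exactly one of ``height`` (keep merges with height <= h) or
        ``k`` (undo the last k-1 merges) must be given.  Clusters are
        returned as sorted member lists, ordered by first member.
        """
        if (height is None) == (k is None):
            raise ValueError("give exactly one of height= or k=")
        n = len(self.leaves)
        if k is not None:
            if not 1 <= k <= n:
                raise ValueError(f"k={k} out of range for {n} leaves")
            use = self.merges[: n - k]
        else:
            use = [m for m in self.merges if m.height <= height]
        parent = list(range(n + len(self.merges)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # heights are non-decreasing, so `use` is always a prefix of merges
        for idx, m in enumerate(use):
            node = n + idx
            parent[find(m.left)] = node
            parent[find(m.right)] = node
        groups: dict[int, list[str]] = {}
        for leaf in range(n):
            groups.setdefault(find(leaf), []).append(self.leaves[leaf])
        clusters = [sorted(g) for g in groups.values()]
        return sorted(clusters, key=lambda c: c[0])

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Node id -> set of descendant leaf labels."""
        n = len(self.leaves)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.leaves)
        }
        for i, m in enumerate(self.merges):
            sets[n + i] = sets[m.left] | sets[m.right]
        return sets


# ---------------------------------------------------------------------------
# distances


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson r; in [0, 2].  Constant vectors are rejected."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc * xc).sum())
    ny = np.sqrt((yc * yc).sum())
    if nx == 0 or ny == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip((xc * yc).sum() / (nx * ny), -1.0, 1.0))
    return 1.0 - r


# ---------------------------------------------------------------------------
# agglomeration


def hierarchical_cluster(
    m: ExpressionMatrix,
    axis: str = "genes",
    linkage: str = "centroid",
) -> Dendrogram:
    """Agglomerative clustering of genes or samples with correlation
    distance.

    ``centroid`` linkage recomputes the mean profile of each cluster
    after every merge and measures 1 - r between the means; ``average``
    linkage is the mean pairwise leaf-leaf correlation distance
    (Lance-Williams update).  The merge sequence is deterministic: ties
    in minimum distance are broken by the lexicographically smallest
    pair of cluster representatives.
    """
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    if linkage not in ("centroid", "average"):
        raise ValueError("linkage must be 'centroid' or 'average'")
    if axis == "genes":
        labels = m.gene_ids
        profiles = m.values.to_numpy(dtype=float)
    else:
        labels = m.sample_ids
        profiles = m.values.to_numpy(dtype=float).T
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    for i, lab in enumerate(labels):
        if np.ptp(profiles[i]) == 0:
            raise ValueError(f"constant profile for {axis[:-1]} {lab!r}")

    # cluster state keyed by node id
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: labels[i] for i in range(n)}
    sums: dict[int, np.ndarray] = {i: profiles[i].copy() for i in range(n)}
    active: set[int] = set(range(n))

    dist: dict[frozenset[int], float] = {}
    if linkage == "average":
        base = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base[i, j] = base[j, i] = correlation_distance(
                    profiles[i], profiles[j]
                )
        for i in range(n):
            for j in range(i + 1, n):
                dist[frozenset((i, j))] = base[i, j]
    else:
        for i in range(n):
            for j in range(i + 1, n):
                dist[frozenset((i, j))] = correlation_distance(
                    profiles[i], profiles[j]
                )

    def centroid(node: int) -> np.ndarray:
        return sums[node] / len(members[node])

    merges: list[Merge] = []
    warnings: list[str] = []
    last_height = -np.inf
    while len(active) > 1:
        best_key = None
        best_pair: tuple[int, int] | None = None
        best_d = np.inf
        ordered = sorted(active, key=lambda c: rep[c])
        for ai in range(len(ordered)):
            for bi in range(ai + 1, len(ordered)):
                a, b = ordered[ai], ordered[bi]
                d = dist[frozenset((a, b))]
                key = (d, tuple(sorted((rep[a], rep[b]))))
                if d < best_d - _TIE_EPS or (
                    abs(d - best_d) <= _TIE_EPS and (best_key is None or key < best_key)
                ):
                    best_d, best_key, best_pair = d, key, (a, b)
        assert best_pair is not None
        a, b = best_pair
        height = best_d
        if height < last_height:
            warnings.append(
                f"inversion flattened: merge of ({rep[a]}, {rep[b]}) at "
                f"{height:.6g} raised to {last_height:.6g}"
            )
            height = last_height
        last_height = height
        node = n + len(merges)
        merges.append(Merge(a, b, float(height)))
        members[node] = members[a] + members[b]
        rep[node] = min(rep[a], rep[b])
        sums[node] = sums[a] + sums[b]
        active.discard(a)
        active.discard(b)
        size_a, size_b = len(members[a]), len(members[b])
        for c in active:
            key = frozenset((node, c))
            if linkage == "centroid":
                dist[key] = correlation_distance(centroid(node), centroid(c))
            else:
                da = dist[frozenset((a, c))]
                db = dist[frozenset((b, c))]
                dist[key] = (size_a * da + size_b * db) / (size_a + size_b)
        active.add(node)
    if warnings:
        for w in warnings:
            logger.warning(w)
    return Dendrogram(leaves=list(labels), merges=merges, axis=axis, warnings=warnings)


# ---------------------------------------------------------------------------
# modules


@dataclass
class GeneModule:
    name: str
    genes: list[str]
    mean_within_correlation: float | None = None
    dominant_classes: list[str] = field(default_factory=list)


def _mean_within_correlation(m: ExpressionMatrix, genes: list[str]) -> float | None:
    if len(genes) < 2:
        return None
    x = m.values.loc[genes].to_numpy(dtype=float)
    r = np.corrcoef(x)
    iu = np.triu_indices(len(genes), k=1)
    return float(np.mean(r[iu]))


def _dominant_classes(genes: list[str], immunome: ImmunomeModel) -> list[str]:
    counts: dict[str, int] = {}
    for g in genes:
        for c in immunome.classes.get(g, ()):
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return []
    top = max(counts.values())
    return sorted(c for c, k in counts.items() if k == top)


def extract_modules(
    d: Dendrogram,
    height: float | None = None,
    k: int | None = None,
    min_size: int = 2,
    matrix: ExpressionMatrix | None = None,
    immunome: ImmunomeModel | None = None,
) -> tuple[list[GeneModule], list[str]]:
    """Cut a gene dendrogram into co-expression modules.

    Clusters with >= ``min_size`` members become named modules
    (annotated with dominant immunome classes when a taxonomy is
    given); smaller clusters are returned as unassigned genes.  When
    neither ``height`` nor ``k`` is given, the tree is cut at the 25th
    percentile of merge heights (a convention, flagged in the log).
    """
    if d.axis != "genes":
        raise ValueError("extract_modules expects a gene dendrogram")
    if height is None and k is None:
        heights = [m.height for m in d.merges]
        height = float(np.quantile(heights, 0.25)) if heights else 0.0
        logger.info(
            "extract_modules: no cut given, using 25th-percentile height %.4g",
            height,
        )
    clusters = d.cut(height=height, k=k)
    modules: list[GeneModule] = []
    unassigned: list[str] = []
    idx = 1
    for cl in clusters:
        if len(cl) >= min_size:
            mod = GeneModule(name=f"module_{idx}", genes=cl)
            if matrix is not None:
                mod.mean_within_correlation = _mean_within_correlation(matrix, cl)
            if immunome is not None:
                mod.dominant_classes = _dominant_classes(cl, immunome)
            modules.append(mod)
            idx += 1
        else:
            unassigned.extend(cl)
    return modules, sorted(unassigned)


def select_focus_set(
    modules: list[GeneModule],
    immunome: ImmunomeModel,
    classes_of_interest: list[str],
) -> list[str]:
    """Union of module genes whose dominant immunome classes intersect
    the classes of interest, in sorted (deterministic) order — the
    class-filtered focus set used for sample re-clustering."""
    vocab = immunome.vocabulary
    unknown = [c for c in classes_of_interest if c not in vocab]
    if unknown:
        raise ValueError(f"classes not in the immunome vocabulary: {unknown}")
    wanted = set(classes_of_interest)
    genes: set[str] = set()
    for mod in modules:
        if wanted & set(mod.dominant_classes):
            genes.update(mod.genes)
    if not genes:
        raise ValueError(
            "no module matches the requested classes; review class "
            "annotations or broaden classes_of_interest"
        )
    return sorted(genes)


def partition_samples(
    d: Dendrogram,
    m: ExpressionMatrix,
    focus_genes: list[str],
    k: int = 2,
    min_separation_d: float = 2.0,
) -> pd.Series:
    """Two-group immune-active / immune-silent partition of the sample
    tree.

    The tree is cut at ``k`` clusters and the cluster with the higher
    mean log2 expression over the focus set is labelled ``active``.
    Whether two groups genuinely exist is judged by Ashman's D on the
    per-sample mean focus expression,

        D = |m_A - m_B| / sqrt((s_A^2 + s_B^2) / 2),

    with the conventional bimodality threshold D >= 2: below it the
    cohort is treated as a degenerate single group and every sample is
    labelled ``active`` with a warning.  An exact tie in cluster means
    is broken by labelling the larger cluster active.
    """
    if d.axis != "samples":
        raise ValueError("partition_samples expects a sample dendrogram")
    focus = [g for g in focus_genes if g in m.values.index]
    if not focus:
        raise ValueError("no focus gene present in the matrix")
    clusters = d.cut(k=k)
    per_sample = m.values.loc[focus].mean(axis=0)
    means = [float(per_sample[cl].mean()) for cl in clusters]
    sds = [float(per_sample[cl].std(ddof=1)) if len(cl) > 1 else 0.0 for cl in clusters]
    labels = pd.Series("silent", index=pd.Index(m.sample_ids, name="sample_id"))
    order = np.argsort(means)[::-1]
    top, second = int(order[0]), int(order[1]) if len(order) > 1 else int(order[0])
    spread = means[top] - means[second]
    pooled = math.sqrt((sds[top] ** 2 + sds[second] ** 2) / 2.0) if len(clusters) > 1 else 0.0
    if len(clusters) > 1 and spread == 0.0:
        big = int(np.argmax([len(c) for c in clusters]))
        logger.warning(
            "partition_samples: exact tie in cluster means; labelling the "
            "larger cluster active"
        )
        labels.loc[clusters[big]] = "active"
        return labels
    if len(clusters) > 1 and pooled > 0 and spread / pooled < min_separation_d:
        logger.warning(
            "partition_samples: Ashman's D = %.2f < %.2f — degenerate "
            "single-group cohort, labelling all samples active",
            spread / pooled,
            min_separation_d,
        )
        labels[:] = "active"
        return labels
    labels.loc[clusters[top]] = "active"
    return labels


# ---------------------------------------------------------------------------
# newick round-trip


def _escape(label: str) -> str:
    return label.replace(" ", "_").replace(",", "_").replace("(", "_").replace(")", "_")


def to_newick(d: Dendrogram) -> str:
    """Ultrametric newick string; leaf branch lengths place all leaves
    at height 0 and internal nodes at their merge heights."""
    n = len(d.leaves)
    height = {i: 0.0 for i in range(n)}
    for i, m in enumerate(d.merges):
        height[n + i] = m.height
    children = {n + i: (m.left, m.right) for i, m in enumerate(d.merges)}

    def render(node: int, parent_h: float | None) -> str:
        if node < n:
            s = _escape(d.leaves[node])
        else:
            l, r = children[node]
            s = f"({render(l, height[node])},{render(r, height[node])})"
        if parent_h is None:
            return s
        return f"{s}:{max(parent_h - height[node], 0.0):.10g}"

    root = n + len(d.merges) - 1 if d.merges else 0
    return render(root, None) + ";"


def from_newick(text: str, axis: str = "genes") -> Dendrogram:
    """Rebuild a Dendrogram from an ultrametric newick string written by
    :func:`to_newick` (binary topology, heights as depth below root)."""
    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(text), "newick")
    root = tree.root

    records: list[tuple[frozenset[str], frozenset[str], frozenset[str], float]] = []
    leaves_in_order: list[str] = []

    def walk(clade) -> tuple[frozenset[str], float]:
        if not clade.clades:
            name = str(clade.name)
            leaves_in_order.append(name)
            return frozenset([name]), 0.0
        if len(clade.clades) != 2:
            raise ValueError("dendrogram newick must be strictly binary")
        (sl, hl), (sr, hr) = walk(clade.clades[0]), walk(clade.clades[1])
        bl = clade.clades[0].branch_length or 0.0
        h = hl + bl
        records.append((sl | sr, sl, sr, h))
        return sl | sr, h

    walk(root)
    n = len(leaves_in_order)
    ids: dict[frozenset[str], int] = {
        frozenset([lab]): i for i, lab in enumerate(leaves_in_order)
    }
    merges: list[Merge] = []
    # sort by height; ties broken by subtree size so children precede parents
    for full, sl, sr, h in sorted(
        records, key=lambda r: (r[3], len(r[0]), min(r[0]))
    ):
        node = n + len(merges)
        merges.append(Merge(ids[sl], ids[sr], float(h)))
        ids[full] = node
    return Dendrogram(leaves=leaves_in_order, merges=merges, axis=axis)
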