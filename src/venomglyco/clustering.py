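"""Binary feature matrices, hierarchical clustering, and exclusive intersections.

Samples (venoms) are compared on presence/absence of features — intact
glycopeptides (backbone + composition), neutral precursor masses, or bare
peptide backbones.  On binary rows the squared Euclidean distance is the
count of differing features, so complete-linkage/Euclidean clustering groups
samples by repertoire overlap.

The agglomeration is written out explicitly rather than delegated so the
merge order is fully reproducible: on equal heights the pair whose smallest
member labels sort first is merged.  A test cross-checks the merge heights
against scipy's implementation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .assembly import IntactGlycopeptide

__all__ = ["FeatureMatrix", "Dendrogram", "build_matrix", "cluster", "intersections", "mass_bin"]

FEATURE_KINDS = ("glycopeptide", "neutral_mass", "backbone")


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples x features presence/absence matrix."""

    values: pd.DataFrame  # index: sample labels; columns: feature labels; 0/1
    feature_kind: str

    def __post_init__(self) -> None:
        v = self.values
        if not v.isin([0, 1]).all().all():
            raise ValueError("feature matrix must be binary")
        if (v.sum(axis=0) == 0).any():
            raise ValueError("all-zero feature column")

    def feature_sets(self) -> dict[str, set[str]]:
        return {
            s: set(self.values.columns[self.values.loc[s] == 1]) for s in self.values.index
        }


def mass_bin(masses: list[float], bin_da: float = 0.02) -> list[list[float]]:
    """Single-linkage 1-D binning: masses closer than ``bin_da`` chain together."""
    if not masses:
        return []
    ordered = sorted(masses)
    groups: list[list[float]] = [[ordered[0]]]
    for m in ordered[1:]:
        if m - groups[-1][-1] <= bin_da:
            groups[-1].append(m)
        else:
            groups.append([m])
    return groups


def build_matrix(
    records: list[IntactGlycopeptide],
    feature_kind: str = "glycopeptide",
    mass_bin_da: float = 0.02,
) -> FeatureMatrix:
    """Binary sample x feature matrix for one feature kind.

    Glycopeptide features are (backbone, composition) pairs; backbone
    features bare sequences; neutral-mass features are single-linkage mass
    bins at ``mass_bin_da`` across all samples, each merged group one
    feature labelled by its mean m/z.
    """
    if not records:
        raise ValueError("no records")
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind: {feature_kind!r}")
    samples = sorted({r.sample_id for r in records})
    presence: dict[str, set[str]] = defaultdict(set)
    if feature_kind == "neutral_mass":
        groups = mass_bin([r.neutral_mass for r in records], mass_bin_da)
        edges = [g[0] for g in groups]  # group lower bounds, sorted

        def bin_label(mass: float) -> str:
            idx = int(np.searchsorted(edges, mass, side="right")) - 1
            return f"m{np.mean(groups[idx]):.4f}"

        for r in records:
            presence[r.sample_id].add(bin_label(r.neutral_mass))
    else:
        for r in records:
            feat = (
                f"{r.backbone}|{r.composition_key}" if feature_kind == "glycopeptide" else r.backbone
            )
            presence[r.sample_id].add(feat)
    features = sorted(set().union(*presence.values()))
    mat = pd.DataFrame(
        [[1 if f in presence[s] else 0 for f in features] for s in samples],
        index=pd.Index(samples, name="sample_id"),
        columns=features,
    )
    return FeatureMatrix(mat, feature_kind)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history over sample labels.

    ``merges`` lists (members_a, members_b, height, merged_size) in merge
    order; heights are non-decreasing for complete linkage (ultrametric).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float, int], ...]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        tree = self._tree()
        order: list[str] = []

        def walk(node):
            if isinstance(node, str):
                order.append(node)
            else:
                walk(node[0]); walk(node[1])

        walk(tree[0])
        return tuple(order)

    def _tree(self):
        nodes: dict[tuple[str, ...], object] = {(lab,): lab for lab in self.labels}
        heights: dict[tuple[str, ...], float] = {(lab,): 0.0 for lab in self.labels}
        for a, b, h, _ in self.merges:
            merged = tuple(sorted(a + b))
            nodes[merged] = (nodes[tuple(a)], nodes[tuple(b)], h)
            heights[merged] = h
        root = tuple(sorted(self.labels))
        return nodes[root], heights

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels after cutting the dendrogram into ``k`` clusters."""
        n = len(self.labels)
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}]")
        parent = {lab: lab for lab in self.labels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, _, _ in self.merges[: n - k]:
            ra, rb = find(a[0]), find(b[0])
            parent[ra] = rb
        roots = sorted({find(lab) for lab in self.labels})
        idx = {r: i for i, r in enumerate(roots)}
        return {lab: idx[find(lab)] for lab in self.labels}

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences to the parent."""
        tree, _ = self._tree()

        def render(node, parent_h: float) -> str:
            if isinstance(node, str):
                return f"{node}:{parent_h:.6g}"
            left, right, h = node
            return f"({render(left, h)},{render(right, h)}):{max(parent_h - h, 0.0):.6g}"

        if isinstance(tree, str):
            return f"{tree};"
        left, right, h = tree
        return f"({render(left, h)},{render(right, h)});"


def cluster(matrix: FeatureMatrix | pd.DataFrame, linkage: str = "complete",
            metric: str = "euclidean") -> Dendrogram:
    """Agglomerative clustering of the sample rows.

    Complete linkage over Euclidean distances, with a deterministic
    tie-break: among pairs at the minimal height, merge the pair whose
    sorted member labels are lexicographically smallest.
    """
    df = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    if df.shape[0] < 2:
        raise ValueError("clustering requires >= 2 samples")
    if linkage != "complete":
        raise ValueError(f"unsupported linkage: {linkage!r}")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric: {metric!r}")
    labels = [str(x) for x in df.index]
    X = df.to_numpy(dtype=float)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))

    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    cdist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
    }
    merges = []
    active = list(range(len(clusters)))
    while len(active) > 1:
        best = None
        for ii, jj in combinations(active, 2):
            key = (min(ii, jj), max(ii, jj))
            cand = (cdist[key], tuple(sorted(clusters[ii] + clusters[jj])), key)
            if best is None or cand < best:
                best = cand
        h, _, (ii, jj) = best
        a, b = clusters[ii], clusters[jj]
        if b < a:
            a, b = b, a
        merged = tuple(sorted(a + b))
        merges.append((a, b, float(h), len(merged)))
        new_idx = len(clusters)
        clusters.append(merged)
        active = [x for x in active if x not in (ii, jj)]
        for x in active:
            key_i = (min(x, ii), max(x, ii))
            key_j = (min(x, jj), max(x, jj))
            cdist[(x, new_idx)] = max(cdist[key_i], cdist[key_j])  # complete linkage
        active.append(new_idx)
    return Dendrogram(tuple(labels), tuple(merges))


def intersections(feature_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection counts (UpSet semantics).

    For every nonempty subset of samples that actually owns features, the
    count of features present in exactly that subset.  Counts sum to the
    union size.
    """
    if not feature_sets:
        raise ValueError("at least one feature set required")
    pattern_counts: dict[tuple[str, ...], int] = defaultdict(int)
    union = set().union(*feature_sets.values())
    for feat in union:
        members = tuple(sorted(s for s, fs in feature_sets.items() if feat in fs))
        pattern_counts[members] += 1
    rows = [
        {"members": "&".join(members), "degree": len(members), "count": n}
        for members, n in sorted(pattern_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["members", "degree", "count"])
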