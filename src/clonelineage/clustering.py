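"""Redundancy detection: Jaccard distance, Ward agglomeration, cluster
cutting, 'Unique' detection and the burden-downsampling experiment.

Redundant clonal lines descend from the same recent founder and therefore
share most of their mosaic mutations; with independent ~50% detection per
line at 5x coverage, two redundant lines still share about a third of their
detected call sites, far above the sharing of unrelated lineages.  The
distance between call-site sets is 1 - J (J = Jaccard index), agglomerated
with Ward's minimum-variance method (the D2 variant, squared distances in
the Lance-Williams update).

The agglomeration loop is written out here rather than delegated so that
ties merge deterministically (lowest index pair first); scipy's linkage is
used as an independent cross-check in the test-suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

UNIQUE_LABEL = "Unique"


@dataclass
class DistanceMatrix:
    """Symmetric matrix of 1-J distances over an ordered sample list."""

    ids: list[str]
    values: np.ndarray
    #: Upper bound of the distance range: 1 for 1-J, 2 for 1-rho.
    max_value: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > self.max_value + 1e-12:
            raise ValueError(f"distances must lie in [0, {self.max_value}]")
        self.values = v

    def similarity(self) -> np.ndarray:
        return 1.0 - self.values


@dataclass
class Dendrogram:
    """Agglomeration record: leaves 0..n-1; merge k creates node n+k."""

    ids: list[str]
    merges: list[tuple[int, int, float, int]]  # (left, right, height, size)

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def to_scipy(self) -> np.ndarray:
        """Linkage-matrix form (for plotting with scipy/matplotlib)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def leaves_under(self, node: int) -> list[int]:
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            x = stack.pop()
            if x < n:
                out.append(x)
            else:
                a, b, _, _ = self.merges[x - n]
                stack.extend((a, b))
        return sorted(out)

    def to_json(self) -> str:
        return json.dumps(
            {"ids": self.ids,
             "merges": [[a, b, h, s] for a, b, h, s in self.merges]}
        )


@dataclass
class ClusterAssignment:
    """Partition of samples into labelled clusters plus the 'Unique' pool."""

    labels: dict[str, str]
    unique: dict[str, bool] = field(default_factory=dict)
    dendrogram: Dendrogram | None = None

    def __post_init__(self) -> None:
        if not self.unique:
            self.unique = {s: lab == UNIQUE_LABEL for s, lab in self.labels.items()}
        for s, u in self.unique.items():
            if u and self.labels[s] != UNIQUE_LABEL:
                raise ValueError(f"sample {s} flagged unique but labelled {self.labels[s]}")

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, lab in self.labels.items():
            out.setdefault(lab, []).append(s)
        return {lab: sorted(ms) for lab, ms in out.items()}


def jaccard_distance(callsets: Mapping[str, Iterable[Hashable]]) -> DistanceMatrix:
    """Pairwise 1 - J over call-site sets.

    J is the fraction of sites called in both samples relative to those
    called in at least one.  Two empty sets get distance 1: absence of
    evidence is not redundancy.
    """
    ids = list(callsets)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    sets = [set(callsets[i]) for i in ids]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            if union == 0:
                dij = 1.0
            else:
                dij = 1.0 - len(sets[i] & sets[j]) / union
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=ids, values=d)


def ward_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerate by Ward's minimum-variance method (Ward.D2).

    Squared distances follow the Lance-Williams update
    ``d(k, ij)^2 = [(n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2 - n_k d(i,j)^2]
    / (n_i+n_j+n_k)``.  On equal heights the pair with the lowest (i, j)
    node indices merges first, so results are library-independent.
    """
    n = len(dist.ids)
    if n < 2:
        raise ValueError("ward_cluster needs at least two samples")
    total = 2 * n - 1
    d2 = np.full((total, total), np.inf)
    d2[:n, :n] = dist.values ** 2
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                key = (d2[i, j], i, j)
                if best is None or key < best:
                    best = key
        h2, i, j = best
        new = n + step
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            val = ((ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * h2) / (ni + nj + nk)
            d2[new, k] = d2[k, new] = max(val, 0.0)
        sizes[new] = ni + nj
        active = [k for k in active if k not in (i, j)] + [new]
        merges.append((i, j, math.sqrt(max(h2, 0.0)), int(ni + nj)))
    return Dendrogram(ids=dist.ids, merges=merges)


def _components_after(dend: Dendrogram, n_merges: int) -> dict[str, str]:
    n = dend.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in range(n_merges):
        a, b, _, _ = dend.merges[k]
        node = n + k
        parent[find(a)] = node
        parent[find(b)] = node
    comp: dict[int, list[int]] = {}
    for leaf in range(n):
        comp.setdefault(find(leaf), []).append(leaf)
    return _label(dend.ids, comp.values())


def _label(ids: Sequence[str], groups: Iterable[list[int]]) -> dict[str, str]:
    ordered = sorted(groups, key=min)
    labels: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        for leaf in members:
            labels[ids[leaf]] = f"C{k}"
    return labels


def cut_clusters(
    dendrogram: Dendrogram,
    policy: str = "min_within_similarity",
    *,
    dist: DistanceMatrix | None = None,
    k: int | None = None,
    height: float | None = None,
    s_min: float = 0.10,
) -> ClusterAssignment:
    """Cut a dendrogram into clusters.

    Policies: ``fixed_k`` (exactly k clusters), ``height_threshold`` (apply
    merges at height <= threshold), ``min_within_similarity`` (default:
    top-down descent accepting the largest nodes in which every within-pair
    Jaccard similarity is >= ``s_min``; requires ``dist``).
    """
    n = dendrogram.n_leaves
    if policy == "fixed_k":
        if k is None or not 1 <= k <= n:
            raise ValueError(f"fixed_k requires 1 <= k <= {n}")
        labels = _components_after(dendrogram, n - k)
    elif policy == "height_threshold":
        if height is None:
            raise ValueError("height_threshold requires height=")
        m = sum(1 for _, _, h, _ in dendrogram.merges if h <= height)
        labels = _components_after(dendrogram, m)
    elif policy == "min_within_similarity":
        if dist is None:
            raise ValueError("min_within_similarity requires dist=")
        sim = dist.similarity()
        groups: list[list[int]] = []
        stack = [2 * n - 2]  # root
        while stack:
            node = stack.pop()
            leaves = dendrogram.leaves_under(node)
            ok = all(
                sim[a, b] >= s_min for ii, a in enumerate(leaves) for b in leaves[ii + 1:]
            )
            if ok or node < n:
                groups.append(leaves)
            else:
                a, b, _, _ = dendrogram.merges[node - n]
                stack.extend((b, a))
        labels = _label(dendrogram.ids, groups)
    else:
        raise ValueError(f"unknown cut policy {policy!r}")
    return ClusterAssignment(labels=labels, dendrogram=dendrogram)


def detect_unique(
    dist: DistanceMatrix, assignment: ClusterAssignment, j_max: float = 0.02
) -> ClusterAssignment:
    """Pool samples that share essentially nothing with any other sample.

    A sample is unique iff its maximum Jaccard similarity to every other
    sample is < ``j_max``.  Unique samples are removed from their clusters
    and pooled under the 'Unique' label; they represent lineages sampled
    once, which must be sequenced deeply.
    """
    if not 0 <= j_max < 1:
        raise ValueError("j_max must lie in [0, 1)")
    sim = dist.similarity()
    np.fill_diagonal(sim, -np.inf)
    labels = dict(assignment.labels)
    unique: dict[str, bool] = {}
    for idx, sample in enumerate(dist.ids):
        is_unique = bool(sim[idx].max() < j_max)
        unique[sample] = is_unique
        if is_unique:
            labels[sample] = UNIQUE_LABEL
    return ClusterAssignment(labels=labels, unique=unique, dendrogram=assignment.dendrogram)


def subsample_burden(
    callsets: Mapping[str, Iterable[Hashable]], fraction: float, seed: int
) -> dict[str, set]:
    """Emulate a lower mutation burden by downsampling the union call set.

    ``floor(fraction * |union|)`` sites are drawn uniformly without
    replacement from the union of all call sites; each sample's set is
    intersected with the draw.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    sets = {s: set(v) for s, v in callsets.items()}
    union = sorted(set().union(*sets.values())) if sets else []
    if fraction == 1.0:
        return sets
    n_keep = math.floor(fraction * len(union))
    rng = np.random.default_rng(seed)
    keep = set(
        union[i] for i in rng.choice(len(union), size=n_keep, replace=False)
    )
    return {s: v & keep for s, v in sets.items()}


def adjusted_rand_index(truth: Mapping[str, Hashable], pred: Mapping[str, Hashable]) -> float:
    """Chance-corrected agreement of two partitions over the same samples."""
    samples = sorted(truth)
    if sorted(pred) != samples:
        raise ValueError("partitions cover different sample sets")
    return float(adjusted_rand_score([truth[s] for s in samples],
                                     [pred[s] for s in samples]))


def write_assignment(assignment: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tcluster\tis_unique\n")
        for s in sorted(assignment.labels):
            fh.write(f"{s}\t{assignment.labels[s]}\t{int(assignment.unique[s])}\n")


def write_distance(dist: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\t" + "\t".join(dist.ids) + "\n")
        for i, s in enumerate(dist.ids):
            fh.write(s + "\t" + "\t".join(f"{x:.6f}" for x in dist.values[i]) + "\n")
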