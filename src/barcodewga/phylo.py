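"""Phylogeny and spatial statistics over binary mutation profiles.

Samples (spatial microniches) are encoded as a samples x sites matrix with
entries 1 (variant detected), 0 (not detected at adequate coverage) and NA
(coverage < 5 and not detected — the locus is unassessable). Pairwise
Manhattan distances over jointly assessable sites, rescaled to the full
site count, feed a balanced-minimum-evolution tree (neighbor joining
followed by NNI refinement under Pauplin's balanced length) rooted at an
artificial all-zero diploid taxon. The same matrix, NA-imputed to 0,
yields principal components whose spatial clustering is quantified by
Moran's I over a k-nearest-neighbour weight graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

DIPLOID_ROOT = "diploid"


@dataclass
class VariantMatrix:
    """Samples x sites binary mutation matrix with NA for unassessable loci."""

    samples: list[str]
    sites: list
    data: np.ndarray       # float matrix, entries 0.0 / 1.0 / nan
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.samples), len(self.sites)):
            raise ValueError("data shape must be (n_samples, n_sites)")
        valid = np.isnan(self.data) | np.isin(self.data, (0.0, 1.0))
        if not valid.all():
            raise ValueError("entries must be 0, 1 or NA")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.samples, columns=self.sites)


def build_variant_matrix(
    genotypes: pd.DataFrame,
    coverage: pd.DataFrame,
    min_cov: int = 5,
) -> VariantMatrix:
    """Apply the 1 / NA / 0 coding rule.

    ``genotypes`` holds per-sample detection (truthy = detected) and
    ``coverage`` the matching per-sample, per-site depths. An entry is 1
    whenever the variant was detected (regardless of depth), NA when it was
    not detected and depth < ``min_cov``, and 0 otherwise.
    """
    if genotypes.shape != coverage.shape:
        raise ValueError("genotypes and coverage must have identical shape")
    det = genotypes.to_numpy()
    det = (det == "called") if det.dtype == object else det.astype(bool)
    cov = coverage.to_numpy(dtype=float)
    data = np.where(det, 1.0, np.where(cov < min_cov, np.nan, 0.0))
    return VariantMatrix(
        samples=list(genotypes.index),
        sites=list(genotypes.columns),
        data=data,
        coverage=cov,
    )


def variant_distances(matrix: VariantMatrix) -> pd.DataFrame:
    """Pairwise Manhattan distances with NA rescaling.

    For each pair, the Manhattan distance over jointly non-NA sites is
    scaled by n_sites / n_used so sparsely covered pairs remain comparable.
    A pair with no jointly assessable site is an error.
    """
    X = matrix.data
    n_samples, n_sites = X.shape
    if n_samples < 2:
        raise ValueError("need at least two samples")
    D = np.zeros((n_samples, n_samples))
    for i, j in itertools.combinations(range(n_samples), 2):
        both = ~np.isnan(X[i]) & ~np.isnan(X[j])
        n_used = int(both.sum())
        if n_used == 0:
            raise ValueError(
                f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} share "
                "no assessable site"
            )
        d = np.abs(X[i, both] - X[j, both]).sum() * (n_sites / n_used)
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=matrix.samples, columns=matrix.samples)


def append_diploid_root(matrix: VariantMatrix, label: str = DIPLOID_ROOT) -> VariantMatrix:
    """Append the artificial diploid outgroup: all-zero, fully assessed."""
    if label in matrix.samples:
        raise ValueError(f"sample {label!r} already present")
    data = np.vstack([matrix.data, np.zeros((1, len(matrix.sites)))])
    cov = None
    if matrix.coverage is not None:
        cov = np.vstack([matrix.coverage, np.full((1, len(matrix.sites)), np.inf)])
    return VariantMatrix(matrix.samples + [label], matrix.sites, data, cov)


# ---------------------------------------------------------------------------
# balanced-minimum-evolution tree: NJ construction + NNI refinement
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted binary tree over leaf taxa, rooted for output at one leaf."""

    # adjacency: node -> {neighbor: branch_length}; leaves are taxon names,
    # internal nodes are integers
    adjacency: dict
    leaves: list[str]
    root_label: str | None = None
    flags: list[str] = field(default_factory=list)

    def newick(self) -> str:
        """Serialize rooted at the internal node adjacent to ``root_label``."""
        root_leaf = self.root_label or self.leaves[0]
        if root_leaf not in self.adjacency:
            raise ValueError(f"root taxon {root_leaf!r} not in tree")

        def subtree(node, parent) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                return f"{node}:{self.adjacency[parent][node]:.6g}"
            inner = ",".join(subtree(c, node) for c in children)
            length = self.adjacency[parent][node] if parent is not None else None
            return f"({inner})" + (f":{length:.6g}" if length is not None else "")

        anchor = next(iter(self.adjacency[root_leaf]))
        others = ",".join(subtree(c, anchor) for c in self.adjacency[anchor]
                          if c != root_leaf)
        return f"({root_leaf}:{self.adjacency[anchor][root_leaf]:.6g},{others});"


def _nj_topology(D: np.ndarray, names: list) -> dict:
    """Classic neighbor joining; returns unrooted adjacency without lengths."""
    n = len(names)
    nodes = list(range(n))
    label = {i: names[i] for i in range(n)}
    next_internal = n
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i != j}
    adjacency: dict = {names[i]: {} for i in range(n)}

    def d(i, j):
        return dist[(i, j)]

    while len(nodes) > 3:
        m = len(nodes)
        r = {i: sum(d(i, k) for k in nodes if k != i) for i in nodes}
        best, pair = None, None
        for i, j in itertools.combinations(nodes, 2):
            q = (m - 2) * d(i, j) - r[i] - r[j]
            if best is None or q < best:
                best, pair = q, (i, j)
        i, j = pair
        u = next_internal
        next_internal += 1
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        adjacency.setdefault(u, {})
        for child, length in ((i, li), (j, lj)):
            cl = label.get(child, child)
            adjacency[u][cl] = max(length, 0.0)
            adjacency.setdefault(cl, {})[u] = max(length, 0.0)
        for k in nodes:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(u, k)] = dist[(k, u)] = duk
        nodes = [k for k in nodes if k not in (i, j)] + [u]
        label[u] = u

    if len(nodes) == 3:
        i, j, k = nodes
        u = next_internal
        adjacency.setdefault(u, {})
        li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
        lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
        lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        for child, length in ((i, li), (j, lj), (k, lk)):
            cl = label.get(child, child)
            adjacency[u][cl] = max(length, 0.0)
            adjacency.setdefault(cl, {})[u] = max(length, 0.0)
    elif len(nodes) == 2:
        i, j = nodes
        ci, cj = label.get(i, i), label.get(j, j)
        adjacency.setdefault(ci, {})[cj] = max(d(i, j), 0.0)
        adjacency.setdefault(cj, {})[ci] = max(d(i, j), 0.0)
    return adjacency


def _topological_paths(adjacency: dict, leaves: list[str]) -> dict:
    """Edge counts between every leaf pair (for Pauplin's formula)."""
    paths = {}
    for src in leaves:
        seen = {src: 0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb in adjacency[node]:
                if nb not in seen:
                    seen[nb] = seen[node] + 1
                    stack.append(nb)
        for dst in leaves:
            if dst != src:
                paths[(src, dst)] = seen[dst]
    return paths


def _bme_length(adjacency: dict, leaves: list[str], D: pd.DataFrame) -> float:
    """Pauplin's balanced tree length: sum over pairs of 2^(1-p_ij) * D_ij."""
    paths = _topological_paths(adjacency, leaves)
    total = 0.0
    for a, b in itertools.combinations(leaves, 2):
        total += 2.0 ** (1 - paths[(a, b)]) * D.loc[a, b]
    return total


def _internal_edges(adjacency: dict) -> list[tuple]:
    out = []
    for a in adjacency:
        if isinstance(a, str):
            continue
        for b in adjacency[a]:
            if isinstance(b, str) or not (isinstance(a, int) and a < b):
                continue
            out.append((a, b))
    return out


def _nni_neighbors(adjacency: dict, edge: tuple):
    """The two alternative topologies from swapping subtrees across an edge."""
    a, b = edge
    a_subs = [n for n in adjacency[a] if n != b]
    b_subs = [n for n in adjacency[b] if n != a]
    if len(a_subs) != 2 or len(b_subs) != 2:
        return

    def rewire(swap_a, swap_b):
        new = {node: dict(nbrs) for node, nbrs in adjacency.items()}
        for node, old, new_nb in ((a, swap_a, swap_b), (b, swap_b, swap_a)):
            length = new[node].pop(old)
            del new[old][node]
            new[node][new_nb] = length
            new[new_nb][node] = length
        return new

    yield rewire(a_subs[0], b_subs[0])
    yield rewire(a_subs[0], b_subs[1])


def _estimate_branch_lengths(adjacency: dict, leaves: list[str], D: pd.DataFrame):
    """Ordinary least-squares branch lengths on the fixed topology."""
    edges = []
    for a in adjacency:
        for b in adjacency[a]:
            key = tuple(sorted((str(a), str(b))))
            if key not in {tuple(sorted((str(x), str(y)))) for x, y in edges}:
                edges.append((a, b))
    edge_index = {frozenset((a, b)): k for k, (a, b) in enumerate(edges)}
    pairs = list(itertools.combinations(leaves, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (src, dst) in enumerate(pairs):
        # recover path edges via DFS parent pointers
        parent = {src: None}
        stack = [src]
        while stack:
            node = stack.pop()
            if node == dst:
                break
            for nb in adjacency[node]:
                if nb not in parent:
                    parent[nb] = node
                    stack.append(nb)
        node = dst
        while parent[node] is not None:
            A[row, edge_index[frozenset((node, parent[node]))]] = 1.0
            node = parent[node]
        y[row] = D.loc[src, dst]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    flags = []
    if (lengths < -1e-9).any():
        flags.append("negative branch-length estimates clamped to 0")
    lengths = np.maximum(lengths, 0.0)
    new = {node: {} for node in adjacency}
    for (a, b) in edges:
        new[a][b] = new[b][a] = float(lengths[edge_index[frozenset((a, b))]])
    return new, flags


def bme_tree(
    distances: pd.DataFrame,
    root_label: str = DIPLOID_ROOT,
    nni: bool = True,
) -> PhyloTree:
    """Balanced-minimum-evolution tree from a distance matrix.

    Neighbor joining (the greedy BME heuristic) builds the initial
    topology; nearest-neighbour-interchange moves are then accepted while
    they decrease Pauplin's balanced tree length. Branch lengths are OLS
    estimates on the final topology, negatives clamped to zero. The tree is
    rooted at ``root_label`` when that taxon is present.
    """
    D = distances
    if not np.allclose(D.values, D.values.T):
        raise ValueError("distance matrix must be symmetric")
    if (D.values < 0).any():
        raise ValueError("distances must be non-negative")
    leaves = [str(x) for x in D.index]
    D = D.copy()
    D.index = D.columns = leaves
    adjacency = _nj_topology(D.values, leaves)
    if nni and len(leaves) >= 4:
        improved = True
        current_len = _bme_length(adjacency, leaves, D)
        while improved:
            improved = False
            for edge in _internal_edges(adjacency):
                for candidate in _nni_neighbors(adjacency, edge):
                    cand_len = _bme_length(candidate, leaves, D)
                    if cand_len < current_len - 1e-12:
                        adjacency, current_len, improved = candidate, cand_len, True
                        break
                if improved:
                    break
    adjacency, flags = _estimate_branch_lengths(adjacency, leaves, D)
    root = root_label if root_label in adjacency else None
    return PhyloTree(adjacency=adjacency, leaves=leaves, root_label=root, flags=flags)


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def knn_weights(coords: np.ndarray, k: int = 4) -> np.ndarray:
    """Row-standardized k-nearest-neighbour spatial weights."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    W = np.zeros((n, n))
    for i in range(n):
        for j in idx[i][1:]:
            W[i, j] = 1.0
    return W / W.sum(axis=1, keepdims=True)


def inverse_distance_weights(coords: np.ndarray, power: float = 1.0) -> np.ndarray:
    """Row-standardized inverse-distance spatial weights."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        W = 1.0 / dist ** power
    np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)


def morans_i(
    values: np.ndarray,
    coords: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    k: int = 4,
) -> float:
    """Moran's I spatial autocorrelation.

        I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with w_ii = 0 and W the total weight. ``weights`` may be supplied
    directly (any non-negative matrix with zero diagonal); otherwise a
    row-standardized k-nearest-neighbour graph is built from ``coords``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if weights is None:
        if coords is None:
            raise ValueError("provide coords or a weight matrix")
        weights = knn_weights(coords, k=k)
    W = np.asarray(weights, dtype=float)
    if W.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    if np.diag(W).any():
        raise ValueError("weight matrix must have zero diagonal")
    z = x - x.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("values are constant; Moran's I undefined")
    return float(n / W.sum() * (z @ W @ z) / denom)


def profile_pca(matrix: VariantMatrix, n_components: int = 2) -> pd.DataFrame:
    """Principal-component scores of the mutation profile.

    NA entries are imputed to 0 (unassessable treated as reference),
    columns centered, and each component's sign fixed so its
    largest-magnitude loading is positive.
    """
    X = np.nan_to_num(matrix.data, nan=0.0)
    if min(X.shape) < 2:
        raise ValueError("need at least 2 samples and 2 sites")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not Xc.any():
        raise ValueError("degenerate (rank-0) matrix")
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xc)
    for c in range(scores.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(
        scores, index=matrix.samples,
        columns=[f"PC{c + 1}" for c in range(scores.shape[1])],
    )


def consolidate_subclones(
    presence: pd.DataFrame,
    subclone_map: dict[str, str],
    mutation_class: str = "snv",
    bulk_presence: set | None = None,
) -> pd.DataFrame:
    """Consolidate per-sample mutation presence into subclone profiles.

    SNV / kataegis: present in a subclone iff detected in a strict majority
    of its samples (exactly half counts as absent). SV: present iff
    detected in >= 2 samples of the subclone or present in bulk.
    """
    if mutation_class not in ("snv", "kataegis", "sv"):
        raise ValueError(f"unknown mutation class {mutation_class!r}")
    missing = set(presence.index) - set(subclone_map)
    if missing:
        raise ValueError(f"samples without subclone label: {sorted(missing)}")
    bulk_presence = bulk_presence or set()
    rows = {}
    labels = sorted(set(subclone_map.values()))
    for sub in labels:
        members = [s for s in presence.index if subclone_map[s] == sub]
        if not members:
            raise ValueError(f"subclone {sub!r} has no samples")
        block = presence.loc[members].astype(bool)
        counts = block.sum(axis=0)
        if mutation_class == "sv":
            rows[sub] = (counts >= 2) | presence.columns.isin(list(bulk_presence))
        else:
            rows[sub] = counts > len(members) / 2
    return pd.DataFrame(rows).T.loc[labels]


def cluster_profiles(profiles: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Hierarchical clustering linkage of per-sample profiles (Euclidean)."""
    return linkage(profiles.to_numpy(dtype=float), method=method, metric="euclidean")
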