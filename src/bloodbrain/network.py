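"""Blood co-expression network construction and module detection.

The network stage mirrors the multiscale co-expression workflow used for
module discovery in bulk transcriptomes:

1. a permutation-calibrated correlation cutoff (each gene's values are
   shuffled across samples to estimate the false discovery rate of
   |Pearson r| cutoffs on a fixed grid);
2. a planar maximally filtered graph (PMFG): significant gene pairs are
   inserted in decreasing |r| order, each kept only if the graph stays
   planar, giving at most 3(n-2) edges;
3. recursive multiscale clustering that splits modules by maximizing
   Newman's weighted modularity Q, exhaustively for small modules and by
   greedy agglomeration otherwise;
4. a permutation hub test on within-module weighted connectivity; and
5. per-module principal components ("eigengenes" and deeper PCs) that
   summarize each module for downstream prediction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import networkx as nx
import numpy as np

from .containers import ExpressionMatrix
from .utils import substream

__all__ = [
    "CorrelationCalibration",
    "PlanarNetwork",
    "Module",
    "ModuleSet",
    "ModulePCSpec",
    "PCARecipe",
    "calibrate_cutoff",
    "build_pmfg",
    "multiscale_cluster",
    "hub_nodes",
    "module_pcs",
    "weighted_modularity",
    "exhaustive_best_partition",
]

DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.01, 1.00, 0.01), 2))


# ---------------------------------------------------------------------------
# correlation cutoff calibration
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCalibration:
    """FDR curve over a grid of |Pearson r| cutoffs and the chosen cutoff."""

    cutoffs: np.ndarray
    observed: np.ndarray        # significant-pair counts per cutoff
    permuted_mean: np.ndarray   # mean counts over permutations
    fdr: np.ndarray
    rho_star: float
    achieved: bool              # False when no cutoff met the FDR target


def _corr_abs_offdiag(values: np.ndarray) -> np.ndarray:
    """|Pearson r| for all gene pairs (upper triangle, 1-d)."""
    r = np.corrcoef(values)
    iu = np.triu_indices(r.shape[0], k=1)
    return np.abs(r[iu])


def _counts_at(cutoffs: np.ndarray, abs_r: np.ndarray) -> np.ndarray:
    """Number of pairs with |r| >= cutoff, per cutoff (non-increasing)."""
    s = np.sort(abs_r)
    return s.size - np.searchsorted(s, cutoffs, side="left")


def _drop_constant(expr: ExpressionMatrix) -> np.ndarray:
    values = expr.values
    sd = values.std(axis=1)
    const = sd == 0
    if const.any():
        names = [expr.gene_ids[i] for i in np.flatnonzero(const)]
        warnings.warn(f"excluded {const.sum()} constant gene(s) from pair "
                      f"counting: {names[:5]}...")
        values = values[~const]
    return values


def calibrate_cutoff(expr: ExpressionMatrix, n_perm: int = 10,
                     fdr: float = 0.05, seed: int = 0,
                     cutoffs: Sequence[float] = DEFAULT_CUTOFF_GRID,
                     ) -> CorrelationCalibration:
    """Choose the smallest correlation cutoff whose permutation FDR is at
    or below the target.

    Permutations shuffle every gene's values independently across samples,
    which destroys inter-gene correlation while preserving marginals.
    FDR(c) = mean permuted pair count at c / max(observed count at c, 1).
    If no cutoff reaches the target the largest grid cutoff is returned
    with a warning.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples to calibrate correlations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cutoffs = np.asarray(cutoffs, dtype=float)
    values = _drop_constant(expr)
    observed = _counts_at(cutoffs, _corr_abs_offdiag(values))

    rng = substream(seed, "calibrate")
    perm_counts = np.zeros((n_perm, cutoffs.size))
    for b in range(n_perm):
        perm = np.empty_like(values)
        for i in range(values.shape[0]):
            perm[i] = values[i, rng.permutation(values.shape[1])]
        perm_counts[b] = _counts_at(cutoffs, _corr_abs_offdiag(perm))
    permuted_mean = perm_counts.mean(axis=0)

    fdr_curve = permuted_mean / np.maximum(observed, 1)
    ok = np.flatnonzero(fdr_curve <= fdr)
    if ok.size:
        rho_star, achieved = float(cutoffs[ok[0]]), True
    else:
        rho_star, achieved = float(cutoffs[-1]), False
        warnings.warn(f"no cutoff achieved FDR <= {fdr}; using the largest "
                      f"grid cutoff {rho_star}")
    return CorrelationCalibration(cutoffs, observed, permuted_mean,
                                  fdr_curve, rho_star, achieved)


# ---------------------------------------------------------------------------
# planar maximally filtered graph
# ---------------------------------------------------------------------------

@dataclass
class PlanarNetwork:
    """Weighted undirected planar graph over genes.

    Edge weights are |Pearson r|; the correlation sign is kept alongside.
    """

    node_ids: list[str]
    edges: list[tuple[str, str, float, int]]  # (a, b, |r|, sign)
    planar: bool = True

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for a, b, w, s in self.edges:
            g.add_edge(a, b, weight=w, sign=s)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def candidate_pairs(expr: ExpressionMatrix, rho_star: float,
                    ) -> list[tuple[str, str, float, int]]:
    """Gene pairs with |r| >= rho_star, sorted by decreasing |r| with ties
    broken lexicographically by the (sorted) gene-pair id."""
    values = expr.values
    sd = values.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    genes = [expr.gene_ids[i] for i in keep]
    r = np.corrcoef(values[keep])
    iu, ju = np.triu_indices(len(keep), k=1)
    absr = np.abs(r[iu, ju])
    mask = absr >= rho_star
    pairs = []
    for i, j, w in zip(iu[mask], ju[mask], absr[mask]):
        a, b = sorted((genes[i], genes[j]))
        pairs.append((a, b, float(w), int(np.sign(r[i, j]) or 1)))
    pairs.sort(key=lambda e: (-e[2], e[0], e[1]))
    return pairs


def _planar_with_edge(g: nx.Graph, u: str, v: str,
                      component: dict[str, str]) -> bool:
    """Planarity of g + (u, v), tested on the affected component only.

    Planarity is a per-connected-component property, so only the union of
    the components containing u and v needs testing.
    """
    cu, cv = component[u], component[v]
    nodes = [n for n, c in component.items() if c in (cu, cv)]
    sub = g.subgraph(nodes).copy()
    sub.add_edge(u, v)
    ok, _ = nx.check_planarity(sub, counterexample=False)
    return ok


def pmfg_from_pairs(pairs: Sequence[tuple[str, str, float, int]],
                    nodes: Optional[Sequence[str]] = None) -> PlanarNetwork:
    """Greedy planar insertion over pre-sorted candidate edges."""
    if nodes is None:
        nodes = sorted({n for a, b, *_ in pairs for n in (a, b)})
    nodes = list(nodes)
    n = len(nodes)
    if n < 3:
        return PlanarNetwork(nodes, [(a, b, w, s) for a, b, w, s in pairs],
                             planar=True)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    component = {v: v for v in nodes}  # union-find by representative
    edge_cap = 3 * (n - 2)
    kept: list[tuple[str, str, float, int]] = []
    for a, b, w, s in pairs:
        if len(kept) >= edge_cap:
            break
        if component[a] == component[b]:
            if not _planar_with_edge(g, a, b, component):
                continue
            g.add_edge(a, b, weight=w, sign=s)
        else:
            # joining two planar components is always planar
            g.add_edge(a, b, weight=w, sign=s)
            old, new = component[b], component[a]
            for vtx, c in component.items():
                if c == old:
                    component[vtx] = new
        kept.append((a, b, w, s))
    return PlanarNetwork(nodes, kept, planar=True)


def build_pmfg(expr: ExpressionMatrix, rho_star: float) -> PlanarNetwork:
    """Planar maximally filtered graph of the |r| >= rho_star pairs."""
    pairs = candidate_pairs(expr, rho_star)
    return pmfg_from_pairs(pairs)


# ---------------------------------------------------------------------------
# multiscale modularity clustering
# ---------------------------------------------------------------------------

@dataclass
class Module:
    module_id: str
    parent_id: Optional[str]
    level: int
    gene_ids: list[str]
    q: float  # modularity of the split that produced this module (nan=root)
    hub_p: dict[str, float] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)


@dataclass
class ModuleSet:
    modules: list[Module]

    def __iter__(self) -> Iterator[Module]:
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def by_id(self, module_id: str) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def roots(self) -> list[Module]:
        return [m for m in self.modules if m.parent_id is None]

    @property
    def leaves(self) -> list[Module]:
        parents = {m.parent_id for m in self.modules if m.parent_id}
        return [m for m in self.modules if m.module_id not in parents]


def weighted_modularity(g: nx.Graph, labels: dict[str, int]) -> float:
    """Newman's weighted modularity Q = sum_c (w_in/W - (s_c / 2W)^2)."""
    w_total = g.size(weight="weight")
    if w_total == 0:
        return 0.0
    w_in: dict[int, float] = {}
    s: dict[int, float] = {}
    for u, v, w in g.edges(data="weight", default=1.0):
        if labels[u] == labels[v]:
            w_in[labels[u]] = w_in.get(labels[u], 0.0) + w
        s[labels[u]] = s.get(labels[u], 0.0) + w
        s[labels[v]] = s.get(labels[v], 0.0) + w
    return sum(w_in.get(c, 0.0) / w_total - (s.get(c, 0.0) / (2 * w_total)) ** 2
               for c in set(labels.values()))


def _rgs_partitions(n: int, k_max: int) -> Iterator[list[int]]:
    """Restricted growth strings: all set partitions of n items into at
    most k_max blocks (canonical labelling)."""
    a = [0] * n

    def rec(i: int, m: int) -> Iterator[list[int]]:
        if i == n:
            yield a
            return
        for j in range(min(m + 1, k_max - 1) + 1):
            a[i] = j
            yield from rec(i + 1, max(m, j))

    yield from rec(1, 0)


def exhaustive_best_partition(g: nx.Graph, k_max: int = 4,
                              ) -> tuple[dict[str, int], float]:
    """Best partition into 2..k_max parts by exhaustive Q maximization.

    Feasible for subgraphs of roughly a dozen nodes; ties resolve to the
    first partition in canonical enumeration order.
    """
    nodes = sorted(g.nodes())
    n = len(nodes)
    w_total = g.size(weight="weight")
    edges = [(nodes.index(u), nodes.index(v), w)
             for u, v, w in g.edges(data="weight", default=1.0)]
    strength = [0.0] * n
    for i, j, w in edges:
        strength[i] += w
        strength[j] += w
    best_q = -np.inf
    best: Optional[list[int]] = None
    two_w = 2 * w_total if w_total else 1.0
    for labels in _rgs_partitions(n, k_max):
        k = max(labels) + 1
        if k < 2:
            continue
        w_in = [0.0] * k
        s = [0.0] * k
        for i, j, w in edges:
            if labels[i] == labels[j]:
                w_in[labels[i]] += w
        for i in range(n):
            s[labels[i]] += strength[i]
        q = sum(w_in[c] / w_total - (s[c] / two_w) ** 2 for c in range(k)) \
            if w_total else 0.0
        if q > best_q + 1e-12:
            best_q = q
            best = list(labels)
    assert best is not None
    return {nodes[i]: best[i] for i in range(n)}, float(best_q)


def _greedy_best_partition(g: nx.Graph, k_max: int = 4,
                           ) -> tuple[dict[str, int], float]:
    """Greedy agglomerative Q maximization, then merge down to <= k_max
    communities, keeping the best-Q candidate seen on the merge path."""
    from networkx.algorithms.community import greedy_modularity_communities

    try:
        comms = [set(c) for c in
                 greedy_modularity_communities(g, weight="weight")]
    except (ZeroDivisionError, nx.NetworkXError, StopIteration, KeyError):
        comms = [set(c) for c in nx.connected_components(g)]
    if len(comms) < 2:
        # force a bipartition candidate by Fiedler-style spectral split
        comms = _spectral_bipartition(g)
        if len(comms) < 2:
            labels = {v: 0 for v in g.nodes()}
            return labels, -np.inf

    def q_of(parts: list[set[str]]) -> float:
        labels = {v: c for c, part in enumerate(parts) for v in part}
        return weighted_modularity(g, labels)

    best_parts, best_q = None, -np.inf
    parts = comms
    while True:
        if len(parts) <= k_max:
            q = q_of(parts)
            if q > best_q:
                best_parts, best_q = [set(p) for p in parts], q
        if len(parts) <= 2:
            break
        # merge the pair whose merge loses the least modularity
        best_merge, best_merge_q = None, -np.inf
        for i, j in itertools.combinations(range(len(parts)), 2):
            merged = [p for k, p in enumerate(parts) if k not in (i, j)]
            merged.append(parts[i] | parts[j])
            q = q_of(merged)
            if q > best_merge_q:
                best_merge, best_merge_q = merged, q
        parts = best_merge
    if best_parts is None:
        best_parts = parts
        best_q = q_of(parts)
    labels = {v: c for c, part in enumerate(best_parts) for v in part}
    return labels, float(best_q)


def _spectral_bipartition(g: nx.Graph) -> list[set[str]]:
    nodes = sorted(g.nodes())
    if len(nodes) < 2:
        return [set(nodes)]
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    d = a.sum(axis=1)
    lap = np.diag(d) - a
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1] if vecs.shape[1] > 1 else vecs[:, 0]
    left = {nodes[i] for i in range(len(nodes)) if fiedler[i] < 0}
    right = set(nodes) - left
    return [p for p in (left, right) if p]


def multiscale_cluster(net: PlanarNetwork, min_size: int = 10,
                       max_depth: int = 4, k_cap: int = 4,
                       exhaustive_max_n: int = 12) -> ModuleSet:
    """Recursive modularity-maximizing decomposition of the planar network.

    Connected components of at least ``min_size`` genes become root
    modules. Each module is split by the best 2..k_cap-way partition of
    its weighted subgraph (exhaustive when the module has at most
    ``exhaustive_max_n`` genes, greedy agglomerative otherwise); the split
    is accepted only if its modularity is strictly positive and every
    child has at least ``min_size`` genes. Accepted children recurse up
    to ``max_depth`` levels.
    """
    g = net.to_graph()
    modules: list[Module] = []
    counter = itertools.count(1)

    def split(module: Module, depth: int) -> None:
        if depth >= max_depth or len(module.gene_ids) < 2 * min_size:
            return
        sub = g.subgraph(module.gene_ids)
        if sub.number_of_edges() == 0:
            return
        if len(module.gene_ids) <= exhaustive_max_n:
            labels, q = exhaustive_best_partition(sub, k_cap)
        else:
            labels, q = _greedy_best_partition(sub, k_cap)
        if not np.isfinite(q) or q <= 1e-12:
            return
        groups: dict[int, list[str]] = {}
        for v, c in labels.items():
            groups.setdefault(c, []).append(v)
        children = sorted((sorted(gs) for gs in groups.values()),
                          key=lambda gs: gs[0])
        if len(children) < 2 or any(len(c) < min_size for c in children):
            return
        for gene_ids in children:
            child = Module(f"M{next(counter)}", module.module_id,
                           module.level + 1, gene_ids, q)
            modules.append(child)
            split(child, depth + 1)

    components = sorted((sorted(c) for c in nx.connected_components(g)),
                        key=lambda c: (-len(c), c[0]))
    for comp in components:
        if len(comp) < min_size:
            continue
        root = Module(f"M{next(counter)}", None, 1, comp, float("nan"))
        modules.append(root)
        split(root, 1)
    modules.sort(key=lambda m: int(m.module_id[1:]))
    return ModuleSet(modules)


# ---------------------------------------------------------------------------
# hub analysis
# ---------------------------------------------------------------------------

def hub_nodes(net: PlanarNetwork, modules: ModuleSet, n_perm: int = 100,
              p: float = 0.05, seed: int = 0) -> ModuleSet:
    """Flag module hubs by a permutation test on within-module weighted
    degree.

    The null pools within-module degrees from ``n_perm`` replicates in
    which edge weights are shuffled over the fixed planar topology and
    node labels are shuffled within the module. A gene is a hub when its
    observed within-module degree exceeds the pooled (1-p) quantile;
    an add-one empirical p-value is reported per gene. Modules with
    fewer than 3 genes have no hubs. Flags are written onto the input
    ModuleSet (returned for convenience).
    """
    g = net.to_graph()
    rng = substream(seed, "hubs")
    for module in modules:
        module.hub_p = {}
        module.hubs = []
        if len(module.gene_ids) < 3:
            continue
        sub = g.subgraph(module.gene_ids)
        weights = np.array([w for *_, w in sub.edges(data="weight",
                                                     default=1.0)])
        genes = sorted(module.gene_ids)
        degree = {v: 0.0 for v in genes}
        for u, v, w in sub.edges(data="weight", default=1.0):
            degree[u] += w
            degree[v] += w
        if weights.size == 0:
            continue
        edge_index = [(u, v) for u, v, _ in sub.edges(data="weight")]
        null_degrees = np.zeros((n_perm, len(genes)))
        pos = {v: i for i, v in enumerate(genes)}
        for b in range(n_perm):
            shuffled = weights[rng.permutation(weights.size)]
            d = np.zeros(len(genes))
            for (u, v), w in zip(edge_index, shuffled):
                d[pos[u]] += w
                d[pos[v]] += w
            null_degrees[b] = d[rng.permutation(len(genes))]
        pooled = null_degrees.ravel()
        threshold = np.quantile(pooled, 1 - p)
        for v in genes:
            d_obs = degree[v]
            emp_p = (1 + np.count_nonzero(pooled >= d_obs)) / (1 + pooled.size)
            module.hub_p[v] = float(emp_p)
            if d_obs > threshold:
                module.hubs.append(v)
    return modules


# ---------------------------------------------------------------------------
# module principal components
# ---------------------------------------------------------------------------

@dataclass
class ModulePCSpec:
    """How many PCs to keep per module: a fixed count or a cumulative
    explained-variance target (percent)."""

    mode: str  # "count" | "variance"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("count", "variance"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def label(self) -> str:
        if self.mode == "count":
            return f"{int(self.value)}PC"
        return f"{int(self.value)}%var"


@dataclass
class PCARecipe:
    """Frozen projection mapping expression rows to PC scores.

    Stores only training-fold statistics (per-gene centering/scale and
    loadings), so applying it to held-out samples cannot leak their
    values into the feature space.
    """

    gene_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # genes x components
    feature_names: list[str]
    explained_ratio: np.ndarray

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        sub = expr.subset_genes(self.gene_ids)
        x = (sub.values.T - self.center) / self.scale
        return x @ self.loadings


def fit_pca(values: np.ndarray, gene_ids: list[str], unit_scale: bool = True,
            name_prefix: str = "PC") -> PCARecipe:
    """PCA over genes-as-variables (samples are observations).

    Component signs are fixed by forcing the largest-|loading| entry of
    each component positive, for run-to-run determinism.
    """
    x = values.T.astype(float)  # samples x genes
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1) if unit_scale else np.ones(x.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    xs = (x - center) / scale
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    # rank cut: keep components with non-negligible singular value
    tol = max(xs.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    u, s, vt = u[:, :r], s[:r], vt[:r]
    for c in range(r):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    total = float(np.sum(s ** 2))
    ratio = (s ** 2) / total if total > 0 else np.zeros(r)
    loadings = vt.T  # genes x r
    names = [f"{name_prefix}{c + 1}" for c in range(r)]
    return PCARecipe(list(gene_ids), center, scale, loadings, names, ratio)


def n_components_for(recipe: PCARecipe, spec: ModulePCSpec) -> int:
    if spec.mode == "count":
        return min(int(spec.value), recipe.loadings.shape[1])
    target = spec.value / 100.0
    cum = np.cumsum(recipe.explained_ratio)
    if cum.size == 0:
        return 0
    idx = np.searchsorted(cum, target - 1e-12) + 1
    return int(min(idx, cum.size))


def module_pcs(expr: ExpressionMatrix, modules: ModuleSet,
               spec: ModulePCSpec) -> tuple[np.ndarray, list[str],
                                            list[tuple[PCARecipe, int]]]:
    """Per-module PC scores on the given (training) samples.

    Returns the feature matrix (samples x features), namespaced feature
    names (``<module_id>:PC<j>``), and the per-module projection recipes
    with their kept component counts for held-out projection. Modules
    with fewer than two genes contribute no features.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    recipes: list[tuple[PCARecipe, int]] = []
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    for module in modules:
        genes = [g for g in module.gene_ids if g in gene_index]
        if len(genes) < 2:
            continue
        rows = [gene_index[g] for g in genes]
        recipe = fit_pca(expr.values[rows], genes,
                         name_prefix=f"{module.module_id}:PC")
        k = n_components_for(recipe, spec)
        if k == 0:
            continue
        kept = PCARecipe(recipe.gene_ids, recipe.center, recipe.scale,
                         recipe.loadings[:, :k], recipe.feature_names[:k],
                         recipe.explained_ratio[:k])
        scores = kept.transform(expr.subset_genes(genes))
        blocks.append(scores)
        names.extend(kept.feature_names)
        recipes.append((kept, k))
    if not blocks:
        n = expr.n_samples
        return np.empty((n, 0)), [], []
    return np.hstack(blocks), names, recipes
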