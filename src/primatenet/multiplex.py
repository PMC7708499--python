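"""Multiplex network construction and multilayer network measures.

A multiplex network here is an ordered node set shared by four directed,
weighted, zero-diagonal adjacency layers (one per interaction type).  The
module provides:

* densities, strengths, eigenvector centrality (per layer / aggregate) and
  eigenvector versatility via the supra-adjacency matrix;
* interlayer edge overlap (Jaccard on directed edge supports);
* Von Neumann graph entropy and the quantum Jensen-Shannon distance between
  layers, both computed from the rescaled combinatorial Laplacian spectrum of
  the symmetrised layer;
* structural reducibility: Ward clustering of layers on the JSD matrix,
  greedily aggregating the most similar layers while tracking the relative
  entropy of the partly aggregated multiplex against the fully aggregated
  network.

All spectral computations symmetrise a directed layer as (A + Aᵀ)/2; the
Laplacian-spectrum entropy needs a symmetric operator.  Directionality is
preserved everywhere else (densities, strengths, the dyadic models).
Logarithms are base 2, so entropies are in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import spearmanr

from primatenet.indices import LAYERS

__all__ = [
    "MultiplexNetwork",
    "ReducibilityResult",
    "CentralityReport",
    "build_multiplex",
    "layer_density",
    "multiplex_density",
    "strength",
    "eigenvector_centrality",
    "aggregate_layers",
    "eigenvector_versatility",
    "edge_overlap",
    "global_edge_overlap",
    "von_neumann_entropy",
    "quantum_jsd",
    "reducibility",
    "rank_report",
]

_EIG_TOL = 1e-10


@dataclass
class MultiplexNetwork:
    """Named directed weighted layers over a common ordered node set."""

    nodes: list[str]
    layer_names: list[str]
    layers: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(self.layers) != len(self.layer_names):
            raise ValueError("layer_names and layers length mismatch")
        for name, m in zip(self.layer_names, self.layers):
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"layer {name}: shape {m.shape} != ({n},{n})")
            if (m < 0).any():
                raise ValueError(f"layer {name}: negative weights")
            if np.abs(np.diag(m)).max(initial=0.0) > 0:
                raise ValueError(f"layer {name}: nonzero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, name: str) -> np.ndarray:
        return self.layers[self.layer_names.index(name)]


def build_multiplex(
    table: pd.DataFrame, group: str, weight: str = "index"
) -> MultiplexNetwork:
    """Build the 4-layer multiplex of one group from a long-format index table.

    ``weight`` selects the ``index`` (raw proportion) or ``weighted``
    (cross-group max-normalised) column.  Layers appear in the fixed order
    stationary_vicinity, affiliative, grooming, passive_close_proximity.
    """
    if weight not in ("index", "weighted"):
        raise ValueError("weight must be 'index' or 'weighted'")
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    if weight == "weighted" and sub["weighted"].isna().any():
        raise ValueError("weighted column not filled; run normalize_weighted first")
    nodes = sorted(set(sub["sender"]) | set(sub["receiver"]))
    idx = {n: i for i, n in enumerate(nodes)}
    layers = []
    for layer in LAYERS:
        rows = sub[sub["layer"] == layer]
        expected = len(nodes) * (len(nodes) - 1)
        if len(rows) != expected:
            raise ValueError(
                f"group {group} layer {layer}: {len(rows)} dyad rows, expected {expected}"
            )
        m = np.zeros((len(nodes), len(nodes)))
        for r in rows.itertuples():
            m[idx[r.sender], idx[r.receiver]] = getattr(r, weight)
        layers.append(m)
    return MultiplexNetwork(nodes=nodes, layer_names=list(LAYERS), layers=layers)


# ---------------------------------------------------------------------------
# densities / strength / centrality


def layer_density(layer: np.ndarray) -> float:
    """Fraction of possible directed edges (off-diagonal entries > 0)."""
    layer = np.asarray(layer, dtype=float)
    n = layer.shape[0]
    present = int((layer > 0).sum())
    return present / (n * (n - 1)) if n > 1 else 0.0


def multiplex_density(net: MultiplexNetwork) -> float:
    """Present edges over all layers / (N (N-1) L)."""
    n, L = net.n_nodes, net.n_layers
    present = sum(int((m > 0).sum()) for m in net.layers)
    return present / (n * (n - 1) * L)


def strength(layer: np.ndarray, node: int | None = None):
    """Sum of in- plus out-weights per node (or for one node index)."""
    layer = np.asarray(layer, dtype=float)
    s = layer.sum(axis=0) + layer.sum(axis=1)
    return s if node is None else float(s[node])


def _symmetrize(layer: np.ndarray) -> np.ndarray:
    layer = np.asarray(layer, dtype=float)
    return 0.5 * (layer + layer.T)


def eigenvector_centrality(layer: np.ndarray) -> np.ndarray:
    """Leading-eigenvector scores of the symmetrised layer, max-normalised to 1.

    An all-zero layer yields all zeros with a warning.  By Perron-Frobenius
    the leading eigenvector of a non-negative symmetric matrix can be taken
    non-negative; tiny negative round-off is clipped.
    """
    sym = _symmetrize(layer)
    if not sym.any():
        warnings.warn("eigenvector centrality of an empty layer: returning zeros",
                      stacklevel=2)
        return np.zeros(sym.shape[0])
    vals, vecs = np.linalg.eigh(sym)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / v.max()


def aggregate_layers(net: MultiplexNetwork, subset: list[str] | None = None) -> np.ndarray:
    """Element-wise sum of the selected layers (default: all)."""
    names = net.layer_names if subset is None else list(subset)
    if not names:
        raise ValueError("aggregate_layers needs a nonempty layer subset")
    return sum(net.layer(name) for name in names)


def eigenvector_versatility(net: MultiplexNetwork, omega: float = 1.0) -> np.ndarray:
    """Multiplex eigenvector scores via the supra-adjacency matrix.

    The NL x NL supra-adjacency carries the symmetrised layers on its
    diagonal blocks and categorical interlayer coupling ``omega`` on the
    diagonal of every off-diagonal (replica) block.  The leading
    eigenvector's L replica entries are summed per node and the result is
    max-normalised to 1.
    """
    if omega <= 0:
        raise ValueError("interlayer coupling omega must be positive")
    if net.n_layers < 2:
        raise ValueError("versatility needs at least two layers")
    n, L = net.n_nodes, net.n_layers
    supra = np.kron(np.ones((L, L)) - np.eye(L), omega * np.eye(n))
    for k, layer in enumerate(net.layers):
        supra[k * n : (k + 1) * n, k * n : (k + 1) * n] = _symmetrize(layer)
    vals, vecs = np.linalg.eigh(supra)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    scores = v.reshape(L, n).sum(axis=0)
    return scores / scores.max()


# ---------------------------------------------------------------------------
# interlayer similarity


def _support(layer: np.ndarray) -> np.ndarray:
    layer = np.asarray(layer, dtype=float)
    return layer > 0


def edge_overlap(layer_a: np.ndarray, layer_b: np.ndarray, norm: str = "jaccard") -> float:
    """Fraction of directed edges shared between two layers' supports.

    ``norm`` chooses the denominator: ``jaccard`` (default) divides the
    shared-edge count by the union support, ``min`` by the smaller of the two
    supports.  The published overlap values cannot be recomputed without the
    raw matrices, so the convention is explicit and configurable.
    """
    sa, sb = _support(layer_a), _support(layer_b)
    shared = int((sa & sb).sum())
    if norm == "jaccard":
        denom = int((sa | sb).sum())
    elif norm == "min":
        denom = min(int(sa.sum()), int(sb.sum()))
    else:
        raise ValueError("norm must be 'jaccard' or 'min'")
    if denom == 0:
        warnings.warn("edge overlap of empty layers defined as 0", stacklevel=2)
        return 0.0
    return shared / denom


def global_edge_overlap(net: MultiplexNetwork) -> float:
    """Fraction of the union support present in every layer."""
    supports = [_support(m) for m in net.layers]
    union = supports[0].copy()
    inter = supports[0].copy()
    for s in supports[1:]:
        union |= s
        inter &= s
    total = int(union.sum())
    if total == 0:
        warnings.warn("global edge overlap of an empty multiplex defined as 0",
                      stacklevel=2)
        return 0.0
    return int(inter.sum()) / total


def _density_operator(layer: np.ndarray) -> np.ndarray:
    """Laplacian of the symmetrised layer rescaled to unit trace."""
    sym = _symmetrize(layer)
    total = sym.sum()
    if total <= 0:
        raise ValueError("layer has zero total weight; entropy undefined")
    lap = np.diag(sym.sum(axis=1)) - sym
    return lap / np.trace(lap)


def _spectral_entropy(rho: np.ndarray) -> float:
    vals = np.linalg.eigvalsh(rho)
    if vals.min() < -_EIG_TOL:
        raise ValueError(f"density operator has eigenvalue {vals.min():.3e} < 0")
    vals = np.clip(vals, 0.0, None)
    nz = vals[vals > 0]
    return float(-(nz * np.log2(nz)).sum())


def von_neumann_entropy(layer: np.ndarray) -> float:
    """Von Neumann graph entropy in bits.

    Shannon entropy of the symmetrised layer's Laplacian eigenvalues rescaled
    to sum to one.  Scale-invariant: multiplying all weights by c > 0 leaves
    the value unchanged.  The complete graph K_n has entropy log2(n-1).
    """
    return _spectral_entropy(_density_operator(layer))


def quantum_jsd(layer_a: np.ndarray, layer_b: np.ndarray) -> float:
    """Quantum Jensen-Shannon distance between two layers, in [0, 1].

    sqrt of the Jensen-Shannon divergence between the two layers' density
    operators: h((rho_a + rho_b)/2) - (h(rho_a) + h(rho_b))/2.  Zero iff the
    rescaled Laplacians coincide; symmetric; round-off below zero is clipped.
    """
    rho_a = _density_operator(layer_a)
    rho_b = _density_operator(layer_b)
    h_m = _spectral_entropy(0.5 * (rho_a + rho_b))
    jsd = h_m - 0.5 * (_spectral_entropy(rho_a) + _spectral_entropy(rho_b))
    return float(np.sqrt(max(jsd, 0.0)))


# ---------------------------------------------------------------------------
# structural reducibility


@dataclass
class ReducibilityResult:
    """Outcome of the greedy layer-aggregation (reducibility) analysis."""

    layer_names: list[str]
    jsd_matrix: np.ndarray
    #: (step, merged layer-name sets, Ward linkage distance), L-1 entries
    merge_sequence: list[tuple[int, tuple[frozenset[str], frozenset[str]], float]]
    #: relative entropy for L, L-1, ..., 1 layers (in that order)
    relative_entropy_curve: list[float]
    #: number of layers at which the curve is maximal
    optimal_n_layers: int


def _relative_entropy(layers: list[np.ndarray], aggregate: np.ndarray) -> float:
    h_layers = [von_neumann_entropy(m) for m in layers]
    h_agg = von_neumann_entropy(aggregate)
    if h_agg <= 0:
        raise ValueError("aggregated network has zero entropy")
    return 1.0 - float(np.mean(h_layers)) / h_agg


def reducibility(net: MultiplexNetwork) -> ReducibilityResult:
    """Greedy structural reducibility of the multiplex.

    Pairwise quantum JSD between layers feeds Ward agglomerative clustering;
    following the resulting merge order, the two most similar layers are
    aggregated (summed) at each step and the relative entropy
    q = 1 - mean(h(layer)) / h(aggregate) is recorded, from L layers down to
    the fully aggregated network (q = 0 by construction).  The multiplex is
    irreducible when q is maximal at L layers.
    """
    L = net.n_layers
    if L < 2:
        raise ValueError("reducibility needs at least two layers")
    jsd = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            jsd[i, j] = jsd[j, i] = quantum_jsd(net.layers[i], net.layers[j])
    condensed = jsd[np.triu_indices(L, k=1)]
    links = linkage(condensed, method="ward")

    aggregate = sum(net.layers)
    current: dict[int, tuple[frozenset[str], np.ndarray]] = {
        i: (frozenset([name]), net.layers[i].copy())
        for i, name in enumerate(net.layer_names)
    }
    curve = [_relative_entropy([m for _, m in current.values()], aggregate)]
    merges: list[tuple[int, tuple[frozenset[str], frozenset[str]], float]] = []
    for step, (ia, ib, dist, _count) in enumerate(links, start=1):
        ia, ib = int(ia), int(ib)
        names_a, mat_a = current.pop(ia)
        names_b, mat_b = current.pop(ib)
        current[L - 1 + step] = (names_a | names_b, mat_a + mat_b)
        merges.append((step, (names_a, names_b), float(dist)))
        curve.append(_relative_entropy([m for _, m in current.values()], aggregate))
    n_layers_axis = list(range(L, 0, -1))
    optimal = n_layers_axis[int(np.argmax(curve))]
    return ReducibilityResult(
        layer_names=list(net.layer_names),
        jsd_matrix=jsd,
        merge_sequence=merges,
        relative_entropy_curve=curve,
        optimal_n_layers=optimal,
    )


# ---------------------------------------------------------------------------
# centrality report


@dataclass
class CentralityReport:
    """Eigenvector scores and dense ranks per ring (layers, aggregate, multiplex)."""

    nodes: list[str]
    strengths: pd.DataFrame  # node x layer
    scores: pd.DataFrame  # node x ring, max-normalised
    ranks: pd.DataFrame  # node x ring, dense ranks (1 = top, ties share)
    ring_order: list[str]  # rings ordered by rank-correlation similarity


def _dense_ranks(scores: pd.Series) -> pd.Series:
    return scores.rank(method="dense", ascending=False).astype(int)


def rank_report(net: MultiplexNetwork, omega: float = 1.0) -> CentralityReport:
    """Per-ring eigenvector scores and ranks.

    Rings are the four layers, the fully aggregated network and the multiplex
    (versatility).  Ring order starts from the multiplex ring and greedily
    appends the ring with the highest Spearman rank correlation to the
    previous one, mirroring a similarity-ordered annular display.
    """
    rings: dict[str, np.ndarray] = {}
    for name in net.layer_names:
        rings[name] = eigenvector_centrality(net.layer(name))
    rings["aggregate"] = eigenvector_centrality(aggregate_layers(net))
    rings["multiplex"] = eigenvector_versatility(net, omega=omega)

    scores = pd.DataFrame(rings, index=net.nodes)
    ranks = scores.apply(_dense_ranks)
    strengths = pd.DataFrame(
        {name: strength(net.layer(name)) for name in net.layer_names}, index=net.nodes
    )

    order = ["multiplex"]
    remaining = [r for r in scores.columns if r != "multiplex"]
    while remaining:
        last = order[-1]
        best = max(
            remaining,
            key=lambda r: _safe_spearman(scores[last].values, scores[r].values),
        )
        order.append(best)
        remaining.remove(best)
    return CentralityReport(
        nodes=list(net.nodes), strengths=strengths, scores=scores, ranks=ranks,
        ring_order=order,
    )


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return -2.0  # constant ring: least similar
    rho = spearmanr(a, b).statistic
    return -2.0 if np.isnan(rho) else float(rho)
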