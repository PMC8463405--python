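"""Signed consensus network inference with permutation and graph nulls.

The method infers co-occurrence (positive) and co-exclusion (negative) edges
from rank correlations, calibrated by two classes of null models:

1. *Matrix nulls.*  In each of ``n_monte_carlo`` iterations, uniform noise on
   ``[0, noise_scale)`` is added to every OTU entry (environmental rows are
   left untouched), and the noise-added matrix is permuted within rows
   ``n_perm`` times.  The pooled permutation distribution of pairwise Spearman
   coefficients sets a lower bound for the correlation threshold — by default
   the upper/lower 0.1% tails, taken separately per sign.

2. *Graph nulls.*  Starting at the permutation bound, the candidate threshold
   is raised in steps of ``candidate_step`` until the thresholded graph's
   global transitivity exceeds the ``graph_null_quantile`` of transitivity in
   three null ensembles: the permuted-matrix graphs thresholded at the same
   candidate (the exchangeable null — tails of a sample correlation matrix
   are triangle-enriched even without any real association, because two
   chance pairs sharing a row make the closing pair more likely), plus
   Erdős–Rényi realizations matched on the average degree and Chung–Lu
   realizations matched on the degree sequence.  This accepts the smallest
   threshold at which the graph carries more clustering than chance
   correlation geometry, density or degrees explain.  Co-exclusion edges
   alone carry almost no triangles, so acceptance is evaluated on the
   combined signed graph while the positive/negative bounds advance on a
   common grid.

An iteration in which no candidate is accepted contributes an empty edge
set.  The consensus network keeps every signed pair present in at least
``consensus_fraction`` (default 90%) of the Monte-Carlo iterations; the
reported thresholds are the means of the accepted per-iteration thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .io import EdgeRecord, TaxonomyTable, TraitTable, ValidationError, round_sig
from .preprocess import AnalysisMatrix

__all__ = [
    "NullModelConfig",
    "Thresholds",
    "NodeRecord",
    "SignedNetwork",
    "MonteCarloResult",
    "spearman_matrix",
    "monte_carlo_networks",
    "er_graph",
    "chung_lu_graph",
    "consensus",
    "infer_network",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullModelConfig:
    """Tunables of the inference; defaults are the pipeline's defaults."""

    n_monte_carlo: int = 100
    consensus_fraction: float = 0.90
    noise_scale: float = 1.0
    perm_quantile: float = 0.999
    n_perm: int = 30
    candidate_step: float = 0.01
    n_graph_null: int = 100
    graph_null_quantile: float = 0.95
    mode: str = "separate"  # 'separate' per-sign permutation tails | 'symmetric'
    drop_env_env: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.consensus_fraction <= 1:
            raise ValidationError("consensus_fraction must be in (0, 1]")
        if not 0.5 < self.perm_quantile < 1:
            raise ValidationError("perm_quantile must be in (0.5, 1)")
        if self.n_monte_carlo < 1 or self.n_perm < 1 or self.n_graph_null < 1:
            raise ValidationError("iteration counts must be >= 1")
        if self.noise_scale < 0 or self.candidate_step <= 0:
            raise ValidationError("noise_scale must be >= 0 and candidate_step > 0")
        if not 0 < self.graph_null_quantile < 1:
            raise ValidationError("graph_null_quantile must be in (0, 1)")
        if self.mode not in ("separate", "symmetric"):
            raise ValidationError("mode must be 'separate' or 'symmetric'")


@dataclass(frozen=True)
class Thresholds:
    """Accepted Spearman thresholds: t_pos in (0,1), t_neg in (-1,0)."""

    t_pos: float
    t_neg: float


@dataclass
class NodeRecord:
    id: str
    kind: str  # 'otu' | 'env'
    group: str = "Unknown"
    phylum: str = ""
    trait: str = ""
    abundance: float = 0.0
    degree: int = 0


@dataclass
class SignedNetwork:
    """Finalized consensus network: no self edges, no isolated nodes."""

    nodes: list[NodeRecord]
    edges: list[EdgeRecord]
    thresholds: Thresholds
    config: NullModelConfig | None = None

    def to_networkx(self, scope: str = "all") -> nx.Graph:
        """Unsigned graph of one scope: 'all', 'co_occurrence' or 'co_exclusion'.

        Subgraph scopes keep only the endpoints of their edges (a network
        contains no isolated nodes by construction).
        """
        if scope not in ("all", "co_occurrence", "co_exclusion"):
            raise ValidationError(f"unknown scope {scope!r}")
        want = {"all": ("pos", "neg"), "co_occurrence": ("pos",),
                "co_exclusion": ("neg",)}[scope]
        edges = [e for e in self.edges if e.sign in want]
        used = {e.node_a for e in edges} | {e.node_b for e in edges}
        g = nx.Graph()
        for n in self.nodes:
            if n.id in used:
                g.add_node(n.id, kind=n.kind, group=n.group, phylum=n.phylum,
                           trait=n.trait, abundance=n.abundance)
        for e in edges:
            g.add_edge(e.node_a, e.node_b, sign=e.sign, weight=e.weight,
                       support=e.support)
        return g


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def _corr_of_rows(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; zero-variance rows give NaN, diag 1."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc * xc).sum(axis=1))
    bad = norm == 0
    norm_safe = np.where(bad, 1.0, norm)
    xn = xc / norm_safe[:, None]
    r = np.clip(xn @ xn.T, -1.0, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def spearman_matrix(m: AnalysisMatrix | np.ndarray) -> np.ndarray:
    """All pairwise Spearman rank correlations between rows.

    Ties get mid-ranks; constant rows yield NaN against every other row (and
    can therefore never form edges); the diagonal is 1.
    """
    values = m.values if isinstance(m, AnalysisMatrix) else np.asarray(m, float)
    if values.shape[1] < 3:
        raise ValidationError("Spearman correlation needs at least 3 samples")
    ranks = rankdata(values, axis=1)
    return _corr_of_rows(ranks)


# ---------------------------------------------------------------------------
# random-graph nulls
# ---------------------------------------------------------------------------


def _bernoulli_edges(n: int, p, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli edges over the upper-triangle pair list.

    ``p`` is a scalar or a per-pair vector aligned with ``np.triu_indices``.
    Returns an (m, 2) array of node index pairs.
    """
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(iu.size) < p
    return np.column_stack((iu[hit], ju[hit]))


def _chung_lu_probs(degree_seq: np.ndarray) -> tuple[int, np.ndarray]:
    d = np.asarray(degree_seq, dtype=float)
    if np.any(d < 0):
        raise ValidationError("degrees must be non-negative")
    n = d.size
    total = d.sum()
    iu, ju = np.triu_indices(n, k=1)
    if total == 0:
        return n, np.zeros(iu.size)
    return n, np.minimum(1.0, d[iu] * d[ju] / total)


def er_graph(n: int, avg_degree: float, rng: np.random.Generator) -> nx.Graph:
    """G(n, p) with p = avg_degree / (n - 1)."""
    if n < 2:
        raise ValidationError("er_graph needs n >= 2")
    if not 0 <= avg_degree <= n - 1:
        raise ValidationError("avg_degree must be in [0, n-1]")
    g = nx.empty_graph(n)
    g.add_edges_from(map(tuple, _bernoulli_edges(n, avg_degree / (n - 1), rng)))
    return g


def chung_lu_graph(degree_seq: Iterable[int], rng: np.random.Generator) -> nx.Graph:
    """Edge (i, j) present independently with probability min(1, d_i d_j / Σd)."""
    d = np.asarray(list(degree_seq), dtype=float)
    n, probs = _chung_lu_probs(d)
    g = nx.empty_graph(n)
    if n >= 2:
        g.add_edges_from(map(tuple, _bernoulli_edges(n, probs, rng)))
    return g


def _transitivity_of_edges(n: int, edges: np.ndarray) -> float:
    """Global clustering 3*triangles / paths-of-length-2 from an edge array."""
    if len(edges) == 0:
        return 0.0
    deg = np.zeros(n, dtype=np.int64)
    adj: list[set[int]] = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
        deg[u] += 1
        deg[v] += 1
    paths2 = int((deg * (deg - 1) // 2).sum())
    if paths2 == 0:
        return 0.0
    tri3 = sum(len(adj[u] & adj[v]) for u, v in edges)  # each triangle counted 3x
    return tri3 / paths2


# ---------------------------------------------------------------------------
# Monte-Carlo inference
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloResult:
    edge_sets: list[dict[tuple[str, str, str], float]]
    thresholds: Thresholds
    accepted_t_pos: list[float]
    accepted_t_neg: list[float]


def _permutation_null(ranks: np.ndarray, allowed: np.ndarray,
                      cfg: NullModelConfig, rng: np.random.Generator):
    """Within-row permutation null: threshold lower bounds and tail graphs.

    Returns ``(l_pos, l_neg, perm_tails)`` where the bounds are the
    ``perm_quantile`` tails of the pooled permuted pairwise Spearman
    distribution (per sign in 'separate' mode, on |rho| in 'symmetric'
    mode), and ``perm_tails`` holds, for every permutation replicate, the
    pair values at or beyond the bounds — the material for permutation-graph
    transitivity at any candidate threshold.
    """
    n = ranks.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = allowed[iu, ju]
    per_perm = []
    for _ in range(cfg.n_perm):
        perm = rng.permuted(ranks, axis=1)
        r = _corr_of_rows(perm)
        v = r[iu[keep], ju[keep]]
        per_perm.append(np.where(np.isfinite(v), v, 0.0))
    pool = np.concatenate(per_perm)
    if pool.size == 0:
        return 1.0, 1.0, []
    if cfg.mode == "separate":
        l_pos = float(np.quantile(pool, cfg.perm_quantile))
        l_neg = float(-np.quantile(pool, 1.0 - cfg.perm_quantile))
    else:
        l_pos = l_neg = float(np.quantile(np.abs(pool), cfg.perm_quantile))
    step = cfg.candidate_step
    l_pos, l_neg = max(l_pos, step), max(l_neg, step)
    ik, jk = iu[keep], ju[keep]
    tails = []
    for v in per_perm:
        hit = (v >= l_pos) | (v <= -l_neg)
        tails.append((ik[hit], jk[hit], v[hit]))
    return l_pos, l_neg, tails


def _null_transitivity_quantile(n: int, edges: np.ndarray, degrees: np.ndarray,
                                cfg: NullModelConfig,
                                rng: np.random.Generator) -> float:
    """Max of the ER and Chung–Lu ensembles' transitivity quantiles."""
    avg_degree = 2.0 * len(edges) / n if n > 1 else 0.0
    p_er = avg_degree / (n - 1) if n > 1 else 0.0
    _, p_cl = _chung_lu_probs(degrees)
    out = []
    for p in (p_er, p_cl):
        trans = [
            _transitivity_of_edges(n, _bernoulli_edges(n, p, rng))
            for _ in range(cfg.n_graph_null)
        ]
        out.append(float(np.quantile(trans, cfg.graph_null_quantile)))
    return max(out)


def _perm_transitivity_quantile(perm_tails, tp: float, tn: float,
                                n_total: int, quantile: float) -> float:
    """Transitivity quantile of the permuted-matrix graphs at (tp, tn).

    Sample correlation tails are intrinsically triangle-enriched (two pairs
    sharing a row make the closing pair more likely), so the permutation
    graphs — which carry the same geometry without any real association —
    are the exchangeable null for the clustering test.
    """
    trans = []
    for pi, pj, pv in perm_tails:
        hit = (pv >= tp) | (pv <= -tn)
        if not hit.any():
            trans.append(0.0)
            continue
        nodes = np.union1d(pi[hit], pj[hit])
        relabel = np.full(n_total, -1, dtype=np.int64)
        relabel[nodes] = np.arange(nodes.size)
        edges = np.column_stack((relabel[pi[hit]], relabel[pj[hit]]))
        trans.append(_transitivity_of_edges(nodes.size, edges))
    return float(np.quantile(trans, quantile)) if trans else 0.0


def _sweep(r: np.ndarray, l_pos: float, l_neg: float, allowed: np.ndarray,
           perm_tails, cfg: NullModelConfig, rng: np.random.Generator):
    """Raise the signed thresholds on a common grid until the combined graph
    beats the permutation-graph, Erdős–Rényi and Chung–Lu transitivity
    ensembles; return (t_pos, t_neg, edge index arrays) or None if no
    candidate is accepted."""
    rz = np.where(np.isfinite(r), r, 0.0)
    rz = np.where(allowed, rz, 0.0)
    n_total = r.shape[0]
    iu, ju = np.triu_indices(n_total, k=1)
    vals = rz[iu, ju]
    max_pos = vals.max(initial=0.0)
    max_neg = (-vals).max(initial=0.0)
    step = cfg.candidate_step
    k = 0
    while l_pos + k * step <= max_pos or l_neg + k * step <= max_neg:
        tp = l_pos + k * step
        tn = l_neg + k * step
        hit = (vals >= tp) | (vals <= -tn)
        k += 1
        m_edges = int(hit.sum())
        if m_edges == 0:
            break
        nodes = np.union1d(iu[hit], ju[hit])
        relabel = np.full(n_total, -1, dtype=np.int64)
        relabel[nodes] = np.arange(nodes.size)
        edges = np.column_stack((relabel[iu[hit]], relabel[ju[hit]]))
        obs = _transitivity_of_edges(nodes.size, edges)
        if obs <= 0.0:
            continue  # cannot strictly exceed a non-negative null quantile
        if obs <= _perm_transitivity_quantile(perm_tails, tp, tn, n_total,
                                              cfg.graph_null_quantile):
            continue
        degrees = np.bincount(edges.ravel(), minlength=nodes.size)
        if obs > _null_transitivity_quantile(nodes.size, edges, degrees, cfg, rng):
            return tp, tn, iu[hit], ju[hit], vals[hit]
    return None


def monte_carlo_networks(m: AnalysisMatrix, cfg: NullModelConfig) -> MonteCarloResult:
    """Run the noise-injection / permutation / graph-null loop.

    Each iteration draws from its own RNG stream keyed by (seed, iteration),
    and samples are put in a canonical (sorted id) order before any random
    draw, so the result does not depend on the input's column order.
    """
    cfg.validate()
    order = np.argsort(np.asarray(m.sample_ids, dtype=object))
    x0 = m.values[:, order]
    otu = m.row_kind == "otu"
    n_rows = m.n_rows

    allowed = np.ones((n_rows, n_rows), dtype=bool)
    np.fill_diagonal(allowed, False)
    if cfg.drop_env_env:
        env = ~otu
        allowed[np.ix_(env, env)] = False

    ids = np.asarray(m.row_ids, dtype=object)
    edge_sets: list[dict[tuple[str, str, str], float]] = []
    acc_pos: list[float] = []
    acc_neg: list[float] = []

    for it in range(cfg.n_monte_carlo):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), it]))
        x = x0.copy()
        if cfg.noise_scale > 0:
            x[otu] += cfg.noise_scale * rng.random((int(otu.sum()), x.shape[1]))
        ranks = rankdata(x, axis=1)
        r = _corr_of_rows(ranks)
        l_pos, l_neg, perm_tails = _permutation_null(ranks, allowed, cfg, rng)
        accepted = _sweep(r, l_pos, l_neg, allowed, perm_tails, cfg, rng)
        if accepted is None:
            log.debug("iteration %d: no threshold accepted; empty edge set", it)
            edge_sets.append({})
            continue
        tp, tn, ei, ej, rho = accepted
        acc_pos.append(tp)
        acc_neg.append(tn)
        es: dict[tuple[str, str, str], float] = {}
        for a, b, v in zip(ids[ei], ids[ej], rho):
            lo, hi = (a, b) if a < b else (b, a)
            es[(lo, hi, "pos" if v > 0 else "neg")] = float(v)
        edge_sets.append(es)

    if not acc_pos:
        warnings.warn("no Monte-Carlo iteration accepted a threshold; "
                      "the consensus network is empty")
    thresholds = Thresholds(
        t_pos=float(np.mean(acc_pos)) if acc_pos else float("nan"),
        t_neg=-float(np.mean(acc_neg)) if acc_neg else float("nan"),
    )
    return MonteCarloResult(edge_sets, thresholds, acc_pos, acc_neg)


def consensus(edge_sets: list[dict[tuple[str, str, str], float]],
              fraction: float) -> list[EdgeRecord]:
    """Keep each signed pair present in at least ``fraction`` of the sets.

    Support is the containing fraction (3 decimals); the weight is the mean
    Spearman coefficient over the containing iterations (6 significant
    digits).  A pair with conflicting signs across iterations is counted
    separately per sign — both cannot pass a fraction above one half.
    """
    if not edge_sets:
        raise ValidationError("consensus needs at least one edge set")
    n = len(edge_sets)
    counts: dict[tuple[str, str, str], int] = {}
    sums: dict[tuple[str, str, str], float] = {}
    for es in edge_sets:
        for key, rho in es.items():
            counts[key] = counts.get(key, 0) + 1
            sums[key] = sums.get(key, 0.0) + rho
    records = []
    for key, c in counts.items():
        supp = c / n
        if supp < fraction - 1e-12:
            continue
        a, b, sign = key
        records.append(EdgeRecord(a, b, sign,
                                  weight=round_sig(sums[key] / c, 6),
                                  support=round(supp, 3)))
    return sorted(records, key=lambda e: e.key)


def infer_network(
    m: AnalysisMatrix,
    cfg: NullModelConfig,
    taxonomy: TaxonomyTable | None = None,
    traits: TraitTable | None = None,
) -> SignedNetwork:
    """Full inference: Monte-Carlo edge sets → consensus → finalized network.

    Isolated nodes are dropped; nodes carry kind, taxonomy, trait and total
    (normalized) abundance annotations.
    """
    mc = monte_carlo_networks(m, cfg)
    edges = consensus(mc.edge_sets, cfg.consensus_fraction)
    degree: dict[str, int] = {}
    for e in edges:
        degree[e.node_a] = degree.get(e.node_a, 0) + 1
        degree[e.node_b] = degree.get(e.node_b, 0) + 1
    row_pos = {rid: i for i, rid in enumerate(m.row_ids)}
    nodes = []
    for nid in sorted(degree):
        i = row_pos[nid]
        kind = str(m.row_kind[i])
        group, phylum, trait = "", "", ""
        abundance = 0.0
        if kind == "otu":
            group = taxonomy.group_of(nid) if taxonomy else "Unknown"
            phylum = taxonomy.phylum_of(nid) if taxonomy else ""
            trait = traits.trait_of(nid) if traits else ""
            abundance = round_sig(float(m.values[i].sum()), 6)
        nodes.append(NodeRecord(nid, kind, group, phylum, trait, abundance,
                                degree[nid]))
    return SignedNetwork(nodes, edges, mc.thresholds, cfg)


def with_seed(cfg: NullModelConfig, seed: int) -> NullModelConfig:
    """A copy of ``cfg`` with a different RNG seed."""
    return replace(cfg, seed=int(seed))
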