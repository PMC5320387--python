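"""Integrative network construction.

One streamwise sparse regression is fit per RNA (the RNA as response, every
other RNA as a candidate predictor).  A model is retained only when its
adjusted R^2 surpasses a cutoff (0.8 by default), and each retained
(target, regulator) relation contributes one undirected edge.  Because the
regressions cannot orient causality — a selected regulator may drive the
target or vice versa — relations discovered in either or both directions
collapse onto a single undirected edge, annotated with the best adjusted
R^2 that produced it and, for provenance, the direction(s) of discovery.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .expression import RNA_TYPES, ExpressionMatrix
from .regression import StreamwiseVifRegressor, VifParams

logger = logging.getLogger(__name__)


class RegulatoryGraph:
    """Undirected graph over typed RNA vertices.

    Vertices carry an RNA type (mRNA / lncRNA / miRNA); edges carry the
    adjusted R^2 of the best model that produced them plus the list of
    (target, regulator, adj_r2) discovery records.  Self-loops are
    rejected, and a vertex exists only while it touches at least one edge
    (isolated vertices are never stored).
    """

    def __init__(self):
        self._g = nx.Graph()

    # -- construction --------------------------------------------------

    def add_relation(self, target: str, regulator: str,
                     target_type: str, regulator_type: str,
                     adj_r2: float) -> None:
        """Record one retained (target, regulator) relation as an edge."""
        if target == regulator:
            raise ValidationError(f"self-loop rejected: {target}")
        for t in (target_type, regulator_type):
            if t not in RNA_TYPES:
                raise ValidationError(f"unknown RNA type: {t!r}")
        for node, typ in ((target, target_type), (regulator, regulator_type)):
            known = self._g.nodes.get(node, {}).get("rna_type")
            if known is not None and known != typ:
                raise ValidationError(
                    f"conflicting RNA type for {node}: {known} vs {typ}")
            self._g.add_node(node, rna_type=typ)
        record = (target, regulator, float(adj_r2))
        if self._g.has_edge(target, regulator):
            data = self._g.edges[target, regulator]
            data["adj_r2"] = max(data["adj_r2"], float(adj_r2))
            if record not in data["discovered"]:
                data["discovered"].append(record)
        else:
            self._g.add_edge(target, regulator,
                             adj_r2=float(adj_r2), discovered=[record])

    # -- queries -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def vertices(self) -> dict[str, str]:
        """Mapping gene id -> RNA type."""
        return {n: d["rna_type"] for n, d in self._g.nodes(data=True)}

    def vertex_type(self, gene_id: str) -> str:
        return self._g.nodes[gene_id]["rna_type"]

    def edges(self):
        """Iterate (gene_a, gene_b, adj_r2) with a < b lexicographically."""
        for u, v, d in self._g.edges(data=True):
            a, b = (u, v) if str(u) <= str(v) else (v, u)
            yield a, b, d["adj_r2"]

    def edge_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self._g.edges()}

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, gene_id: str) -> set:
        return set(self._g.neighbors(gene_id))

    def degree(self, gene_id: str) -> int:
        return self._g.degree[gene_id]

    def to_networkx(self) -> nx.Graph:
        """The underlying networkx graph (a live view, not a copy)."""
        return self._g

    def __eq__(self, other):
        if not isinstance(other, RegulatoryGraph):
            return NotImplemented
        return (self.vertices() == other.vertices()
                and self.edge_set() == other.edge_set())


@dataclass(frozen=True)
class RegressionTask:
    """One per-target regression task: the target RNA against all others.

    The predictor list is derived lazily from the shared gene roster —
    a genome-wide manifest has ~3e4 tasks x ~3e4 predictors, which is
    cheap to describe but wasteful to materialize eagerly.
    """

    target_id: str
    target_index: int
    gene_ids: tuple = field(repr=False)

    @property
    def n_predictors(self) -> int:
        return len(self.gene_ids) - 1

    @property
    def predictor_ids(self) -> list:
        return [g for g in self.gene_ids if g != self.target_id]


def enumerate_tasks(combined: ExpressionMatrix) -> list[RegressionTask]:
    """One regression task per gene, predictors = every other gene.

    Order is deterministic (input row order).  Requires at least three
    genes, the minimum for a nontrivial triangle downstream.
    """
    if combined.n_genes < 3:
        raise ValidationError(
            f"need >= 3 genes to build a network, got {combined.n_genes}")
    roster = tuple(combined.gene_ids)
    return [RegressionTask(g, i, roster) for i, g in enumerate(roster)]


def _task_seed(global_seed: int, target_id: str) -> int:
    """Stable per-task seed so the graph is independent of task order."""
    h = hashlib.blake2b(f"{global_seed}:{target_id}".encode(),
                        digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31 - 1)


@dataclass
class NetworkBuildResult:
    graph: "RegulatoryGraph"
    n_tasks: int
    n_retained: int
    n_skipped_zero_variance: int


class IntegrativeNetworkBuilder:
    """Fits one streamwise model per RNA and integrates retained relations.

    scikit-learn-style: configure in ``__init__``, call :meth:`fit` with an
    :class:`ExpressionMatrix`, read the ``graph_`` attribute.

    Parameters
    ----------
    cutoff : float, default 0.8
        Adjusted-R^2 retention cutoff; a model contributes edges only when
        ``adj_r2 > cutoff`` (strict, "surpasses").
    params : VifParams, optional
        Streamwise-selection parameters; ``params.seed`` is the root seed
        from which per-task seeds derive.
    """

    def __init__(self, cutoff: float = 0.8, params: VifParams | None = None):
        self.cutoff = cutoff
        self.params = params

    def get_params(self, deep=True):
        return {"cutoff": self.cutoff, "params": self.params}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in ("cutoff", "params"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, combined: ExpressionMatrix) -> "IntegrativeNetworkBuilder":
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValidationError(f"cutoff must be in [0, 1], got {self.cutoff}")
        params = self.params if self.params is not None else VifParams()
        tasks = enumerate_tasks(combined)

        V = combined.values.to_numpy(dtype=float)          # genes x samples
        X_all = V.T                                        # samples x genes
        sds = X_all.std(axis=0)
        usable = sds > 0.0
        n_zero_var = int((~usable).sum())
        if n_zero_var:
            logger.warning("excluding %d zero-variance gene(s) from regression",
                           n_zero_var)

        gene_ids = combined.gene_ids
        types = combined.gene_types
        graph = RegulatoryGraph()
        n_retained = 0

        usable_idx = np.flatnonzero(usable)
        for task in tasks:
            ti = task.target_index
            if not usable[ti]:
                continue
            pred_idx = usable_idx[usable_idx != ti]
            if pred_idx.size == 0:
                continue
            y = X_all[:, ti]
            X = X_all[:, pred_idx]
            est = StreamwiseVifRegressor(
                presample_size=params.presample_size,
                initial_wealth=params.initial_wealth,
                payout=params.payout,
                max_passes=params.max_passes,
                lambda0=params.lambda0,
                random_state=_task_seed(params.seed, task.target_id),
            )
            try:
                est.fit(X, y)
            except Exception:
                logger.warning("regression failed for target %s; skipping",
                               task.target_id, exc_info=True)
                continue
            if est.adj_r2_ > self.cutoff and est.support_.size > 0:
                n_retained += 1
                for j in est.support_:
                    reg = gene_ids[pred_idx[j]]
                    graph.add_relation(task.target_id, reg,
                                       types[task.target_id], types[reg],
                                       est.adj_r2_)
        self.graph_ = graph
        self.result_ = NetworkBuildResult(graph, len(tasks), n_retained,
                                          n_zero_var)
        return self


def build_integrative_network(combined: ExpressionMatrix,
                              cutoff: float = 0.8,
                              params: VifParams | None = None
                              ) -> RegulatoryGraph:
    """Functional wrapper over :class:`IntegrativeNetworkBuilder`."""
    return IntegrativeNetworkBuilder(cutoff=cutoff, params=params).fit(
        combined).graph_


def degree_summary(graph: RegulatoryGraph) -> dict:
    """Degree statistics and per-type vertex counts.

    Mean degree is 2|E|/|V| — on the biological reading, the average
    number of regulators per RNA in the network.  An empty graph yields
    all zeros.
    """
    g = graph.to_networkx()
    degrees = [d for _, d in g.degree()]
    by_type = {t: 0 for t in RNA_TYPES}
    for _, typ in graph.vertices().items():
        by_type[typ] += 1
    if not degrees:
        return {"n_vertices": 0, "n_edges": 0, "mean_degree": 0.0,
                "median_degree": 0.0, "max_degree": 0,
                "vertices_per_type": by_type}
    return {
        "n_vertices": graph.n_vertices,
        "n_edges": graph.n_edges,
        "mean_degree": 2.0 * graph.n_edges / graph.n_vertices,
        "median_degree": float(np.median(degrees)),
        "max_degree": int(max(degrees)),
        "vertices_per_type": by_type,
    }
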