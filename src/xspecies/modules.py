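"""Cross-species co-expression module detection on a multilayer network.

Each species contributes a weighted co-expression layer (rank correlation
of log expression, sparsified to top-k neighbors); cross-species
orthology pairs couple the layers with strength kappa. Modules are found
by simulated annealing on a coupled objective: the sum of per-layer
Newman–Girvan modularities (resolution gamma) plus kappa times the
fraction of coupling pairs whose endpoints share a module. Repeated
stochastic runs are summarized by a co-association matrix, from which
consensus modules are read off as connected components above a
co-clustering frequency cutoff and classified as conserved or
species-specific by their species composition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, OrthologyMap, ValidationError

logger = logging.getLogger(__name__)

Node = tuple[str, str]  # (species, gene)

__all__ = [
    "MultilayerNetwork",
    "Partition",
    "CoAssociationMatrix",
    "ModuleSet",
    "AnnealSchedule",
    "build_coexpression_layer",
    "build_multilayer_network",
    "score_partition",
    "anneal_partition",
    "coassociation",
    "consensus_modules",
    "ortholog_enrichment",
    "term_enrichment",
    "conservation_fraction",
    "CrossSpeciesModuleModel",
    "CrossSpeciesModuleResults",
]


@dataclass
class MultilayerNetwork:
    """Per-species co-expression layers joined by orthology couplings.

    ``layers`` maps species tag to an undirected weighted graph whose
    nodes are ``(species, gene)`` tuples; ``couplings`` lists cross-layer
    node pairs. ``kappa`` weights the coupling term and ``gamma`` is the
    modularity resolution applied in every layer.
    """

    layers: dict[str, nx.Graph]
    couplings: list[tuple[Node, Node]]
    kappa: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kappa) and math.isfinite(self.gamma)):
            raise ValidationError("kappa and gamma must be finite")
        if self.kappa < 0 or self.gamma <= 0:
            raise ValidationError("need kappa >= 0 and gamma > 0")
        for sp, g in self.layers.items():
            for u, v in g.edges:
                if u == v:
                    raise ValidationError(f"self-loop {u} in layer {sp}")
        for a, b in self.couplings:
            if a[0] == b[0]:
                raise ValidationError(f"coupling within one species: {a}-{b}")

    @property
    def nodes(self) -> list[Node]:
        out: list[Node] = []
        for sp in sorted(self.layers):
            out.extend(sorted(self.layers[sp].nodes))
        return out


@dataclass
class Partition:
    """A node→module assignment with its objective value."""

    assignment: dict[Node, int]
    score: float

    def labels_for(self, nodes: list[Node]) -> np.ndarray:
        return np.array([self.assignment[n] for n in nodes])


@dataclass
class CoAssociationMatrix:
    """Pairwise co-assignment frequency across annealing runs."""

    nodes: list[Node]
    frequency: np.ndarray

    def __post_init__(self) -> None:
        f = self.frequency
        if f.shape != (len(self.nodes), len(self.nodes)):
            raise ValidationError("frequency shape mismatch")
        if not np.allclose(f, f.T) or (f < 0).any() or (f > 1).any():
            raise ValidationError("frequency must be a symmetric [0,1] matrix")


@dataclass
class ModuleSet:
    """Disjoint consensus modules with species-composition classes."""

    modules: dict[int, set[Node]]
    classes: dict[int, str]


def build_coexpression_layer(
    expr: ExpressionMatrix,
    method: str = "spearman",
    top_k: int = 10,
    pseudocount: float = 1.0,
) -> nx.Graph:
    """Top-k positive rank-correlation graph over one species' genes.

    Correlations are computed on ``log(expr + pseudocount)`` across
    samples; each gene keeps edges to its ``top_k`` most-correlated
    partners (ties broken by gene id), edge sets are unioned over both
    endpoints, and non-positive correlations are dropped. Zero-variance
    genes become isolated nodes.
    """
    if method != "spearman":
        raise ValidationError(f"unsupported correlation method {method!r}")
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    if len(expr.samples) < 3:
        raise ValidationError("need at least 3 samples for co-expression")
    logged = np.log(expr.values.to_numpy(dtype=float) + pseudocount)
    genes = expr.genes
    graph = nx.Graph()
    graph.add_nodes_from((expr.species, g) for g in genes)
    constant = np.std(logged, axis=1) == 0
    for g in np.array(genes)[constant]:
        logger.info("zero-variance gene %s isolated in layer %s", g, expr.species)
    if constant.all() or len(genes) < 2:
        return graph
    ranked = stats.rankdata(logged, axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranked)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.nan)
    order = np.argsort(genes)  # lexicographic tie-break helper
    for i, g in enumerate(genes):
        row = corr[i]
        valid = np.flatnonzero(~np.isnan(row))
        if valid.size == 0:
            continue
        # sort by descending correlation, then lexicographic gene id
        key = sorted(valid, key=lambda j: (-row[j], genes[j]))
        for j in key[:top_k]:
            w = row[j]
            if w > 0:
                graph.add_edge((expr.species, g), (expr.species, genes[j]), weight=float(w))
    del order
    return graph


def build_multilayer_network(
    exprs: dict[str, ExpressionMatrix],
    orthology: OrthologyMap,
    kappa: float = 1.0,
    gamma: float = 1.0,
    top_k: int = 10,
    orthologs_only: bool = False,
) -> MultilayerNetwork:
    """Assemble per-species layers and orthology couplings into one network.

    With ``orthologs_only`` the layers are restricted to genes that have
    at least one ortholog partner before graph construction (the
    conserved-module focus mode).
    """
    keep: dict[str, set[str]] | None = None
    if orthologs_only:
        keep = {sp: set() for sp in exprs}
        for (s1, g1), (s2, g2) in orthology:
            if s1 in keep:
                keep[s1].add(g1)
            if s2 in keep:
                keep[s2].add(g2)
    layers = {}
    for sp, expr in sorted(exprs.items()):
        if keep is not None:
            genes = [g for g in expr.genes if g in keep[sp]]
            expr = ExpressionMatrix(
                species=sp,
                values=expr.values.loc[genes],
                sample_meta=expr.sample_meta,
            )
        layers[sp] = build_coexpression_layer(expr, top_k=top_k)
    node_set = {n for g in layers.values() for n in g.nodes}
    couplings = []
    for (s1, g1), (s2, g2) in orthology:
        a, b = (s1, g1), (s2, g2)
        if a in node_set and b in node_set:
            couplings.append((a, b))
    return MultilayerNetwork(layers=layers, couplings=couplings, kappa=kappa, gamma=gamma)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _layer_modularity(graph: nx.Graph, labels: dict[Node, int], gamma: float) -> float:
    two_m = sum(d for _, d in graph.degree(weight="weight"))
    if two_m == 0:
        return 0.0
    s_in: dict[int, float] = {}
    s_tot: dict[int, float] = {}
    for node, deg in graph.degree(weight="weight"):
        c = labels[node]
        s_tot[c] = s_tot.get(c, 0.0) + deg
    for u, v, w in graph.edges(data="weight", default=1.0):
        if labels[u] == labels[v]:
            s_in[labels[u]] = s_in.get(labels[u], 0.0) + 2.0 * w
    q = 0.0
    for c, tot in s_tot.items():
        q += s_in.get(c, 0.0) / two_m - gamma * (tot / two_m) ** 2
    return q


def score_partition(net: MultilayerNetwork, part: Partition | dict[Node, int]) -> float:
    """Coupled-modularity objective of a partition.

    Sum over layers of Newman–Girvan modularity at resolution gamma, plus
    ``kappa`` times the fraction of coupling pairs co-assigned. A layer
    with no edges contributes 0; so does an empty coupling set.
    """
    labels = part.assignment if isinstance(part, Partition) else part
    missing = [n for g in net.layers.values() for n in g.nodes if n not in labels]
    if missing:
        raise ValidationError(f"partition misses nodes, e.g. {missing[0]}")
    score = sum(_layer_modularity(g, labels, net.gamma) for g in net.layers.values())
    if net.couplings:
        co = sum(1 for a, b in net.couplings if labels[a] == labels[b])
        score += net.kappa * co / len(net.couplings)
    return score


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric simulated-annealing schedule.

    ``steps_per_t`` of ``None`` means ``moves_per_node * n_nodes`` move
    proposals per temperature.
    """

    t0: float = 1.0
    cooling: float = 0.98
    steps_per_t: int | None = None
    t_min: float = 1e-3
    moves_per_node: int = 100

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.t_min <= 0 or not 0 < self.cooling < 1:
            raise ValidationError("invalid annealing schedule")


class _AnnealState:
    """Flat-array annealing state with O(degree) move evaluation."""

    def __init__(self, net: MultilayerNetwork):
        self.nodes = net.nodes
        self.n = len(self.nodes)
        self.index = {node: i for i, node in enumerate(self.nodes)}
        self.gamma = net.gamma
        self.kappa = net.kappa
        # per-node adjacency within its own layer
        self.adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n)]
        self.strength = np.zeros(self.n)
        self.layer_of = np.zeros(self.n, dtype=int)
        self.layer_m = []  # total edge weight per layer
        for li, sp in enumerate(sorted(net.layers)):
            graph = net.layers[sp]
            m = 0.0
            for u, v, w in graph.edges(data="weight", default=1.0):
                iu, iv = self.index[u], self.index[v]
                self.adj[iu].append((iv, w))
                self.adj[iv].append((iu, w))
                self.strength[iu] += w
                self.strength[iv] += w
                m += w
            for node in graph.nodes:
                self.layer_of[self.index[node]] = li
            self.layer_m.append(m)
        self.partners: list[list[int]] = [[] for _ in range(self.n)]
        for a, b in net.couplings:
            ia, ib = self.index[a], self.index[b]
            self.partners[ia].append(ib)
            self.partners[ib].append(ia)
        self.n_couplings = len(net.couplings)

    def init_labels(self, rng: np.random.Generator) -> None:
        self.labels = np.arange(self.n)
        # community strength per (layer, label): labels range over 0..n-1
        self.comm_strength = np.zeros((len(self.layer_m), self.n))
        for i in range(self.n):
            self.comm_strength[self.layer_of[i], self.labels[i]] += self.strength[i]
        self.label_counts = np.ones(self.n, dtype=int)

    def delta(self, i: int, new_label: int) -> float:
        old = self.labels[i]
        if new_label == old:
            return 0.0
        li = self.layer_of[i]
        m = self.layer_m[li]
        d = 0.0
        if m > 0:
            w_old = 0.0
            w_new = 0.0
            for j, w in self.adj[i]:
                lab = self.labels[j]
                if lab == old:
                    w_old += w
                elif lab == new_label:
                    w_new += w
            k_i = self.strength[i]
            k_old = self.comm_strength[li, old]
            k_new = self.comm_strength[li, new_label]
            d += (w_new - w_old) / m
            d -= self.gamma * k_i * (k_new - k_old + k_i) / (2.0 * m * m)
        if self.n_couplings:
            co = 0
            for j in self.partners[i]:
                if self.labels[j] == new_label:
                    co += 1
                elif self.labels[j] == old:
                    co -= 1
            d += self.kappa * co / self.n_couplings
        return d

    def apply(self, i: int, new_label: int) -> None:
        old = self.labels[i]
        li = self.layer_of[i]
        self.comm_strength[li, old] -= self.strength[i]
        self.comm_strength[li, new_label] += self.strength[i]
        self.labels[i] = new_label
        self.label_counts[old] -= 1
        self.label_counts[new_label] += 1


def anneal_partition(
    net: MultilayerNetwork,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> Partition:
    """Optimize the coupled-modularity objective by simulated annealing.

    Single-node relabeling moves are proposed uniformly (random node,
    random target label among the labels in use plus one fresh label) and
    accepted with probability ``min(1, exp(delta/T))`` under a geometric
    cooling schedule. The best partition seen is returned with its score
    recomputed exactly; labels are renumbered densely from 0.
    """
    schedule = schedule or AnnealSchedule()
    state = _AnnealState(net)
    if state.n == 0:
        return Partition(assignment={}, score=0.0)
    rng = np.random.default_rng(seed)
    state.init_labels(rng)
    current = score_partition(net, dict(zip(state.nodes, state.labels.tolist())))
    best_labels = state.labels.copy()
    best = current
    steps = schedule.steps_per_t or schedule.moves_per_node * state.n
    t = schedule.t0
    while t > schedule.t_min:
        for _ in range(steps):
            i = int(rng.integers(state.n))
            used = np.flatnonzero(state.label_counts)
            # candidate labels: those in use, plus one unused (module birth)
            free = np.flatnonzero(state.label_counts == 0)
            options = used if free.size == 0 else np.append(used, free[0])
            new_label = int(options[rng.integers(options.size)])
            d = state.delta(i, new_label)
            if d >= 0 or rng.random() < math.exp(d / t):
                state.apply(i, new_label)
                current += d
                if current > best + 1e-12:
                    best = current
                    best_labels = state.labels.copy()
        t *= schedule.cooling
    # greedy polish at T->0: guarantee single-move local optimality
    state.labels = best_labels.copy()
    state.comm_strength[:] = 0.0
    for i in range(state.n):
        state.comm_strength[state.layer_of[i], state.labels[i]] += state.strength[i]
    state.label_counts = np.bincount(state.labels, minlength=state.n)
    improved = True
    while improved:
        improved = False
        for i in range(state.n):
            used = np.flatnonzero(state.label_counts)
            free = np.flatnonzero(state.label_counts == 0)
            options = used if free.size == 0 else np.append(used, free[0])
            deltas = [state.delta(i, int(lab)) for lab in options]
            j = int(np.argmax(deltas))
            if deltas[j] > 1e-12:
                state.apply(i, int(options[j]))
                improved = True
    best_labels = state.labels
    # dense relabeling, stable in node order
    remap: dict[int, int] = {}
    assignment: dict[Node, int] = {}
    for node, lab in zip(state.nodes, best_labels.tolist()):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[node] = remap[lab]
    return Partition(assignment=assignment, score=score_partition(net, assignment))


def coassociation(partitions: list[Partition]) -> CoAssociationMatrix:
    """Fraction of runs co-assigning each node pair to one module."""
    if not partitions:
        raise ValidationError("need at least one partition")
    nodes = sorted(partitions[0].assignment)
    node_set = set(nodes)
    freq = np.zeros((len(nodes), len(nodes)))
    for part in partitions:
        if set(part.assignment) != node_set:
            raise ValidationError("partitions cover different node sets")
        labels = part.labels_for(nodes)
        freq += (labels[:, None] == labels[None, :]).astype(float)
    freq /= len(partitions)
    return CoAssociationMatrix(nodes=nodes, frequency=freq)


def classify_module(members: set[Node], min_share: float = 0.1) -> str:
    """Composition class: conserved-k when >= ``min_share`` of the nodes
    come from each of k species (k >= 2), else species-specific."""
    counts: dict[str, int] = {}
    for sp, _ in members:
        counts[sp] = counts.get(sp, 0) + 1
    k = sum(1 for c in counts.values() if c / len(members) >= min_share)
    return f"conserved-{k}" if k >= 2 else "species-specific"


def consensus_modules(
    coassoc: CoAssociationMatrix, cutoff: float = 0.5, min_share: float = 0.1
) -> ModuleSet:
    """Consensus modules: connected components of the co-association graph
    thresholded at frequency >= ``cutoff``; singletons are dropped."""
    if not 0 < cutoff <= 1:
        raise ValidationError("cutoff must be in (0, 1]")
    n = len(coassoc.nodes)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(coassoc.frequency >= cutoff, k=1))
    graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
    modules: dict[int, set[Node]] = {}
    classes: dict[int, str] = {}
    label = 0
    for comp in sorted(nx.connected_components(graph), key=min):
        if len(comp) < 2:
            continue
        members = {coassoc.nodes[i] for i in comp}
        modules[label] = members
        classes[label] = classify_module(members, min_share)
        label += 1
    return ModuleSet(modules=modules, classes=classes)


def ortholog_enrichment(
    module: set[Node], orthology: OrthologyMap, background: set[Node]
) -> tuple[float, float]:
    """Hypergeometric enrichment of within-module ortholog membership.

    The test statistic is the number of module genes with at least one
    ortholog partner also inside the module; the null draws module-sized
    gene sets from the background, where a gene counts as a potential
    success when it has an ortholog partner anywhere in the background.
    Returns ``(fold, p)`` with fold = observed / expected under the null.
    """
    if not module:
        raise ValidationError("empty module")
    if not module <= background:
        raise ValidationError("module must be a subset of the background")
    bg = sorted(background)
    has_bg_partner = {
        n: any(p in background for p in orthology.partners(*n)) for n in bg
    }
    big_k = sum(1 for n in bg if has_bg_partner[n])
    k = sum(
        1 for n in module if any(p in module for p in orthology.partners(*n))
    )
    big_n, n = len(bg), len(module)
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
    expected = n * big_k / big_n
    fold = k / expected if expected > 0 else float("nan")
    return fold, min(p, 1.0)


def term_enrichment(
    module: set[str],
    term_map: dict[str, set[str]],
    background: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment with BH correction.

    ``term_map`` maps gene → set of terms. Returns one row per term with
    counts (k in module, K in background, n module size, N background
    size), p, q, and a significance flag at ``q <= fdr``. Terms with no
    background gene are skipped and logged.
    """
    if not module <= background:
        raise ValidationError("module must be a subset of the background")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    rows = []
    big_n, n = len(background), len(module)
    for term in sorted(term_genes):
        in_bg = term_genes[term] & background
        if not in_bg:
            logger.info("term %s absent from background, skipped", term)
            continue
        big_k = len(in_bg)
        k = len(term_genes[term] & module)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n, "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] <= fdr
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def conservation_fraction(
    module: set[Node] | set[str],
    presence: dict,
    min_species: int,
) -> float:
    """Fraction of module genes present in at least ``min_species`` species
    of a user-supplied presence table."""
    if not module:
        return 0.0
    missing = [g for g in module if g not in presence]
    if missing:
        raise ValidationError(f"presence undefined for {sorted(missing)[:3]}")
    return sum(1 for g in module if presence[g] >= min_species) / len(module)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class CrossSpeciesModuleModel:
    """Orthology-coupled module detection as a fittable model.

    Parameters
    ----------
    exprs : dict of species tag -> ExpressionMatrix
    orthology : OrthologyMap
    kappa, gamma : float
        Coupling strength and modularity resolution.
    top_k : int
        Neighbors kept per gene in each co-expression layer.
    orthologs_only : bool
        Restrict layers to genes with at least one ortholog.
    """

    def __init__(
        self,
        exprs: dict[str, ExpressionMatrix],
        orthology: OrthologyMap,
        kappa: float = 1.0,
        gamma: float = 1.0,
        top_k: int = 10,
        orthologs_only: bool = False,
    ) -> None:
        self.exprs = exprs
        self.orthology = orthology
        self.network = build_multilayer_network(
            exprs, orthology, kappa=kappa, gamma=gamma, top_k=top_k,
            orthologs_only=orthologs_only,
        )

    def fit(
        self,
        n_runs: int = 50,
        schedule: AnnealSchedule | None = None,
        consensus_cutoff: float = 0.5,
        seed: int = 0,
    ) -> "CrossSpeciesModuleResults":
        """Run repeated annealing and build the consensus module set."""
        seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
        partitions = [
            anneal_partition(self.network, schedule, int(s)) for s in seeds
        ]
        coassoc = coassociation(partitions)
        modules = consensus_modules(coassoc, cutoff=consensus_cutoff)
        return CrossSpeciesModuleResults(
            model=self, partitions=partitions, coassoc=coassoc, modules=modules
        )


@dataclass
class CrossSpeciesModuleResults:
    """Fitted module structure: runs, co-association, consensus modules."""

    model: CrossSpeciesModuleModel
    partitions: list[Partition]
    coassoc: CoAssociationMatrix
    modules: ModuleSet

    @property
    def best_partition(self) -> Partition:
        return max(self.partitions, key=lambda p: p.score)

    def module_table(self) -> pd.DataFrame:
        rows = []
        for label, members in sorted(self.modules.modules.items()):
            for sp, gene in sorted(members):
                rows.append(
                    {"module": label, "class": self.modules.classes[label],
                     "species": sp, "gene": gene}
                )
        return pd.DataFrame(rows, columns=["module", "class", "species", "gene"])

    def ortholog_enrichment(self) -> pd.DataFrame:
        background = set(self.coassoc.nodes)
        rows = []
        for label, members in sorted(self.modules.modules.items()):
            fold, p = ortholog_enrichment(members, self.model.orthology, background)
            rows.append(
                {"module": label, "class": self.modules.classes[label],
                 "size": len(members), "fold": fold, "p": p}
            )
        return pd.DataFrame(rows, columns=["module", "class", "size", "fold", "p"])

    def summary(self) -> str:
        lines = [
            "Cross-species co-expression modules",
            f"  layers: {', '.join(sorted(self.model.network.layers))}",
            f"  nodes: {len(self.coassoc.nodes)}; couplings: "
            f"{len(self.model.network.couplings)}; "
            f"kappa={self.model.network.kappa:g} gamma={self.model.network.gamma:g}",
            f"  annealing runs: {len(self.partitions)}; "
            f"best objective: {self.best_partition.score:.4f}",
            f"  consensus modules: {len(self.modules.modules)}",
        ]
        for label, members in sorted(self.modules.modules.items()):
            by_sp: dict[str, int] = {}
            for sp, _ in members:
                by_sp[sp] = by_sp.get(sp, 0) + 1
            comp = ", ".join(f"{sp}:{c}" for sp, c in sorted(by_sp.items()))
            lines.append(
                f"    module {label} [{self.modules.classes[label]}] "
                f"size={len(members)} ({comp})"
            )
        return "\n".join(lines)
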