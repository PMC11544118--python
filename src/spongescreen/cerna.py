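"""ceRNA sponge-triplet screening.

The screen follows the competing-endogenous-RNA logic: among
differentially expressed lncRNAs, keep those whose expression tracks an
immune-checkpoint ligand (Spearman rho > 0.4, p < 0.001, tumor samples),
intersect the two ligand-related sets, intersect the binding-prediction
sources per edge class, and assemble co-expressed competing triplets — a
lncRNA-mRNA pair with rho > 0.5 and p < 0.001 that are both negatively
co-expressed with a shared, binding-predicted miRNA.  The lncRNA most
correlated with both ligands is ranked as the hub.

Raw (unadjusted) p cutoffs are used inside the correlation screens;
BH adjustment is applied only in stages that call for adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .matrix import ExpressionMatrix, normalize_gene_id
from .rankstats import CorrelationResult, spearman

__all__ = [
    "InteractionTable", "CeRNATriplet",
    "ligand_correlated_lncs", "intersect_gene_sets",
    "intersect_interaction_sources", "assemble_triplets",
    "rank_hub_lnc", "export_network",
]

EDGE_CLASSES = ("lnc_mi", "mi_mrna")


@dataclass
class InteractionTable:
    """A set of predicted (regulator, target) edges from one source."""

    edges: set
    edge_class: str
    source_db: str
    edge_sources: dict = field(default_factory=dict)  # edge -> [source_db, ...]

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASSES:
            raise ValueError(f"unknown edge_class: {self.edge_class!r}")
        normalized = set()
        for r, t in self.edges:
            r, t = normalize_gene_id(r), normalize_gene_id(t)
            if r == t:
                raise ValueError(f"self-edge {r!r} not allowed")
            normalized.add((r, t))
        self.edges = normalized
        if not self.edge_sources:
            self.edge_sources = {e: [self.source_db] for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, regulator: str) -> set:
        reg = normalize_gene_id(regulator)
        return {t for r, t in self.edges if r == reg}


@dataclass(frozen=True)
class CeRNATriplet:
    """One lncRNA-miRNA-mRNA candidate with its three correlations."""

    lnc_id: str
    mi_id: str
    mrna_id: str
    rho_lnc_mrna: float
    p_lnc_mrna: float
    rho_lnc_mi: float
    p_lnc_mi: float
    rho_mi_mrna: float
    p_mi_mrna: float
    sources: tuple = ()

    def key(self) -> tuple:
        return (self.lnc_id, self.mi_id, self.mrna_id)


def ligand_correlated_lncs(expr: ExpressionMatrix, de_lncs, ligand: str,
                           rho_min: float = 0.4, p_max: float = 0.001,
                           tumor_only: bool = True) -> dict:
    """DE lncRNAs positively correlated with a checkpoint ligand.

    Returns ``{lnc_id: CorrelationResult}`` for lncRNAs with Spearman
    rho > ``rho_min`` and p < ``p_max`` against the ligand, computed on
    tumor samples by default.
    """
    if ligand not in expr.values.index:
        raise KeyError(f"ligand {ligand!r} not in expression matrix")
    mat = expr.tumor_only() if tumor_only else expr
    y = mat.expression_of(ligand).to_numpy(float)
    out: dict[str, CorrelationResult] = {}
    for lnc in sorted(de_lncs):
        if lnc not in mat.values.index:
            raise KeyError(f"DE lncRNA {lnc!r} not in expression matrix")
        res = spearman(mat.expression_of(lnc).to_numpy(float), y, exact=False)
        if not res.degenerate and res.rho > rho_min and res.p < p_max:
            out[lnc] = res
    return out


def intersect_gene_sets(set_a, set_b) -> list:
    """Exact intersection of two gene-id sets, id-normalised, sorted."""
    a = {normalize_gene_id(g) for g in set_a}
    b = {normalize_gene_id(g) for g in set_b}
    return sorted(a & b)


def intersect_interaction_sources(tables) -> InteractionTable:
    """Edges present in every prediction source, source labels merged."""
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one interaction table")
    classes = {t.edge_class for t in tables}
    if len(classes) > 1:
        raise ValueError(f"mixed edge classes: {sorted(classes)}")
    edges = set(tables[0].edges)
    for t in tables[1:]:
        edges &= t.edges
    sources = "+".join(t.source_db for t in tables)
    edge_sources = {e: [t.source_db for t in tables] for e in edges}
    return InteractionTable(edges=edges, edge_class=tables[0].edge_class,
                            source_db=sources, edge_sources=edge_sources)


def assemble_triplets(expr: ExpressionMatrix, candidate_lncs,
                      lnc_mi: InteractionTable, mi_mrna: InteractionTable,
                      targets, rho_pos_min: float = 0.5,
                      p_max: float = 0.001, neg_p_max: float = 0.05,
                      tumor_only: bool = True,
                      warnings_out: list | None = None) -> list:
    """Assemble co-expressed competing triplets.

    For every candidate lncRNA and target mRNA with Spearman rho >
    ``rho_pos_min`` and p < ``p_max``, emit one triplet per miRNA that is
    binding-predicted for both ((lnc, mi) and (mi, mrna) edges present in
    the intersected tables) and negatively co-expressed with both at
    p < ``neg_p_max``.  Target genes absent from the matrix are skipped
    with a warning collected in ``warnings_out``.
    """
    if lnc_mi.edge_class != "lnc_mi" or mi_mrna.edge_class != "mi_mrna":
        raise ValueError("interaction tables have the wrong edge classes")
    mat = expr.tumor_only() if tumor_only else expr
    series = {}

    def values_of(g):
        if g not in series:
            series[g] = mat.expression_of(g).to_numpy(float)
        return series[g]

    corr_cache: dict[tuple, CorrelationResult] = {}

    def corr(g1, g2):
        k = (g1, g2)
        if k not in corr_cache:
            corr_cache[k] = spearman(values_of(g1), values_of(g2), exact=False)
        return corr_cache[k]

    present_targets = []
    for t in sorted({normalize_gene_id(t) for t in targets}):
        if t in mat.values.index:
            present_targets.append(t)
        elif warnings_out is not None:
            warnings_out.append(f"target {t!r} absent from matrix; skipped")

    triplets: dict[tuple, CeRNATriplet] = {}
    for lnc in sorted({normalize_gene_id(g) for g in candidate_lncs}):
        if lnc not in mat.values.index:
            if warnings_out is not None:
                warnings_out.append(f"candidate {lnc!r} absent from matrix; skipped")
            continue
        lnc_mis = lnc_mi.targets_of(lnc)
        if not lnc_mis:
            continue
        for mrna in present_targets:
            c_lm = corr(lnc, mrna)
            if c_lm.degenerate or not (c_lm.rho > rho_pos_min and c_lm.p < p_max):
                continue
            for mi in sorted(lnc_mis):
                if (mi, mrna) not in mi_mrna.edges:
                    continue
                if mi not in mat.values.index:
                    continue
                c_li = corr(lnc, mi)
                c_im = corr(mi, mrna)
                if c_li.degenerate or c_im.degenerate:
                    continue
                if not (c_li.rho < 0 and c_li.p < neg_p_max):
                    continue
                if not (c_im.rho < 0 and c_im.p < neg_p_max):
                    continue
                sources = tuple(lnc_mi.edge_sources.get((lnc, mi), [])
                                + mi_mrna.edge_sources.get((mi, mrna), []))
                trip = CeRNATriplet(
                    lnc_id=lnc, mi_id=mi, mrna_id=mrna,
                    rho_lnc_mrna=c_lm.rho, p_lnc_mrna=c_lm.p,
                    rho_lnc_mi=c_li.rho, p_lnc_mi=c_li.p,
                    rho_mi_mrna=c_im.rho, p_mi_mrna=c_im.p,
                    sources=sources,
                )
                triplets[trip.key()] = trip
    return [triplets[k] for k in sorted(triplets)]


def rank_hub_lnc(candidates, ligand_correlations: dict) -> list:
    """Candidates sorted by descending mean correlation with both ligands.

    ``ligand_correlations`` maps lnc_id -> (CorrelationResult, CorrelationResult)
    for the two ligands.  Ties break lexicographically by gene id.
    """
    scored = []
    for lnc in sorted(candidates):
        if lnc not in ligand_correlations:
            raise KeyError(f"candidate {lnc!r} is missing a ligand correlation")
        pair = ligand_correlations[lnc]
        if len(pair) != 2:
            raise KeyError(f"candidate {lnc!r} needs correlations with both ligands")
        mean_rho = (pair[0].rho + pair[1].rho) / 2.0
        scored.append((-mean_rho, lnc))
    return [lnc for _, lnc in sorted(scored)]


def export_network(triplets, sif_path=None, graphml_path=None) -> nx.DiGraph:
    """Triplet list as a directed network; optional SIF / GraphML files.

    Edges are ``lnc -sponges-> mi`` and ``mi -targets-> mrna`` with the
    triplet correlations attached; node ordering is deterministic.
    """
    graph = nx.DiGraph()
    for t in sorted(triplets, key=lambda x: x.key()):
        graph.add_node(t.lnc_id, gene_class="lncRNA")
        graph.add_node(t.mi_id, gene_class="miRNA")
        graph.add_node(t.mrna_id, gene_class="mRNA")
        graph.add_edge(t.lnc_id, t.mi_id, interaction="sponges",
                       rho=float(t.rho_lnc_mi))
        graph.add_edge(t.mi_id, t.mrna_id, interaction="targets",
                       rho=float(t.rho_mi_mrna))
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                relation = "sponges" if data["interaction"] == "sponges" else "targets"
                fh.write(f"{u}\t{relation}\t{v}\n")
    if graphml_path is not None:
        # stable element order for byte-identical replays
        sorted_graph = nx.DiGraph()
        sorted_graph.add_nodes_from(sorted(graph.nodes(data=True)))
        sorted_graph.add_edges_from(sorted(graph.edges(data=True)))
        nx.write_graphml(sorted_graph, graphml_path)
    return graph
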