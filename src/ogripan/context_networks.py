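"""Phyletic pattern tables and gene-vicinity concurrence networks.

Phyletic patterns are ordered dose matrices (protein family x genome) for
a chosen PF subset, with genomes ordered by a guide tree's leaf order or
by rank-table grouping.  Concurrence networks score, for each PF pair,
how often the two families sit within a gene window of each other across
the genomes that carry both; edges are exported as TSV, GraphML and SIF
(Cytoscape-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .io_core import GeneTable, GenomeSet, OgripanError, logger, read_newick
from .pangenome import PangenomeProfile, ProteinFamily

__all__ = [
    "PhyleticPattern", "neighborhood_extract", "concurrence_network",
    "phyletic_pattern", "write_sif",
]

UNASSIGNED = "<unassigned>"


def assignment_map(pfs: list[ProteinFamily]) -> dict[tuple[str, str], str]:
    return {m: pf.pf_id for pf in pfs for m in pf.members}


def neighborhood_extract(
    gene_id: str,
    gene_table: GeneTable,
    assignment: dict[tuple[str, str], str],
    window_k: int = 5,
) -> list[str]:
    """PFs of up to ``window_k`` genes on each side, position-ordered.

    Contig ends truncate the window; neighbors without a PF assignment
    yield the ``UNASSIGNED`` placeholder (counted as a non-match).
    """
    df = gene_table.df
    idx = df.index[df["gene_id"] == gene_id]
    if len(idx) == 0:
        raise OgripanError(f"gene {gene_id!r} not in table")
    i = int(idx[0])
    genome = df.at[i, "genome_id"]
    contig = df.at[i, "contig_id"]
    out = []
    for j in range(max(0, i - window_k), min(len(df), i + window_k + 1)):
        if j == i or df.at[j, "contig_id"] != contig:
            continue
        out.append(assignment.get((genome, df.at[j, "gene_id"]), UNASSIGNED))
    return out


def _positions_by_pf(gene_table: GeneTable,
                     assignment: dict[tuple[str, str], str],
                     wanted: set[str]) -> dict[str, list[tuple[str, int]]]:
    """PF -> [(contig, row index)] for one genome, in table order."""
    df = gene_table.df
    genome = df["genome_id"].iloc[0] if len(df) else ""
    out: dict[str, list[tuple[str, int]]] = {}
    for i, gene in enumerate(df["gene_id"]):
        pf = assignment.get((genome, gene))
        if pf in wanted:
            out.setdefault(pf, []).append((df.at[i, "contig_id"], i))
    return out


def concurrence_network(
    pf_subset: list[str],
    data: GenomeSet,
    assignment: dict[tuple[str, str], str],
    window_k: int = 5,
    min_freq: float = 0.0,
) -> nx.Graph:
    """Gene-vicinity concurrence frequencies between PF pairs.

    For each unordered pair, ``frequency`` = 100 x (#genomes where at
    least one member of each family lies within ``window_k`` genes of the
    other on the same contig) / (#genomes carrying both families).  The
    alternative all-genomes denominator is reported as
    ``frequency_all_genomes``.  Edges below ``min_freq`` are dropped.
    PFs absent from every genome are dropped with a warning.
    """
    if not pf_subset:
        raise OgripanError("empty PF subset")
    wanted = set(pf_subset)
    per_genome = {gid: _positions_by_pf(data.gene_tables[gid], assignment,
                                        wanted)
                  for gid in data.ids}
    carriers = {pf: [g for g in data.ids if pf in per_genome[g]]
                for pf in pf_subset}
    graph = nx.Graph()
    for pf in sorted(wanted):
        if carriers[pf]:
            graph.add_node(pf, n_genomes=len(carriers[pf]))
        else:
            logger.warning("PF %s absent from all genomes; node dropped", pf)
    n_genomes = len(data.ids)
    for pa, pb in combinations(sorted(graph.nodes), 2):
        both = [g for g in data.ids
                if pa in per_genome[g] and pb in per_genome[g]]
        if not both:
            continue
        co = 0
        for g in both:
            pos_a = per_genome[g][pa]
            pos_b = per_genome[g][pb]
            if any(ca == cb and abs(ia - ib) <= window_k
                   for ca, ia in pos_a for cb, ib in pos_b):
                co += 1
        freq = 100.0 * co / len(both)
        if freq >= min_freq:
            graph.add_edge(pa, pb,
                           frequency=freq,
                           frequency_all_genomes=100.0 * co / n_genomes,
                           n_genomes_both=len(both))
    logger.info("concurrence network: %d nodes, %d edges (window_k=%d)",
                graph.number_of_nodes(), graph.number_of_edges(), window_k)
    return graph


def write_sif(graph: nx.Graph, path, relation: str = "co") -> None:
    """Simple interaction format: one ``node relation node`` line per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(graph.nodes):
            if graph.degree[node] == 0:
                fh.write(f"{node}\n")


def write_network(graph: nx.Graph, outdir, stem: str = "network") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, outdir / f"{stem}.graphml")
    write_sif(graph, outdir / f"{stem}.sif")
    rows = [{"pf_a": a, "pf_b": b, **attrs}
            for a, b, attrs in sorted(graph.edges(data=True))]
    pd.DataFrame(rows).to_csv(outdir / "edges.tsv", sep="\t", index=False)


@dataclass
class PhyleticPattern:
    wide: pd.DataFrame      # PF x ordered genomes, cell = dose
    long: pd.DataFrame      # genome, pf, dose

    def to_tsv(self, path) -> None:
        self.long.to_csv(path, sep="\t", index=False)


def phyletic_pattern(
    pf_subset: list[str],
    profile: PangenomeProfile,
    ordering,
) -> PhyleticPattern:
    """Dose submatrix for ``pf_subset`` with genomes in display order.

    ``ordering`` is either a Newick tree / dendropy tree (leaf order) or a
    rank table DataFrame with a ``genome`` column (grouped order).  Doses
    equal the profile's doses exactly.
    """
    missing = [pf for pf in pf_subset if pf not in profile.matrix.index]
    if missing:
        raise OgripanError(f"PFs absent from profile: {missing}")
    if isinstance(ordering, pd.DataFrame):
        order = [str(g) for g in ordering["genome"]]
    else:
        tree = ordering if hasattr(ordering, "leaf_node_iter") \
            else read_newick(ordering)
        order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    genomes = list(profile.matrix.columns)
    if set(order) != set(genomes):
        raise OgripanError("ordering does not cover the profiled genomes")
    wide = profile.matrix.loc[pf_subset, order]
    long = wide.reset_index(names="pf").melt(
        id_vars="pf", var_name="genome", value_name="dose"
    )[["genome", "pf", "dose"]]
    return PhyleticPattern(wide, long)
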