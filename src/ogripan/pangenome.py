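"""Orthology clustering into protein families and pangenome metrics.

Protein families (PFs) are built the COGtriangles way: per-genome-pair
reciprocal best hits (RBH), 3-genome RBH triangles, and transitive merging
of triangles that share an edge.  Genes left unclustered become singleton
PFs unless a paralog-recruitment pass (the ortholog/paralog discrimination
step, identity cutoff 60%) attaches them to an existing family.  The
family x genome dose matrix is then partitioned into core / flexible /
exclusive compartments and summarized, including a Heaps-law openness fit
on genome-addition permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from ._align import ProteinHit, align_proteins, pairwise_proteome_hits, protein_aligner
from .io_core import GeneTable, GenomeSet, OgripanError, SequenceRecord, logger

__all__ = [
    "ProteinFamily", "PangenomeProfile", "HeapsFit", "PangenomeSummary",
    "all_vs_all_protein_hits", "cluster_cog_triangles", "paralog_split",
    "build_pangenome_profile", "heaps_fit", "pangenome_summary",
    "cluster_dataset", "profile_from_dose_matrix",
]


@dataclass
class ProteinFamily:
    pf_id: str
    members: list[tuple[str, str]]          # (genome_id, gene_id)

    @property
    def dose(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for genome, _gene in self.members:
            out[genome] = out.get(genome, 0) + 1
        return out

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


# ---------------------------------------------------------------------------
# all-vs-all hits
# ---------------------------------------------------------------------------


def all_vs_all_protein_hits(
    proteomes: dict[str, list[SequenceRecord]],
    min_coverage: float = 0.75,
    min_score: float = 50.0,
) -> pd.DataFrame:
    """Best hit per query per ordered genome pair.

    Hits must cover >= ``min_coverage`` of the query and reach
    ``min_score`` (the score floor standing in for an E-value cutoff).
    Ties break deterministically by (score, aln_len, subject id).
    """
    ids = sorted(proteomes)
    if len(ids) < 3:
        raise OgripanError("triangle clustering needs >= 3 genomes")
    for gid in ids:
        if not proteomes[gid]:
            raise OgripanError(f"empty proteome for genome {gid!r}")
    rows = []
    for ga, gb in combinations(ids, 2):
        hits = pairwise_proteome_hits(proteomes[ga], proteomes[gb],
                                      min_score=min_score)
        for direction, (qg, sg) in (("fwd", (ga, gb)), ("rev", (gb, ga))):
            per_query: dict[str, ProteinHit] = {}
            for h in hits:
                if direction == "fwd":
                    q, s = h.query_id, h.subject_id
                    q_cov = h.q_cov
                else:
                    q, s = h.subject_id, h.query_id
                    q_cov = h.s_cov
                if q_cov < min_coverage:
                    continue
                cur = per_query.get(q)
                key = (h.score, h.aln_len, s)
                if cur is None or (h.score, h.aln_len) > (cur[1].score, cur[1].aln_len) \
                        or ((h.score, h.aln_len) == (cur[1].score, cur[1].aln_len)
                            and s < cur[0]):
                    per_query[q] = (s, h)
            for q, (s, h) in sorted(per_query.items()):
                rows.append({
                    "query_genome": qg, "query_id": q,
                    "subject_genome": sg, "subject_id": s,
                    "score": h.score, "identities": h.identities,
                    "aln_len": h.aln_len,
                    "identity_pct": h.identity_pct,
                })
    df = pd.DataFrame(rows, columns=[
        "query_genome", "query_id", "subject_genome", "subject_id",
        "score", "identities", "aln_len", "identity_pct"])
    logger.info("all-vs-all hits: %d retained over %d genomes", len(df), len(ids))
    return df


# ---------------------------------------------------------------------------
# COG-triangle clustering
# ---------------------------------------------------------------------------


def _rbh_edges(hits: pd.DataFrame) -> set[tuple[tuple[str, str], tuple[str, str]]]:
    best = {}
    for row in hits.itertuples():
        best[(row.query_genome, row.query_id, row.subject_genome)] = \
            (row.subject_genome, row.subject_id)
    edges = set()
    for (qg, q, sg), (sg2, s) in best.items():
        back = best.get((sg2, s, qg))
        if back == (qg, q):
            a, b = sorted([(qg, q), (sg2, s)])
            edges.add((a, b))
    return edges


def cluster_cog_triangles(
    hits: pd.DataFrame,
    all_genes: list[tuple[str, str]] | None = None,
    recruit_identity: float | None = 60.0,
) -> list[ProteinFamily]:
    """Merge RBH triangles sharing an edge into protein families.

    Triangles are 3-cliques of reciprocal best hits spanning 3 distinct
    genomes.  Genes in no triangle become singleton PFs, unless
    ``recruit_identity`` is set, in which case each such gene joins the
    family of its best hit at >= that percent identity, and remaining
    mutually-best pairs at >= that identity form two-member families
    (families carried by only two genomes cannot form a triangle).  Pass
    ``None`` to disable both recruitment steps.
    """
    edges = _rbh_edges(hits)
    graph = nx.Graph(edges)
    edge_graph = nx.Graph()   # nodes = RBH edges that belong to a triangle
    for a, b in edges:
        common = set(graph[a]) & set(graph[b])
        for c in common:
            if len({a[0], b[0], c[0]}) == 3:
                e1, e2, e3 = (tuple(sorted([a, b])), tuple(sorted([a, c])),
                              tuple(sorted([b, c])))
                edge_graph.add_edge(e1, e2)
                edge_graph.add_edge(e2, e3)
                edge_graph.add_edge(e1, e3)
    clusters: list[set[tuple[str, str]]] = []
    for comp in nx.connected_components(edge_graph):
        genes = set()
        for e in comp:
            genes.update(e)
        clusters.append(genes)
    clustered = set().union(*clusters) if clusters else set()

    if all_genes is None:
        all_genes = sorted(
            set(zip(hits["query_genome"], hits["query_id"]))
            | set(zip(hits["subject_genome"], hits["subject_id"])))
    unassigned = [g for g in sorted(all_genes) if g not in clustered]

    gene_to_cluster: dict[tuple[str, str], int] = {}
    clusters.sort(key=lambda genes: min(genes))
    for idx, genes in enumerate(clusters):
        for g in genes:
            gene_to_cluster[g] = idx

    if recruit_identity is not None and unassigned:
        best_for: dict[tuple[str, str], tuple] = {}
        for row in hits.itertuples():
            for q, s in (((row.query_genome, row.query_id),
                          (row.subject_genome, row.subject_id)),
                         ((row.subject_genome, row.subject_id),
                          (row.query_genome, row.query_id))):
                if q in clustered or s not in gene_to_cluster:
                    continue
                if row.identity_pct < recruit_identity:
                    continue
                key = (row.score, row.aln_len, s)
                if q not in best_for or key > best_for[q]:
                    best_for[q] = key
        recruited = 0
        still = []
        for g in unassigned:
            if g in best_for:
                gene_to_cluster[g] = gene_to_cluster[best_for[g][2]]
                clusters[gene_to_cluster[g]].add(g)
                recruited += 1
            else:
                still.append(g)
        unassigned = still
        # mutually-best pairs among the leftovers: 2-genome families
        ident = {}
        for row in hits.itertuples():
            key = tuple(sorted([(row.query_genome, row.query_id),
                                (row.subject_genome, row.subject_id)]))
            ident[key] = max(ident.get(key, 0.0), row.identity_pct)
        leftover = set(unassigned)
        pair_edges = [e for e in sorted(edges)
                      if e[0] in leftover and e[1] in leftover
                      and ident.get(e, 0.0) >= recruit_identity]
        if pair_edges:
            pair_graph = nx.Graph(pair_edges)
            for comp in sorted(nx.connected_components(pair_graph),
                               key=min):
                clusters.append(set(comp))
                leftover -= comp
                recruited += len(comp)
            unassigned = sorted(leftover)
        logger.info("recruited %d unclustered genes into families", recruited)

    pfs = []
    for idx, genes in enumerate(clusters):
        pfs.append(ProteinFamily(f"PF{idx + 1:05d}", sorted(genes)))
    next_id = len(clusters) + 1
    for g in unassigned:
        pfs.append(ProteinFamily(f"PF{next_id:05d}", [g]))
        next_id += 1
    logger.info("COG-triangle clustering: %d families (%d singletons)",
                len(pfs), len(unassigned))
    return pfs


# ---------------------------------------------------------------------------
# paralog curation
# ---------------------------------------------------------------------------


def paralog_merge(
    pfs: list[ProteinFamily],
    proteomes: dict[str, list[SequenceRecord]],
    identity_cutoff: float = 60.0,
    min_coverage: float = 0.70,
) -> list[ProteinFamily]:
    """Merge families whose same-genome members are in-paralogs.

    A lineage-wide duplication puts the second copies into their own
    reciprocal-best-hit cluster; the copy-number scoring step resolves
    this by aligning same-genome members of different families and
    merging the families when identity >= ``identity_cutoff`` percent
    over >= ``min_coverage`` of the shorter sequence (the
    ortholog/paralog discrimination rule applied within genomes).
    """
    parent = {pf.pf_id: pf.pf_id for pf in pfs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pf_of = {m: pf.pf_id for pf in pfs for m in pf.members}
    merged_pairs = 0
    for genome in sorted(proteomes):
        prots = proteomes[genome]
        idx = {p.id: k for k, p in enumerate(prots)}
        hits = pairwise_proteome_hits(prots, prots)
        for h in hits:
            if h.query_id >= h.subject_id:  # one direction, skip self
                continue
            a = pf_of.get((genome, h.query_id))
            b = pf_of.get((genome, h.subject_id))
            if a is None or b is None or find(a) == find(b):
                continue
            if h.identity_pct >= identity_cutoff \
                    and h.shorter_cov >= min_coverage:
                parent[max(find(a), find(b))] = min(find(a), find(b))
                merged_pairs += 1
        del idx
    groups: dict[str, list[ProteinFamily]] = {}
    for pf in pfs:
        groups.setdefault(find(pf.pf_id), []).append(pf)
    out = []
    for root in sorted(groups):
        members = sorted({m for pf in groups[root] for m in pf.members})
        out.append(ProteinFamily(root, members))
    if merged_pairs:
        logger.info("in-paralog curation merged %d family pairs",
                    merged_pairs)
    return out


def _neighbor_pfs(genome: str, gene: str, gene_tables: dict[str, GeneTable],
                  assignment: dict[tuple[str, str], str], window: int = 2) -> set[str]:
    df = gene_tables[genome].df
    idx = df.index[df["gene_id"] == gene]
    if len(idx) == 0:
        return set()
    i = int(idx[0])
    contig = df.at[i, "contig_id"]
    out = set()
    for j in range(max(0, i - window), min(len(df), i + window + 1)):
        if j == i or df.at[j, "contig_id"] != contig:
            continue
        pf = assignment.get((genome, df.at[j, "gene_id"]))
        if pf is not None:
            out.add(pf)
    return out


def paralog_split(
    pfs: list[ProteinFamily],
    proteomes: dict[str, list[SequenceRecord]],
    gene_tables: dict[str, GeneTable] | None = None,
    identity_cutoff: float = 60.0,
) -> list[ProteinFamily]:
    """Split out same-genome copies that are not credible in-paralogs.

    Within each multi-copy family, same-genome extra copies are compared
    with a representative member from another genome (lexicographically
    first; or the first copy in a single-genome family); copies below
    ``identity_cutoff`` percent identity to it are split into new
    families — unless their +/-2-gene neighborhood shares a PF with the
    neighborhoods of other members (genomic-context rescue, an automated
    stand-in for manual curation; rescued copies are kept and flagged in
    the log).
    """
    seq_of = {(g, p.id): p for g, prots in proteomes.items() for p in prots}
    aligner = protein_aligner()
    assignment = {m: pf.pf_id for pf in pfs for m in pf.members}
    out: list[ProteinFamily] = []
    n_split = 0
    next_id = max((int(pf.pf_id[2:]) for pf in pfs), default=0) + 1
    for pf in pfs:
        multi = {g for g, d in pf.dose.items() if d > 1}
        if not multi:
            out.append(pf)
            continue
        split_members: list[tuple[str, str]] = []
        for genome in sorted(multi):
            copies = [m for m in pf.members if m[0] == genome]
            others = [m for m in pf.members if m[0] != genome]
            ref = others[0] if others else copies[0]
            kept_here = [ref] if ref in copies else []
            for m in copies:
                if m == ref:
                    continue
                hit = align_proteins(seq_of[m], seq_of[ref], aligner)
                ident = hit.identity_pct if hit else 0.0
                if ident >= identity_cutoff:
                    kept_here.append(m)
                    continue
                if gene_tables is not None:
                    mine = _neighbor_pfs(m[0], m[1], gene_tables, assignment)
                    rest: set[str] = set()
                    for o in kept_here + others:
                        rest |= _neighbor_pfs(o[0], o[1], gene_tables,
                                              assignment)
                    if mine & rest:
                        logger.info("paralog %s/%s rescued by genomic context",
                                    m[0], m[1])
                        kept_here.append(m)
                        continue
                split_members.append(m)
        keep = [m for m in pf.members if m not in split_members]
        out.append(ProteinFamily(pf.pf_id, sorted(keep)))
        for m in split_members:
            out.append(ProteinFamily(f"PF{next_id:05d}", [m]))
            next_id += 1
            n_split += 1
    if n_split:
        logger.info("paralog curation split %d copies into new families",
                    n_split)
    return [pf for pf in out if pf.members]


# ---------------------------------------------------------------------------
# profile, compartments, summaries
# ---------------------------------------------------------------------------


@dataclass
class PangenomeProfile:
    matrix: pd.DataFrame            # PF x genome dose matrix
    compartments: pd.Series         # PF -> {core, flexible, exclusive}
    lineage_map: pd.DataFrame       # genome, genus, species

    @property
    def pangenome_size(self) -> int:
        return len(self.matrix)

    @property
    def core_size(self) -> int:
        return int((self.compartments == "core").sum())

    def compartment_sizes(self) -> dict[str, int]:
        return {c: int((self.compartments == c).sum())
                for c in ("core", "flexible", "exclusive")}


def profile_from_dose_matrix(
    matrix: pd.DataFrame,
    lineage_map: pd.DataFrame,
    core_occupancy: float = 1.0,
) -> PangenomeProfile:
    """Assign compartments to a PF x genome dose matrix.

    core: present (dose >= 1) in >= ``core_occupancy`` of genomes;
    exclusive: confined to a single species-level lineage (and not core);
    flexible: the remainder.
    """
    genomes = list(matrix.columns)
    missing = set(genomes) - set(lineage_map["genome"])
    if missing:
        raise OgripanError(f"genomes missing from lineage map: {sorted(missing)}")
    species_of = dict(zip(lineage_map["genome"], lineage_map["species"]))
    present = matrix >= 1
    occupancy = present.sum(axis=1) / len(genomes)
    comp = []
    for pf in matrix.index:
        if occupancy[pf] >= core_occupancy:
            comp.append("core")
        else:
            lineages = {species_of[g] for g in genomes if present.at[pf, g]}
            comp.append("exclusive" if len(lineages) == 1 else "flexible")
    return PangenomeProfile(matrix.copy(),
                            pd.Series(comp, index=matrix.index),
                            lineage_map)


def build_pangenome_profile(
    pfs: list[ProteinFamily],
    genomes: list[str],
    lineage_map: pd.DataFrame,
    core_occupancy: float = 1.0,
) -> PangenomeProfile:
    mat = pd.DataFrame(0, index=[pf.pf_id for pf in pfs],
                       columns=list(genomes), dtype=int)
    for pf in pfs:
        for g, d in pf.dose.items():
            mat.at[pf.pf_id, g] = d
    return profile_from_dose_matrix(mat, lineage_map, core_occupancy)


@dataclass
class HeapsFit:
    """Power-law fit n(N) = kappa * N^(-alpha) to median new-PF counts."""

    kappa: float
    alpha: float
    n_permutations: int
    rng_seed: int
    flagged: bool = False
    median_new: list[float] = field(default_factory=list)

    @property
    def is_open(self) -> bool:
        if self.flagged:
            raise OgripanError("Heaps fit is flagged undefined")
        return self.alpha < 1.0


def heaps_fit(profile: PangenomeProfile, n_permutations: int = 100,
              seed: int = 0) -> HeapsFit:
    """Tettelin-style openness fit.

    For each random permutation of genome order, count PFs first seen at
    each addition step; fit the median counts over permutations by
    least squares on logs over N >= 2 (only steps with positive medians).
    alpha < 1 reads as an open pangenome.  All-identical genomes (no new
    PFs beyond the first step) yield a flagged, undefined fit.
    """
    genomes = list(profile.matrix.columns)
    if len(genomes) < 4:
        raise OgripanError("Heaps fit needs >= 4 genomes")
    present = (profile.matrix >= 1).to_numpy()
    rng = np.random.default_rng(seed)
    n = len(genomes)
    new_counts = np.zeros((n_permutations, n), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen = np.zeros(len(profile.matrix), dtype=bool)
        for step, g in enumerate(order):
            fresh = present[:, g] & ~seen
            new_counts[p, step] = int(fresh.sum())
            seen |= fresh
    medians = np.median(new_counts, axis=0)
    ns = np.arange(1, n + 1)
    mask = (ns >= 2) & (medians > 0)
    if mask.sum() < 2:
        return HeapsFit(float("nan"), float("nan"), n_permutations, seed,
                        flagged=True, median_new=medians.tolist())
    slope, intercept = np.polyfit(np.log(ns[mask]), np.log(medians[mask]), 1)
    return HeapsFit(float(math.exp(intercept)), float(-slope),
                    n_permutations, seed, median_new=medians.tolist())


@dataclass
class PangenomeSummary:
    pangenome_size: int
    core_size: int
    flexible_size: int
    exclusive_size: int
    mean_genome_pf_count: float
    mean_fraction_of_pangenome: float
    copy_number_variable_fraction: float
    dose_range: tuple[int, int]
    core_vs_n_correlation: float = float("nan")


def pangenome_summary(profile: PangenomeProfile) -> PangenomeSummary:
    """Headline pangenome statistics.

    ``copy_number_variable_fraction`` is the fraction of genes that belong
    to copy-number-variable PFs (dose >= 2 in at least one genome);
    ``dose_range`` spans the carrier doses seen in those PFs.
    When >= 3 species-level lineages are present, the Pearson correlation
    between per-lineage core size and lineage sample size is included.
    """
    mat = profile.matrix
    present = mat >= 1
    sizes = profile.compartment_sizes()
    per_genome = present.sum(axis=0)
    n_pf = len(mat)
    carrier_max = mat.max(axis=1)
    carrier_min = mat.where(present).min(axis=1)
    variable = carrier_max >= 2
    genes_total = int(mat.to_numpy().sum())
    genes_variable = int(mat.loc[variable].to_numpy().sum())
    if variable.any():
        dose_range = (int(carrier_min[variable].min()),
                      int(carrier_max[variable].max()))
    else:
        dose_range = (0, 0)
    corr = float("nan")
    lineages = profile.lineage_map.groupby("species")["genome"].apply(list)
    if len(lineages) >= 3:
        core_sizes, ns = [], []
        for genomes in lineages:
            cols = [g for g in genomes if g in mat.columns]
            sub = present[cols]
            carried = sub.any(axis=1)
            core_sizes.append(int(sub.loc[carried].all(axis=1).sum()))
            ns.append(len(cols))
        if len(set(ns)) > 1 and len(set(core_sizes)) > 1:
            corr = float(np.corrcoef(ns, core_sizes)[0, 1])
    return PangenomeSummary(
        pangenome_size=n_pf,
        core_size=sizes["core"],
        flexible_size=sizes["flexible"],
        exclusive_size=sizes["exclusive"],
        mean_genome_pf_count=float(per_genome.mean()),
        mean_fraction_of_pangenome=float((per_genome / n_pf).mean()),
        copy_number_variable_fraction=(genes_variable / genes_total
                                       if genes_total else 0.0),
        dose_range=dose_range,
        core_vs_n_correlation=corr,
    )


def cluster_dataset(
    data: GenomeSet,
    lineage_map: pd.DataFrame,
    min_coverage: float = 0.75,
    min_score: float = 50.0,
    identity_cutoff: float = 60.0,
    core_occupancy: float = 1.0,
    _hits: pd.DataFrame | None = None,
) -> tuple[list[ProteinFamily], PangenomeProfile]:
    """Convenience pipeline: hits -> triangles -> curation -> profile."""
    hits = _hits if _hits is not None else all_vs_all_protein_hits(
        data.proteomes, min_coverage, min_score)
    all_genes = sorted((g, p.id) for g, prots in data.proteomes.items()
                       for p in prots)
    pfs = cluster_cog_triangles(hits, all_genes,
                                recruit_identity=identity_cutoff)
    pfs = paralog_merge(pfs, data.proteomes, identity_cutoff)
    pfs = paralog_split(pfs, data.proteomes, data.gene_tables,
                        identity_cutoff)
    profile = build_pangenome_profile(pfs, data.ids, lineage_map,
                                      core_occupancy)
    return pfs, profile
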