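"""Concatenated single-copy-marker distance phylogenomics.

Markers are protein families filtered for occupancy, copy number, length
homogeneity and sequence integrity; their (positionally defined)
alignments are concatenated into a supermatrix, trimmed at a gap-fraction
threshold, converted to p or Poisson-corrected distances, and fed to a
Saitou-Nei neighbor-joining implementation with column-bootstrap
supports.  Robinson-Foulds distance on non-trivial bipartitions serves as
the tree-comparison metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .io_core import OgripanError, SequenceRecord, logger, read_newick
from .pangenome import PangenomeProfile

__all__ = [
    "MarkerSet", "Supermatrix", "AlignmentStats",
    "select_markers", "concatenate_and_trim", "parsimony_informative_count",
    "protein_distance", "nj_tree", "bootstrap_support", "robinson_foulds",
]

GAP = "-"


@dataclass
class MarkerSet:
    """Single-copy marker families and their per-genome sequences."""

    sequences: dict[str, dict[str, SequenceRecord]]  # pf -> genome -> protein
    criteria: dict = field(default_factory=dict)

    @property
    def pf_ids(self) -> list[str]:
        return sorted(self.sequences)


def select_markers(
    profile: PangenomeProfile,
    proteomes: dict[str, list[SequenceRecord]],
    pfs,
    min_occupancy: float = 1.0,
    max_copies: int = 1,
    len_tolerance: float = 0.25,
    max_x_fraction: float = 0.02,
) -> MarkerSet:
    """Filter families for use as concatenated phylogenomic markers.

    Keeps PFs present in >= ``min_occupancy`` of genomes with <=
    ``max_copies`` everywhere, every member length within
    ``len_tolerance`` of the family median, and X/stop fraction <=
    ``max_x_fraction`` (gene-integrity check).
    """
    mat = profile.matrix
    genomes = list(mat.columns)
    seq_of = {}
    for genome, prots in proteomes.items():
        for p in prots:
            seq_of[(genome, p.id)] = p
    # map pf -> genome -> records
    by_pf: dict[str, dict[str, list[SequenceRecord]]] = {}
    for pf in pfs:
        for genome, gene in pf.members:
            by_pf.setdefault(pf.pf_id, {}).setdefault(genome, []).append(
                seq_of[(genome, gene)])

    selected: dict[str, dict[str, SequenceRecord]] = {}
    reasons = {"occupancy": 0, "copies": 0, "length": 0, "integrity": 0,
               "kept": 0}
    for pf_id in sorted(by_pf):
        fam = by_pf[pf_id]
        present = mat.loc[pf_id] >= 1 if pf_id in mat.index else None
        occupancy = (present.sum() / len(genomes)) if present is not None \
            else len(fam) / len(genomes)
        if occupancy < min_occupancy:
            reasons["occupancy"] += 1
            continue
        if any(len(v) > max_copies for v in fam.values()):
            reasons["copies"] += 1
            continue
        lens = [len(v[0].seq) for v in fam.values()]
        med = float(np.median(lens))
        if any(abs(l - med) > len_tolerance * med for l in lens):
            reasons["length"] += 1
            continue
        if any(
            (v[0].seq.count("X") + v[0].seq.count("*")) / max(len(v[0].seq), 1)
            > max_x_fraction
            for v in fam.values()
        ):
            reasons["integrity"] += 1
            continue
        reasons["kept"] += 1
        selected[pf_id] = {g: v[0] for g, v in fam.items()}
    if not selected:
        raise OgripanError(
            "no markers survive the filters; relax min_occupancy")
    logger.info("marker selection: %s", reasons)
    return MarkerSet(selected, {
        "min_occupancy": min_occupancy, "max_copies": max_copies,
        "len_tolerance": len_tolerance, "max_x_fraction": max_x_fraction,
        "filter_counts": reasons,
    })


@dataclass
class Supermatrix:
    """Concatenated genome x column protein character matrix."""

    genome_ids: list[str]
    chars: np.ndarray               # (n_genomes, n_columns) of single chars
    partitions: dict[str, tuple[int, int]]  # marker -> [start, end)

    @property
    def n_columns(self) -> int:
        return self.chars.shape[1]

    def row(self, genome: str) -> str:
        return "".join(self.chars[self.genome_ids.index(genome)])

    @property
    def gap_fraction(self) -> float:
        return float((self.chars == GAP).mean()) if self.chars.size else 0.0


@dataclass
class AlignmentStats:
    n_columns: int
    n_parsimony_informative: int
    gap_fraction: float


def concatenate_and_trim(
    marker_set: MarkerSet,
    gap_threshold: float = 0.5,
) -> tuple[Supermatrix, AlignmentStats]:
    """Concatenate markers (sorted pf_id order) and drop gappy columns.

    Within each marker all member sequences must have equal length
    (positionally defined alignment; substitution-only data or
    user-supplied aligned FASTA).  Genomes missing a marker are padded
    with gaps.  Columns whose gap fraction exceeds ``gap_threshold`` are
    removed and the partition map updated.
    """
    genomes = sorted({g for fam in marker_set.sequences.values() for g in fam})
    blocks = []
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for pf_id in marker_set.pf_ids:
        fam = marker_set.sequences[pf_id]
        lens = {len(rec.seq) for rec in fam.values()}
        if len(lens) != 1:
            raise OgripanError(
                f"marker {pf_id} has unequal member lengths {sorted(lens)}; "
                "supply aligned sequences")
        length = lens.pop()
        block = np.full((len(genomes), length), GAP, dtype="<U1")
        for gi, genome in enumerate(genomes):
            if genome in fam:
                block[gi] = list(fam[genome].seq)
        blocks.append(block)
        partitions[pf_id] = (col, col + length)
        col += length
    chars = np.concatenate(blocks, axis=1) if blocks else np.empty((0, 0))
    gap_frac = (chars == GAP).mean(axis=0)
    keep = gap_frac <= gap_threshold
    removed = int((~keep).sum())
    # remap partitions onto the trimmed coordinate system
    kept_before = np.concatenate([[0], np.cumsum(keep)])
    new_parts = {}
    for pf_id, (s, e) in partitions.items():
        ns, ne = int(kept_before[s]), int(kept_before[e])
        if ne > ns:
            new_parts[pf_id] = (ns, ne)
    sm = Supermatrix(genomes, chars[:, keep], new_parts)
    stats = AlignmentStats(sm.n_columns, parsimony_informative_count(sm),
                           sm.gap_fraction)
    logger.info("supermatrix: %d genomes x %d columns (%d trimmed)",
                len(genomes), sm.n_columns, removed)
    return sm, stats


def parsimony_informative_count(sm: Supermatrix) -> int:
    """Columns with >= 2 distinct non-gap states each in >= 2 rows."""
    count = 0
    for j in range(sm.n_columns):
        col = sm.chars[:, j]
        states, freqs = np.unique(col[col != GAP], return_counts=True)
        if (freqs >= 2).sum() >= 2:
            count += 1
    return count


def protein_distance(
    sm: Supermatrix,
    model: str = "poisson",
    min_overlap: int = 50,
) -> pd.DataFrame:
    """Pairwise distances with pairwise gap deletion.

    ``p``: mismatches/overlap; ``poisson``: -ln(1 - p).  Pairs with
    overlap < ``min_overlap`` columns, or p >= 1 under poisson, are
    flagged NaN.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    ids = sm.genome_ids
    n = len(ids)
    d = np.zeros((n, n))
    gap = sm.chars == GAP
    for i, j in combinations(range(n), 2):
        ok = ~gap[i] & ~gap[j]
        overlap = int(ok.sum())
        if overlap < min_overlap:
            d[i, j] = d[j, i] = np.nan
            continue
        p = float((sm.chars[i, ok] != sm.chars[j, ok]).sum()) / overlap
        if model == "poisson":
            if p >= 1:
                d[i, j] = d[j, i] = np.nan
                continue
            val = -np.log(1.0 - p)
        else:
            val = p
        d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties on minimal Q break by the lexicographically lowest taxon pair;
    negative branch lengths are clamped to 0 with the deficit logged.
    Returns an unrooted tree (trifurcating seed node for n >= 3).
    """
    ids = list(dist.index)
    d = dist.to_numpy(dtype=float).copy()
    if np.isnan(d).any():
        raise OgripanError("incomplete distance matrix")
    if len(ids) < 3:
        raise OgripanError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(ids)
    nodes = []
    for label in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    names = list(ids)
    deficit = 0.0

    while len(nodes) > 3:
        m = len(nodes)
        tot = d.sum(axis=1)
        best = None
        for i, j in combinations(range(m), 2):
            q = (m - 2) * d[i, j] - tot[i] - tot[j]
            key = (q, *sorted((names[i], names[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (tot[i] - tot[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        for v in (vi, vj):
            if v < 0:
                deficit += -v
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)],
                       dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
        names = [names[x] for x in keep] + [f"({min(names[i], names[j])})"]

    root = dendropy.Node()
    if len(nodes) == 3:
        # closed-form three-point branch lengths
        a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        b = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        c = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for node, v in zip(nodes, (a, b, c)):
            if v < 0:
                deficit += -v
            node.edge.length = max(v, 0.0)
            root.add_child(node)
    else:  # n == 2 cannot happen (guarded above); n==3 after loop
        for node in nodes:
            root.add_child(node)
    if deficit:
        logger.info("NJ clamped negative branch lengths (total deficit %.4g)",
                    deficit)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, RF, bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonicalized leaf-name sets."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if anchor in below else leaves - below
        if len(side) >= 2 and len(leaves) - len(side) >= 2:
            out.add(side)
    return out


def robinson_foulds(t1: dendropy.Tree | str, t2: dendropy.Tree | str) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if isinstance(t1, str):
        t1 = read_newick(t1)
    if isinstance(t2, str):
        t2 = read_newick(t2)
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise OgripanError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    return len(b1 ^ b2)


def _distance_from_chars(chars: np.ndarray, gap: np.ndarray, ids,
                         model: str, min_overlap: int) -> pd.DataFrame:
    n = chars.shape[0]
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ok = ~gap[i] & ~gap[j]
        overlap = int(ok.sum())
        if overlap < min_overlap:
            d[i, j] = d[j, i] = np.nan
            continue
        p = float((chars[i, ok] != chars[j, ok]).sum()) / overlap
        if model == "poisson":
            p = min(p, 0.999999)
            val = -np.log(1.0 - p)
        else:
            val = p
        d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=ids, columns=ids)


def bootstrap_support(
    sm: Supermatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "poisson",
    min_overlap: int = 50,
) -> dendropy.Tree:
    """NJ point-estimate tree with column-bootstrap supports.

    Columns are resampled with replacement per replicate; the support of
    each internal bipartition of the point tree is the percent of
    replicate trees containing it, stored as the internal node label.
    Deterministic given ``seed``.
    """
    point = nj_tree(protein_distance(sm, model, min_overlap))
    target = _bipartitions(point)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    gap_all = sm.chars == GAP
    for _ in range(n_replicates):
        idx = rng.integers(0, sm.n_columns, sm.n_columns)
        chars = sm.chars[:, idx]
        d = _distance_from_chars(chars, gap_all[:, idx], sm.genome_ids,
                                 model, min_overlap)
        rep = nj_tree(d)
        for bp in _bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    leaves = frozenset(sm.genome_ids)
    anchor = min(leaves)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if anchor in below else leaves - below
        if side in counts:
            node.label = f"{100.0 * counts[side] / n_replicates:.0f}"
    return point


def mean_support(tree: dendropy.Tree) -> float:
    vals = [float(n.label) for n in tree.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
            and n.parent_node is not None]
    if not vals:
        raise OgripanError("tree carries no support labels")
    return float(np.mean(vals))
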