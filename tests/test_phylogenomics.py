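from collections import Counter
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
import pytest

from ogripan.io_core import OgripanError, SequenceRecord, read_newick
from ogripan.pangenome import ProteinFamily, build_pangenome_profile
from ogripan.phylogenomics import (
    MarkerSet,
    Supermatrix,
    bootstrap_support,
    concatenate_and_trim,
    mean_support,
    nj_tree,
    parsimony_informative_count,
    protein_distance,
    robinson_foulds,
    select_markers,
)
from test_io_core import _random_tree_newick


def _family_setup(fams):
    """fams: pf -> genome -> protein string."""
    proteomes = {}
    pfs = []
    for pf_id, members in fams.items():
        pf_members = []
        for genome, seqs in members.items():
            if isinstance(seqs, str):
                seqs = [seqs]
            for i, s in enumerate(seqs):
                gene = f"{genome}_{pf_id}_{i}"
                proteomes.setdefault(genome, []).append(
                    SequenceRecord(gene, s, "protein"))
                pf_members.append((genome, gene))
        pfs.append(ProteinFamily(pf_id, sorted(pf_members)))
    genomes = sorted(proteomes)
    lineage = pd.DataFrame({"genome": genomes, "genus": "G",
                            "species": "S"})
    profile = build_pangenome_profile(pfs, genomes, lineage)
    return profile, proteomes, pfs


def test_select_markers_keeps_clean_single_copy():
    profile, proteomes, pfs = _family_setup({
        "PF1": {"a": "MKVLITGASG", "b": "MKVLITGASG", "c": "MKVLITGASG"},
        "PF2": {"a": "MKWWITGASG", "b": "MKWWITGASG"},          # occupancy
        "PF3": {"a": ["MKYLITGASG", "MKYLITGASG"], "b": "MKYLITGASG",
                "c": "MKYLITGASG"},                             # copies
        "PF4": {"a": "MK", "b": "MKVLITGASGMKVLITGASG",
                "c": "MKVLITGASG"},                             # length
        "PF5": {"a": "MKXXITGASG", "b": "MKXXITGASG",
                "c": "MKXXITGASG"},                             # integrity
    })
    ms = select_markers(profile, proteomes, pfs)
    assert ms.pf_ids == ["PF1"]
    counts = ms.criteria["filter_counts"]
    assert counts == {"occupancy": 1, "copies": 1, "length": 1,
                      "integrity": 1, "kept": 1}


def test_select_markers_rates_zero_selects_all(small_sim):
    from ogripan.synthetic_clade import SimulationConfig, simulate_clade
    from ogripan.pangenome import profile_from_dose_matrix
    ds = simulate_clade(SimulationConfig(
        tree="((A:0.01,B:0.01):0.05,(C:0.02,D:0.02):0.05);",
        n_genes=10, gene_len_mean=60, gain_rate=0, loss_rate=0, dup_rate=0,
        rng_seed=2))
    profile = profile_from_dose_matrix(ds.truth.dose_matrix(),
                                       ds.truth.lineage_map)
    pfs = [ProteinFamily(fam, sorted(
        (g, p.id) for g, prots in ds.data.proteomes.items() for p in prots
        if p.description == fam))
        for fam in ds.truth.family_history]
    ms = select_markers(profile, ds.data.proteomes, pfs)
    assert len(ms.pf_ids) == 10


def test_select_markers_zero_survivors_raises():
    profile, proteomes, pfs = _family_setup({
        "PF1": {"a": "MKVLITGASG", "b": "MKVLITGASG"}})
    with pytest.raises(OgripanError, match="relax"):
        select_markers(profile, proteomes, pfs, min_occupancy=1.0,
                       max_copies=0)


def test_concatenate_gap_free():
    profile, proteomes, pfs = _family_setup({
        "PF1": {"a": "MKVLI", "b": "MKVLI", "c": "MKVLI"},
        "PF2": {"a": "WWYY", "b": "WWYY", "c": "WWYF"},
    })
    ms = select_markers(profile, proteomes, pfs, min_occupancy=0.5)
    sm, stats = concatenate_and_trim(ms)
    assert stats.n_columns == 9
    assert stats.gap_fraction == 0.0
    assert sm.partitions == {"PF1": (0, 5), "PF2": (5, 9)}


def test_trim_removes_gappy_marker_columns():
    # PF2 present in 2 of 5 genomes -> its columns are 60% gaps -> removed
    profile, proteomes, pfs = _family_setup({
        "PF1": {g: "MKVLI" for g in "abcde"},
        "PF2": {"a": "WW", "b": "WW"},
    })
    ms = select_markers(profile, proteomes, pfs, min_occupancy=0.3)
    sm, stats = concatenate_and_trim(ms, gap_threshold=0.5)
    assert stats.n_columns == 5
    assert "PF2" not in sm.partitions


def test_unequal_marker_lengths_rejected():
    ms = MarkerSet({"PF1": {
        "a": SequenceRecord("a_1", "MKV", "protein"),
        "b": SequenceRecord("b_1", "MKVL", "protein")}})
    with pytest.raises(OgripanError, match="unequal"):
        concatenate_and_trim(ms)


def _sm(rows, ids=None):
    rows = [list(r) for r in rows]
    ids = ids or [f"t{i}" for i in range(len(rows))]
    chars = np.array(rows, dtype="<U1")
    return Supermatrix(ids, chars, {"m": (0, chars.shape[1])})


def test_parsimony_definition():
    assert parsimony_informative_count(_sm(["AAAA"] * 4)) == 0
    assert parsimony_informative_count(_sm(["A", "A", "V", "V"])) == 1
    assert parsimony_informative_count(_sm(["A", "A", "A", "V"])) == 0
    # gaps are not a state
    assert parsimony_informative_count(_sm(["A", "A", "-", "-"])) == 0


def test_parsimony_matches_brute_force_and_row_permutation():
    rng = np.random.default_rng(5)
    chars = rng.choice(list("AVLIG-"), size=(8, 100))
    sm = Supermatrix([f"t{i}" for i in range(8)], chars, {})
    count = parsimony_informative_count(sm)
    brute = 0
    for j in range(100):
        freq = Counter(c for c in chars[:, j] if c != "-")
        if sum(1 for v in freq.values() if v >= 2) >= 2:
            brute += 1
    assert count == brute
    perm = rng.permutation(8)
    sm_p = Supermatrix([f"t{i}" for i in perm], chars[perm], {})
    assert parsimony_informative_count(sm_p) == count


def test_protein_distance_arithmetic():
    a = "A" * 100
    b = "A" * 90 + "V" * 10
    sm = _sm([a, b, a])
    d_p = protein_distance(sm, "p")
    assert d_p.iloc[0, 1] == pytest.approx(0.10)
    assert d_p.iloc[0, 2] == 0.0
    d_poi = protein_distance(sm, "poisson")
    assert d_poi.iloc[0, 1] == pytest.approx(-np.log(0.9))


def test_protein_distance_flags_low_overlap():
    sm = _sm(["A" * 30 + "-" * 70, "-" * 70 + "A" * 30, "A" * 100])
    d = protein_distance(sm, "p", min_overlap=50)
    assert np.isnan(d.iloc[0, 1])


def _additive_distances(newick):
    tree = read_newick(newick)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=ids, columns=ids)


def test_nj_three_taxa_closed_form():
    d = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                     index=list("ABC"), columns=list("ABC"), dtype=float)
    tree = nj_tree(d)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == {"A": 2.0, "B": 3.0, "C": 7.0}


@pytest.mark.parametrize("seed", range(6))
def test_nj_consistent_on_additive_matrices(seed):
    """NJ must recover topology and branch lengths exactly from any
    additive (tree-derived) distance matrix."""
    rng = np.random.default_rng(seed)
    nwk = _random_tree_newick(rng, 8)
    d = _additive_distances(nwk)
    tree = nj_tree(d)
    assert robinson_foulds(tree, nwk) == 0
    total_true = sum(e.length for e in read_newick(nwk).preorder_edge_iter()
                     if e.length)
    total_nj = sum(e.length for e in tree.preorder_edge_iter() if e.length)
    # unrooted NJ merges the two root-adjacent edges; total length matches
    assert total_nj == pytest.approx(total_true, abs=1e-9)


def test_nj_cross_checked_against_scikit_bio():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    rng = np.random.default_rng(10)
    base = _additive_distances(_random_tree_newick(rng, 7))
    noisy = base + rng.uniform(0, 0.01, base.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy.values, 0)
    ours = nj_tree(noisy)
    theirs = skbio_nj(DistanceMatrix(noisy.to_numpy(), ids=list(noisy.index)))
    assert robinson_foulds(ours, str(theirs).strip()) == 0


def test_nj_deterministic_under_ties():
    d = pd.DataFrame(1.0 - np.eye(4), index=list("ABCD"), columns=list("ABCD"))
    from ogripan.io_core import write_newick
    t1, t2 = nj_tree(d.copy()), nj_tree(d.copy())
    assert write_newick(t1) == write_newick(t2)


def test_nj_rejects_incomplete():
    d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("AB"),
                     columns=list("AB"))
    with pytest.raises(OgripanError):
        nj_tree(d)


def test_rf_trivial_and_enumerable():
    t = "((A:1,B:1):1,(C:1,D:1):1);"
    assert robinson_foulds(t, t) == 0
    other = "((A:1,C:1):1,(B:1,D:1):1);"
    assert robinson_foulds(t, other) == 2


@pytest.mark.parametrize("seed", range(5))
def test_rf_equals_dendropy_oracle(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = _random_tree_newick(rng, 10), _random_tree_newick(rng, 10)
    # rename leaves so both trees share the same set
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    expected = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    assert robinson_foulds(read_newick(n1), read_newick(n2)) == expected


def test_bootstrap_deterministic_and_binary_at_one_replicate():
    rng = np.random.default_rng(3)
    chars = rng.choice(list("AVLI"), size=(6, 60))
    sm = Supermatrix([f"t{i}" for i in range(6)], chars, {})
    t1 = bootstrap_support(sm, n_replicates=20, seed=4)
    t2 = bootstrap_support(sm, n_replicates=20, seed=4)
    from ogripan.io_core import write_newick
    assert write_newick(t1) == write_newick(t2)
    tb = bootstrap_support(sm, n_replicates=1, seed=4)
    sups = [float(n.label) for n in tb.preorder_node_iter()
            if n.label and not n.is_leaf()]
    assert set(sups) <= {0.0, 100.0}


def test_bootstrap_saturated_signal_max_support():
    """Every column repeated 50x: all bipartitions supported >= 99%."""
    rng = np.random.default_rng(8)
    base = rng.choice(list("AVLIGSTD"), size=(6, 30))
    chars = np.repeat(base, 50, axis=1)
    sm = Supermatrix([f"t{i}" for i in range(6)], chars, {})
    tree = bootstrap_support(sm, n_replicates=50, seed=2)
    assert mean_support(tree) >= 99.0
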