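from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ogripan.io_core import OgripanError, SequenceRecord
from ogripan.pangenome import (
    ProteinFamily,
    all_vs_all_protein_hits,
    build_pangenome_profile,
    cluster_cog_triangles,
    heaps_fit,
    pangenome_summary,
    paralog_split,
    profile_from_dose_matrix,
)
from ogripan.synthetic_clade import SimulationConfig, simulate_clade

LINEAGE3 = pd.DataFrame({
    "genome": ["g1", "g2", "g3"],
    "genus": ["G1"] * 3,
    "species": ["S1", "S1", "S2"],
})


def _hit_frame(rows):
    return pd.DataFrame(rows, columns=[
        "query_genome", "query_id", "subject_genome", "subject_id",
        "score", "identities", "aln_len", "identity_pct"])


def _mutual(a_genome, a_gene, b_genome, b_gene, score=100.0, ident=95.0):
    return [
        {"query_genome": a_genome, "query_id": a_gene,
         "subject_genome": b_genome, "subject_id": b_gene,
         "score": score, "identities": 90, "aln_len": 100,
         "identity_pct": ident},
        {"query_genome": b_genome, "query_id": b_gene,
         "subject_genome": a_genome, "subject_id": a_gene,
         "score": score, "identities": 90, "aln_len": 100,
         "identity_pct": ident},
    ]


def test_triangle_of_three_genomes_is_one_family():
    rows = (_mutual("g1", "a", "g2", "b") + _mutual("g1", "a", "g3", "c")
            + _mutual("g2", "b", "g3", "c"))
    pfs = cluster_cog_triangles(_hit_frame(rows))
    assert len(pfs) == 1 and len(pfs[0].members) == 3


def test_disjoint_triangles_stay_separate():
    rows = []
    for gene in ("x", "y"):
        rows += (_mutual("g1", f"{gene}1", "g2", f"{gene}2")
                 + _mutual("g1", f"{gene}1", "g3", f"{gene}3")
                 + _mutual("g2", f"{gene}2", "g3", f"{gene}3"))
    pfs = cluster_cog_triangles(_hit_frame(rows))
    assert sorted(len(pf.members) for pf in pfs) == [3, 3]


def test_unclustered_genes_become_singletons():
    rows = _mutual("g1", "a", "g2", "b")  # RBH pair but no triangle
    pfs = cluster_cog_triangles(_hit_frame(rows), recruit_identity=None)
    assert sorted(len(pf.members) for pf in pfs) == [1, 1]


def _oracle_triangle_clusters(edges, genes):
    """Exhaustive enumeration: all RBH triangles + transitive edge merge."""
    triangles = []
    for trio in combinations(sorted(genes), 3):
        if len({g[0] for g in trio}) != 3:
            continue
        e = [tuple(sorted([trio[0], trio[1]])),
             tuple(sorted([trio[0], trio[2]])),
             tuple(sorted([trio[1], trio[2]]))]
        if all(x in edges for x in e):
            triangles.append(set(e))
    merged = []
    for tri in triangles:
        hit = [c for c in merged if c & tri]
        for c in hit:
            merged.remove(c)
            tri |= c
        merged.append(tri)
    # keep merging until fixed point (edge-sharing transitivity)
    changed = True
    while changed:
        changed = False
        for i, j in combinations(range(len(merged)), 2):
            if merged[i] & merged[j]:
                merged[i] |= merged[j]
                del merged[j]
                changed = True
                break
    return sorted(sorted({g for e in c for g in e}) for c in merged)


@pytest.mark.parametrize("seed", range(4))
def test_clusters_equal_exhaustive_oracle(seed):
    """Random 5-genome RBH graphs: implementation == brute-force oracle."""
    rng = np.random.default_rng(seed)
    genomes = [f"g{i}" for i in range(5)]
    genes = [(g, f"{g}p{k}") for g in genomes for k in range(4)]
    rows = []
    edges = set()
    for a, b in combinations(genes, 2):
        if a[0] == b[0] or rng.random() > 0.25:
            continue
        edges.add(tuple(sorted([a, b])))
    # encode each chosen edge as a mutual best-hit pair, one per query/pair
    seen = set()
    for a, b in sorted(edges):
        if (a, b[0]) in seen or (b, a[0]) in seen:
            edges.discard((a, b))
            continue
        seen.add((a, b[0]))
        seen.add((b, a[0]))
        rows += _mutual(a[0], a[1], b[0], b[1])
    pfs = cluster_cog_triangles(_hit_frame(rows), all_genes=genes,
                                recruit_identity=None)
    got = sorted(sorted(pf.members) for pf in pfs if len(pf.members) > 1)
    expected = _oracle_triangle_clusters(edges, genes)
    assert got == expected


def test_all_vs_all_requires_three_genomes():
    prots = {"g1": [SequenceRecord("p", "MKV" * 30, "protein")],
             "g2": [SequenceRecord("q", "MKV" * 30, "protein")]}
    with pytest.raises(OgripanError, match="3 genomes"):
        all_vs_all_protein_hits(prots)


def test_all_vs_all_coverage_filter():
    full = "MKVLITGASGFIGSHLVDRLMSKGYEVIGLDNFNDYYDVRLKEARLELLAS" * 4
    prots = {"g1": [SequenceRecord("a", full, "protein")],
             "g2": [SequenceRecord("b", full, "protein")],
             "g3": [SequenceRecord("c", full[:int(len(full) * 0.6)],
                                   "protein")]}
    hits = all_vs_all_protein_hits(prots, min_coverage=0.75)
    # the 60%-length fragment cannot cover 75% of a full-length query
    assert not ((hits["query_genome"].isin(["g1", "g2"]))
                & (hits["subject_genome"] == "g3")).any()
    # identical full-length pair is retained at identity 100
    pair = hits[(hits["query_genome"] == "g1")
                & (hits["subject_genome"] == "g2")]
    assert len(pair) == 1 and pair.iloc[0]["identity_pct"] == 100.0


# ---------------------------------------------------------------------------
# paralog curation
# ---------------------------------------------------------------------------

PROT = ("MKVLITGASGFIGSHLVDRLMSKGYEVIGLDNFNDYYDVRLKEARLELLASERFEFVHG"
        "DIRNAELVDELFAEHQPDAVVHLAAQAGVRYSLENPHAYVDSNIVGFLNLLEACRHNHV")


def _mutate(seq, n, seed):
    rng = np.random.default_rng(seed)
    out = list(seq)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for i in rng.choice(len(seq), n, replace=False):
        out[i] = aas[(aas.index(out[i]) + 7) % 20]
    return "".join(out)


def test_tandem_duplicate_kept():
    prots = {
        "g1": [SequenceRecord("a1", PROT, "protein"),
               SequenceRecord("a2", _mutate(PROT, 1, 0), "protein")],
        "g2": [SequenceRecord("b1", PROT, "protein")],
    }
    pf = ProteinFamily("PF00001", [("g1", "a1"), ("g1", "a2"), ("g2", "b1")])
    out = paralog_split([pf], prots)
    assert len(out) == 1 and out[0].dose == {"g1": 2, "g2": 1}


def test_divergent_copy_split():
    rng = np.random.default_rng(1)
    unrelated = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[
        rng.integers(0, 20, len(PROT))])
    prots = {
        "g1": [SequenceRecord("a1", PROT, "protein"),
               SequenceRecord("a2", unrelated, "protein")],
        "g2": [SequenceRecord("b1", PROT, "protein")],
    }
    pf = ProteinFamily("PF00001", [("g1", "a1"), ("g1", "a2"), ("g2", "b1")])
    out = paralog_split([pf], prots)
    assert sorted(len(p.members) for p in out) == [1, 2]
    singleton = next(p for p in out if len(p.members) == 1)
    assert singleton.members == [("g1", "a2")]


def test_no_multicopy_identity_case():
    prots = {"g1": [SequenceRecord("a1", PROT, "protein")],
             "g2": [SequenceRecord("b1", PROT, "protein")]}
    pf = ProteinFamily("PF00001", [("g1", "a1"), ("g2", "b1")])
    assert paralog_split([pf], prots) == [pf]


# ---------------------------------------------------------------------------
# profile / compartments
# ---------------------------------------------------------------------------


def test_profile_compartments():
    mat = pd.DataFrame(
        {"g1": [1, 1, 2, 0], "g2": [1, 1, 0, 0], "g3": [1, 0, 0, 3]},
        index=["pfA", "pfB", "pfC", "pfD"])
    profile = profile_from_dose_matrix(mat, LINEAGE3)
    assert profile.compartments.to_dict() == {
        "pfA": "core", "pfB": "exclusive",  # S1-only
        "pfC": "exclusive", "pfD": "exclusive"}
    assert profile.compartment_sizes() == {"core": 1, "flexible": 0,
                                           "exclusive": 3}


def test_profile_flexible_crosses_lineages():
    mat = pd.DataFrame({"g1": [1], "g2": [0], "g3": [1]}, index=["pfX"])
    profile = profile_from_dose_matrix(mat, LINEAGE3)
    assert profile.compartments["pfX"] == "flexible"


def test_profile_missing_lineage_rejected():
    mat = pd.DataFrame({"gX": [1]}, index=["pf"])
    with pytest.raises(OgripanError, match="lineage"):
        profile_from_dose_matrix(mat, LINEAGE3)


def test_dropping_genome_never_shrinks_core():
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(rng.integers(0, 2, (30, 6)),
                       index=[f"pf{i}" for i in range(30)],
                       columns=[f"g{i}" for i in range(6)])
    lm = pd.DataFrame({"genome": mat.columns, "genus": "G",
                       "species": ["S1"] * 3 + ["S2"] * 3})
    full = profile_from_dose_matrix(mat, lm)
    sub = profile_from_dose_matrix(mat.drop(columns="g5")[mat.drop(
        columns="g5").sum(axis=1) > 0], lm[lm["genome"] != "g5"])
    assert sub.core_size >= full.core_size


def test_pangenome_monotone_under_addition():
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(rng.integers(0, 2, (40, 6)),
                       index=[f"pf{i}" for i in range(40)],
                       columns=[f"g{i}" for i in range(6)])
    present = mat >= 1
    for _ in range(5):
        order = rng.permutation(mat.columns)
        pan_prev, core_prev = 0, len(mat)
        seen = pd.Series(False, index=mat.index)
        core = pd.Series(True, index=mat.index)
        for g in order:
            seen |= present[g]
            core &= present[g]
            assert int(seen.sum()) >= pan_prev
            assert int(core.sum()) <= core_prev
            pan_prev, core_prev = int(seen.sum()), int(core.sum())


# ---------------------------------------------------------------------------
# Heaps fit
# ---------------------------------------------------------------------------

OPEN_TREE = ("(((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05):0.05,"
             "((e:0.05,f:0.05):0.05,(g:0.05,h:0.05):0.05):0.05);")


def _truth_profile(cfg):
    ds = simulate_clade(cfg)
    return profile_from_dose_matrix(ds.truth.dose_matrix(),
                                    ds.truth.lineage_map)


def test_heaps_open_under_sustained_gain():
    from ogripan.synthetic_clade import gain_sustained_config
    alphas = []
    for seed in (1, 2, 3):
        profile = _truth_profile(gain_sustained_config(seed))
        fit = heaps_fit(profile, n_permutations=100, seed=seed)
        assert not fit.flagged and fit.is_open
        alphas.append(fit.alpha)
    assert max(alphas) - min(alphas) <= 0.2  # stable within +/-0.1 of mean


def test_heaps_flagged_for_identical_genomes():
    profile = _truth_profile(SimulationConfig(
        tree=OPEN_TREE, n_genes=50, gene_len_mean=60, gain_rate=0,
        loss_rate=0, dup_rate=0, rng_seed=5))
    fit = heaps_fit(profile, n_permutations=20, seed=1)
    assert fit.flagged
    with pytest.raises(OgripanError):
        fit.is_open


def test_heaps_closed_under_loss_only():
    profile = _truth_profile(SimulationConfig(
        tree=OPEN_TREE, n_genes=150, gene_len_mean=60, gain_rate=0,
        loss_rate=0.5, dup_rate=0, rng_seed=9))
    fit = heaps_fit(profile, n_permutations=100, seed=2)
    assert fit.flagged or fit.alpha > 1.0


def test_heaps_determinism():
    profile = _truth_profile(SimulationConfig(
        tree=OPEN_TREE, n_genes=80, gene_len_mean=60, gain_rate=0.5,
        loss_rate=0.2, dup_rate=0.1, rng_seed=4))
    f1 = heaps_fit(profile, 30, seed=11)
    f2 = heaps_fit(profile, 30, seed=11)
    assert f1 == f2


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


def test_summary_single_genome():
    mat = pd.DataFrame({"g1": [1, 2, 1]}, index=["a", "b", "c"])
    lm = pd.DataFrame({"genome": ["g1"], "genus": ["G"], "species": ["S"]})
    s = pangenome_summary(profile_from_dose_matrix(mat, lm))
    assert s.mean_fraction_of_pangenome == 1.0
    assert s.copy_number_variable_fraction == pytest.approx(2 / 4)
    assert s.dose_range == (2, 2)


def test_summary_fields_consistency():
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(rng.integers(0, 3, (25, 6)),
                       index=[f"pf{i}" for i in range(25)],
                       columns=[f"g{i}" for i in range(6)])
    mat = mat[mat.sum(axis=1) > 0]
    lm = pd.DataFrame({"genome": mat.columns, "genus": "G",
                       "species": [f"S{i // 2}" for i in range(6)]})
    profile = profile_from_dose_matrix(mat, lm)
    s = pangenome_summary(profile)
    assert s.core_size + s.flexible_size + s.exclusive_size == s.pangenome_size
    assert 0 <= s.mean_fraction_of_pangenome <= 1
    assert s.mean_genome_pf_count <= s.pangenome_size


# ---------------------------------------------------------------------------
# full-pipeline truth agreement (gene-level, small instance)
# ---------------------------------------------------------------------------


def test_clustering_partitions_all_genes(small_sim):
    from ogripan.pangenome import cluster_dataset
    pfs, _profile = cluster_dataset(small_sim.data,
                                    small_sim.truth.lineage_map)
    seen = [m for pf in pfs for m in pf.members]
    all_genes = [(g, p.id) for g, prots in small_sim.data.proteomes.items()
                 for p in prots]
    assert sorted(seen) == sorted(all_genes)  # no gene lost or duplicated
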