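import math
from itertools import product

import numpy as np
import pytest

from conftest import random_dna
from ogripan.io_core import OgripanError, SequenceRecord
from ogripan.ogri import (
    AaiResult,
    OgriMatrix,
    TetraProfile,
    aai_pair,
    anib_pair,
    d2_to_ddh,
    ddh_formula2,
    gc_content,
    identity_16s,
    ogri_matrix,
    tetra_correlation,
    tetra_zscores,
    tzmd,
)
from ogripan.synthetic_clade import evolve_sequence, expected_identity


# ---------------------------------------------------------------------------
# G+C
# ---------------------------------------------------------------------------


def test_gc_trivial():
    assert gc_content(SequenceRecord("g", "ATGC")) == 50.0


def test_gc_excludes_ambiguity():
    assert gc_content(SequenceRecord("g", "GGNNRYAT")) == 50.0
    with pytest.raises(OgripanError):
        gc_content(SequenceRecord("g", "NNNN"))


def test_gc_against_independent_counter():
    rng = np.random.default_rng(12)
    seq = "".join(rng.choice(list("ACGT"), 10_000,
                             p=[0.225, 0.275, 0.275, 0.225]))
    expected = round(100 * (seq.count("G") + seq.count("C")) / len(seq), 1)
    assert gc_content(SequenceRecord("g", seq)) == expected


# ---------------------------------------------------------------------------
# TETRA / TZMD
# ---------------------------------------------------------------------------


def _brute_force_tetra(seq: str) -> np.ndarray:
    """Windowed-count oracle applying the Markov z-score formulas."""
    from Bio.Seq import Seq

    strands = [seq, str(Seq(seq).reverse_complement())]
    counts = {k: {} for k in (2, 3, 4)}
    for s in strands:
        for k in (2, 3, 4):
            for i in range(len(s) - k + 1):
                w = s[i:i + k]
                if set(w) <= set("ACGT"):
                    counts[k][w] = counts[k].get(w, 0) + 1
    z = np.zeros(256)
    for idx, word in enumerate("".join(p)
                               for p in product("ACGT", repeat=4)):
        n2 = counts[2].get(word[1:3], 0)
        if n2 == 0:
            continue
        left = counts[3].get(word[:3], 0)
        right = counts[3].get(word[1:], 0)
        e = left * right / n2
        var = e * (n2 - left) * (n2 - right) / n2 ** 2
        if var > 0:
            z[idx] = (counts[4].get(word, 0) - e) / math.sqrt(var)
    return z


def test_tetra_zscores_equal_brute_force_oracle():
    seq = random_dna(np.random.default_rng(3), 2000)
    profile = tetra_zscores(SequenceRecord("g", seq))
    assert np.allclose(profile.z, _brute_force_tetra(seq), atol=1e-10)


def test_tetra_skips_ambiguous_words():
    seq = random_dna(np.random.default_rng(4), 1000)
    noisy = seq[:500] + "N" + seq[500:]
    p1 = tetra_zscores(SequenceRecord("g", noisy))
    assert np.allclose(p1.z, _brute_force_tetra(noisy), atol=1e-10)


def test_tetra_homopolymer_degenerate():
    # only the two homopolymer words are observable; their variances are
    # vanishingly small, so the whole profile collapses to ~0
    profile = tetra_zscores(SequenceRecord("g", "A" * 5000))
    assert np.abs(profile.z).max() < 0.1
    assert np.count_nonzero(profile.z) <= 2


def test_tetra_correlation_self_and_antisymmetry():
    seq = random_dna(np.random.default_rng(5), 3000)
    p = tetra_zscores(SequenceRecord("g", seq))
    assert tetra_correlation(p, p) == pytest.approx(1.0, abs=1e-12)
    neg = TetraProfile("neg", -p.z, p.n_words)
    assert tetra_correlation(p, neg) == pytest.approx(-1.0, abs=1e-12)
    flat = TetraProfile("flat", np.zeros(256), 0)
    with pytest.raises(OgripanError, match="undefined"):
        tetra_correlation(p, flat)


def test_tzmd_metric_properties():
    rng = np.random.default_rng(6)
    ps = [TetraProfile(f"p{i}", rng.normal(size=256), 1000) for i in range(3)]
    assert tzmd(ps[0], ps[0]) == 0.0
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        assert tzmd(ps[a], ps[b]) == pytest.approx(tzmd(ps[b], ps[a]))
        assert tzmd(ps[a], ps[c]) <= tzmd(ps[a], ps[b]) + tzmd(ps[b], ps[c])
    assert tzmd(ps[0], ps[1], "raw") == pytest.approx(
        256 * tzmd(ps[0], ps[1], "mean"))


def test_signature_divergence_orders_pairs():
    """Closer genomes have higher TETRA correlation and lower TZMD."""
    for seed in (0, 1):
        rng = np.random.default_rng(seed)
        anc = random_dna(rng, 30_000)
        near = evolve_sequence(anc, 0.02, seed + 10)
        far = evolve_sequence(anc, 0.5, seed + 10)
        pa = tetra_zscores(SequenceRecord("anc", anc))
        pn = tetra_zscores(SequenceRecord("near", near))
        pf = tetra_zscores(SequenceRecord("far", far))
        assert tetra_correlation(pa, pn) > tetra_correlation(pa, pf)
        assert tzmd(pa, pn) < tzmd(pa, pf)


# ---------------------------------------------------------------------------
# ANIb
# ---------------------------------------------------------------------------


def test_anib_self_is_100():
    genome = [SequenceRecord("g", random_dna(np.random.default_rng(7), 20_000))]
    res = anib_pair(genome, genome)
    assert res.ani == 100.0
    assert res.aligned_fraction >= 0.99
    assert res.n_fragments_aligned == res.n_fragments_total


def test_anib_unrelated_flagged_or_sparse():
    rng = np.random.default_rng(8)
    a = [SequenceRecord("a", random_dna(rng, 50_000))]
    b = [SequenceRecord("b", random_dna(rng, 50_000))]
    res = anib_pair(a, b)
    assert res.aligned_fraction < 0.1
    assert res.flagged or res.n_fragments_aligned < 0.1 * res.n_fragments_total


def test_anib_terminal_fragment_kept():
    # 2.5 kb genome -> fragments of 1020, 1020, 460; all should align to self
    genome = [SequenceRecord("g", random_dna(np.random.default_rng(9), 2500))]
    res = anib_pair(genome, genome)
    assert res.n_fragments_total == 3
    assert res.n_fragments_aligned == 3


# ---------------------------------------------------------------------------
# dDDH
# ---------------------------------------------------------------------------


def test_ddh_self_d2_zero():
    genome = [SequenceRecord("g", random_dna(np.random.default_rng(10), 20_000))]
    res = ddh_formula2(genome, genome)
    assert res.d2 == 0.0
    assert res.ddh == pytest.approx(d2_to_ddh(0.0))


def test_ddh_single_hsp_arithmetic():
    """A 1 kb pair with exactly 50 interior substitutions: d2 = 0.05."""
    rng = np.random.default_rng(11)
    a = random_dna(rng, 1000)
    b = list(a)
    positions = list(range(10, 990, 20)) + [995]  # 50 interior sites
    for p in positions:
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    assert sum(x != y for x, y in zip(a, b)) == 50
    res = ddh_formula2([SequenceRecord("a", a)],
                       [SequenceRecord("b", "".join(b))])
    assert res.sum_hsp_len == 1000 and res.sum_identities == 950
    assert res.d2 == pytest.approx(0.05)


def test_ddh_logistic_monotone_decreasing():
    grid = np.linspace(0, 0.3, 20)
    vals = [d2_to_ddh(d) for d in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_ddh_no_hsps_flagged():
    rng = np.random.default_rng(12)
    a = [SequenceRecord("a", random_dna(rng, 2000))]
    b = [SequenceRecord("b", random_dna(rng, 2000))]
    res = ddh_formula2(a, b)
    assert res.flagged or res.sum_hsp_len < 200


# ---------------------------------------------------------------------------
# AAI
# ---------------------------------------------------------------------------


def test_aai_self(small_sim):
    prots = small_sim.data.proteomes["S1"]
    res = aai_pair(prots, prots)
    assert res.aai == 100.0
    assert res.n_rbh == len(prots)
    assert res.orthologous_fraction == 1.0


def test_aai_empty_proteome_rejected():
    with pytest.raises(OgripanError):
        aai_pair([], [SequenceRecord("p", "MKV", "protein")])


def test_aai_genus_separation(small_sim):
    """Conspecific pair high AAI; the distant pair much lower."""
    near = aai_pair(small_sim.data.proteomes["S1"],
                    small_sim.data.proteomes["S2"])
    far = aai_pair(small_sim.data.proteomes["S1"],
                   small_sim.data.proteomes["S3"])
    assert near.aai > 95
    assert far.aai < near.aai - 10


# ---------------------------------------------------------------------------
# 16S
# ---------------------------------------------------------------------------


def test_identity_16s_identical():
    seq = random_dna(np.random.default_rng(13), 1500)
    assert identity_16s(seq, seq) == 100.0


def test_identity_16s_overhang_excluded():
    seq = random_dna(np.random.default_rng(14), 1500)
    assert identity_16s(seq, seq[50:1450]) == 100.0


def test_identity_16s_matches_jc_expectation():
    seq = random_dna(np.random.default_rng(15), 1500)
    d = 0.02
    other = evolve_sequence(seq, d, 44)
    expected = 100 * expected_identity(d)
    assert identity_16s(seq, other) == pytest.approx(expected, abs=1.0)


def test_identity_16s_short_warns(caplog):
    seq = random_dna(np.random.default_rng(16), 400)
    with caplog.at_level("WARNING"):
        assert identity_16s(seq, seq) == 100.0
    assert "500" in caplog.text


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_matrices(small_sim):
    from ogripan.ogri import compute_all_ogri
    return compute_all_ogri(
        small_sim.data,
        indices=("ani", "aai", "tetra", "tzmd", "d2", "id16s"))


def test_matrix_symmetry_and_diagonal(small_matrices):
    self_values = {"ani": 100.0, "aai": 100.0, "tetra": 1.0, "tzmd": 0.0,
                   "d2": 0.0, "id16s": 100.0}
    for name, mat in small_matrices.items():
        assert np.allclose(mat.values, mat.values.T, equal_nan=True), name
        assert np.allclose(np.diag(mat.values), self_values[name]), name
        assert mat.is_complete, name


def test_matrix_tracks_divergence(small_matrices):
    ani = small_matrices["ani"]
    # S1-S2 (d=0.01) must beat S3-S4 (d=0.10) and S1-S3 (d=0.255)
    assert ani.value("S1", "S2") > ani.value("S3", "S4") > ani.value("S1", "S3")


def test_ani_rank_agreement_with_truth(default_matrices, default_sim):
    """ANI on the 12-genome simulation reproduces the pairwise ordering of
    the true divergences.

    The default tree has only four distinct path lengths, so large rank
    ties cap attainable |Spearman rho| around 0.93; the check therefore
    asserts perfect concordance across every strictly-ordered pair of
    true divergences (the stronger form of rank agreement) alongside the
    tie-limited correlation.
    """
    from scipy.stats import spearmanr
    ani = default_matrices["ani"]
    truth = default_sim.truth.pairwise_d.loc[ani.genome_ids, ani.genome_ids]
    n = len(ani.genome_ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    tv = np.array([truth.iloc[i, j] for i, j in pairs])
    av = np.array([ani.values[i, j] for i, j in pairs])
    for x in range(len(pairs)):
        closer = tv < tv[x]
        assert (av[closer] > av[x]).all()
    rho = spearmanr(tv, av).statistic
    assert rho <= -0.90


def test_matrix_rejects_unknown_index(small_sim):
    with pytest.raises(OgripanError, match="unknown index"):
        ogri_matrix(small_sim.data, "anim")


def test_matrix_tsv_roundtrip(small_matrices, tmp_path):
    mat = small_matrices["ani"]
    f = tmp_path / "ani.tsv"
    mat.to_tsv(f)
    back = OgriMatrix.from_tsv(f, "ani")
    assert back.genome_ids == mat.genome_ids
    assert np.allclose(back.values, np.round(mat.values, 4))
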