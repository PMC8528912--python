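"""Overall genome relatedness indices (OGRIs).

Implements the five pairwise whole-genome indices used for prokaryotic
rank delimitation — fragment-based average nucleotide identity (ANIb),
tetranucleotide z-score correlation (TETRA) and Manhattan distance (TZMD),
digital DNA-DNA hybridization distance (formula 2: 1 - identities/HSP
length, mapped to a percent estimate by a configurable logistic), average
amino-acid identity of reciprocal best hits (AAI) — plus 16S identity and
G+C content, and assembles them into symmetric :class:`OgriMatrix` objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from ._align import (
    AlignmentHit,
    DnaAlignParams,
    ProteinHit,
    SubjectIndex,
    encode_dna,
    local_align,
    pairwise_proteome_hits,
    revcomp_codes,
    _words,
)
from .io_core import (
    GenomeSet,
    OgripanError,
    PipelineConfig,
    SequenceRecord,
    logger,
    read_matrix_tsv,
    write_matrix_tsv,
)

__all__ = [
    "AlignmentHit", "DnaAlignParams", "local_align",
    "TetraProfile", "AniResult", "DdhResult", "AaiResult", "OgriMatrix",
    "gc_content", "tetra_zscores", "tetra_correlation", "tzmd",
    "anib_pair", "ddh_formula2", "aai_pair", "identity_16s",
    "ogri_matrix", "compute_all_ogri", "INDEX_NAMES",
]

INDEX_NAMES = ("ani", "aai", "tetra", "tzmd", "ddh", "d2", "id16s")


# ---------------------------------------------------------------------------
# G+C content
# ---------------------------------------------------------------------------


def gc_content(genome: list[SequenceRecord] | SequenceRecord) -> float:
    """G+C mol% over unambiguous bases, reported to 1 decimal.

    N and every other ambiguity code are excluded from numerator and
    denominator.
    """
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    at = gc = 0
    for rec in records:
        codes = encode_dna(rec.seq)
        counts = np.bincount(codes, minlength=5)
        at += int(counts[0] + counts[3])
        gc += int(counts[1] + counts[2])
    if at + gc == 0:
        raise OgripanError("no unambiguous bases in genome")
    return round(100.0 * gc / (at + gc), 1)


# ---------------------------------------------------------------------------
# Tetranucleotide z-scores (Teeling maximal-order Markov model)
# ---------------------------------------------------------------------------


@dataclass
class TetraProfile:
    """256 tetranucleotide z-scores in lexicographic ACGT order."""

    genome_id: str
    z: np.ndarray
    n_words: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (256,):
            raise ValueError("tetra profile must have length 256")
        if not np.isfinite(self.z).all():
            raise ValueError("tetra profile must be finite")


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    _pos, words = _words(codes, k)
    return np.bincount(words, minlength=4 ** k).astype(float)


def tetra_zscores(genome: list[SequenceRecord] | SequenceRecord,
                  genome_id: str | None = None) -> TetraProfile:
    """Observed-vs-Markov-expected tetranucleotide z-scores.

    Counts are taken over every contig and its reverse complement; words
    containing ambiguous bases are skipped.  For w = n1n2n3n4 with
    trinucleotide counts N3 and dinucleotide counts N2:

        E(w)   = N3(n1n2n3) * N3(n2n3n4) / N2(n2n3)
        Var(w) = E(w) * (N2(n2n3)-N3(n1n2n3)) * (N2(n2n3)-N3(n2n3n4)) / N2(n2n3)^2
        Z(w)   = (O(w) - E(w)) / sqrt(Var(w)),  Z = 0 where Var = 0.
    """
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    if not records or all(len(r) == 0 for r in records):
        raise OgripanError("empty genome")
    if genome_id is None:
        genome_id = records[0].id
    c4 = np.zeros(256)
    c3 = np.zeros(64)
    c2 = np.zeros(16)
    for rec in records:
        for codes in (encode_dna(rec.seq), revcomp_codes(encode_dna(rec.seq))):
            c4 += _kmer_counts(codes, 4)
            c3 += _kmer_counts(codes, 3)
            c2 += _kmer_counts(codes, 2)
    n_words = int(c4.sum())
    if n_words == 0:
        raise OgripanError("no unambiguous tetranucleotide words in genome")
    if n_words < 256:
        logger.warning("only %d tetranucleotide words counted (<256) for %s",
                       n_words, genome_id)
    idx = np.arange(256)
    left = idx >> 2            # n1n2n3
    right = idx & 63           # n2n3n4
    mid = left & 15            # n2n3
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(c2[mid] > 0, c3[left] * c3[right] / c2[mid], 0.0)
        var = np.where(
            c2[mid] > 0,
            e * (c2[mid] - c3[left]) * (c2[mid] - c3[right]) / c2[mid] ** 2,
            0.0,
        )
        z = np.where(var > 0, (c4 - e) / np.sqrt(var), 0.0)
    if not np.any(var > 0):
        logger.warning("all tetranucleotide variances are zero for %s "
                       "(degenerate sequence)", genome_id)
    return TetraProfile(genome_id, z, n_words)


def tetra_correlation(p1: TetraProfile, p2: TetraProfile) -> float:
    """Pearson correlation of two 256-component z-score vectors."""
    if p1.z.std() == 0 or p2.z.std() == 0:
        raise OgripanError(
            "undefined correlation: zero-variance tetranucleotide profile")
    return float(np.corrcoef(p1.z, p2.z)[0, 1])


def tzmd(p1: TetraProfile, p2: TetraProfile,
         normalization: str = "mean") -> float:
    """Tetranucleotide-derived z-value Manhattan distance.

    ``normalization="mean"`` (default) divides the raw 256-term sum by 256;
    ``"raw"`` returns the plain sum.
    """
    d = float(np.abs(p1.z - p2.z).sum())
    if normalization == "mean":
        return d / 256.0
    if normalization == "raw":
        return d
    raise ValueError(f"unknown TZMD normalization {normalization!r}")


# ---------------------------------------------------------------------------
# ANIb (fragment method)
# ---------------------------------------------------------------------------


@dataclass
class AniResult:
    ani: float                 # percent; nan = flagged (no retained fragment)
    n_fragments_total: int
    n_fragments_aligned: int
    aligned_fraction: float

    @property
    def flagged(self) -> bool:
        return math.isnan(self.ani)


def _concat_with_junctions(genome: list[SequenceRecord]) -> str:
    # 'N' junctions prevent k-mer seeds from spanning contig boundaries
    return ("N" * 25).join(rec.seq for rec in genome)


def _subject_indexes(genome: list[SequenceRecord], params: DnaAlignParams):
    seq = _concat_with_junctions(genome)
    codes = encode_dna(seq)
    return seq, (SubjectIndex.build(codes, params.k),
                 SubjectIndex.build(revcomp_codes(codes), params.k))


def anib_pair(
    query_genome: list[SequenceRecord],
    subject_genome: list[SequenceRecord],
    fragment_size: int = 1020,
    params: DnaAlignParams | None = None,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    _subject: tuple | None = None,
) -> AniResult:
    """One-directional fragment-based average nucleotide identity.

    The query is cut into consecutive ``fragment_size`` bp fragments
    (terminal shorter fragment kept and judged by coverage relative to its
    own length); each fragment is aligned to the subject and retained iff
    its best hit has identity >= ``min_identity`` percent over
    >= ``min_coverage`` of the fragment.  ANI is the mean percent identity
    of retained fragments.
    """
    params = params or DnaAlignParams()
    subject_seq, indexes = _subject or _subject_indexes(subject_genome, params)
    identities = []
    aligned_len = 0
    total_len = 0
    n_frag = 0
    for rec in query_genome:
        total_len += len(rec.seq)
        for off in range(0, len(rec.seq), fragment_size):
            frag = rec.seq[off:off + fragment_size]
            if len(frag) < params.k:
                continue
            n_frag += 1
            hits = local_align(frag, subject_seq, params,
                               subject_indexes=indexes)
            if not hits:
                continue
            best = hits[0]
            cov = (best.q_end - best.q_start) / len(frag)
            if best.identity_pct >= min_identity and cov >= min_coverage:
                identities.append(best.identity_pct)
                aligned_len += best.q_end - best.q_start
    if not identities:
        return AniResult(float("nan"), n_frag, 0, 0.0)
    return AniResult(float(np.mean(identities)), n_frag, len(identities),
                     aligned_len / total_len if total_len else 0.0)


# ---------------------------------------------------------------------------
# dDDH (GGDC formula 2)
# ---------------------------------------------------------------------------


@dataclass
class DdhResult:
    sum_identities: int
    sum_hsp_len: int
    d2: float                 # 1 - identities/HSP length; nan = flagged
    ddh: float                # percent estimate from the logistic map

    @property
    def flagged(self) -> bool:
        return math.isnan(self.d2)


def d2_to_ddh(d2: float, a: float = 2.149435, b: float = -24.452202) -> float:
    """Logistic map from the formula-2 distance to a percent dDDH estimate.

    Constants are configurable (``PipelineConfig.ddh_logistic_*``); d2 = 0
    maps to the maximal ddh of the transform and ddh decreases
    monotonically in d2.
    """
    return 100.0 / (1.0 + math.exp(-(a + b * d2)))


def ddh_formula2(
    genome_a: list[SequenceRecord],
    genome_b: list[SequenceRecord],
    params: DnaAlignParams | None = None,
    logistic: tuple[float, float] = (2.149435, -24.452202),
    _subject: tuple | None = None,
) -> DdhResult:
    """Formula-2 digital DDH from whole-genome HSPs (both strands)."""
    params = params or DnaAlignParams()
    subject_seq, indexes = _subject or _subject_indexes(genome_b, params)
    query_seq = _concat_with_junctions(genome_a)
    hits = local_align(query_seq, subject_seq, params,
                       subject_indexes=indexes)
    sum_id = sum(h.identities for h in hits)
    sum_len = sum(h.aln_len for h in hits)
    if sum_len == 0:
        return DdhResult(0, 0, float("nan"), float("nan"))
    d2 = 1.0 - sum_id / sum_len
    return DdhResult(sum_id, sum_len, d2, d2_to_ddh(d2, *logistic))


# ---------------------------------------------------------------------------
# AAI (reciprocal best hits)
# ---------------------------------------------------------------------------


@dataclass
class AaiResult:
    aai: float                 # percent; nan = flagged (zero RBHs)
    n_rbh: int
    orthologous_fraction: float

    @property
    def flagged(self) -> bool:
        return math.isnan(self.aai)


def _swap_hit(h: ProteinHit) -> ProteinHit:
    return ProteinHit(h.subject_id, h.query_id, h.score, h.identities,
                      h.aln_len, h.s_aligned, h.q_aligned, h.s_len, h.q_len)


def _best_per_query(hits: list[ProteinHit]) -> dict[str, ProteinHit]:
    # ties broken by score, aln_len, self-hit preference, subject id
    best: dict[str, ProteinHit] = {}
    for h in sorted(hits, key=lambda h: (
            h.query_id, -h.score, -h.aln_len,
            h.subject_id != h.query_id, h.subject_id)):
        best.setdefault(h.query_id, h)
    return best


def aai_pair(
    proteome_a: list[SequenceRecord],
    proteome_b: list[SequenceRecord],
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    min_score: float = 50.0,
    _hits: list[ProteinHit] | None = None,
) -> AaiResult:
    """Average amino-acid identity of reciprocal best hits.

    Hits are filtered at ``min_identity`` percent identity and
    ``min_coverage`` of the shorter sequence before best-hit selection.
    """
    if not proteome_a or not proteome_b:
        raise OgripanError("empty proteome")
    hits = _hits if _hits is not None else pairwise_proteome_hits(
        proteome_a, proteome_b, min_score=min_score)
    hits = [h for h in hits
            if h.identity_pct >= min_identity and h.shorter_cov >= min_coverage]
    fwd = _best_per_query(hits)
    rev = _best_per_query([_swap_hit(h) for h in hits])
    rbh = []
    for qid in sorted(fwd):
        h = fwd[qid]
        back = rev.get(h.subject_id)
        if back is not None and back.subject_id == qid:
            rbh.append(h)
    if not rbh:
        return AaiResult(float("nan"), 0, 0.0)
    aai = float(np.mean([h.identity_pct for h in rbh]))
    return AaiResult(aai, len(rbh),
                     len(rbh) / min(len(proteome_a), len(proteome_b)))


# ---------------------------------------------------------------------------
# 16S identity
# ---------------------------------------------------------------------------


def identity_16s(seq_a: SequenceRecord | str, seq_b: SequenceRecord | str) -> float:
    """Percent identity from a global end-gap-free alignment.

    Terminal overhangs (columns before the first / after the last position
    where both sequences are aligned) are excluded from the denominator.
    """
    sa = seq_a.seq if isinstance(seq_a, SequenceRecord) else seq_a
    sb = seq_b.seq if isinstance(seq_b, SequenceRecord) else seq_b
    if min(len(sa), len(sb)) < 500:
        logger.warning("16S identity on sequence shorter than 500 bp")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    aln = aligner.align(sa, sb)[0]
    a, b = str(aln[0]), str(aln[1])
    non_gap = [i for i, (x, y) in enumerate(zip(a, b))
               if x != "-" and y != "-"]
    lo, hi = non_gap[0], non_gap[-1] + 1
    core_a, core_b = a[lo:hi], b[lo:hi]
    ident = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    return 100.0 * ident / (hi - lo)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

_SELF_VALUE = {"ani": 100.0, "aai": 100.0, "tetra": 1.0, "tzmd": 0.0,
               "d2": 0.0, "id16s": 100.0}


@dataclass
class OgriMatrix:
    """Symmetric pairwise index matrix with per-cell metadata."""

    index_name: str
    genome_ids: list[str]
    values: np.ndarray
    meta: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.genome_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match genome ids")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.genome_ids.index(a),
                                 self.genome_ids.index(b)])

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids,
                            columns=self.genome_ids)

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.genome_ids, self.values, path)

    @classmethod
    def from_tsv(cls, path, index_name: str) -> "OgriMatrix":
        ids, values = read_matrix_tsv(path)
        return cls(index_name, ids, values)


def _pair_loop(ids, fn, self_value):
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, self_value)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(ids[i], ids[j])
    return values


def ogri_matrix(
    data: GenomeSet,
    index_name: str,
    config: PipelineConfig | None = None,
    params: DnaAlignParams | None = None,
    _cache: dict | None = None,
) -> OgriMatrix:
    """Compute one index over all unordered genome pairs.

    Directional indices (ANI, dDDH, AAI) are symmetrized by the mean of the
    two directions; TETRA, TZMD and 16S identity are inherently symmetric.
    Incomputable cells propagate as NaN (flagged) and mark the matrix
    incomplete; they are never silently zero.
    """
    config = config or PipelineConfig()
    params = params or DnaAlignParams(min_score=config.min_dna_score)
    ids = data.ids
    if len(ids) < 2:
        raise OgripanError("need at least 2 genomes")
    cache = _cache if _cache is not None else {}
    meta: dict[str, np.ndarray] = {}
    n = len(ids)

    def dna_indexes(gid):
        key = ("idx", gid)
        if key not in cache:
            cache[key] = _subject_indexes(data.genomes[gid], params)
        return cache[key]

    def prot_hits(a, b):
        key = ("phits", a, b)
        if key not in cache:
            cache[key] = pairwise_proteome_hits(
                data.proteomes[a], data.proteomes[b],
                min_score=config.min_protein_score)
        return cache[key]

    if index_name == "ani":
        frac = np.full((n, n), np.nan)
        np.fill_diagonal(frac, 1.0)

        def fn(a, b):
            ra = anib_pair(data.genomes[a], data.genomes[b],
                           config.fragment_size, params,
                           _subject=dna_indexes(b))
            rb = anib_pair(data.genomes[b], data.genomes[a],
                           config.fragment_size, params,
                           _subject=dna_indexes(a))
            i, j = ids.index(a), ids.index(b)
            frac[i, j] = frac[j, i] = np.mean(
                [ra.aligned_fraction, rb.aligned_fraction])
            return np.mean([ra.ani, rb.ani])

        values = _pair_loop(ids, fn, 100.0)
        meta["aligned_fraction"] = frac
    elif index_name in ("ddh", "d2"):
        logistic = (config.ddh_logistic_a, config.ddh_logistic_b)
        d2m = np.full((n, n), np.nan)
        np.fill_diagonal(d2m, 0.0)

        def fn(a, b):
            key = ("d2pair", a, b)
            if key not in cache:
                ra = ddh_formula2(data.genomes[a], data.genomes[b], params,
                                  logistic, _subject=dna_indexes(b))
                rb = ddh_formula2(data.genomes[b], data.genomes[a], params,
                                  logistic, _subject=dna_indexes(a))
                cache[key] = float(np.mean([ra.d2, rb.d2]))
            d2 = cache[key]
            i, j = ids.index(a), ids.index(b)
            d2m[i, j] = d2m[j, i] = d2
            return d2 if index_name == "d2" else d2_to_ddh(d2, *logistic)

        self_val = 0.0 if index_name == "d2" else d2_to_ddh(0.0, *logistic)
        values = _pair_loop(ids, fn, self_val)
        meta["d2"] = d2m
    elif index_name == "aai":
        def fn(a, b):
            return aai_pair(data.proteomes[a], data.proteomes[b],
                            config.aai_min_identity, config.aai_min_coverage,
                            config.min_protein_score,
                            _hits=prot_hits(a, b)).aai

        values = _pair_loop(ids, fn, 100.0)
    elif index_name in ("tetra", "tzmd"):
        profiles = {}
        for gid in ids:
            key = ("tetra", gid)
            if key not in cache:
                cache[key] = tetra_zscores(data.genomes[gid], gid)
            profiles[gid] = cache[key]
        if index_name == "tetra":
            values = _pair_loop(
                ids, lambda a, b: tetra_correlation(profiles[a], profiles[b]),
                1.0)
        else:
            values = _pair_loop(
                ids, lambda a, b: tzmd(profiles[a], profiles[b],
                                       config.tzmd_normalization), 0.0)
    elif index_name == "id16s":
        if not data.markers_16s:
            raise OgripanError("no 16S markers in dataset")
        values = _pair_loop(
            ids, lambda a, b: identity_16s(data.markers_16s[a],
                                           data.markers_16s[b]), 100.0)
    else:
        raise OgripanError(f"unknown index {index_name!r}")

    mat = OgriMatrix(index_name, ids, values, meta)
    logger.info("%s matrix over %d genomes (%scomplete)", index_name, n,
                "" if mat.is_complete else "in")
    return mat


def compute_all_ogri(
    data: GenomeSet,
    config: PipelineConfig | None = None,
    indices: tuple[str, ...] = INDEX_NAMES,
) -> dict[str, OgriMatrix]:
    """All requested matrices, sharing per-genome caches across indices."""
    config = config or PipelineConfig()
    cache: dict = {}
    return {name: ogri_matrix(data, name, config, _cache=cache)
            for name in indices}
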