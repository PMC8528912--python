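"""Internal pairwise alignment engines.

DNA: a k-mer-seeded heuristic local aligner (seed matching on both strands,
per-diagonal ungapped extension by maximal-scoring-segment search, then
banded gapped chaining of nearby HSPs with affine gap costs).  A full
dynamic-programming mode (Biopython local affine DP) is available as an
independent oracle for inputs of a few kb.

Proteins: BLOSUM62 local DP (Biopython) behind a shared-k-mer candidate
prefilter, plus best-hit/reciprocal-best-hit bookkeeping with deterministic
tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_core import SequenceRecord

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_dna(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; N and every other IUPAC ambiguity code -> 4."""
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)].copy()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[::-1]


@dataclass
class DnaAlignParams:
    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5       # charged once per gap
    gap_extend: int = -2     # charged per gap column (incl. the first)
    min_score: int = 25
    band: int = 50           # max indel bridged when chaining HSPs
    chain_gap: int = 200     # max ungapped distance bridged when chaining
    max_diagonals: int = 5000
    min_diag_seeds_small: int = 2   # seed floor for fragment-sized queries
    min_diag_seeds_large: int = 3   # seed floor for queries > large_query
    large_query: int = 5000
    max_segments_per_diagonal: int = 32


@dataclass
class AlignmentHit:
    """One high-scoring pair between query and subject."""

    query_id: str
    subject_id: str
    identities: int
    aln_len: int
    q_cov: float
    score: float
    q_start: int = 0      # 0-based half-open on the query
    q_end: int = 0
    s_start: int = 0      # on the forward subject strand coordinate system
    s_end: int = 0
    strand: str = "+"

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aln_len if self.aln_len else 0.0


# ---------------------------------------------------------------------------
# seed machinery
# ---------------------------------------------------------------------------


def _words(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, word values) of all k-mers free of ambiguous bases."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    w = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        w = w * 4 + codes[i:n - k + 1 + i]
    bad = (codes >= 4).astype(np.int64)
    cb = np.concatenate([[0], np.cumsum(bad)])
    valid = (cb[k:] - cb[:-k]) == 0
    pos = np.flatnonzero(valid)
    return pos, w[pos]


@dataclass
class SubjectIndex:
    """Sorted k-mer table of one subject strand, for vectorized lookup."""

    sorted_words: np.ndarray
    sorted_pos: np.ndarray
    length: int
    k: int
    codes: np.ndarray = None

    @classmethod
    def build(cls, codes: np.ndarray, k: int) -> "SubjectIndex":
        pos, words = _words(codes, k)
        order = np.argsort(words, kind="stable")
        return cls(words[order], pos[order], len(codes), k, codes)

    def matches(self, qpos: np.ndarray, qwords: np.ndarray):
        """All (query position, subject position) seed matches."""
        left = np.searchsorted(self.sorted_words, qwords, "left")
        right = np.searchsorted(self.sorted_words, qwords, "right")
        counts = right - left
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        offs = np.concatenate([[0], np.cumsum(counts)])
        idx = (np.arange(total) - np.repeat(offs[:-1], counts)
               + np.repeat(left, counts))
        return np.repeat(qpos, counts), self.sorted_pos[idx]


# ---------------------------------------------------------------------------
# ungapped extension: best local segment(s) on a diagonal
# ---------------------------------------------------------------------------


def _best_segment(scores: np.ndarray) -> tuple[int, int, float]:
    """Maximal-scoring contiguous segment (start, end half-open, score).

    Among co-optimal segments the shortest is returned (zero-net edges
    trimmed), matching the boundary convention of the DP oracle.
    """
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    j = int(np.argmax(gains))
    best = float(gains[j])
    head = prefix[:j + 1]
    i = int(len(head) - 1 - np.argmin(head[::-1]))  # last argmin: trim edges
    return i, j + 1, best


def _segments_on_diagonal(eq: np.ndarray, params: DnaAlignParams,
                          min_len: int = 15) -> list[tuple[int, int, float, int]]:
    """Recursively peel maximal segments (BLAST-style two-hit free)."""
    scores = np.where(eq, float(params.match), float(params.mismatch))
    out: list[tuple[int, int, float, int]] = []

    def recurse(lo: int, hi: int, depth: int):
        if hi - lo < min_len or depth > params.max_segments_per_diagonal:
            return
        i, j, sc = _best_segment(scores[lo:hi])
        if sc < params.min_score:
            return
        i, j = lo + i, lo + j
        out.append((i, j, sc, int(eq[i:j].sum())))
        recurse(lo, i, depth + 1)
        recurse(j, hi, depth + 1)

    recurse(0, len(eq), 0)
    return out


@dataclass
class _Hsp:
    qs: int
    qe: int
    ss: int
    se: int
    score: float
    matches: int
    aln_len: int
    strand: str


def _diagonal_hsps(q: np.ndarray, index: SubjectIndex,
                   params: DnaAlignParams, strand: str) -> list[_Hsp]:
    s = index.codes
    qpos, qwords = _words(q, params.k)
    if qpos.size == 0:
        return []
    qm, sm = index.matches(qpos, qwords)
    if qm.size == 0:
        return []
    diag = sm - qm
    uniq, inv, counts = np.unique(diag, return_inverse=True, return_counts=True)
    min_seeds = (params.min_diag_seeds_small if len(q) <= params.large_query
                 else params.min_diag_seeds_large)
    keep = counts >= min_seeds
    if not keep.any() and counts.size:  # fall back to the strongest seeds
        keep = counts == counts.max()
    if keep.sum() > params.max_diagonals:
        order = np.argsort(counts)[::-1][:params.max_diagonals]
        keep = np.zeros_like(keep)
        keep[order] = True
    hsps: list[_Hsp] = []
    margin = params.chain_gap
    for di in np.flatnonzero(keep):
        d = int(uniq[di])
        on = inv == di
        q_lo = max(0, int(qm[on].min()) - margin, -d)
        q_hi = min(len(q), int(qm[on].max()) + params.k + margin,
                   index.length - d)
        if q_hi <= q_lo:
            continue
        a = q[q_lo:q_hi]
        b = s[q_lo + d:q_hi + d]
        eq = (a == b) & (a < 4) & (b < 4)
        for i, j, sc, matches in _segments_on_diagonal(eq, params):
            hsps.append(_Hsp(q_lo + i, q_lo + j, q_lo + d + i, q_lo + d + j,
                             sc, matches, j - i, strand))
    return hsps


def _chain_hsps(hsps: list[_Hsp], params: DnaAlignParams) -> list[_Hsp]:
    """Greedy banded gapped chaining of co-linear HSPs (affine gap costs)."""
    hsps = sorted(hsps, key=lambda h: (h.strand, h.qs, h.ss))
    merged: list[_Hsp] = []
    for h in hsps:
        if merged:
            p = merged[-1]
            dq = h.qs - p.qe
            ds = h.ss - p.se
            # small overlaps arise where two diagonal extensions cross an
            # indel junction; trim them from the incoming HSP
            ov = max(0, -min(dq, ds))
            if (p.strand == h.strand and ov <= params.k
                    and dq + ov >= 0 and ds + ov >= 0
                    and max(dq + ov, ds + ov) <= params.chain_gap
                    and abs(dq - ds) <= params.band):
                dq, ds = dq + ov, ds + ov
                indel = abs(dq - ds)
                bridge = min(dq, ds)
                gap_cost = (params.gap_open + params.gap_extend * indel
                            if indel else 0)
                new_score = (p.score + h.score + gap_cost
                             + params.mismatch * bridge - params.match * ov)
                if new_score >= max(p.score, h.score):
                    merged[-1] = _Hsp(
                        p.qs, h.qe, p.ss, h.se, new_score,
                        p.matches + h.matches - ov,
                        p.aln_len + h.aln_len - ov + max(dq, ds), p.strand)
                    continue
        merged.append(h)
    return merged


def _drop_query_overlaps(hsps: list[_Hsp], max_frac: float = 0.2) -> list[_Hsp]:
    kept: list[_Hsp] = []
    for h in sorted(hsps, key=lambda h: (-h.score, h.qs, h.ss, h.strand)):
        olap = 0
        for k in kept:
            olap = max(olap, min(h.qe, k.qe) - max(h.qs, k.qs))
        if olap <= max_frac * (h.qe - h.qs):
            kept.append(h)
    return kept


def local_align(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    params: DnaAlignParams | None = None,
    mode: str = "heuristic",
    subject_indexes: tuple[SubjectIndex, SubjectIndex] | None = None,
) -> list[AlignmentHit]:
    """Local DNA alignment, both strands; returns HSPs sorted by score.

    ``mode="dp"`` runs full local affine dynamic programming (oracle; only
    sensible for inputs of a few kb) and returns the single best hit.
    ``subject_indexes`` lets callers reuse prebuilt (+, -) strand indexes.
    """
    params = params or DnaAlignParams()
    qid = query.id if isinstance(query, SequenceRecord) else "query"
    sid = subject.id if isinstance(subject, SequenceRecord) else "subject"
    qseq = query.seq if isinstance(query, SequenceRecord) else query
    sseq = subject.seq if isinstance(subject, SequenceRecord) else subject
    if not qseq or not sseq:
        raise ValueError("query and subject must be non-empty")
    if params.k > len(qseq):
        raise ValueError(
            f"k={params.k} larger than query length {len(qseq)}")
    if mode == "dp":
        return _dp_align(qid, sid, qseq, sseq, params)
    q = encode_dna(qseq)
    if subject_indexes is None:
        s = encode_dna(sseq)
        subject_indexes = (SubjectIndex.build(s, params.k),
                           SubjectIndex.build(revcomp_codes(s), params.k))
    hsps = _diagonal_hsps(q, subject_indexes[0], params, "+")
    hsps += _diagonal_hsps(q, subject_indexes[1], params, "-")
    hsps = _chain_hsps(hsps, params)
    hsps = [h for h in hsps if h.score >= params.min_score]
    hsps = _drop_query_overlaps(hsps)
    n = len(qseq)
    ns = len(sseq)
    hits = []
    for h in sorted(hsps, key=lambda h: (-h.score, h.qs, h.ss, h.strand)):
        if h.strand == "+":
            ss, se = h.ss, h.se
        else:  # map back to forward-strand coordinates
            ss, se = ns - h.se, ns - h.ss
        hits.append(AlignmentHit(
            qid, sid, h.matches, h.aln_len, (h.qe - h.qs) / n, h.score,
            h.qs, h.qe, ss, se, h.strand))
    return hits


def _dna_dp_aligner(params: DnaAlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _dp_align(qid, sid, qseq, sseq, params) -> list[AlignmentHit]:
    aligner = _dna_dp_aligner(params)
    best = None
    qn = qseq.replace("N", "A")  # placeholder-free DP; Ns scored as mismatch
    for strand, s in (("+", sseq),
                      ("-", str(SequenceRecord("s", sseq).reverse_complement().seq))):
        score = aligner.score(qn, s)
        if best is None or score > best[0]:
            best = (score, strand, s)
    score, strand, s = best
    if score < params.min_score:
        return []
    aln = next(iter(aligner.align(qn, s)))
    counts = aln.counts()
    cols = aln.length
    identities = counts.identities
    if "N" in qseq:  # do not count N-placeholder coincidences as identities
        identities = _identities_excluding_n(aln, qseq)
    qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    return [AlignmentHit(qid, sid, int(identities), int(cols),
                        (qe - qs) / len(qseq), float(score),
                        qs, qe, int(aln.aligned[1][0][0]),
                        int(aln.aligned[1][-1][1]), strand)]


def _identities_excluding_n(aln, qseq: str) -> int:
    a, b = str(aln[0]), str(aln[1])
    qpos = int(aln.aligned[0][0][0])
    ident = 0
    for ca, cb in zip(a, b):
        if ca != "-":
            if ca == cb and qseq[qpos] != "N":
                ident += 1
            qpos += 1
    return ident


# ---------------------------------------------------------------------------
# protein alignment
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_PROT_SANITIZE = str.maketrans({"*": "X", "U": "X", "O": "X", "J": "X",
                                "B": "X", "Z": "X"})


@dataclass
class ProteinHit:
    query_id: str
    subject_id: str
    score: float
    identities: int
    aln_len: int           # alignment columns including gaps
    q_aligned: int         # residues of the query inside the alignment
    s_aligned: int
    q_len: int
    s_len: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aln_len if self.aln_len else 0.0

    @property
    def q_cov(self) -> float:
        return self.q_aligned / self.q_len

    @property
    def s_cov(self) -> float:
        return self.s_aligned / self.s_len

    @property
    def shorter_cov(self) -> float:
        return (self.q_aligned / self.q_len if self.q_len <= self.s_len
                else self.s_aligned / self.s_len)


def align_proteins(a: SequenceRecord, b: SequenceRecord,
                   aligner: Align.PairwiseAligner | None = None) -> ProteinHit | None:
    aligner = aligner or protein_aligner()
    sa = a.seq.translate(_PROT_SANITIZE)
    sb = b.seq.translate(_PROT_SANITIZE)
    if not sa or not sb:
        return None
    alns = aligner.align(sa, sb)
    if alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    q_aligned = int(sum(e - s for s, e in aln.aligned[0]))
    s_aligned = int(sum(e - s for s, e in aln.aligned[1]))
    return ProteinHit(a.id, b.id, float(alns.score), int(counts.identities),
                      int(aln.length), q_aligned, s_aligned, len(sa), len(sb))


def kmer_candidates(
    prots_a: list[SequenceRecord],
    prots_b: list[SequenceRecord],
    k: int = 5,
    min_shared: int = 2,
) -> list[tuple[int, int]]:
    """Index pairs (i into a, j into b) sharing >= ``min_shared`` k-mers."""
    index: dict[str, list[int]] = {}
    for j, p in enumerate(prots_b):
        seen = set()
        s = p.seq
        for x in range(len(s) - k + 1):
            w = s[x:x + k]
            if w not in seen:
                seen.add(w)
                index.setdefault(w, []).append(j)
    pairs = []
    for i, p in enumerate(prots_a):
        counts: dict[int, int] = {}
        seen = set()
        s = p.seq
        for x in range(len(s) - k + 1):
            w = s[x:x + k]
            if w in seen:
                continue
            seen.add(w)
            for j in index.get(w, ()):
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            if c >= min_shared:
                pairs.append((i, j))
    return sorted(pairs)


def diagonal_kmer_candidates(
    prots_a: list[SequenceRecord],
    prots_b: list[SequenceRecord],
    k: int = 3,
    bucket: int = 4,
    min_diag: int = 4,
) -> dict[tuple[int, int], int]:
    """Pairs with >= ``min_diag`` shared k-mers on one alignment diagonal,
    mapped to the representative diagonal of the strongest band.

    Complements :func:`kmer_candidates` for deeply diverged homologs
    (~30-40% identity), whose few surviving exact 5-mers are easily
    missed: true homologs concentrate short-word matches on the alignment
    diagonal, while random pairs scatter them across all diagonals.
    Diagonals are binned into ``bucket``-wide bands to tolerate small
    indels.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    for j, p in enumerate(prots_b):
        s = p.seq
        for x in range(len(s) - k + 1):
            index.setdefault(s[x:x + k], []).append((j, x))
    pairs: dict[tuple[int, int], int] = {}
    for i, p in enumerate(prots_a):
        counts: dict[tuple[int, int], int] = {}
        s = p.seq
        for x in range(len(s) - k + 1):
            for j, y in index.get(s[x:x + k], ()):
                key = (j, (y - x) // bucket)
                counts[key] = counts.get(key, 0) + 1
        best: dict[int, tuple[int, int]] = {}
        for (j, d), c in counts.items():
            if c >= min_diag and (j not in best or c > best[j][0]):
                best[j] = (c, d)
        for j, (_c, d) in best.items():
            pairs[(i, j)] = d * bucket + bucket // 2  # representative diagonal
    return pairs


def _diagonal_identity(sa: str, sb: str, diag: int, halfband: int = 6) -> float:
    """Best ungapped identity fraction near a diagonal (cheap DP screen)."""
    a = np.frombuffer(sa.encode(), dtype=np.uint8)
    b = np.frombuffer(sb.encode(), dtype=np.uint8)
    best = 0.0
    for d in range(diag - halfband, diag + halfband + 1):
        lo = max(0, -d)
        hi = min(len(a), len(b) - d)
        if hi - lo < 30:
            continue
        frac = float((a[lo:hi] == b[lo + d:hi + d]).mean())
        best = max(best, frac)
    return best


def pairwise_proteome_hits(
    prots_a: list[SequenceRecord],
    prots_b: list[SequenceRecord],
    min_score: float = 50.0,
    min_shared_kmers: int = 2,
) -> list[ProteinHit]:
    """All candidate protein alignments between two proteomes.

    Candidates come from two complementary seeding rules — shared 5-mers
    anywhere, or shared 3-mers concentrated on one diagonal (the latter
    pre-screened by a cheap ungapped diagonal identity check) — then get
    a full BLOSUM62 local alignment.
    """
    aligner = protein_aligner()
    cands = set(kmer_candidates(prots_a, prots_b,
                                min_shared=min_shared_kmers))
    for (i, j), diag in diagonal_kmer_candidates(prots_a, prots_b).items():
        if (i, j) in cands:
            continue
        if _diagonal_identity(prots_a[i].seq, prots_b[j].seq, diag) >= 0.25:
            cands.add((i, j))
    out = []
    for i, j in sorted(cands):
        hit = align_proteins(prots_a[i], prots_b[j], aligner)
        if hit is not None and hit.score >= min_score:
            out.append(hit)
    return out


def best_hits(hits: list[ProteinHit]) -> dict[str, ProteinHit]:
    """Best hit per query with deterministic tie-breaking
    (score, then aln_len, then lexicographic subject id)."""
    best: dict[str, ProteinHit] = {}
    for h in sorted(hits, key=lambda h: (h.query_id, -h.score, -h.aln_len,
                                         h.subject_id)):
        best.setdefault(h.query_id, h)
    return best


def reciprocal_best_hits(
    hits_ab: list[ProteinHit], hits_ba: list[ProteinHit]
) -> list[tuple[ProteinHit, ProteinHit]]:
    ba = best_hits(hits_ba)
    out = []
    for qid, h in sorted(best_hits(hits_ab).items()):
        back = ba.get(h.subject_id)
        if back is not None and back.subject_id == qid:
            out.append((h, back))
    return out
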