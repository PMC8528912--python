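"""Readers/writers and shared primitive types for the pipeline.

Formats handled here: FASTA (DNA and protein sequences), a GFF3-subset
gene-table dialect (tab-separated, CDS features only), Newick trees, square
TSV matrices, and YAML configuration.  Coordinates are 1-based inclusive
(GFF3 convention) throughout the package.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("ogripan")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class OgripanError(Exception):
    """Base class for typed pipeline errors."""


class DuplicateIdError(OgripanError):
    pass


class AlphabetError(OgripanError):
    pass


class GeneTableError(OgripanError):
    pass


class NewickError(OgripanError):
    pass


class MatrixFormatError(OgripanError):
    pass


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------

# DNA: unambiguous bases, N, and the IUPAC ambiguity codes. Codes other than
# ACGT are preserved on input but treated as N by all k-mer/alignment code.
_DNA_RE = re.compile(r"^[ACGTNRYSWKMBDHV]*$")
_PROT_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]*$")
_ALPHA_RE = {"dna": _DNA_RE, "protein": _PROT_RE}


@dataclass
class SequenceRecord:
    """A named biological sequence (DNA or protein)."""

    id: str
    seq: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.alphabet not in _ALPHA_RE:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.seq = self.seq.upper()
        m = _ALPHA_RE[self.alphabet]
        if not m.match(self.seq):
            pos = next(
                i for i, c in enumerate(self.seq) if not m.match(c)
            )
            raise AlphabetError(
                f"illegal {self.alphabet} character {self.seq[pos]!r} at "
                f"position {pos + 1} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "dna":
            raise ValueError("reverse complement only defined for DNA")
        return SequenceRecord(
            self.id, str(Seq(self.seq).reverse_complement()), "dna",
            self.description,
        )


def parse_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Parse a FASTA file into validated records (order preserved).

    Lowercase is normalized to uppercase.  Duplicate ids and illegal
    characters raise typed errors; an empty file returns an empty list with
    a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet, desc))
    if not records:
        logger.warning("no records parsed from %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables (GFF3 subset)
# ---------------------------------------------------------------------------

GENE_COLUMNS = [
    "genome_id", "gene_id", "contig_id", "start", "end", "strand",
    "protein_id", "product",
]


class GeneTable:
    """Annotated CDS features of one genome.

    Thin wrapper over a pandas DataFrame with columns ``GENE_COLUMNS``;
    coordinates are 1-based inclusive on the forward strand of the contig
    (strand does not flip coordinates).  Rows are kept sorted by
    (contig_id, start) with a stable sort, so overlapping genes retain
    input order within equal starts.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in GENE_COLUMNS if c not in df.columns]
        if missing:
            raise GeneTableError(f"gene table missing columns {missing}")
        df = df[GENE_COLUMNS].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] < 1).any() or (df["start"] > df["end"]).any():
            bad = df[(df["start"] < 1) | (df["start"] > df["end"])].iloc[0]
            raise GeneTableError(
                f"invalid coordinates for gene {bad['gene_id']!r}: "
                f"start={bad['start']} end={bad['end']}"
            )
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise GeneTableError(
                f"unknown strand symbol "
                f"{df.loc[bad_strand, 'strand'].iloc[0]!r}"
            )
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise GeneTableError(f"duplicate gene_id {dup!r}")
        self.df = df.sort_values(
            ["contig_id", "start"], kind="stable"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneTable) and self.df.equals(other.df)

    @property
    def genome_id(self) -> str:
        return str(self.df["genome_id"].iloc[0]) if len(self.df) else ""

    def validate_against(self, genome: Sequence[SequenceRecord]) -> None:
        """Check every gene fits inside its contig."""
        lengths = {rec.id: len(rec) for rec in genome}
        for row in self.df.itertuples():
            if row.contig_id not in lengths:
                raise GeneTableError(
                    f"gene {row.gene_id!r} on unknown contig {row.contig_id!r}"
                )
            if row.end > lengths[row.contig_id]:
                raise GeneTableError(
                    f"gene {row.gene_id!r} extends past contig end "
                    f"({row.end} > {lengths[row.contig_id]})"
                )


_ATTR_RE = re.compile(r"(\w+)=([^;]*)")


def parse_gene_table(path, genome_id: str | None = None) -> GeneTable:
    """Parse a GFF3-subset gene table (CDS lines only, others ignored).

    Attribute keys used: ``ID`` (gene_id), ``protein_id`` (defaults to ID)
    and ``product``.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GeneTableError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(parts)}"
                )
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            attrd = dict(_ATTR_RE.findall(attrs))
            gene_id = attrd.get("ID")
            if not gene_id:
                raise GeneTableError(f"{path}:{lineno}: CDS without ID attribute")
            rows.append({
                "genome_id": genome_id,
                "gene_id": gene_id,
                "contig_id": seqid,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "protein_id": attrd.get("protein_id", gene_id),
                "product": attrd.get("product", ""),
            })
    return GeneTable(pd.DataFrame(rows, columns=GENE_COLUMNS))


def write_gene_table(table: GeneTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in table.df.itertuples():
            attrs = f"ID={row.gene_id};protein_id={row.protein_id}"
            if row.product:
                attrs += f";product={row.product}"
            fh.write(
                f"{row.contig_id}\togripan\tCDS\t{row.start}\t{row.end}\t."
                f"\t{row.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def _check_parentheses(s: str) -> None:
    depth = 0
    for i, c in enumerate(s):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(f"unbalanced parentheses at character {i}")
    if depth != 0:
        raise NewickError(
            f"unbalanced parentheses: {depth} unclosed at end of string"
        )


def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree from a string or path.

    Internal node labels are interpreted as numeric supports downstream.
    Raises :class:`NewickError` on unbalanced parentheses (with character
    offset) or duplicate leaf names.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).is_file():
        text = Path(source).read_text()
    else:
        text = str(source)
    _check_parentheses(text)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dups = {x for x in labels if labels.count(x) > 1}
    if dups:
        raise NewickError(f"duplicate leaf name(s): {sorted(dups)}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize with 10 significant digits on branch lengths."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


# ---------------------------------------------------------------------------
# Matrix TSV exchange format
# ---------------------------------------------------------------------------


def write_matrix_tsv(ids: Sequence[str], values: np.ndarray, path) -> None:
    """Square TSV with header row/column; values to 4 decimals, NA for
    flagged (incomputable) cells.  Symmetric matrices are stored fully."""
    df = pd.DataFrame(values, index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", float_format="%.4f", na_rep="NA")


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    ids = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != ids:
        raise MatrixFormatError(
            f"{path}: matrix row and column ids differ"
        )
    return ids, df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Genome set container and on-disk layout
# ---------------------------------------------------------------------------


@dataclass
class GenomeSet:
    """In-memory bundle of genomes, proteomes, gene tables and markers."""

    genomes: dict[str, list[SequenceRecord]]  # genome_id -> contigs
    proteomes: dict[str, list[SequenceRecord]]
    gene_tables: dict[str, GeneTable]
    markers_16s: dict[str, SequenceRecord] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return sorted(self.genomes)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        for sub in ("genomes", "proteins", "tables"):
            (outdir / sub).mkdir(parents=True, exist_ok=True)
        for gid in self.ids:
            write_fasta(self.genomes[gid], outdir / "genomes" / f"{gid}.fna")
            write_fasta(self.proteomes[gid], outdir / "proteins" / f"{gid}.faa")
            write_gene_table(self.gene_tables[gid], outdir / "tables" / f"{gid}.gff")
        if self.markers_16s:
            write_fasta(
                [self.markers_16s[g] for g in self.ids],
                outdir / "markers_16s.fasta",
            )

    @classmethod
    def read(cls, indir) -> "GenomeSet":
        indir = Path(indir)
        genomes, proteomes, tables = {}, {}, {}
        for f in sorted((indir / "genomes").glob("*.fna")):
            genomes[f.stem] = parse_fasta(f, "dna")
        for f in sorted((indir / "proteins").glob("*.faa")):
            proteomes[f.stem] = parse_fasta(f, "protein")
        for f in sorted((indir / "tables").glob("*.gff")):
            tables[f.stem] = parse_gene_table(f)
        markers = {}
        mf = indir / "markers_16s.fasta"
        if mf.exists():
            for r in parse_fasta(mf, "dna"):
                gid = r.id[:-4] if r.id.endswith("_16S") else r.id
                markers[gid] = r
        logger.info("read %d genomes from %s", len(genomes), indir)
        return cls(genomes, proteomes, tables, markers)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class OgriThresholds:
    """Rank-delimitation cutoffs (percent).

    ``aai_genus`` carries a documented gray zone [65, 72]; 70 is the
    decision line.  ``ddh_subspecies`` is a configurable stand-in, not a
    literature constant.
    """

    aai_genus: float = 70.0
    aai_genus_gray: tuple[float, float] = (65.0, 72.0)
    ani_species: float = 95.9
    ddh_species: float = 70.0
    id16s_species: float = 98.7
    ddh_subspecies: float = 79.0

    def __post_init__(self) -> None:
        for name in ("aai_genus", "ani_species", "ddh_species",
                     "id16s_species", "ddh_subspecies"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name}={v} outside (0, 100]")


@dataclass
class PipelineConfig:
    """Cutoffs and plumbing shared across pipeline stages.

    The E-value cutoffs of the reference workflow are realized as minimum
    alignment scores (``min_dna_score``, ``min_protein_score``), since the
    internal aligner has no database-size statistics.
    """

    thresholds: OgriThresholds = field(default_factory=OgriThresholds)
    fragment_size: int = 1020        # bp, ANIb fragment length
    window_k: int = 5                # genes, concurrence window half-width
    rng_seed: int = 0
    # dDDH formula-2 logistic map: ddh = 1/(1 + exp(-(a + b * d2)))
    ddh_logistic_a: float = 2.149435
    ddh_logistic_b: float = -24.452202
    # alignment score floors standing in for E-value cutoffs
    min_dna_score: int = 25
    min_protein_score: float = 50.0
    # AAI reciprocal-best-hit filters
    aai_min_identity: float = 30.0
    aai_min_coverage: float = 0.70   # of the shorter sequence
    # pangenome hit filters
    pangenome_min_coverage: float = 0.75  # of the query
    paralog_identity_cutoff: float = 60.0
    tzmd_normalization: str = "mean"  # {"mean", "raw"}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        th = data.pop("thresholds", {})
        cfg = cls(**data)
        if th:
            cfg.thresholds = OgriThresholds(**th)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
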