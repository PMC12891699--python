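"""Genome, protein and metadata I/O, plus the MAG quality gate.

Genomes and proteins arrive as FASTA (proteins typically with prodigal-style
headers); per-genome quality metrics (CheckM-style completeness/contamination
estimates) and taxonomy arrive as a TSV. The quality gate retains
medium-or-better MAGs: completeness >= 50% (inclusive) and contamination
< 10% (exclusive).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted in genome sequences.
NUCLEOTIDE_CODES = frozenset("ACGTURYSWKMBDHVN")
#: IUPAC amino-acid codes (incl. ambiguity codes and X); '*' stops are stripped.
AMINO_ACID_CODES = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO")

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_PRODIGAL_ID = re.compile(r"^(?P<contig>.+)_(?P<n>\d+)$")


def parse_lineage(value) -> Optional[tuple]:
    """Normalize a semicolon-joined 7-rank lineage into a tuple.

    Accepts GTDB-style prefixed ranks (``p__Actinobacteria``) or bare names;
    missing trailing ranks are padded with empty strings. Returns ``None``
    for empty input.
    """
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        parts = [str(p).strip() for p in value]
    else:
        text = str(value).strip()
        if not text or text.lower() == "nan":
            return None
        parts = [p.strip() for p in text.split(";")]
    parts = parts[: len(RANKS)]
    parts += [""] * (len(RANKS) - len(parts))
    return tuple(parts)


def lineage_rank(lineage, rank: str) -> Optional[str]:
    """Extract one rank (e.g. ``'phylum'``) from a lineage, stripping any
    GTDB ``x__`` prefix. Returns ``None`` when absent or empty."""
    lin = parse_lineage(lineage)
    if lin is None:
        return None
    value = lin[RANKS.index(rank)]
    if "__" in value:
        value = value.split("__", 1)[1]
    return value or None


@dataclass
class GenomeRecord:
    """A genome or MAG: contigs plus quality and taxonomy metadata."""

    genome_id: str
    contigs: dict  # contig_id -> uppercase nucleotide sequence, file order
    completeness: Optional[float] = None  # percent in [0, 100]
    contamination: Optional[float] = None  # percent in [0, 100]
    lineage: Optional[tuple] = None  # 7 ranks, empty strings allowed
    source: str = ""

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_length(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])

    @property
    def phylum(self) -> Optional[str]:
        return lineage_rank(self.lineage, "phylum")


@dataclass
class Protein:
    protein_id: str
    aa_sequence: str
    contig_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None  # '+' or '-'


@dataclass
class ProteinSet:
    """Predicted proteins of one genome, keyed by protein id."""

    genome_id: str
    proteins: dict = field(default_factory=dict)  # protein_id -> Protein

    def __len__(self) -> int:
        return len(self.proteins)

    def contig_of(self, protein_id: str) -> Optional[str]:
        prot = self.proteins.get(protein_id)
        return prot.contig_id if prot is not None else None


def read_genome_fasta(
    path, genome_id: str, metadata: Optional[Mapping] = None
) -> GenomeRecord:
    """Read a genome FASTA into a :class:`GenomeRecord`.

    Contig order follows the file; sequences are uppercased and validated
    against IUPAC nucleotide codes. ``metadata`` may supply ``completeness``,
    ``contamination``, ``lineage`` and ``source``.

    Raises
    ------
    ValueError
        If the file is empty, a contig header repeats, or a sequence
        contains a non-IUPAC character.
    """
    path = Path(path)
    contigs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(
                f"duplicate contig header {rec.id!r} in {path}"
            )
        seq = str(rec.seq).upper()
        bad = set(seq) - NUCLEOTIDE_CODES
        if bad:
            raise ValueError(
                f"contig {rec.id!r} in {path} contains non-IUPAC "
                f"nucleotide code(s): {sorted(bad)}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")

    meta = dict(metadata) if metadata is not None else {}

    def _num(key):
        val = meta.get(key)
        return None if val is None or val == "" else float(val)

    return GenomeRecord(
        genome_id=genome_id,
        contigs=contigs,
        completeness=_num("completeness"),
        contamination=_num("contamination"),
        lineage=parse_lineage(meta.get("lineage")),
        source=str(meta.get("source", "")),
    )


def write_genome_fasta(genome: GenomeRecord, path, width: int = 70) -> None:
    """Write contigs to FASTA, wrapping lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for contig_id, seq in genome.contigs.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_prodigal_header(rec) -> Optional[Protein]:
    """Try the prodigal header dialect ``<contig>_<n> # start # end # strand # ...``."""
    fields = [f.strip() for f in rec.description.split("#")]
    if len(fields) < 4:
        return None
    m = _PRODIGAL_ID.match(rec.id)
    if m is None:
        return None
    try:
        start, end = int(fields[1]), int(fields[2])
        strand_raw = fields[3]
    except (ValueError, IndexError):
        return None
    strand = {"1": "+", "+1": "+", "+": "+", "-1": "-", "-": "-"}.get(strand_raw)
    if strand is None or start > end:
        return None
    return Protein(
        protein_id=rec.id,
        aa_sequence="",
        contig_id=m.group("contig"),
        start=start,
        end=end,
        strand=strand,
    )


def read_proteins(path, genome_id: str = "") -> ProteinSet:
    """Read predicted proteins from amino-acid FASTA.

    The prodigal header dialect is auto-detected *per record*: when a header
    reads ``<contig>_<n> # start # end # strand # ...`` the contig id is
    recovered by stripping the trailing ``_<n>``. Records with plain headers
    get ``contig_id=None`` (contig-level screening is skipped for them) and
    a warning is logged.
    """
    path = Path(path)
    pset = ProteinSet(genome_id=genome_id)
    n_plain = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - AMINO_ACID_CODES
        if bad:
            raise ValueError(
                f"protein {rec.id!r} in {path} contains non-amino-acid "
                f"residue(s): {sorted(bad)}"
            )
        prot = _parse_prodigal_header(rec)
        if prot is None:
            n_plain += 1
            prot = Protein(protein_id=rec.id, aa_sequence=seq)
        else:
            prot.aa_sequence = seq
        if prot.protein_id in pset.proteins:
            raise ValueError(f"duplicate protein id {prot.protein_id!r} in {path}")
        pset.proteins[prot.protein_id] = prot
    if n_plain:
        logger.warning(
            "%d protein(s) in %s lack prodigal-style headers; "
            "contig screening will be skipped for them",
            n_plain,
            path,
        )
    return pset


def read_metadata(path) -> pd.DataFrame:
    """Read the genome metadata TSV (columns ``genome_id``, ``completeness``,
    ``contamination``, optional ``lineage``, ``source``), indexed by genome id."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    if "genome_id" not in df.columns:
        raise ValueError(f"metadata file {path} lacks a 'genome_id' column")
    return df.set_index("genome_id")


def quality_filter(
    genomes: Sequence[GenomeRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list:
    """Apply the MAG quality gate.

    A genome is retained iff ``completeness >= min_completeness`` (inclusive)
    and ``contamination < max_contamination`` (strict), matching the
    medium-quality convention for CheckM estimates. Input order is preserved
    and the number removed is logged.

    Raises
    ------
    ValueError
        If any genome lacks a completeness or contamination value.
    """
    kept = []
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            raise ValueError(
                f"genome {g.genome_id!r} lacks completeness/contamination; "
                "cannot apply quality filter"
            )
        if g.completeness >= min_completeness and g.contamination < max_contamination:
            kept.append(g)
    removed = len(genomes) - len(kept)
    if removed:
        logger.info("quality_filter removed %d of %d genomes", removed, len(genomes))
    return kept


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide sequence (IUPAC-aware)."""
    return str(Seq(seq).reverse_complement())
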