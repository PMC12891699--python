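"""Producer/nonproducer 16S rRNA reference construction and OTU annotation.

16S sequences are extracted from classified genomes (via rRNA feature
coordinates), length-filtered and dereplicated into a nonredundant
producer reference plus a nonproducer control set. Amplicon OTU
representatives are then annotated by exact matching: a query hits a
reference iff it is identical to it, or an exact gap-free substring of it,
on either strand — i.e. 100% identity over 100% of the query. Sequences
whose string occurs in both the producer and control sets are quarantined
as conflicted, because a single 16S cannot separate the two phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .genome_io import GenomeRecord, reverse_complement
from .network import AbundanceTable

logger = logging.getLogger(__name__)

PRODUCER_CLASSES = ("very_likely", "likely", "possible")
#: Preference order when several producer references match one OTU.
CLASS_PRIORITY = {"very_likely": 0, "likely": 1, "possible": 2}


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class SSURecord:
    """One 16S rRNA sequence tied to its source genome."""

    seq_id: str
    source_genome_id: str
    sequence: str  # uppercase, U -> T
    phenotype_label: Optional[str] = None
    lineage: Optional[tuple] = None

    def __post_init__(self):
        self.sequence = _normalize(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDB:
    """Curated soil-cobamide-producer 16S reference plus nonproducer control set."""

    producers: list  # of SSURecord
    nonproducers: list
    conflicted: list = field(default_factory=list)
    build_params: dict = field(default_factory=dict)


@dataclass
class OTUAnnotation:
    otu_id: str
    call: str  # producer | nonproducer | ambiguous | unassigned
    phenotype: Optional[str] = None  # best matched producer class
    matched_refs: list = field(default_factory=list)


def extract_ssu(genome: GenomeRecord, rrna_gff) -> list:
    """Extract 16S sequences from a genome using rRNA coordinates in GFF3.

    Rows of type ``rRNA`` whose product/Name attribute mentions ``16S`` are
    sliced out (1-based inclusive coordinates); minus-strand features are
    reverse-complemented.

    Raises
    ------
    ValueError
        If feature coordinates exceed the contig length.
    """
    records = []
    with open(rrna_gff) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype != "rRNA":
                continue
            labels = [
                v
                for key in ("product", "Name", "name", "gene")
                for v in feat.attributes.get(key, [])
            ]
            if not any("16S" in v for v in labels):
                continue
            if feat.seqid not in genome.contigs:
                raise ValueError(
                    f"GFF feature on contig {feat.seqid!r} absent from "
                    f"genome {genome.genome_id!r}"
                )
            contig = genome.contigs[feat.seqid]
            if feat.end > len(contig) or feat.start < 1:
                raise ValueError(
                    f"16S feature {feat.seqid}:{feat.start}-{feat.end} exceeds "
                    f"contig length {len(contig)}"
                )
            seq = contig[feat.start - 1 : feat.end]
            if feat.strand == "-":
                seq = reverse_complement(seq)
            records.append(
                SSURecord(
                    seq_id=f"{genome.genome_id}|{feat.seqid}:{feat.start}-{feat.end}",
                    source_genome_id=genome.genome_id,
                    sequence=seq,
                    lineage=genome.lineage,
                )
            )
    return records


def dereplicate(records: Sequence[SSURecord], min_len: int = 1000) -> list:
    """Length-filter and collapse a 16S set to nonredundant representatives.

    Records shorter than ``min_len`` are dropped (strict). Exact duplicates
    and exact substrings collapse onto one representative — the longest
    sequence, ties broken by lexicographically smallest ``seq_id``. Output
    sorted by ``seq_id``; idempotent.
    """
    survivors = [r for r in records if r.length >= min_len]
    # longest first so every later record is either novel or a substring of a kept one
    ordered = sorted(survivors, key=lambda r: (-r.length, r.seq_id))
    reps: list = []
    for rec in ordered:
        if any(rec.sequence in kept.sequence for kept in reps):
            continue
        reps.append(rec)
    return sorted(reps, key=lambda r: r.seq_id)


def build_db(
    calls: Sequence,
    ssu: Sequence[SSURecord],
    include_classes: Iterable[str] = PRODUCER_CLASSES,
    min_len: int = 1000,
) -> ReferenceDB:
    """Assemble the producer/nonproducer reference from phenotype calls.

    SSU records are routed by their source genome's phenotype (producer set
    = classes in ``include_classes``; control set = nonproducer genomes),
    each set dereplicated, and identical sequence strings across the two
    sets quarantined into ``conflicted``.

    Raises
    ------
    ValueError
        If an SSU record's source genome has no phenotype call.
    """
    include = set(include_classes)
    call_by_genome = {c.genome_id: c for c in calls}
    producers, nonproducers = [], []
    for rec in ssu:
        call = call_by_genome.get(rec.source_genome_id)
        if call is None:
            raise ValueError(
                f"SSU record {rec.seq_id!r} has unknown source genome "
                f"{rec.source_genome_id!r}"
            )
        rec.phenotype_label = call.phenotype
        if call.phenotype in include:
            producers.append(rec)
        elif call.phenotype == "nonproducer":
            nonproducers.append(rec)

    producers = dereplicate(producers, min_len=min_len)
    nonproducers = dereplicate(nonproducers, min_len=min_len)

    producer_strings = {r.sequence for r in producers}
    control_strings = {r.sequence for r in nonproducers}
    clash = producer_strings & control_strings
    conflicted = [r for r in producers + nonproducers if r.sequence in clash]
    if clash:
        logger.warning(
            "%d sequence string(s) occur in both sets; quarantined as conflicted",
            len(clash),
        )
    producers = [r for r in producers if r.sequence not in clash]
    nonproducers = [r for r in nonproducers if r.sequence not in clash]
    if not nonproducers:
        logger.warning("reference built with an empty nonproducer control set")

    return ReferenceDB(
        producers=producers,
        nonproducers=nonproducers,
        conflicted=conflicted,
        build_params={"include_classes": sorted(include), "min_len": min_len},
    )


def write_db(db: ReferenceDB, outdir) -> dict:
    """Write the reference as a FASTA pair plus a metadata TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "producers": outdir / "scp16s_producers.fasta",
        "control": outdir / "scp16s_control.fasta",
        "metadata": outdir / "scp16s_metadata.tsv",
    }
    for key, records in (("producers", db.producers), ("control", db.nonproducers)):
        with paths[key].open("w") as fh:
            for rec in records:
                fh.write(f">{rec.seq_id}\n{rec.sequence}\n")
    rows = [
        {
            "seq_id": rec.seq_id,
            "source_genome": rec.source_genome_id,
            "phenotype": rec.phenotype_label or "",
            "lineage": ";".join(rec.lineage) if rec.lineage else "",
            "length": rec.length,
            "set": which,
        }
        for which, records in (
            ("producer", db.producers),
            ("nonproducer", db.nonproducers),
            ("conflicted", db.conflicted),
        )
        for rec in records
    ]
    pd.DataFrame(
        rows,
        columns=["seq_id", "source_genome", "phenotype", "lineage", "length", "set"],
    ).to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def read_db(producers_fasta, control_fasta, metadata_tsv=None) -> ReferenceDB:
    """Load a reference written by :func:`write_db`."""
    meta = {}
    if metadata_tsv is not None:
        df = pd.read_csv(metadata_tsv, sep="\t")
        meta = {row.seq_id: row for row in df.itertuples()}

    def _load(path, default_label):
        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            info = meta.get(rec.id)
            out.append(
                SSURecord(
                    seq_id=rec.id,
                    source_genome_id=getattr(info, "source_genome", ""),
                    sequence=str(rec.seq),
                    phenotype_label=getattr(info, "phenotype", default_label)
                    or default_label,
                )
            )
        return out

    return ReferenceDB(
        producers=_load(producers_fasta, "possible"),
        nonproducers=_load(control_fasta, "nonproducer"),
    )


QuerySource = Union[str, Path, Sequence]


def _load_queries(query: QuerySource) -> list:
    if isinstance(query, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(query), "fasta")]
    else:
        records = [(qid, seq) for qid, seq in query]
    if not records:
        raise ValueError("no query sequences supplied")
    return records


def annotate_otus(query: QuerySource, db: ReferenceDB) -> list:
    """Annotate OTU representatives against the reference by exact matching.

    A query matches a reference iff the query (or its reverse complement) is
    an exact, gap-free substring of the reference, or equal to it — 100%
    identity over the full query. Calls: ``producer`` if only producer
    references match, ``nonproducer`` if only control references match,
    ``ambiguous`` if both, ``unassigned`` if none. The reported phenotype is
    the best class among matched producers.
    """
    annotations = []
    for otu_id, raw in _load_queries(query):
        q = _normalize(raw)
        qrc = reverse_complement(q)

        def _matches(refs):
            return [
                r.seq_id
                for r in refs
                if q in r.sequence or qrc in r.sequence
            ]

        prod = _matches(db.producers)
        ctrl = _matches(db.nonproducers)
        if prod and ctrl:
            call = "ambiguous"
        elif prod:
            call = "producer"
        elif ctrl:
            call = "nonproducer"
        else:
            call = "unassigned"
        phenotype = None
        if prod:
            by_id = {r.seq_id: r for r in db.producers}
            phenotype = min(
                (by_id[s].phenotype_label or "possible" for s in prod),
                key=lambda c: CLASS_PRIORITY.get(c, 99),
            )
        annotations.append(
            OTUAnnotation(
                otu_id=otu_id,
                call=call,
                phenotype=phenotype,
                matched_refs=prod + ctrl,
            )
        )
    return annotations


def annotations_table(annotations: Sequence[OTUAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu_id": a.otu_id,
                "call": a.call,
                "phenotype": a.phenotype or "",
                "matched_refs": ";".join(a.matched_refs),
            }
            for a in annotations
        ],
        columns=["otu_id", "call", "phenotype", "matched_refs"],
    )


def producer_profile(
    otu_table: AbundanceTable, annotations: Sequence[OTUAnnotation]
) -> pd.DataFrame:
    """Per-sample producer summary from annotated OTU counts.

    Reports, per sample, the relative abundance of producer OTUs, the number
    of producer OTUs with nonzero reads, and the producer-read fraction per
    phenotype class. OTUs lacking an annotation are treated as unassigned
    with a warning; a zero-read sample gets fraction 0 and an
    ``empty_sample`` flag.
    """
    counts = otu_table.counts
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts in abundance table")
    ann_by_otu = {a.otu_id: a for a in annotations}
    missing = [o for o in counts.index if o not in ann_by_otu]
    if missing:
        logger.warning(
            "%d OTU(s) lack annotations; treated as unassigned", len(missing)
        )

    producer_otus = [
        o
        for o in counts.index
        if o in ann_by_otu and ann_by_otu[o].call == "producer"
    ]
    rows = []
    for sample in counts.columns:
        col = counts[sample]
        total = int(col.sum())
        prod_reads = int(col.loc[producer_otus].sum()) if producer_otus else 0
        row = {
            "sample_id": sample,
            "producer_fraction": prod_reads / total if total else 0.0,
            "n_producer_otus": int((col.loc[producer_otus] > 0).sum())
            if producer_otus
            else 0,
            "flags": "" if total else "empty_sample",
        }
        for cls in PRODUCER_CLASSES:
            cls_otus = [
                o
                for o in producer_otus
                if (ann_by_otu[o].phenotype or "possible") == cls
            ]
            reads = int(col.loc[cls_otus].sum()) if cls_otus else 0
            row[f"fraction_{cls}"] = reads / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
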