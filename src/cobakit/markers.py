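"""Cobamide-pathway marker catalog and per-genome marker evidence.

The cobamide (vitamin B12) biosynthesis pathway is detected through profile
searches (HMMER) of predicted proteins against a catalog of marker profiles
drawn from KO/TIGRFAM/PFAM families. This module turns raw per-domain search
output into a clean per-genome presence map:

* an E-value gate (full-sequence E <= 1e-6, boundary inclusive),
* one-protein-one-marker resolution (best bit score wins), so a single
  promiscuous protein cannot inflate pathway completeness,
* contig-level screening against false positives from contamination or
  fragmentary assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .genome_io import GenomeRecord, ProteinSet, lineage_rank

logger = logging.getLogger(__name__)

MODULES = ("precursor", "ring", "chelation", "adenosylation", "loop", "salvage")
BRANCHES = ("aerobic", "anaerobic", "shared")

#: Full-sequence E-value gate for accepting a profile hit.
DEFAULT_E_MAX = 1e-6


@dataclass(frozen=True)
class MarkerEntry:
    """One marker in the pathway ontology."""

    marker_id: str
    gene_symbol: str
    profile_accessions: tuple  # KO/TIGRFAM/PFAM/UniProt identifiers
    module: str  # one of MODULES
    branch: str  # one of BRANCHES
    required: bool = True
    weight: float = 1.0


@dataclass
class MarkerCatalog:
    """The marker ontology for cobamide biosynthesis.

    Invariants: marker ids unique; each oxygen branch has at least one
    required ring-module marker; the catalog has at least one required
    loop-module marker; all weights positive.
    """

    entries: list  # of MarkerEntry

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [e.marker_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker_id(s) in catalog: {dupes}")
        for e in self.entries:
            if e.module not in MODULES:
                raise ValueError(f"marker {e.marker_id}: unknown module {e.module!r}")
            if e.branch not in BRANCHES:
                raise ValueError(f"marker {e.marker_id}: unknown branch {e.branch!r}")
            if e.weight <= 0:
                raise ValueError(f"marker {e.marker_id}: weight must be > 0")
        for branch in ("aerobic", "anaerobic"):
            if not any(
                e.module == "ring" and e.branch == branch and e.required
                for e in self.entries
            ):
                raise ValueError(
                    f"catalog lacks a required ring-module marker for the "
                    f"{branch} branch"
                )
        if not any(e.module == "loop" and e.required for e in self.entries):
            raise ValueError("catalog lacks a required loop-module marker")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, marker_id: str) -> MarkerEntry:
        return self.by_id()[marker_id]

    def by_id(self) -> dict:
        return {e.marker_id: e for e in self.entries}

    def by_accession(self) -> dict:
        """Map every profile accession (and marker id / gene symbol) to its entry."""
        index: dict = {}
        for e in self.entries:
            for acc in e.profile_accessions:
                index[acc] = e
            index.setdefault(e.marker_id, e)
            index.setdefault(e.gene_symbol, e)
        return index

    def required_markers(self, branch: str) -> list:
        """Required markers counting toward ``branch`` (branch-exclusive + shared)."""
        return [
            e
            for e in self.entries
            if e.required and e.branch in (branch, "shared")
        ]

    def exclusive_markers(self, branch: str) -> list:
        """Markers diagnostic for exactly one oxygen branch."""
        return [e for e in self.entries if e.branch == branch]


def load_catalog(path) -> MarkerCatalog:
    """Load a marker catalog from TSV with columns
    ``marker_id, gene_symbol, profile_accessions, module, branch, required, weight``
    (accessions comma-joined; ``required`` as true/false)."""
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        needed = {"marker_id", "gene_symbol", "profile_accessions", "module", "branch"}
        missing = needed - set(idx)
        if missing:
            raise ValueError(f"catalog {path} missing column(s): {sorted(missing)}")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            entries.append(
                MarkerEntry(
                    marker_id=cols[idx["marker_id"]],
                    gene_symbol=cols[idx["gene_symbol"]],
                    profile_accessions=tuple(
                        a.strip()
                        for a in cols[idx["profile_accessions"]].split(",")
                        if a.strip()
                    ),
                    module=cols[idx["module"]],
                    branch=cols[idx["branch"]],
                    required=(
                        cols[idx["required"]].strip().lower() in ("true", "1", "yes")
                        if "required" in idx and len(cols) > idx["required"]
                        else True
                    ),
                    weight=(
                        float(cols[idx["weight"]])
                        if "weight" in idx and len(cols) > idx["weight"]
                        else 1.0
                    ),
                )
            )
    return MarkerCatalog(entries)


def default_catalog() -> MarkerCatalog:
    """The catalog shipped with the package (``data/scp_markers.tsv``).

    A curated default keyed to cobalamin-biosynthesis KO/TIGRFAM accessions;
    it is data, not code, so an authoritative profile list can replace it
    without any code change.
    """
    ref = resources.files("cobakit").joinpath("data/scp_markers.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)


@dataclass(frozen=True)
class MarkerHit:
    """One profile-search hit of a protein against a marker profile."""

    protein_id: str
    marker_id: str
    evalue: float
    bitscore: float
    contig_id: Optional[str] = None
    ali_from: int = 1  # 1-based inclusive, on the protein
    ali_to: int = 1

    def __post_init__(self):
        if self.ali_from > self.ali_to:
            raise ValueError(
                f"hit {self.protein_id}->{self.marker_id}: ali_from > ali_to"
            )
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclass
class PresenceMap:
    """Resolved per-genome marker evidence."""

    genome_id: str
    detected: dict = field(default_factory=dict)  # marker_id -> [MarkerHit]
    flags: list = field(default_factory=list)

    def markers(self) -> list:
        return sorted(self.detected)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.detected


# HMMER3 --domtblout has 22 whitespace-separated columns + free-text description.
_DOMTBL_MIN_COLS = 23


def parse_domtbl(
    path,
    catalog: MarkerCatalog,
    proteins: Optional[ProteinSet] = None,
) -> list:
    """Parse a HMMER3 ``--domtblout`` file into :class:`MarkerHit` records.

    One hit is emitted per domain line whose query name or accession maps to
    a catalog profile accession; unmapped profiles are skipped with a debug
    log. The *full-sequence* E-value and bit score (columns 7-8) are used,
    matching default hmmsearch reporting. When ``proteins`` is given, contig
    ids are attached from it.

    Raises
    ------
    ValueError
        On a non-comment line with fewer than 23 columns (line number named).
    """
    index = catalog.by_accession()
    hits: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {_DOMTBL_MIN_COLS} "
                    f"domtblout columns, found {len(cols)}"
                )
            target, query_name, query_acc = cols[0], cols[3], cols[4]
            entry = index.get(query_acc) or index.get(query_name)
            if entry is None:
                # also tolerate versioned accessions like TIGR01465.1
                entry = index.get(query_acc.split(".")[0])
            if entry is None:
                logger.debug(
                    "domtbl line %d: profile %r/%r not in catalog; skipped",
                    lineno,
                    query_name,
                    query_acc,
                )
                continue
            contig = proteins.contig_of(target) if proteins is not None else None
            hits.append(
                MarkerHit(
                    protein_id=target,
                    marker_id=entry.marker_id,
                    evalue=float(cols[6]),
                    bitscore=float(cols[7]),
                    contig_id=contig,
                    ali_from=int(cols[17]),
                    ali_to=int(cols[18]),
                )
            )
    return hits


def infer_contig_ids(hits: Iterable[MarkerHit], genome: GenomeRecord) -> list:
    """Fill missing contig ids by stripping the prodigal ``_<n>`` suffix from
    protein ids, keeping the result only when it names a contig of ``genome``."""
    out = []
    for h in hits:
        if h.contig_id is not None:
            out.append(h)
            continue
        stem, _, tail = h.protein_id.rpartition("_")
        if tail.isdigit() and stem in genome.contigs:
            out.append(replace(h, contig_id=stem))
        else:
            out.append(h)
    return out


def resolve_hits(
    hits: Sequence[MarkerHit],
    e_max: float = DEFAULT_E_MAX,
    genome_id: str = "",
) -> PresenceMap:
    """Gate hits by E-value and assign each protein to exactly one marker.

    Hits with ``evalue > e_max`` are discarded (the boundary E = e_max is
    kept). Each protein is then assigned to its single best marker: highest
    bit score, ties broken by lower E-value, then lexicographically smallest
    marker id. The detected set contains every marker with at least one
    surviving assignment.
    """
    surviving = [h for h in hits if h.evalue <= e_max]
    by_protein: dict = {}
    for h in surviving:
        by_protein.setdefault(h.protein_id, []).append(h)
    detected: dict = {}
    for protein_id in sorted(by_protein):
        best = min(
            by_protein[protein_id],
            key=lambda h: (-h.bitscore, h.evalue, h.marker_id),
        )
        detected.setdefault(best.marker_id, []).append(best)
    return PresenceMap(genome_id=genome_id, detected=detected)


def _majority_phylum(
    genome: GenomeRecord, contig_taxonomy: Mapping
) -> Optional[str]:
    """Genome-level phylum when annotated, else the contig-length-weighted
    majority phylum over ``contig_taxonomy``."""
    phylum = genome.phylum
    if phylum:
        return phylum
    weights: dict = {}
    for contig_id, lineage in contig_taxonomy.items():
        p = lineage_rank(lineage, "phylum")
        if p and contig_id in genome.contigs:
            weights[p] = weights.get(p, 0) + genome.contig_length(contig_id)
    if not weights:
        return None
    return max(sorted(weights), key=lambda p: weights[p])


def contig_screen(
    presence: PresenceMap,
    genome: GenomeRecord,
    min_contig_len: int = 2000,
    contig_taxonomy: Optional[Mapping] = None,
    single_contig_fraction: float = 0.05,
) -> PresenceMap:
    """Screen marker support against contig-level false positives.

    Three independent guards, each recorded in the output flags:

    a. support on a contig shorter than ``min_contig_len`` that carries no
       other marker is dropped (an isolated gene on a scrap contig is weak
       evidence);
    b. when per-contig taxonomy is supplied, support on contigs whose phylum
       conflicts with the genome's majority phylum is dropped (binning
       contamination);
    c. if every surviving marker sits on one contig comprising less than
       ``single_contig_fraction`` of the genome length, the map is flagged
       ``single_contig_suspect`` (the classifier downgrades one class).

    Markers left without support are removed. Hits without a contig id are
    exempt from the guards (their provenance cannot be checked). Never adds
    markers: detected(after) is a subset of detected(before).

    Raises
    ------
    ValueError
        If a hit references a contig absent from ``genome``.
    """
    for hits in presence.detected.values():
        for h in hits:
            if h.contig_id is not None and h.contig_id not in genome.contigs:
                raise ValueError(
                    f"hit {h.protein_id} references contig {h.contig_id!r} "
                    f"absent from genome {genome.genome_id!r}"
                )

    flags = list(presence.flags)
    markers_per_contig: dict = {}
    for marker_id, hits in presence.detected.items():
        for h in hits:
            if h.contig_id is not None:
                markers_per_contig.setdefault(h.contig_id, set()).add(marker_id)

    majority = (
        _majority_phylum(genome, contig_taxonomy) if contig_taxonomy else None
    )

    detected: dict = {}
    for marker_id, hits in presence.detected.items():
        kept = []
        for h in hits:
            if h.contig_id is None:
                kept.append(h)
                continue
            # guard (a): lone marker on a short contig
            if (
                genome.contig_length(h.contig_id) < min_contig_len
                and markers_per_contig.get(h.contig_id, set()) == {marker_id}
            ):
                flags.append(f"short_contig_drop:{marker_id}@{h.contig_id}")
                continue
            # guard (b): phylum conflict
            if contig_taxonomy is not None and majority is not None:
                contig_phylum = lineage_rank(
                    contig_taxonomy.get(h.contig_id), "phylum"
                )
                if contig_phylum is not None and contig_phylum != majority:
                    flags.append(
                        f"foreign_contig_drop:{marker_id}@{h.contig_id}"
                    )
                    continue
            kept.append(h)
        if kept:
            detected[marker_id] = kept

    # guard (c): all markers on one small contig
    contigs_used = {
        h.contig_id
        for hits in detected.values()
        for h in hits
        if h.contig_id is not None
    }
    if detected and len(contigs_used) == 1:
        (contig,) = contigs_used
        total = genome.total_length
        if total > 0 and genome.contig_length(contig) < single_contig_fraction * total:
            flags.append("single_contig_suspect")

    return PresenceMap(genome_id=presence.genome_id, detected=detected, flags=flags)


def search_markers(
    proteins: ProteinSet,
    catalog: MarkerCatalog,
    profile_db,
    e_max: float = DEFAULT_E_MAX,
):
    """Run a live profile search (pyhmmer hmmsearch) over a protein set.

    A thin delegation boundary: the output contract is identical to
    :func:`parse_domtbl` on the backend's table, so the whole pipeline also
    runs from precomputed ``--domtblout`` tables with no backend installed.

    Raises
    ------
    RuntimeError
        If pyhmmer is not importable; use a precomputed hits table
        (``--hits table.domtbl``) instead.
    """
    try:
        import pyhmmer
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError(
            "no profile-search backend available (pyhmmer not installed); "
            "supply precomputed HMMER output via --hits table.domtbl"
        ) from exc

    index = catalog.by_accession()
    alphabet = pyhmmer.easel.Alphabet.amino()
    sequences = [
        pyhmmer.easel.TextSequence(
            name=p.protein_id.encode(), sequence=p.aa_sequence
        ).digitize(alphabet)
        for p in proteins.proteins.values()
    ]
    hits_out: list = []
    if not sequences:
        return hits_out
    with pyhmmer.plan7.HMMFile(str(profile_db)) as hmm_file:
        for top_hits in pyhmmer.hmmsearch(hmm_file, sequences, E=max(e_max, 10.0)):
            query = top_hits.query

            def _text(value):
                if value is None:
                    return ""
                return value.decode() if isinstance(value, bytes) else str(value)

            name = _text(query.name)
            acc = _text(query.accession)
            entry = index.get(acc) or index.get(name) or index.get(acc.split(".")[0])
            if entry is None:
                logger.debug("profile %r/%r not in catalog; skipped", name, acc)
                continue
            for hit in top_hits:
                if not hit.included and hit.evalue > e_max:
                    continue
                best_dom = hit.best_domain
                pid = _text(hit.name)
                hits_out.append(
                    MarkerHit(
                        protein_id=pid,
                        marker_id=entry.marker_id,
                        evalue=float(hit.evalue),
                        bitscore=float(hit.score),
                        contig_id=proteins.contig_of(pid),
                        ali_from=int(best_dom.alignment.target_from),
                        ali_to=int(best_dom.alignment.target_to),
                    )
                )
    return hits_out
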