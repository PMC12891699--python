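"""Synthetic fixtures with known ground truth for the whole pipeline.

Every generator is driven by one explicit seed (no global RNG state) and
emits its truth alongside the fixture, so closed-loop tests can check that
the classifier recovers planted phenotypes, the annotator recovers planted
OTU calls, and the network module recovers planted correlation blocks.
Genome fixtures ship as domtblout hit tables rather than raw sequences plus
real profile HMMs, so no profile-search backend is needed to exercise the
pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import PHENOTYPES, Rubric
from .genome_io import GenomeRecord, write_genome_fasta
from .markers import MarkerCatalog, MarkerEntry
from .network import AbundanceTable
from .reference16s import ReferenceDB, SSURecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class FixtureTruth:
    """Ground truth emitted alongside a fixture."""

    kind: str
    seed: int
    records: list = field(default_factory=list)  # of dicts
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.records).to_csv(path, sep="\t", index=False)

    def by_id(self, key: str) -> dict:
        return {r[key]: r for r in self.records}


# ---------------------------------------------------------------------------
# marker catalog
# ---------------------------------------------------------------------------

_CATALOG_LAYOUT = (
    # (module, branch, required)
    ("precursor", "shared", True),
    ("ring", "aerobic", True),
    ("ring", "anaerobic", True),
    ("chelation", "aerobic", True),
    ("chelation", "anaerobic", True),
    ("adenosylation", "shared", True),
    ("loop", "shared", True),
    ("salvage", "shared", False),
)


def make_catalog(n_per_module: int = 3, seed: int = 0) -> MarkerCatalog:
    """Build a synthetic marker catalog satisfying all catalog invariants.

    ``n_per_module`` markers per (module, branch) slot; every slot except
    salvage is required. The construction is deterministic (the seed is
    accepted for interface uniformity)."""
    if n_per_module < 1:
        raise ValueError("n_per_module must be >= 1")
    entries = []
    counter = 0
    for module, branch, required in _CATALOG_LAYOUT:
        for i in range(1, n_per_module + 1):
            counter += 1
            marker_id = f"{module[:4]}_{branch[:4]}_{i}"
            entries.append(
                MarkerEntry(
                    marker_id=marker_id,
                    gene_symbol=marker_id,
                    profile_accessions=(f"SYN{counter:04d}",),
                    module=module,
                    branch=branch,
                    required=required,
                    weight=1.0,
                )
            )
    return MarkerCatalog(entries)


def write_catalog(catalog: MarkerCatalog, path) -> None:
    rows = [
        {
            "marker_id": e.marker_id,
            "gene_symbol": e.gene_symbol,
            "profile_accessions": ",".join(e.profile_accessions),
            "module": e.module,
            "branch": e.branch,
            "required": str(e.required).lower(),
            "weight": e.weight,
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# planted genomes + hit tables
# ---------------------------------------------------------------------------

#: Margin kept between a planted completeness and every rubric boundary.
BOUNDARY_MARGIN = 0.05

SCENARIOS = ("none", "short_contig", "foreign_contig", "single_contig")

_GENOME_LINEAGE = ("Bacteria", "Actinobacteria", "", "", "", "", "")
_FOREIGN_LINEAGE = "Bacteria;Proteobacteria"


@dataclass
class PlantedGenome:
    """A synthetic genome fixture: record, hit table lines, and truth."""

    genome: GenomeRecord
    domtbl_lines: list
    truth: dict
    contig_taxonomy: Optional[dict] = None


def _class_band(phenotype: str, rubric: Rubric) -> tuple:
    """Completeness interval for a phenotype, shrunk by the boundary margin."""
    bands = {
        "very_likely": (rubric.t_very, 1.0),
        "likely": (rubric.t_likely, rubric.t_very),
        "possible": (rubric.t_possible, rubric.t_likely),
        "nonproducer": (0.0, rubric.t_possible),
    }
    lo, hi = bands[phenotype]
    lo_m = lo + BOUNDARY_MARGIN if lo > 0 else 0.0
    hi_m = hi - BOUNDARY_MARGIN if hi < 1.0 else 1.0
    return lo_m, hi_m


def _domtbl_line(
    protein_id: str,
    accession: str,
    gene_symbol: str,
    evalue: float,
    bitscore: float,
    qlen: int = 250,
) -> str:
    cols = [
        protein_id,  # target name
        "-",  # target accession
        str(qlen + 20),  # tlen
        gene_symbol,  # query name
        accession,  # query accession
        str(qlen),  # qlen
        f"{evalue:.2e}",  # full-sequence E-value
        f"{bitscore:.1f}",  # full-sequence score
        "0.1",  # bias
        "1",
        "1",
        f"{evalue:.2e}",  # c-Evalue
        f"{evalue:.2e}",  # i-Evalue
        f"{bitscore:.1f}",
        "0.1",
        "1",
        str(qlen),
        "5",  # ali_from
        str(qlen - 5),  # ali_to
        "1",
        str(qlen),
        "0.90",
        "planted",
    ]
    return " ".join(cols)


def plant_genome(
    phenotype: str,
    branch: str,
    catalog: MarkerCatalog,
    seed: int,
    contamination_scenario: str = "none",
    genome_id: Optional[str] = None,
    rubric: Optional[Rubric] = None,
) -> PlantedGenome:
    """Plant a genome fixture whose markers realize a target phenotype.

    The marker subset is sampled so the planted pathway completeness sits at
    least :data:`BOUNDARY_MARGIN` inside the target class band; genuine hits
    get E-values in [1e-30, 1e-7] and decoy hits land in (1e-6, 1e-3] to
    exercise the E-value gate. Contamination scenarios place hits so each
    contig-screen guard can fire:

    * ``short_contig`` — an extra (unplanted) marker alone on an 800 nt
      contig, dropped by the short-contig guard;
    * ``foreign_contig`` — an extra marker on a contig whose phylum
      conflicts with the genome's (taxonomy map supplied in the fixture);
    * ``single_contig`` — every planted marker on one contig comprising
      <5% of the genome, so the one-class downgrade flag fires.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if branch not in ("aerobic", "anaerobic"):
        raise ValueError(f"branch must be aerobic or anaerobic, got {branch!r}")
    if contamination_scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {contamination_scenario!r}")
    rubric = rubric or Rubric()
    rng = np.random.default_rng(seed)
    genome_id = genome_id or f"sim{seed}"

    required = catalog.required_markers(branch)
    n_req = len(required)

    if phenotype == "nonproducer":
        selected: list = []
    else:
        lo, hi = _class_band(phenotype, rubric)
        feasible = [
            k
            for k in range(1, n_req + 1)
            if lo <= k / n_req <= hi
        ]
        if not feasible:
            raise ValueError(
                f"no marker count in [{lo:.2f}, {hi:.2f}] x {n_req} markers; "
                "enlarge the catalog"
            )
        k = int(rng.choice(feasible))
        musts = [
            next(
                e
                for e in required
                if e.module == "ring" and e.branch == branch
            )
        ]
        if phenotype == "very_likely" and rubric.require_chelation_for_very:
            musts.append(
                next(
                    e
                    for e in required
                    if e.module == "chelation" and e.branch == branch
                )
            )
        pool = [e for e in required if e not in musts]
        extra_n = k - len(musts)
        chosen_idx = rng.choice(len(pool), size=extra_n, replace=False)
        selected = musts + [pool[i] for i in sorted(chosen_idx)]

    # contigs: comfortably above the short-contig guard, none dominating
    single_contig = contamination_scenario == "single_contig"
    contigs: dict = {}
    if single_contig:
        contigs["hub1"] = _random_seq(rng, 2500)
        for i in range(1, 5):
            contigs[f"ctg{i}"] = _random_seq(rng, 15000)
    else:
        for i in range(1, 5):
            contigs[f"ctg{i}"] = _random_seq(rng, int(rng.integers(3000, 8000)))
    contig_taxonomy = None
    extra_marker = None
    if contamination_scenario == "short_contig":
        contigs["short1"] = _random_seq(rng, 800)
    elif contamination_scenario == "foreign_contig":
        contigs["foreign1"] = _random_seq(rng, 5000)
        contig_taxonomy = {
            cid: ("Bacteria;Actinobacteria" if cid != "foreign1" else _FOREIGN_LINEAGE)
            for cid in contigs
        }

    normal_contigs = [c for c in contigs if c.startswith("ctg")]
    counters = {cid: 0 for cid in contigs}

    def _new_protein(contig_id: str) -> str:
        counters[contig_id] += 1
        return f"{contig_id}_{counters[contig_id]}"

    lines = []
    for entry in selected:
        contig = "hub1" if single_contig else str(rng.choice(normal_contigs))
        evalue = float(10.0 ** rng.uniform(-30, -7))
        lines.append(
            _domtbl_line(
                _new_protein(contig),
                entry.profile_accessions[0],
                entry.gene_symbol,
                evalue,
                float(rng.uniform(150, 500)),
            )
        )

    # extra marker targeted by a screening guard
    if contamination_scenario in ("short_contig", "foreign_contig"):
        unplanted = [e for e in required if e not in selected]
        if unplanted:
            extra = unplanted[int(rng.integers(len(unplanted)))]
            extra_marker = extra.marker_id
            where = "short1" if contamination_scenario == "short_contig" else "foreign1"
            lines.append(
                _domtbl_line(
                    _new_protein(where),
                    extra.profile_accessions[0],
                    extra.gene_symbol,
                    float(10.0 ** rng.uniform(-30, -7)),
                    float(rng.uniform(150, 500)),
                )
            )

    # decoys straddling (1e-6, 1e-3]: parsed, then dropped by the E gate
    all_entries = list(catalog)
    for _ in range(int(rng.integers(2, 5))):
        decoy = all_entries[int(rng.integers(len(all_entries)))]
        lines.append(
            _domtbl_line(
                _new_protein(str(rng.choice(normal_contigs))),
                decoy.profile_accessions[0],
                decoy.gene_symbol,
                float(10.0 ** rng.uniform(-5.9, -3.0)),
                float(rng.uniform(15, 40)),
            )
        )

    expected = phenotype
    if single_contig and phenotype != "nonproducer":
        expected = PHENOTYPES[PHENOTYPES.index(phenotype) - 1]

    genome = GenomeRecord(
        genome_id=genome_id,
        contigs=contigs,
        completeness=100.0,
        contamination=0.0,
        lineage=_GENOME_LINEAGE,
        source="synthetic",
    )
    truth = {
        "genome_id": genome_id,
        "phenotype": phenotype,
        "branch": branch if phenotype != "nonproducer" else "none",
        "expected_phenotype": expected,
        "completeness": round(len(selected) / n_req, 4),
        "n_markers": len(selected),
        "scenario": contamination_scenario,
        "markers": ";".join(sorted(e.marker_id for e in selected)),
        "extra_marker": extra_marker or "",
        "seed": seed,
    }
    return PlantedGenome(
        genome=genome,
        domtbl_lines=lines,
        truth=truth,
        contig_taxonomy=contig_taxonomy,
    )


def write_domtbl(lines: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic hmmsearch --domtblout fixture\n")
        for line in lines:
            fh.write(line + "\n")
        fh.write("#\n")


# ---------------------------------------------------------------------------
# 16S reference + amplicon community
# ---------------------------------------------------------------------------


@dataclass
class SSUCommunity:
    """A synthetic reference + OTU community with planted annotation truth."""

    db: ReferenceDB
    otu_reps: list  # of (otu_id, sequence)
    table: AbundanceTable
    truth: FixtureTruth


def make_ssu_community(
    n_producer_refs: int = 12,
    n_control_refs: int = 12,
    n_otus: int = 40,
    mutant_fraction: float = 0.2,
    n_samples: int = 10,
    seed: int = 0,
) -> SSUCommunity:
    """Generate a 16S reference pair and OTU representatives with truth.

    OTU representatives are 250 nt exact substrings of a reference (truth:
    producer or nonproducer, per the reference's set) or single-substitution
    mutants of such substrings (truth: unassigned, since matching is exact).
    Counts follow a log-normal(Poisson) mixture.
    """
    if not 0 <= mutant_fraction <= 1:
        raise ValueError("mutant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def _make_refs(n, prefix, labels):
        refs = []
        for i in range(n):
            label = str(rng.choice(labels))
            refs.append(
                SSURecord(
                    seq_id=f"{prefix}{i:03d}",
                    source_genome_id=f"g_{prefix}{i:03d}",
                    sequence=_random_seq(rng, int(rng.integers(1400, 1601))),
                    phenotype_label=label,
                )
            )
        return refs

    producers = _make_refs(
        n_producer_refs, "pref", ["very_likely", "likely", "possible"]
    )
    controls = _make_refs(n_control_refs, "cref", ["nonproducer"])
    db = ReferenceDB(
        producers=producers,
        nonproducers=controls,
        build_params={"synthetic": True, "seed": seed},
    )

    sub_len = 250
    reps, records = [], []
    for j in range(n_otus):
        from_producer = bool(rng.random() < 0.5) if controls else True
        ref = (
            producers[int(rng.integers(len(producers)))]
            if from_producer
            else controls[int(rng.integers(len(controls)))]
        )
        off = int(rng.integers(0, ref.length - sub_len + 1))
        seq = ref.sequence[off : off + sub_len]
        mutated = bool(rng.random() < mutant_fraction)
        if mutated:
            pos = int(rng.integers(sub_len))
            old = seq[pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            seq = seq[:pos] + new + seq[pos + 1 :]
        otu_id = f"otu{j:04d}"
        reps.append((otu_id, seq))
        records.append(
            {
                "otu_id": otu_id,
                "call": "unassigned"
                if mutated
                else ("producer" if from_producer else "nonproducer"),
                "phenotype": ""
                if mutated or not from_producer
                else ref.phenotype_label,
                "source_ref": ref.seq_id,
                "mutated": mutated,
            }
        )

    means = np.exp(rng.normal(math.log(50.0), 1.0, size=n_otus))
    counts = rng.poisson(means[:, None], size=(n_otus, n_samples))
    table = AbundanceTable(
        counts=pd.DataFrame(
            counts,
            index=[r[0] for r in reps],
            columns=[f"s{i:02d}" for i in range(n_samples)],
        ),
        labels={
            rec["otu_id"]: (
                rec["phenotype"]
                if rec["call"] == "producer"
                else ("nonproducer" if rec["call"] == "nonproducer" else "unassigned")
            )
            for rec in records
        },
    )
    truth = FixtureTruth(
        kind="ssu_community",
        seed=seed,
        records=records,
        params={
            "n_producer_refs": n_producer_refs,
            "n_control_refs": n_control_refs,
            "mutant_fraction": mutant_fraction,
        },
    )
    return SSUCommunity(db=db, otu_reps=reps, table=table, truth=truth)


# ---------------------------------------------------------------------------
# correlated count tables (network fixtures)
# ---------------------------------------------------------------------------


def make_correlated_counts(
    n_otus: int = 40,
    n_samples: int = 50,
    n_blocks: int = 4,
    block_rho: float = 0.8,
    seed: int = 0,
) -> tuple:
    """Generate an OTU table with planted correlated blocks.

    Half the OTUs are organized into ``n_blocks`` equal blocks whose latent
    log-abundances follow a multivariate normal with within-block
    correlation ``block_rho``; the other half are independent. Latents are
    exponentiated and Poisson-sampled. The first block is labelled
    ``very_likely`` (the planted hub block), the remaining blocks
    likely/possible, and the independent OTUs ``nonproducer`` — so producer
    hubness is a planted, testable property.

    Returns ``(AbundanceTable, FixtureTruth)``.
    """
    if not 0 <= block_rho <= 1:
        raise ValueError("block_rho must be in [0, 1]")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)

    blocked_total = n_otus // 2
    block_size = blocked_total // n_blocks
    if block_size < 1:
        raise ValueError("too few OTUs for the requested number of blocks")

    block_of = np.full(n_otus, -1)
    for b in range(n_blocks):
        block_of[b * block_size : (b + 1) * block_size] = b

    # latent z: correlated within blocks, independent elsewhere
    z = rng.standard_normal((n_otus, n_samples))
    if block_rho > 0:
        for b in range(n_blocks):
            members = np.flatnonzero(block_of == b)
            shared = rng.standard_normal(n_samples)
            z[members] = (
                math.sqrt(block_rho) * shared
                + math.sqrt(1.0 - block_rho) * rng.standard_normal(
                    (len(members), n_samples)
                )
            )

    mu = rng.normal(math.log(80.0), 0.5, size=n_otus)
    lam = np.exp(mu[:, None] + z)
    counts = rng.poisson(lam)

    block_labels = ["very_likely"] + [
        ("likely" if b % 2 else "possible") for b in range(1, n_blocks)
    ]
    otu_ids = [f"otu{j:04d}" for j in range(n_otus)]
    labels = {
        otu_ids[j]: (block_labels[block_of[j]] if block_of[j] >= 0 else "nonproducer")
        for j in range(n_otus)
    }
    table = AbundanceTable(
        counts=pd.DataFrame(
            counts, index=otu_ids, columns=[f"s{i:03d}" for i in range(n_samples)]
        ),
        labels=labels,
    )
    truth = FixtureTruth(
        kind="correlated_counts",
        seed=seed,
        records=[
            {
                "otu_id": otu_ids[j],
                "block": int(block_of[j]),
                "label": labels[otu_ids[j]],
            }
            for j in range(n_otus)
        ],
        params={"block_rho": block_rho, "n_blocks": n_blocks, "n_samples": n_samples},
    )
    return table, truth


# ---------------------------------------------------------------------------
# on-disk presets
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_classifier(
    outdir,
    seed: int,
    n_per_cell: int = 2,
    scenarios: Sequence[str] = ("none",),
    catalog: Optional[MarkerCatalog] = None,
) -> FixtureTruth:
    """Write classifier fixtures: catalog, genomes, hit tables, metadata, truth.

    Genomes cover every (phenotype x branch) cell ``n_per_cell`` times per
    scenario (nonproducer uses one branch slot only).
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "hits").mkdir(exist_ok=True)
    catalog = catalog or make_catalog(n_per_module=3)
    write_catalog(catalog, outdir / "catalog.tsv")

    cells = []
    for scenario in scenarios:
        for phenotype in ("very_likely", "likely", "possible"):
            for branch in ("aerobic", "anaerobic"):
                cells += [(phenotype, branch, scenario)] * n_per_cell
        cells += [("nonproducer", "aerobic", scenario)] * n_per_cell

    seeds = _spawn_seeds(seed, len(cells))
    records, meta_rows, tax_rows = [], [], []
    for i, ((phenotype, branch, scenario), child_seed) in enumerate(
        zip(cells, seeds)
    ):
        planted = plant_genome(
            phenotype,
            branch,
            catalog,
            seed=child_seed,
            contamination_scenario=scenario,
            genome_id=f"simg{i:04d}",
        )
        gid = planted.genome.genome_id
        write_genome_fasta(planted.genome, outdir / "genomes" / f"{gid}.fasta")
        write_domtbl(planted.domtbl_lines, outdir / "hits" / f"{gid}.domtbl")
        meta_rows.append(
            {
                "genome_id": gid,
                "completeness": planted.genome.completeness,
                "contamination": planted.genome.contamination,
                "lineage": ";".join(planted.genome.lineage),
            }
        )
        if planted.contig_taxonomy:
            tax_rows += [
                {"genome_id": gid, "contig_id": cid, "lineage": lin}
                for cid, lin in planted.contig_taxonomy.items()
            ]
        records.append(planted.truth)

    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    if tax_rows:
        pd.DataFrame(tax_rows).to_csv(
            outdir / "contig_taxonomy.tsv", sep="\t", index=False
        )
    truth = FixtureTruth(
        kind="classifier", seed=seed, records=records,
        params={"scenarios": list(scenarios)},
    )
    truth.to_tsv(outdir / "truth_genomes.tsv")
    return truth


def simulate_ssu(outdir, seed: int, **kwargs) -> SSUCommunity:
    """Write 16S fixtures: reference FASTA pair, OTU reps, counts, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = make_ssu_community(seed=seed, **kwargs)
    for path, records in (
        (outdir / "ref_producers.fasta", community.db.producers),
        (outdir / "ref_control.fasta", community.db.nonproducers),
    ):
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.seq_id}\n{rec.sequence}\n")
    with open(outdir / "otu_reps.fasta", "w") as fh:
        for otu_id, seq in community.otu_reps:
            fh.write(f">{otu_id}\n{seq}\n")
    community.table.to_tsv(outdir / "otu_counts.tsv", outdir / "otu_labels.tsv")
    community.truth.to_tsv(outdir / "truth_otus.tsv")
    return community


def simulate_network(outdir, seed: int, **kwargs) -> tuple:
    """Write network fixtures: counts + labels TSV and block truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = make_correlated_counts(seed=seed, **kwargs)
    table.to_tsv(outdir / "counts.tsv", outdir / "labels.tsv")
    truth.to_tsv(outdir / "truth_blocks.tsv")
    return table, truth


def simulate_full(outdir, seed: int) -> None:
    """Write a coherent end-to-end fixture set under one seed.

    Subdirectories: ``classifier/`` (genomes + hit tables, with a 16S rRNA
    GFF per genome so the reference can be built from the classified
    genomes), ``amplicon/`` (OTU reps drawn from those genomes' 16S genes,
    plus a correlated count table whose planted hub block is made of OTUs
    from very-likely producer genomes), and ``network/`` (a standalone
    block-structured table).
    """
    outdir = Path(outdir)
    seeds = _spawn_seeds(seed, 4)
    truth = simulate_classifier(
        outdir / "classifier", seeds[0], n_per_cell=2, scenarios=("none",)
    )

    # carve one 16S gene into each genome fixture and record it in a GFF
    rng = np.random.default_rng(seeds[1])
    gffdir = outdir / "classifier" / "rrna"
    gffdir.mkdir(exist_ok=True)
    from Bio import SeqIO  # local: only needed to rewrite fixture genomes

    ssu_by_genome: dict = {}
    genome_dir = outdir / "classifier" / "genomes"
    for rec in truth.records:
        gid = rec["genome_id"]
        fasta = genome_dir / f"{gid}.fasta"
        contigs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        contig_id = next(cid for cid, s in contigs.items() if len(s) >= 1600)
        start = int(rng.integers(1, len(contigs[contig_id]) - 1500))
        end = start + 1499
        ssu_by_genome[gid] = contigs[contig_id][start - 1 : end]
        with open(gffdir / f"{gid}.gff", "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(
                f"{contig_id}\tsim\trRNA\t{start}\t{end}\t.\t+\t.\t"
                f"ID=ssu_{gid};product=16S ribosomal RNA\n"
            )

    # amplicon OTUs: hub block from very_likely genomes' 16S, background
    # from nonproducer genomes' 16S, aligned with the correlated-count blocks
    amp = outdir / "amplicon"
    amp.mkdir(parents=True, exist_ok=True)
    table, block_truth = make_correlated_counts(
        n_otus=40, n_samples=50, n_blocks=4, block_rho=0.85, seed=seeds[2]
    )
    by_class: dict = {}
    for rec in truth.records:
        by_class.setdefault(rec["expected_phenotype"], []).append(rec["genome_id"])

    label_to_class = {
        "very_likely": "very_likely",
        "likely": "likely",
        "possible": "possible",
        "nonproducer": "nonproducer",
    }
    rows = []
    reps = []
    for rec in block_truth.records:
        cls = label_to_class[rec["label"]]
        source_pool = by_class.get(cls) or by_class["nonproducer"]
        gid = source_pool[int(rng.integers(len(source_pool)))]
        ssu = ssu_by_genome[gid]
        off = int(rng.integers(0, len(ssu) - 250 + 1))
        reps.append((rec["otu_id"], ssu[off : off + 250]))
        rows.append(
            {
                "otu_id": rec["otu_id"],
                "source_genome": gid,
                "expected_call": "nonproducer" if cls == "nonproducer" else "producer",
                "expected_phenotype": "" if cls == "nonproducer" else cls,
                "block": rec["block"],
            }
        )
    with open(amp / "otu_reps.fasta", "w") as fh:
        for otu_id, seq in reps:
            fh.write(f">{otu_id}\n{seq}\n")
    table.to_tsv(amp / "counts.tsv", amp / "labels.tsv")
    FixtureTruth(kind="amplicon", seed=seed, records=rows).to_tsv(
        amp / "truth_otus.tsv"
    )

    simulate_network(outdir / "network", seeds[3])
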