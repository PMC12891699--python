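"""Pathway-completeness scoring and the four-class producer phenotype.

Cobamide de novo biosynthesis proceeds through an oxygen-dependent (aerobic)
or oxygen-independent (anaerobic) corrin-ring branch, followed by shared
cobalt chelation/adenosylation and nucleotide-loop assembly. Completeness is
scored per branch as the weighted fraction of required markers detected, and
genomes are classified into four confidence phenotypes — very likely,
likely, possible, nonproducer — with an aerobic/anaerobic route call driven
by branch-exclusive diagnostic markers only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .genome_io import GenomeRecord
from .markers import (
    MarkerCatalog,
    MarkerHit,
    PresenceMap,
    contig_screen,
    infer_contig_ids,
    parse_domtbl,
    resolve_hits,
)

logger = logging.getLogger(__name__)

PHENOTYPES = ("nonproducer", "possible", "likely", "very_likely")
#: Ordering used for monotonicity and downgrades.
PHENOTYPE_RANK = {p: i for i, p in enumerate(PHENOTYPES)}

ROUTE_BRANCHES = ("aerobic", "anaerobic", "ambiguous", "none")


@dataclass
class Rubric:
    """Classification rubric: completeness thresholds and evidence rules.

    ``t_very``/``t_likely``/``t_possible`` are inclusive lower bounds on the
    (optionally completeness-adjusted) pathway score. When
    ``require_chelation_for_very`` is set, a genome cannot be called a very
    likely producer without at least one detected cobalt-chelatase marker.
    ``adjust_for_genome_completeness`` divides the raw score by the CheckM
    completeness fraction (floored at ``q_floor``) so fragmentary MAGs are
    not systematically under-called.
    """

    t_very: float = 0.75
    t_likely: float = 0.50
    t_possible: float = 0.25
    require_chelation_for_very: bool = True
    adjust_for_genome_completeness: bool = True
    q_floor: float = 0.5

    def __post_init__(self):
        if not (0 < self.t_possible < self.t_likely < self.t_very <= 1):
            raise ValueError(
                "rubric thresholds must satisfy 0 < t_possible < t_likely "
                "< t_very <= 1"
            )


@dataclass
class PathwayProfile:
    """Per-genome pathway completeness broken down by branch and module."""

    genome_id: str
    completeness_by_branch: dict  # {'aerobic': f, 'anaerobic': f} in [0,1]
    module_completeness: dict  # (branch, module) -> f in [0,1]
    diagnostic_counts: dict  # branch -> int (branch-exclusive markers seen)
    detected_markers: tuple = ()
    has_chelation: bool = False
    has_shared: bool = False
    flags: list = field(default_factory=list)


@dataclass
class ProducerCall:
    """The phenotype call with its evidence trail."""

    genome_id: str
    phenotype: str  # one of PHENOTYPES
    branch: str  # one of ROUTE_BRANCHES
    score: float  # branch completeness used for the class decision
    evidence: list = field(default_factory=list)  # marker ids
    downgraded: bool = False
    flags: list = field(default_factory=list)


def score_pathway(presence: PresenceMap, catalog: MarkerCatalog) -> PathwayProfile:
    """Score branch and module completeness from a resolved presence map.

    For branch *b*, completeness is the sum of weights of detected required
    markers with branch in {b, shared}, divided by the total weight of all
    such required markers. Module completeness is the same fraction
    restricted per module. Diagnostic counts tally detected branch-exclusive
    markers (required or not).
    """
    catalog.validate()
    detected = set(presence.detected)
    unknown = detected - set(catalog.by_id())
    if unknown:
        raise ValueError(f"detected markers absent from catalog: {sorted(unknown)}")

    completeness: dict = {}
    module_completeness: dict = {}
    for branch in ("aerobic", "anaerobic"):
        required = catalog.required_markers(branch)
        total = sum(e.weight for e in required)
        got = sum(e.weight for e in required if e.marker_id in detected)
        completeness[branch] = got / total if total else 0.0
        for module in {e.module for e in required}:
            mod = [e for e in required if e.module == module]
            mod_total = sum(e.weight for e in mod)
            mod_got = sum(e.weight for e in mod if e.marker_id in detected)
            module_completeness[(branch, module)] = (
                mod_got / mod_total if mod_total else 0.0
            )

    diagnostic_counts = {
        branch: sum(
            1 for e in catalog.exclusive_markers(branch) if e.marker_id in detected
        )
        for branch in ("aerobic", "anaerobic")
    }
    has_chelation = any(
        e.module == "chelation" and e.marker_id in detected for e in catalog
    )
    has_shared = any(
        e.branch == "shared" and e.marker_id in detected for e in catalog
    )
    return PathwayProfile(
        genome_id=presence.genome_id,
        completeness_by_branch=completeness,
        module_completeness=module_completeness,
        diagnostic_counts=diagnostic_counts,
        detected_markers=tuple(sorted(detected)),
        has_chelation=has_chelation,
        has_shared=has_shared,
        flags=list(presence.flags),
    )


def call_route(profile: PathwayProfile) -> str:
    """Call the oxygen route from branch-exclusive diagnostics only.

    The branch with strictly more diagnostic markers wins; equal nonzero
    counts are ambiguous; with no diagnostics at all the call is ambiguous
    if any shared marker was detected, else none.
    """
    aero = profile.diagnostic_counts.get("aerobic", 0)
    anae = profile.diagnostic_counts.get("anaerobic", 0)
    if aero > anae:
        return "aerobic"
    if anae > aero:
        return "anaerobic"
    if aero > 0:  # equal nonzero
        return "ambiguous"
    return "ambiguous" if profile.has_shared else "none"


def classify(
    profile: PathwayProfile,
    rubric: Optional[Rubric] = None,
    genome_completeness: Optional[float] = None,
) -> ProducerCall:
    """Assign the four-class phenotype from a pathway profile.

    The raw score is the better branch completeness; when
    ``rubric.adjust_for_genome_completeness`` is on and a CheckM completeness
    is supplied, the score is divided by ``max(completeness/100, q_floor)``
    and capped at 1. Lower class boundaries are inclusive. A score past
    ``t_very`` without the required chelation evidence falls back to likely.
    The ``single_contig_suspect`` screening flag downgrades the call by
    exactly one class.
    """
    rubric = rubric or Rubric()
    c_raw = max(profile.completeness_by_branch.values(), default=0.0)
    if rubric.adjust_for_genome_completeness and genome_completeness is not None:
        c = min(1.0, c_raw / max(genome_completeness / 100.0, rubric.q_floor))
    else:
        c = c_raw

    if c >= rubric.t_very:
        if rubric.require_chelation_for_very and not profile.has_chelation:
            phenotype = "likely"
        else:
            phenotype = "very_likely"
    elif c >= rubric.t_likely:
        phenotype = "likely"
    elif c >= rubric.t_possible:
        phenotype = "possible"
    else:
        phenotype = "nonproducer"

    downgraded = False
    if "single_contig_suspect" in profile.flags and phenotype != "nonproducer":
        phenotype = PHENOTYPES[PHENOTYPE_RANK[phenotype] - 1]
        downgraded = True

    return ProducerCall(
        genome_id=profile.genome_id,
        phenotype=phenotype,
        branch=call_route(profile),
        score=c,
        evidence=list(profile.detected_markers),
        downgraded=downgraded,
        flags=list(profile.flags),
    )


HitsSource = Union[str, Path, Sequence[MarkerHit]]


def classify_genome(
    genome: GenomeRecord,
    hits: HitsSource,
    catalog: MarkerCatalog,
    rubric: Optional[Rubric] = None,
    e_max: float = 1e-6,
    screen: bool = True,
    contig_taxonomy: Optional[Mapping] = None,
    min_contig_len: int = 2000,
) -> ProducerCall:
    """Run the full per-genome pipeline: gate, resolve, screen, score, classify."""
    if isinstance(hits, (str, Path)):
        hits = parse_domtbl(hits, catalog)
    hits = infer_contig_ids(hits, genome)
    presence = resolve_hits(hits, e_max=e_max, genome_id=genome.genome_id)
    if screen:
        presence = contig_screen(
            presence,
            genome,
            min_contig_len=min_contig_len,
            contig_taxonomy=contig_taxonomy,
        )
    profile = score_pathway(presence, catalog)
    return classify(profile, rubric, genome_completeness=genome.completeness)


def classify_batch(
    genomes: Sequence[GenomeRecord],
    hits_source: Mapping,
    catalog: MarkerCatalog,
    rubric: Optional[Rubric] = None,
    e_max: float = 1e-6,
    screen: bool = True,
    contig_taxonomy: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Classify a batch of genomes into a report table.

    ``hits_source`` maps genome id to either a domtblout path or a list of
    :class:`MarkerHit`. Per-genome failures land in the ``error`` column and
    the run continues; row order follows the input order, so reruns on the
    same inputs are byte-identical.
    """
    columns = [
        "genome_id",
        "phenotype",
        "branch",
        "score",
        "n_markers",
        "flags",
        "evidence",
        "error",
    ]
    rows = []
    for genome in genomes:
        row = {
            "genome_id": genome.genome_id,
            "phenotype": "",
            "branch": "",
            "score": "",
            "n_markers": "",
            "flags": "",
            "evidence": "",
            "error": "",
        }
        try:
            if genome.genome_id not in hits_source:
                raise KeyError(f"no hits for genome {genome.genome_id!r}")
            ctax = (
                contig_taxonomy.get(genome.genome_id)
                if contig_taxonomy is not None
                else None
            )
            call = classify_genome(
                genome,
                hits_source[genome.genome_id],
                catalog,
                rubric=rubric,
                e_max=e_max,
                screen=screen,
                contig_taxonomy=ctax,
            )
            row.update(
                phenotype=call.phenotype,
                branch=call.branch,
                score=f"{call.score:.4f}",
                n_markers=len(call.evidence),
                flags=";".join(call.flags),
                evidence=";".join(call.evidence),
            )
        except Exception as exc:  # noqa: BLE001 - isolation contract
            row["error"] = str(exc)
            logger.warning("genome %s failed: %s", genome.genome_id, exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
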