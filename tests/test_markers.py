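import numpy as np
import pytest

from cobakit.genome_io import GenomeRecord
from cobakit.markers import (
    MarkerCatalog,
    MarkerEntry,
    MarkerHit,
    PresenceMap,
    contig_screen,
    parse_domtbl,
    resolve_hits,
)
from cobakit.simulate import _domtbl_line, make_catalog, write_domtbl


def _entry(marker_id, module="ring", branch="aerobic", required=True, acc=None):
    return MarkerEntry(
        marker_id=marker_id,
        gene_symbol=marker_id,
        profile_accessions=(acc or f"ACC_{marker_id}",),
        module=module,
        branch=branch,
        required=required,
    )


class TestCatalogInvariants:
    def test_duplicate_marker_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MarkerCatalog(
                [
                    _entry("a"),
                    _entry("a", branch="anaerobic"),
                    _entry("loop1", module="loop", branch="shared"),
                ]
            )

    def test_missing_required_ring_branch_rejected(self):
        with pytest.raises(ValueError, match="anaerobic"):
            MarkerCatalog(
                [_entry("a"), _entry("loop1", module="loop", branch="shared")]
            )

    def test_nonpositive_weight_rejected(self):
        bad = _entry("a")
        object.__setattr__(bad, "weight", 0.0)
        with pytest.raises(ValueError, match="weight"):
            MarkerCatalog(
                [
                    bad,
                    _entry("b", branch="anaerobic"),
                    _entry("loop1", module="loop", branch="shared"),
                ]
            )


class TestParseDomtbl:
    def test_parses_hits_skips_comments_and_unmapped(self, tmp_path, toy_catalog):
        entry = toy_catalog.entries[3]  # a ring marker
        lines = [
            _domtbl_line("p1", entry.profile_accessions[0], entry.gene_symbol, 3e-12, 80.0),
            _domtbl_line("p2", "NOT_A_PROFILE", "mystery", 1e-20, 90.0),
        ]
        path = tmp_path / "hits.domtbl"
        write_domtbl(lines, path)
        hits = parse_domtbl(path, toy_catalog)
        assert len(hits) == 1
        assert hits[0].protein_id == "p1"
        assert hits[0].marker_id == entry.marker_id
        assert hits[0].evalue == pytest.approx(3e-12)

    def test_malformed_line_reports_line_number(self, tmp_path, toy_catalog):
        path = tmp_path / "bad.domtbl"
        path.write_text("# header\np1 too few columns\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_domtbl(path, toy_catalog)


class TestResolveHits:
    def test_evalue_boundary_inclusive(self):
        hits = [
            MarkerHit("p1", "m1", evalue=1e-6, bitscore=50.0),
            MarkerHit("p2", "m1", evalue=1.01e-6, bitscore=50.0),
        ]
        pm = resolve_hits(hits)
        assert [h.protein_id for h in pm.detected["m1"]] == ["p1"]

    def test_one_protein_one_marker_by_bitscore(self):
        hits = [
            MarkerHit("p1", "cbiD", evalue=1e-10, bitscore=80.0),
            MarkerHit("p1", "cobJ", evalue=1e-12, bitscore=75.0),
        ]
        pm = resolve_hits(hits)
        assert "cbiD" in pm.detected and "cobJ" not in pm.detected

    def test_bitscore_tie_broken_by_evalue_then_marker_id(self):
        hits = [
            MarkerHit("p1", "mB", evalue=1e-10, bitscore=80.0),
            MarkerHit("p1", "mA", evalue=1e-10, bitscore=80.0),
            MarkerHit("p1", "mC", evalue=1e-12, bitscore=80.0),
        ]
        pm = resolve_hits(hits)
        assert list(pm.detected) == ["mC"]

    def test_two_proteins_union_into_one_marker(self):
        hits = [
            MarkerHit("p1", "cbiD", evalue=1e-10, bitscore=80.0),
            MarkerHit("p2", "cbiD", evalue=1e-9, bitscore=60.0),
        ]
        pm = resolve_hits(hits)
        assert len(pm.detected["cbiD"]) == 2

    @staticmethod
    def _oracle(hits, e_max):
        """Independent re-derivation: per protein, scan every gated hit and
        keep the maximum under (bitscore, -evalue, reversed marker_id)."""
        best = {}
        for h in hits:
            if h.evalue > e_max:
                continue
            cur = best.get(h.protein_id)
            if cur is None:
                best[h.protein_id] = h
                continue
            better = False
            if h.bitscore != cur.bitscore:
                better = h.bitscore > cur.bitscore
            elif h.evalue != cur.evalue:
                better = h.evalue < cur.evalue
            else:
                better = h.marker_id < cur.marker_id
            if better:
                best[h.protein_id] = h
        detected = {}
        for h in best.values():
            detected.setdefault(h.marker_id, set()).add(h.protein_id)
        return detected

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        markers = [f"m{i}" for i in range(6)]
        for _ in range(100):
            n = int(rng.integers(0, 21))
            hits = [
                MarkerHit(
                    protein_id=f"p{rng.integers(0, 8)}",
                    marker_id=str(rng.choice(markers)),
                    evalue=float(10.0 ** rng.uniform(-12, -4)),
                    bitscore=float(rng.integers(1, 6) * 10.0),
                )
                for _ in range(n)
            ]
            pm = resolve_hits(hits)
            got = {m: {h.protein_id for h in hs} for m, hs in pm.detected.items()}
            assert got == self._oracle(hits, 1e-6)

    def test_raising_e_max_never_shrinks_detected_set(self):
        rng = np.random.default_rng(7)
        hits = [
            MarkerHit(
                protein_id=f"p{i}",
                marker_id=f"m{rng.integers(0, 4)}",
                evalue=float(10.0 ** rng.uniform(-10, -3)),
                bitscore=float(rng.uniform(10, 100)),
            )
            for i in range(30)
        ]
        thresholds = [1e-8, 1e-6, 1e-4, 1e-2]
        detected = [set(resolve_hits(hits, e_max=t).detected) for t in thresholds]
        for smaller, larger in zip(detected, detected[1:]):
            assert smaller <= larger


def _screen_genome():
    return GenomeRecord(
        "g",
        {
            "big1": "A" * 10000,
            "big2": "C" * 10000,
            "tiny": "G" * 800,
        },
        lineage=("Bacteria", "Actinobacteria", "", "", "", "", ""),
    )


def _pm(assignments):
    detected = {}
    for marker, protein, contig in assignments:
        detected.setdefault(marker, []).append(
            MarkerHit(protein, marker, evalue=1e-10, bitscore=50.0, contig_id=contig)
        )
    return PresenceMap(genome_id="g", detected=detected)


class TestContigScreen:
    def test_lone_marker_on_short_contig_dropped(self):
        pm = _pm([("m1", "p1", "big1"), ("m2", "p2", "tiny")])
        out = contig_screen(pm, _screen_genome())
        assert "m2" not in out.detected and "m1" in out.detected
        assert any("short_contig_drop" in f for f in out.flags)

    def test_short_contig_with_two_markers_kept(self):
        pm = _pm([("m1", "p1", "tiny"), ("m2", "p2", "tiny"), ("m3", "p3", "big1")])
        out = contig_screen(pm, _screen_genome())
        assert set(out.detected) == {"m1", "m2", "m3"}

    def test_foreign_phylum_support_dropped(self):
        pm = _pm([("m1", "p1", "big1"), ("m2", "p2", "big2")])
        taxonomy = {
            "big1": "Bacteria;Actinobacteria",
            "big2": "Bacteria;Proteobacteria",
        }
        out = contig_screen(pm, _screen_genome(), contig_taxonomy=taxonomy)
        assert "m2" not in out.detected
        assert any("foreign_contig_drop" in f for f in out.flags)

    def test_single_small_contig_sets_suspect_flag_but_keeps_markers(self):
        genome = GenomeRecord("g", {"small": "A" * 2000, "big": "C" * 98000})
        pm = _pm([(f"m{i}", f"p{i}", "small") for i in range(12)])
        out = contig_screen(pm, genome)
        assert len(out.detected) == 12
        assert "single_contig_suspect" in out.flags

    def test_never_adds_markers(self):
        rng = np.random.default_rng(11)
        genome = _screen_genome()
        contigs = list(genome.contigs)
        for _ in range(25):
            pm = _pm(
                [
                    (f"m{rng.integers(0, 5)}", f"p{i}", str(rng.choice(contigs)))
                    for i in range(int(rng.integers(0, 10)))
                ]
            )
            out = contig_screen(pm, genome)
            assert set(out.detected) <= set(pm.detected)

    def test_unknown_contig_errors(self):
        pm = _pm([("m1", "p1", "nope")])
        with pytest.raises(ValueError, match="nope"):
            contig_screen(pm, _screen_genome())


def test_search_markers_self_match_with_toy_profile(tmp_path):
    """A protein that is an exact emission of a toy profile must hit it."""
    pyhmmer = pytest.importorskip("pyhmmer")
    from cobakit.genome_io import Protein, ProteinSet
    from cobakit.markers import search_markers

    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    digital = pyhmmer.easel.TextSequence(name=b"seed", sequence=seq).digitize(alphabet)
    hmm, _, _ = builder.build(digital, background)
    hmm.name = b"ring_aero_1"
    hmm.accession = b"SYN0004"
    hmm_path = tmp_path / "toy.hmm"
    with open(hmm_path, "wb") as fh:
        hmm.write(fh)

    catalog = make_catalog(n_per_module=3)
    proteins = ProteinSet(
        genome_id="g", proteins={"p1": Protein("p1", seq, contig_id="c1")}
    )
    hits = search_markers(proteins, catalog, hmm_path)
    assert any(h.protein_id == "p1" and h.evalue <= 1e-6 for h in hits)

    empty = ProteinSet(genome_id="g")
    assert search_markers(empty, catalog, hmm_path) == []
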