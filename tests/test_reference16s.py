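import numpy as np
import pandas as pd
import pytest

from cobakit.classify import ProducerCall
from cobakit.genome_io import GenomeRecord, reverse_complement
from cobakit.network import AbundanceTable
from cobakit.reference16s import (
    ReferenceDB,
    SSURecord,
    annotate_otus,
    build_db,
    dereplicate,
    extract_ssu,
    producer_profile,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _seq(rng, n):
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _rec(seq_id, seq, genome="g", label=None):
    return SSURecord(
        seq_id=seq_id, source_genome_id=genome, sequence=seq, phenotype_label=label
    )


class TestExtractSSU:
    def _gff(self, tmp_path, rows):
        path = tmp_path / "rrna.gff"
        lines = ["##gff-version 3"] + [
            "\t".join(str(x) for x in row) for row in rows
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_plus_strand_slice_is_one_based_inclusive(self, tmp_path):
        genome = GenomeRecord("g", {"c1": "A" * 10 + "C" * 1500 + "G" * 490})
        gff = self._gff(
            tmp_path,
            [("c1", "sim", "rRNA", 11, 1510, ".", "+", ".",
              "ID=r1;product=16S ribosomal RNA")],
        )
        records = extract_ssu(genome, gff)
        assert len(records) == 1
        assert records[0].sequence == "C" * 1500

    def test_minus_strand_reverse_complemented(self, tmp_path):
        rng = np.random.default_rng(1)
        contig = _seq(rng, 2000)
        genome = GenomeRecord("g", {"c1": contig})
        gff = self._gff(
            tmp_path,
            [("c1", "sim", "rRNA", 101, 1600, ".", "-", ".",
              "ID=r1;product=16S ribosomal RNA")],
        )
        records = extract_ssu(genome, gff)
        assert records[0].sequence == reverse_complement(contig[100:1600])

    def test_non_16s_rrna_rows_skipped(self, tmp_path):
        genome = GenomeRecord("g", {"c1": "A" * 4000})
        gff = self._gff(
            tmp_path,
            [
                ("c1", "sim", "rRNA", 1, 2900, ".", "+", ".",
                 "ID=r1;product=23S ribosomal RNA"),
                ("c1", "sim", "gene", 1, 1500, ".", "+", ".",
                 "ID=g1;product=16S ribosomal RNA"),
            ],
        )
        assert extract_ssu(genome, gff) == []

    def test_out_of_range_coordinates_error(self, tmp_path):
        genome = GenomeRecord("g", {"c1": "A" * 1000})
        gff = self._gff(
            tmp_path,
            [("c1", "sim", "rRNA", 1, 1500, ".", "+", ".",
              "ID=r1;product=16S ribosomal RNA")],
        )
        with pytest.raises(ValueError, match="exceeds"):
            extract_ssu(genome, gff)


class TestDereplicate:
    def test_duplicates_and_substrings_collapse_to_longest(self):
        rng = np.random.default_rng(3)
        full = _seq(rng, 1500)
        records = [
            _rec("a_full", full),
            _rec("b_copy", full),
            _rec("c_sub", full[100:1300]),
        ]
        reps = dereplicate(records)
        assert [r.seq_id for r in reps] == ["a_full"]

    def test_equal_length_duplicate_tie_broken_by_seq_id(self):
        rng = np.random.default_rng(4)
        s = _seq(rng, 1200)
        reps = dereplicate([_rec("zz", s), _rec("aa", s)])
        assert [r.seq_id for r in reps] == ["aa"]

    def test_min_len_strict(self):
        rng = np.random.default_rng(5)
        reps = dereplicate([_rec("short", _seq(rng, 999)), _rec("ok", _seq(rng, 1000))])
        assert [r.seq_id for r in reps] == ["ok"]

    def test_point_mutants_both_kept(self):
        rng = np.random.default_rng(6)
        s = _seq(rng, 1200)
        s2 = ("A" if s[0] != "A" else "C") + s[1:]
        reps = dereplicate([_rec("a", s), _rec("b", s2)])
        assert len(reps) == 2

    def test_idempotent_and_substring_free(self):
        rng = np.random.default_rng(7)
        base = [_seq(rng, rng.integers(1000, 1600)) for _ in range(6)]
        records = [_rec(f"r{i}", s) for i, s in enumerate(base)]
        records += [_rec(f"d{i}", base[i]) for i in range(3)]
        records += [_rec(f"s{i}", base[i][50:1100]) for i in range(2)]
        once = dereplicate(records)
        assert dereplicate(once) == once
        for a in once:
            for b in once:
                if a.seq_id != b.seq_id:
                    assert a.sequence not in b.sequence


def _call(genome_id, phenotype):
    return ProducerCall(genome_id=genome_id, phenotype=phenotype, branch="none",
                        score=0.0)


class TestBuildDB:
    def test_routing_and_cross_set_conflict(self):
        rng = np.random.default_rng(8)
        shared = _seq(rng, 1400)
        ssu = [
            _rec("s1", _seq(rng, 1500), genome="gA"),
            _rec("s2", shared, genome="gB"),
            _rec("s3", shared, genome="gC"),
            _rec("s4", _seq(rng, 1500), genome="gC"),
        ]
        calls = [_call("gA", "very_likely"), _call("gB", "likely"),
                 _call("gC", "nonproducer")]
        db = build_db(calls, ssu)
        assert [r.seq_id for r in db.producers] == ["s1"]
        assert [r.seq_id for r in db.nonproducers] == ["s4"]
        assert {r.seq_id for r in db.conflicted} == {"s2", "s3"}

    def test_unknown_source_genome_errors(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="ghost"):
            build_db([_call("gA", "likely")],
                     [_rec("s1", _seq(rng, 1400), genome="ghost")])

    def test_empty_control_set_is_valid(self):
        rng = np.random.default_rng(10)
        db = build_db([_call("gA", "possible")],
                      [_rec("s1", _seq(rng, 1400), genome="gA")])
        assert db.nonproducers == []
        assert len(db.producers) == 1


def _db(rng):
    producers = [
        _rec(f"P{i}", _seq(rng, 1500), label=label)
        for i, label in enumerate(["very_likely", "likely", "possible"])
    ]
    controls = [_rec(f"C{i}", _seq(rng, 1500), label="nonproducer") for i in range(2)]
    return ReferenceDB(producers=producers, nonproducers=controls)


class TestAnnotateOTUs:
    def test_exact_substring_is_producer_one_substitution_is_unassigned(self):
        rng = np.random.default_rng(11)
        db = _db(rng)
        q = db.producers[0].sequence[500:750]
        mutated = q[:100] + ("A" if q[100] != "A" else "C") + q[101:]
        anns = annotate_otus([("exact", q), ("mut", mutated)], db)
        assert anns[0].call == "producer"
        assert anns[0].phenotype == "very_likely"
        assert anns[1].call == "unassigned"

    def test_dual_set_match_is_ambiguous(self):
        rng = np.random.default_rng(12)
        db = _db(rng)
        shared = _seq(rng, 250)
        db.producers[1].sequence += shared
        db.nonproducers[0].sequence += shared
        (ann,) = annotate_otus([("q", shared)], db)
        assert ann.call == "ambiguous"

    def test_reverse_complement_call_invariant(self):
        rng = np.random.default_rng(13)
        db = _db(rng)
        queries = [
            ("fwd", db.producers[2].sequence[10:260]),
            ("ctrl", db.nonproducers[1].sequence[0:250]),
            ("nohit", _seq(rng, 250)),
        ]
        fwd = annotate_otus(queries, db)
        rc = annotate_otus(
            [(n, reverse_complement(s)) for n, s in queries], db
        )
        assert [a.call for a in fwd] == [a.call for a in rc]
        assert fwd[0].call == "producer" and fwd[1].call == "nonproducer"
        assert fwd[2].call == "unassigned"

    def test_matches_exhaustive_offset_scan_oracle(self):
        rng = np.random.default_rng(14)
        refs_p = [_rec(f"P{i}", _seq(rng, 400), label="likely") for i in range(6)]
        refs_c = [_rec(f"C{i}", _seq(rng, 400), label="nonproducer") for i in range(6)]
        db = ReferenceDB(producers=refs_p, nonproducers=refs_c)
        queries = []
        for i in range(15):
            pool = refs_p + refs_c
            ref = pool[int(rng.integers(len(pool)))]
            off = int(rng.integers(0, 320))
            q = ref.sequence[off : off + 80]
            if rng.random() < 0.3:
                pos = int(rng.integers(80))
                q = q[:pos] + ("A" if q[pos] != "A" else "T") + q[pos + 1 :]
            if rng.random() < 0.5:
                q = reverse_complement(q)
            queries.append((f"q{i}", q))

        def oracle_hits(q, refs):
            found = []
            for ref in refs:
                for target in (ref.sequence, reverse_complement(ref.sequence)):
                    for off in range(len(target) - len(q) + 1):
                        if all(target[off + k] == q[k] for k in range(len(q))):
                            found.append(ref.seq_id)
                            break
                    else:
                        continue
                    break
            return found

        anns = annotate_otus(queries, db)
        for (qid, q), ann in zip(queries, anns):
            p = oracle_hits(q, refs_p)
            c = oracle_hits(q, refs_c)
            expected = (
                "ambiguous" if p and c else
                "producer" if p else
                "nonproducer" if c else "unassigned"
            )
            assert ann.call == expected, qid
            assert sorted(ann.matched_refs) == sorted(p + c)

    def test_empty_query_errors(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError, match="no query"):
            annotate_otus([], _db(rng))


class TestProducerProfile:
    def _table(self, counts, otus, samples):
        return AbundanceTable(
            counts=pd.DataFrame(counts, index=otus, columns=samples)
        )

    def test_fractions_and_class_breakdown(self):
        from cobakit.reference16s import OTUAnnotation

        table = self._table(
            [[60, 0], [140, 0], [0, 0]], ["o1", "o2", "o3"], ["sA", "sB"]
        )
        anns = [
            OTUAnnotation("o1", "producer", phenotype="very_likely"),
            OTUAnnotation("o2", "nonproducer"),
            OTUAnnotation("o3", "producer", phenotype="possible"),
        ]
        profile = producer_profile(table, anns)
        assert profile.loc["sA", "producer_fraction"] == pytest.approx(60 / 200)
        assert profile.loc["sA", "fraction_very_likely"] == pytest.approx(0.30)
        assert profile.loc["sA", "n_producer_otus"] == 1
        # zero-read sample: fraction 0 with an explicit flag
        assert profile.loc["sB", "producer_fraction"] == 0.0
        assert profile.loc["sB", "flags"] == "empty_sample"

    def test_negative_counts_error(self):
        from cobakit.reference16s import OTUAnnotation

        table = self._table([[5], [1]], ["o1", "o2"], ["sA"])
        table.counts.iloc[1, 0] = -1  # corrupt after construction
        with pytest.raises(ValueError, match="negative"):
            producer_profile(table, [OTUAnnotation("o1", "producer")])
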