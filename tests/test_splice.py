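"""Alternative-transcript comparison: exclusion, truncation, intron retention."""

import numpy as np
import pandas as pd
import pytest

from nlrforge.io import DomainHit, GeneModel, TranscriptModel
from nlrforge.splice import (
    compare_transcript_domains,
    detect_retained_introns,
    join_expression,
)


def hit(pid, acc, start, end, name=""):
    return DomainHit(pid, acc, name, start, end)


def gene(tids):
    return GeneModel("g1", "1A", 0, 10_000, "+", transcript_ids=list(tids))


class TestCompareTranscriptDomains:
    def test_variant_lacking_wrky_is_excluded_nlr_only(self):
        hits = {
            "t1": [hit("t1", "PF00931", 100, 400), hit("t1", "PF18052", 10, 50),
                   hit("t1", "PF13855", 420, 600), hit("t1", "PF03106", 650, 710)],
            "t2": [hit("t2", "PF00931", 100, 400), hit("t2", "PF18052", 10, 50),
                   hit("t2", "PF13855", 420, 600)],
        }
        rep = compare_transcript_domains(gene(["t1", "t2"]), hits)
        assert rep.reference_transcript_id == "t1"
        (row,) = [r for r in rep.rows if not r.is_reference]
        assert row.excluded_ids == ["PF03106"]
        assert row.truncated_ids == []
        assert row.transcript_class == "NLR-only"
        assert rep.has_id_excluding_variant()

    def test_half_length_id_is_truncated(self):
        hits = {
            "t1": [hit("t1", "PF00931", 100, 400), hit("t1", "PF03106", 650, 710)],
            "t2": [hit("t2", "PF00931", 100, 400), hit("t2", "PF03106", 650, 680)],
        }
        rep = compare_transcript_domains(gene(["t1", "t2"]), hits)
        (row,) = [r for r in rep.rows if not r.is_reference]
        assert row.truncated_ids == ["PF03106"]
        assert row.excluded_ids == []

    def test_exclusion_and_truncation_mutually_exclusive(self):
        hits = {
            "t1": [hit("t1", "PF00931", 100, 400), hit("t1", "PF03106", 650, 710)],
            "t2": [hit("t2", "PF00931", 100, 400)],
        }
        rep = compare_transcript_domains(gene(["t1", "t2"]), hits)
        (row,) = [r for r in rep.rows if not r.is_reference]
        assert row.excluded_ids and not row.truncated_ids

    def test_single_transcript_gene_gives_report_without_comparisons(self):
        hits = {"t1": [hit("t1", "PF00931", 100, 400)]}
        rep = compare_transcript_domains(gene(["t1"]), hits)
        assert len(rep.rows) == 1 and rep.rows[0].is_reference

    def test_transcript_classes(self):
        hits = {
            "t1": [hit("t1", "PF00931", 100, 400), hit("t1", "PF03106", 500, 560)],
            "t2": [hit("t2", "PF03106", 100, 160)],
            "t3": [],
        }
        rep = compare_transcript_domains(gene(["t1", "t2", "t3"]), hits)
        classes = {r.transcript_id: r.transcript_class for r in rep.rows}
        assert classes == {"t1": "NLR-ID", "t2": "ID-only", "t3": "neither"}

    def test_planted_exclusion_rate_recovered(self, small_parsed):
        """Detected per-gene exclusion flags equal the planted flags."""
        truth = small_parsed["truth"]
        gene_by_id = {g.gene_id: g for g in small_parsed["genes"]}
        tx_by_id = {t.transcript_id: t for t in small_parsed["transcripts"]}
        plen = {p.protein_id: p.length for p in small_parsed["proteome"]}
        n = 0
        for gid, info in truth["genes"].items():
            if not info["is_nlr"] or len(info["transcripts"]) < 2:
                continue
            g = gene_by_id[gid]
            rep = compare_transcript_domains(
                g,
                {t: small_parsed["hits_by_protein"].get(t, []) for t in g.transcript_ids},
                transcripts=tx_by_id,
                protein_lengths=plen,
            )
            for row in rep.rows:
                t = info["transcripts"][row.transcript_id]
                if row.is_reference:
                    assert t["kind"] == "reference"
                    continue
                assert sorted(row.excluded_ids) == sorted(t["excluded_ids"])
                assert sorted(row.truncated_ids) == sorted(t["truncated_ids"])
                assert row.retained_introns == t["retained_introns"]
                n += 1
        assert n >= 5


def tx(tid, exons, strand="+"):
    return TranscriptModel(tid, "g1", strand, exons=sorted(exons))


class TestRetainedIntrons:
    def test_exon_spanning_fourth_intron(self):
        # reference: five 100-bp exons separated by 50-bp introns
        ref_exons = [(i * 150, i * 150 + 100) for i in range(5)]
        ref = tx("t1", ref_exons)
        # query merges exons 4 and 5 across intron 4
        q_exons = ref_exons[:3] + [(450, 700)]
        assert detect_retained_introns(tx("t2", q_exons), ref) == [4]

    def test_identical_transcripts_retain_nothing(self):
        ref_exons = [(0, 100), (200, 300)]
        assert detect_retained_introns(tx("t2", ref_exons), tx("t1", ref_exons)) == []

    def test_different_strands_is_error(self):
        with pytest.raises(ValueError, match="different strands"):
            detect_retained_introns(tx("t2", [(0, 10)], "-"), tx("t1", [(0, 10)], "+"))

    def test_minus_strand_indices_count_from_transcription_start(self):
        # genomic exons left->right; transcription runs right->left on '-'
        ref_exons = [(0, 100), (200, 300), (400, 500)]
        ref = tx("t1", ref_exons, "-")
        # retain the genomic-left intron (0-based gap 100..200): that is the
        # *second* intron in transcription order
        q = tx("t2", [(0, 300), (400, 500)], "-")
        assert detect_retained_introns(q, ref) == [2]

    def test_strand_reversal_maps_index_i_to_n_plus_1_minus_i(self):
        ref_exons = [(0, 100), (200, 300), (400, 500), (600, 700)]
        q_exons = [(0, 100), (200, 500), (600, 700)]  # spans middle intron 2 of 3
        plus = detect_retained_introns(tx("q", q_exons, "+"), tx("r", ref_exons, "+"))
        minus = detect_retained_introns(tx("q", q_exons, "-"), tx("r", ref_exons, "-"))
        n = len(ref_exons) - 1
        assert sorted(n + 1 - i for i in plus) == minus

    def test_planted_retained_introns_recovered(self, small_parsed):
        truth = small_parsed["truth"]
        tx_by_id = {t.transcript_id: t for t in small_parsed["transcripts"]}
        n = 0
        for gid, info in truth["genes"].items():
            ref_tid = gid + ".1"
            for tid, t_info in info["transcripts"].items():
                if t_info["kind"] != "retention":
                    continue
                got = detect_retained_introns(tx_by_id[tid], tx_by_id[ref_tid])
                assert got == t_info["retained_introns"]
                n += 1
        assert n >= 3


class TestJoinExpression:
    def _report(self):
        hits = {
            "t1": [hit("t1", "PF00931", 100, 400)],
            "t2": [hit("t2", "PF00931", 100, 400)],
        }
        return compare_transcript_domains(gene(["t1", "t2"]), hits)

    def test_both_transcripts_gain_vectors(self):
        table = pd.DataFrame(
            {"transcript_id": ["t1", "t2"], "leaf": [1.0, 2.0], "root": [3.0, 4.0]}
        )
        rep = join_expression(self._report(), table)
        assert all(r.expression is not None for r in rep.rows)
        assert rep.rows[0].expression == {"leaf": 1.0, "root": 3.0}

    def test_missing_transcript_gets_null_vector(self):
        table = pd.DataFrame({"transcript_id": ["t1"], "leaf": [1.0]})
        rep = join_expression(self._report(), table)
        by_tid = {r.transcript_id: r.expression for r in rep.rows}
        assert by_tid["t1"] == {"leaf": 1.0}
        assert by_tid["t2"] is None

    def test_no_overlap_warns_and_leaves_report_unmodified(self, caplog):
        table = pd.DataFrame({"transcript_id": ["zzz"], "leaf": [1.0]})
        with caplog.at_level("WARNING"):
            rep = join_expression(self._report(), table)
        assert "no transcripts" in caplog.text
        assert all(r.expression is None for r in rep.rows)

    def test_row_permutation_leaves_output_identical(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"transcript_id": ["t2", "t1"], "leaf": [2.0, 1.0], "root": [4.0, 3.0]}
        )
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = join_expression(self._report(), table)
        b = join_expression(self._report(), shuffled)
        assert [r.expression for r in a.rows] == [r.expression for r in b.rows]
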