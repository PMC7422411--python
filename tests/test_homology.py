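"""Seed-and-extend homology search and progenitor categories."""

import numpy as np
import pytest

from nlrforge.align import make_aligner
from nlrforge.homology import (
    HomologyHit,
    assign_progenitor_category,
    flag_nlr_homologs,
    nlr_homolog_fraction,
    search_homologs,
)
from nlrforge.io import DomainHit, GeneModel, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_seq(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


class TestSearchHomologs:
    def test_identical_subject_full_identity(self):
        rng = np.random.default_rng(0)
        q = rand_seq(rng, 60)
        proteome = [ProteinRecord("s1", q), ProteinRecord("s2", rand_seq(rng, 60))]
        hits = search_homologs(q, proteome, species="HV")
        assert len(hits) == 1
        assert hits[0].subject_protein_id == "s1"
        assert hits[0].pct_identity == 100.0
        assert hits[0].coverage == 1.0

    def test_no_shared_kmer_gives_empty(self):
        proteome = [ProteinRecord("s1", "W" * 50)]
        assert search_homologs("A" * 50, proteome) == []

    def test_empty_proteome_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert search_homologs("AAAAA", [], species="OS") == []
        assert "empty target proteome" in caplog.text

    def test_result_invariant_to_record_order(self):
        rng = np.random.default_rng(3)
        q = rand_seq(rng, 50)
        subjects = [ProteinRecord(f"s{i}", q[:40] + rand_seq(rng, 10)) for i in range(5)]
        fwd = search_homologs(q, subjects, min_identity=50, min_coverage=0.5)
        rev = search_homologs(q, subjects[::-1], min_identity=50, min_coverage=0.5)
        assert [(h.subject_protein_id, h.pct_identity) for h in fwd] == [
            (h.subject_protein_id, h.pct_identity) for h in rev
        ]

    def test_seed_and_extend_matches_full_smith_waterman(self):
        """No filtering loss at k=5 for >= 70%-identical pairs of length <= 40."""
        rng = np.random.default_rng(7)
        aligner = make_aligner("local", "BLOSUM62", 10, 1)
        n_compared = 0
        for _ in range(100):
            n = int(rng.integers(20, 41))
            q = rand_seq(rng, n)
            s = list(q)
            for i in range(n):  # ~15% divergence keeps identity >= 70%
                if rng.random() < 0.15:
                    s[i] = AA[int(rng.integers(0, 20))]
            subject = ProteinRecord("s", "".join(s))
            hits = search_homologs(q, [subject], min_identity=70, min_coverage=0.5)
            aln = aligner.align(q, subject.sequence)[0]
            row_q, row_s = str(aln[0]), str(aln[1])
            ident = sum(1 for x, y in zip(row_q, row_s) if x == y and x != "-")
            full_pct = 100.0 * ident / len(row_q)
            if full_pct >= 70:
                assert hits, (q, subject.sequence)
                assert hits[0].pct_identity == pytest.approx(full_pct)
                n_compared += 1
        assert n_compared >= 80


class TestFlagNlrHomologs:
    def _hit(self, sid, species="HV"):
        return HomologyHit("q", "PF03106", species, sid, 90.0, 1.0)

    def test_subject_with_nbarc_flagged(self):
        hits = [self._hit("s1"), self._hit("s2")]
        tables = {"HV": [DomainHit("s1", "PF00931", "NB-ARC", 0, 100)]}
        out = flag_nlr_homologs(hits, tables)
        assert [h.subject_has_nbarc for h in out] == [True, False]

    def test_missing_species_table_warns_and_flags_false(self, caplog):
        with caplog.at_level("WARNING"):
            out = flag_nlr_homologs([self._hit("s1", species="ZM")], {})
        assert not out[0].subject_has_nbarc
        assert "no domain table" in caplog.text

    def test_planted_nlr_homolog_fraction_recovered(self, small_parsed):
        """Truth NLR/non-NLR homolog flags match the domain-table flags."""
        truth = small_parsed["truth"]
        import collections

        from nlrforge import io as nio

        paths = small_parsed["paths"]
        table = nio.read_domain_table(paths["comparator_HV_domains"])
        planted = {}
        for info in truth["genes"].values():
            hv = info.get("progenitors", {}).get("HV")
            if hv:
                planted[hv["protein_id"]] = hv["is_nlr"]
        assert planted
        hits = [self._hit(pid) for pid in sorted(planted)]
        out = flag_nlr_homologs(hits, {"HV": table})
        for h in out:
            assert h.subject_has_nbarc == planted[h.subject_protein_id]
        frac = nlr_homolog_fraction(out)
        expected = sum(planted.values()) / len(planted)
        assert frac["nlr_fraction"].iloc[0] == pytest.approx(expected)


class TestProgenitorCategory:
    def _gene(self, chrom):
        return GeneModel("g1", chrom, 0, 1000, "+")

    def test_a_gene_best_tu_is_match_high_identity(self):
        a = assign_progenitor_category(self._gene("4A"), 95.0, 80.0)
        assert (a.category, a.identity_bin) == ("Match", ">90")

    def test_b_gene_is_always_b(self):
        a = assign_progenitor_category(self._gene("4B"), 95.0, 99.0)
        assert a.category == "B"

    def test_unknown_subgenome_is_u(self):
        a = assign_progenitor_category(self._gene("scaffold123"), 80.0, 85.0)
        assert a.category == "U"
        assert a.subgenome == "unknown"

    def test_a_gene_closer_to_at_is_mislabeled_a(self):
        a = assign_progenitor_category(self._gene("1A"), 75.0, 92.0)
        assert a.category == "A"
        assert a.best_progenitor == "AT"

    def test_d_gene_closer_to_tu_is_mislabeled_d(self):
        a = assign_progenitor_category(self._gene("1D"), 92.0, 75.0)
        assert a.category == "D"

    def test_expected_progenitor_wins_ties(self):
        a = assign_progenitor_category(self._gene("1A"), 85.0, 85.0)
        assert a.category == "Match"
        d = assign_progenitor_category(self._gene("1D"), 85.0, 85.0)
        assert d.category == "Match"

    def test_no_hits_fall_back_to_subgenome_category(self):
        a = assign_progenitor_category(self._gene("1A"), 0.0, 0.0)
        assert (a.category, a.identity_bin) == ("A", "<70")

    def test_categories_partition_gene_set(self):
        chroms = ["1A", "2B", "3D", "scaffold", "5A", "6D"]
        rng = np.random.default_rng(1)
        cats = []
        for i, c in enumerate(chroms):
            g = GeneModel(f"g{i}", c, 0, 10, "+")
            cats.append(
                assign_progenitor_category(
                    g, float(rng.uniform(0, 100)), float(rng.uniform(0, 100))
                ).category
            )
        assert all(c in ("Match", "A", "B", "D", "U") for c in cats)
        assert len(cats) == len(chroms)

    def test_match_fraction_increases_with_cross_progenitor_divergence(self, tmp_path):
        """More cross-progenitor divergence -> cleaner progenitor signal."""
        import collections

        from nlrforge import io as nio
        from nlrforge.homology import build_kmer_index
        from nlrforge.simulate import SimulationConfig, generate

        fractions = []
        for cross in (0.06, 0.15, 0.30):
            cfg = SimulationConfig(
                seed=9, n_chromosomes=3, genes_per_chromosome=40,
                id_insertion_prob=0.6, cross_progenitor_divergence=cross,
                progenitor_presence=1.0, other_progenitor_presence=1.0,
            )
            truth, paths = generate(cfg, tmp_path / f"c{cross}")
            prot = {p.protein_id: p for p in nio.read_fasta(paths["proteome"])}
            targets = {
                sp: nio.read_fasta(paths[f"progenitor_{sp}"]) for sp in ("TU", "AT")
            }
            indexes = {sp: build_kmer_index(targets[sp]) for sp in targets}
            n_match = n_tot = 0
            for gid, info in truth["genes"].items():
                if not info.get("ids") or info["subgenome"] not in ("A", "D"):
                    continue
                d = info["ids"][0]
                q = prot[gid + ".1"].sequence[d["start"]: d["end"]]
                best = {}
                for sp in ("TU", "AT"):
                    hits = search_homologs(
                        q, targets[sp], min_identity=0, min_coverage=0.5,
                        kmer_index=indexes[sp], species=sp,
                    )
                    best[sp] = hits[0].pct_identity if hits else 0.0
                g = GeneModel(gid, info["chromosome"], 0, 1, "+")
                cat = assign_progenitor_category(g, best["TU"], best["AT"]).category
                n_tot += 1
                n_match += cat == "Match"
            fractions.append(n_match / n_tot)
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[-1] > 0.8
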