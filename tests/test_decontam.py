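"""The four contamination screens and their composition."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sagtools.decontam import (
    apply_decontamination,
    assign_gene_domain,
    euk_signature_keep,
    flag_bacterial_scaffolds,
    flag_cross_taxon,
    flag_organelle,
    fragment_scaffold,
)
from sagtools.types import AssemblyBundle, GeneModel, HitRecord, Scaffold


def _scaffold(length, sid="s1"):
    return Scaffold(sid, "A" * length)


class TestFragmentation:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (2000, [(0, 1000), (500, 1500), (1000, 2000)]),
            (800, [(0, 800)]),
            (1700, [(0, 1000), (500, 1500), (700, 1700)]),
            (1000, [(0, 1000)]),
            (1001, [(0, 1000), (1, 1001)]),
        ],
    )
    def test_window_layout(self, length, expected):
        frags = fragment_scaffold(_scaffold(length))
        assert [(f.start, f.end) for f in frags] == expected

    @given(st.integers(min_value=1, max_value=5000))
    @settings(max_examples=60, deadline=None)
    def test_every_base_covered(self, length):
        frags = fragment_scaffold(_scaffold(length))
        covered = np.zeros(length, dtype=bool)
        for f in frags:
            assert len(f.sequence) == f.end - f.start
            covered[f.start:f.end] = True
        assert covered.all()

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            fragment_scaffold(Scaffold("s", ""))


class TestCrossTaxonScreen:
    TAXA = {"m3_s1": "MAST-3", "chr_s1": "chrysophytes",
            "m4a1_s1": "MAST-4", "m4a2_s1": "MAST-4"}

    def _hit(self, frag, subject, identity, coverage):
        return HitRecord(frag, subject, identity, 900, 1e-100, 900.0,
                         "Eukaryota", query_coverage=coverage)

    def test_distant_match_above_thresholds_flags_parent(self):
        hits = [self._hit("m3_s1|0-1000", "chr_s1", 96.0, 0.85)]
        assert flag_cross_taxon(hits, self.TAXA) == {"m3_s1"}

    def test_coverage_at_or_below_80_percent_does_not_flag(self):
        hits = [self._hit("m3_s1|0-1000", "chr_s1", 96.0, 0.75),
                self._hit("m3_s1|500-1500", "chr_s1", 96.0, 0.80)]
        assert flag_cross_taxon(hits, self.TAXA) == set()

    def test_identity_below_95_does_not_flag(self):
        hits = [self._hit("m3_s1|0-1000", "chr_s1", 94.9, 1.0)]
        assert flag_cross_taxon(hits, self.TAXA) == set()

    def test_same_taxon_group_never_flags(self):
        hits = [self._hit("m4a1_s1|0-1000", "m4a2_s1", 100.0, 1.0)]
        assert flag_cross_taxon(hits, self.TAXA) == set()

    def test_hit_order_irrelevant(self):
        hits = [self._hit("m3_s1|0-1000", "chr_s1", 96.0, 0.85),
                self._hit("chr_s1|0-1000", "m3_s1", 96.0, 0.85)]
        assert flag_cross_taxon(hits, self.TAXA) == \
            flag_cross_taxon(hits[::-1], self.TAXA) == {"m3_s1", "chr_s1"}

    def test_unresolvable_ids_raise(self):
        with pytest.raises(KeyError):
            flag_cross_taxon([self._hit("nope|0-1000", "chr_s1", 96, 1.0)], self.TAXA)


class TestOrganelleScreen:
    GENES = [GeneModel(f"g{i}", "s1", 100 * i, 100 * i + 50) for i in range(4)]

    def _nt(self, sid, score):
        return HitRecord(sid, "org_ref", 90, 500, 0.0, score, "Eukaryota", "organelle_nt")

    def _prot(self, gid, cls):
        return HitRecord(gid, "ref", 60, 100, 1e-40, 200, "Eukaryota", cls)

    def test_nt_bit_score_above_1000_flags(self):
        assert flag_organelle([self._nt("s1", 1200)], [], self.GENES) == {"s1"}

    def test_two_organelle_proteins_insufficient(self):
        prots = [self._prot("g0", "MTH"), self._prot("g1", "MTH")]
        assert flag_organelle([], prots, self.GENES) == set()

    def test_three_chl_proteins_flag(self):
        prots = [self._prot("g0", "CHL"), self._prot("g1", "CHL"), self._prot("g2", "CHL")]
        assert flag_organelle([], prots, self.GENES) == {"s1"}

    def test_score_1000_is_not_above_threshold(self):
        assert flag_organelle([self._nt("s1", 1000)], [], self.GENES) == set()

    def test_repeated_hits_to_one_gene_count_once(self):
        prots = [self._prot("g0", "MTH")] * 5
        assert flag_organelle([], prots, self.GENES) == set()


class TestEukSignature:
    def _genes(self, n, sid="s1"):
        return {sid: [GeneModel(f"{sid}_g{i}", sid, 10 * i, 10 * i + 5) for i in range(n)]}

    def test_one_eukaryotic_gene_keeps_scaffold(self):
        genes = self._genes(2)
        keep = euk_signature_keep({"s1_g0": "Eukaryota", "s1_g1": "other"}, genes)
        assert keep == {"s1"}

    def test_all_non_eukaryotic_discards(self):
        genes = self._genes(2)
        keep = euk_signature_keep({"s1_g0": "other", "s1_g1": "other"}, genes)
        assert keep == set()

    def test_all_anonymous_keeps(self):
        genes = self._genes(2)
        keep = euk_signature_keep({"s1_g0": "no_hit", "s1_g1": "no_hit"}, genes)
        assert keep == {"s1"}

    def test_mixed_no_hit_and_other_discards(self):
        genes = self._genes(2)
        keep = euk_signature_keep({"s1_g0": "no_hit", "s1_g1": "other"}, genes)
        assert keep == set()

    def test_geneless_scaffold_kept_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            keep = euk_signature_keep({}, {"s1": []})
        assert keep == {"s1"}
        assert "vacuous" in caplog.text

    def test_assignment_uses_best_hit(self):
        hits = {
            "g1": [HitRecord("g1", "b", 50, 100, 1e-60, 300, "Bacteria"),
                   HitRecord("g1", "e", 50, 100, 1e-20, 100, "Eukaryota")],
        }
        assert assign_gene_domain(hits, ["g1", "g2"]) == {"g1": "other", "g2": "no_hit"}


class TestBacterialAiScreen:
    def _genes(self, ais, sid="s1"):
        genes = [GeneModel(f"g{i}", sid, 10 * i, 10 * i + 5) for i in range(len(ais))]
        return {sid: genes}, {f"g{i}": a for i, a in enumerate(ais)}

    def test_exclusively_high_ai_flags(self):
        genes, ai = self._genes([50.0, 60.0, 70.0])
        assert flag_bacterial_scaffolds(ai, genes) == {"s1"}

    def test_one_low_ai_gene_prevents_flag(self):
        genes, ai = self._genes([50.0, 60.0, 30.0])
        assert flag_bacterial_scaffolds(ai, genes) == set()

    def test_undefined_ai_is_neutral(self):
        genes, ai = self._genes([50.0, None])
        assert flag_bacterial_scaffolds(ai, genes) == {"s1"}

    def test_all_undefined_not_flagged(self):
        genes, ai = self._genes([None, None])
        assert flag_bacterial_scaffolds(ai, genes) == set()

    def test_threshold_is_strict(self):
        genes, ai = self._genes([45.0])
        assert flag_bacterial_scaffolds(ai, genes) == set()


class TestComposition:
    def _bundle(self):
        scaffolds = {
            "s1": Scaffold("s1", "A" * 10_000),
            "s2": Scaffold("s2", "C" * 4_000),
            "s3": Scaffold("s3", "G" * 6_000),
        }
        genes = [GeneModel("g1", "s1", 0, 500), GeneModel("g2", "s2", 0, 500)]
        return AssemblyBundle("org", scaffolds, genes)

    def test_no_flags_is_identity(self):
        bundle = self._bundle()
        cleaned, report = apply_decontamination(bundle, {})
        assert cleaned.assembly_size_bp == bundle.assembly_size_bp
        assert set(report.verdicts["verdict"]) == {"kept"}
        assert report.removed_total_bp == 0

    def test_removed_bp_accounted_per_category(self):
        bundle = self._bundle()
        cleaned, report = apply_decontamination(bundle, {"cross_taxon": {"s1"}})
        assert report.removed_bp["cross_taxon"] == 10_000
        assert cleaned.assembly_size_bp == 10_000
        assert "s1" not in cleaned.scaffolds
        assert all(g.scaffold_id != "s1" for g in cleaned.genes)

    def test_double_flag_reported_once_under_earlier_category(self):
        bundle = self._bundle()
        _, report = apply_decontamination(
            bundle, {"organelle": {"s2"}, "non_eukaryotic_signature": {"s2"}}
        )
        row = report.verdicts.set_index("scaffold_id").loc["s2"]
        assert row["verdict"] == "organelle"
        assert report.removed_bp["organelle"] == 4_000
        assert report.removed_bp["non_eukaryotic_signature"] == 0

    def test_bp_conservation(self):
        bundle = self._bundle()
        _, report = apply_decontamination(
            bundle, {"cross_taxon": {"s1"}, "bacterial_AI": {"s3"}}
        )
        assert report.kept_bp + report.removed_total_bp == bundle.assembly_size_bp
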