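import pytest

from barcodedb.curation import (ContaminantParams, CullParams, MisidParams,
                                cull_sequences, dereplicate,
                                filter_contaminants, filter_misidentified)
from barcodedb.store import SequenceRecord
from tests.conftest import make_db, make_lineage
from tests.helpers import mutate, random_seq, substitute


def clean_seq(rng, length=60):
    """Random sequence with no homopolymer run >= 4 (cull-safe)."""
    while True:
        s = random_seq(rng, length)
        from barcodedb.curation import longest_homopolymer
        if longest_homopolymer(s) < 4:
            return s


class TestCull:
    @pytest.mark.parametrize("n_degenerate,removed", [(4, False), (5, True)])
    def test_degenerate_boundary(self, rng, n_degenerate, removed):
        base = clean_seq(rng)
        seq = base[:-n_degenerate] + "N" * n_degenerate if n_degenerate else base
        db = make_db([("x", seq, make_lineage("FamA"))])
        out = cull_sequences(db)
        assert ("x" not in out.identifiers) is removed

    @pytest.mark.parametrize("run,removed", [(11, False), (12, True)])
    def test_homopolymer_boundary(self, rng, run, removed):
        seq = clean_seq(rng) + "A" * run + clean_seq(rng)
        out = cull_sequences(make_db([("x", seq, make_lineage("FamA"))]))
        assert ("x" not in out.identifiers) is removed

    def test_both_just_below_thresholds_kept(self, rng):
        seq = clean_seq(rng) + "NNNN" + clean_seq(rng) + "A" * 11
        out = cull_sequences(make_db([("x", seq, make_lineage("FamA"))]))
        assert "x" in out.identifiers

    def test_idempotent(self, rng):
        db = make_db([("a", clean_seq(rng) + "N" * 6, make_lineage("FamA")),
                      ("b", clean_seq(rng), make_lineage("FamB"))])
        once = cull_sequences(db)
        twice = cull_sequences(once)
        assert once.identifiers == twice.identifiers


class TestDereplicate:
    def identical_group(self, rng):
        seq = clean_seq(rng, 80)
        lin_a = make_lineage("FamA", species="GenFamA spA")
        lin_b = make_lineage("FamB", species="GenFamB spB")
        return make_db([
            ("r1", seq, lin_a), ("r2", seq, lin_a), ("r3", seq, lin_b),
        ])

    def test_uniq_keeps_one_per_lineage(self, rng):
        out = dereplicate(self.identical_group(rng), mode="uniq")
        assert out.identifiers == ["r1", "r3"]
        assert out.species_labels() == {"GenFamA spA", "GenFamB spB"}

    def test_uniq_preserves_species_set(self, rng):
        db = self.identical_group(rng)
        assert dereplicate(db, "uniq").species_labels() == db.species_labels()

    def test_majority_keeps_modal_label(self, rng):
        with pytest.warns(UserWarning, match="majority"):
            out = dereplicate(self.identical_group(rng), mode="majority")
        assert out.identifiers == ["r1"]
        assert out.taxonomy["r1"].family == "FamA"

    def test_majority_tie_lexicographic(self, rng):
        seq = clean_seq(rng, 80)
        db = make_db([("r1", seq, make_lineage("FamB")),
                      ("r2", seq, make_lineage("FamA"))])
        with pytest.warns(UserWarning):
            out = dereplicate(db, mode="majority")
        assert out.taxonomy["r1"].family == "FamA"

    def test_distinct_sequences_untouched(self, rng):
        db = make_db([("a", clean_seq(rng), make_lineage("FamA")),
                      ("b", clean_seq(rng), make_lineage("FamB"))])
        for mode in ("uniq",):
            out = dereplicate(db, mode)
            assert out.identifiers == db.identifiers
            assert out.taxonomy == db.taxonomy

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError, match="mode"):
            dereplicate(self.identical_group(rng), mode="best")

    def test_order_stability(self, rng):
        seq = clean_seq(rng, 80)
        db = make_db([("z", clean_seq(rng, 80), make_lineage("FamC")),
                      ("m", seq, make_lineage("FamA")),
                      ("a", seq, make_lineage("FamA"))])
        out = dereplicate(db, "uniq")
        assert out.identifiers == ["z", "a"]


class TestFilterContaminants:
    def test_identical_to_contaminant_removed(self, rng):
        seq = random_seq(rng, 120)
        db = make_db([("x", seq, make_lineage("FamA")),
                      ("y", random_seq(rng, 120), make_lineage("FamA"))])
        out = filter_contaminants(db, [SequenceRecord("c", seq)])
        assert out.identifiers == ["y"]

    def test_identity_below_floor_kept(self, rng):
        seq = random_seq(rng, 100)
        # 11 interior substitutions -> 89% identity over the full length
        cont = substitute(seq, [8 * i + 6 for i in range(11)])
        db = make_db([("x", seq, make_lineage("FamA"))])
        out = filter_contaminants(db, [SequenceRecord("c", cont)])
        assert "x" in out.identifiers

    def test_coverage_below_floor_kept(self, rng):
        seq = random_seq(rng, 100)
        db = make_db([("x", seq, make_lineage("FamA"))])
        # contaminant covers only 90% of the query at 100% identity
        out = filter_contaminants(db, [SequenceRecord("c", seq[5:95])])
        assert "x" in out.identifiers

    def test_empty_contaminant_set_rejected(self, rng):
        db = make_db([("x", random_seq(rng, 100), make_lineage("FamA"))])
        with pytest.raises(ValueError, match="empty"):
            filter_contaminants(db, [])

    def test_idempotent(self, rng):
        seq = random_seq(rng, 120)
        db = make_db([("x", seq, make_lineage("FamA")),
                      ("y", random_seq(rng, 120), make_lineage("FamB"))])
        refs = [SequenceRecord("c", seq)]
        once = filter_contaminants(db, refs)
        twice = filter_contaminants(once, refs)
        assert once.identifiers == twice.identifiers


class TestFilterMisidentified:
    def planted_db(self, rng, relabel=True):
        entries = []
        for fam in ("FamA", "FamB"):
            ancestor = random_seq(rng, 200)
            for i in range(6):
                entries.append((f"{fam}-{i}", mutate(rng, ancestor, 0.01),
                                make_lineage(fam)))
        db = make_db(entries)
        if relabel:
            # FamA-0 claims FamB membership but is sequence-similar to FamA
            db.taxonomy["FamA-0"] = make_lineage("FamB")
        return db

    def test_planted_mislabel_removed_clean_kept(self, rng):
        db = self.planted_db(rng)
        out = filter_misidentified(db)
        assert set(db.identifiers) - set(out.identifiers) == {"FamA-0"}

    def test_correctly_labeled_family_all_kept(self, rng):
        out = filter_misidentified(self.planted_db(rng, relabel=False))
        assert len(out) == 12

    def test_singleton_divergent_family_is_collateral_loss(self, rng):
        db = self.planted_db(rng, relabel=False)
        lone = SequenceRecord("lone-0", random_seq(rng, 200))
        db.sequences.append(lone)
        db.taxonomy["lone-0"] = make_lineage("FamZ")
        out = filter_misidentified(db)
        assert "lone-0" not in out.identifiers
        removed = out.provenance_log[-1].params["removed"]
        assert any(r["identifier"] == "lone-0" for r in removed)

    def test_exempt_singleton_families_switch(self, rng):
        db = self.planted_db(rng, relabel=False)
        db.sequences.append(SequenceRecord("lone-0", random_seq(rng, 200)))
        db.taxonomy["lone-0"] = make_lineage("FamZ")
        out = filter_misidentified(db, exempt_singleton_families=True)
        assert "lone-0" in out.identifiers

    def test_missing_family_label_kept_and_reported(self, rng):
        db = self.planted_db(rng, relabel=False)
        from dataclasses import replace
        db.taxonomy["FamA-0"] = replace(make_lineage("FamA"), family=None)
        out = filter_misidentified(db)
        assert "FamA-0" in out.identifiers
        assert out.provenance_log[-1].params["missing_rank_label"] == ["FamA-0"]

    def test_monotone_and_lineages_unchanged(self, rng):
        db = self.planted_db(rng)
        out = filter_misidentified(db)
        assert set(out.identifiers) <= set(db.identifiers)
        assert all(out.taxonomy[i] == db.taxonomy[i] for i in out.identifiers)
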