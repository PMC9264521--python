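import math

import numpy as np
import pytest

from barcodedb.evaluate import (CVConfig, classify, cross_validate,
                                entropy_profile, evaluate, fit_classifier,
                                length_summary)
from barcodedb.synthetic import FixtureSpec, generate
from barcodedb.taxonomy import Lineage
from tests.conftest import make_db, make_lineage
from tests.helpers import random_seq


def db_with_sequences(seqs, species=None):
    entries = []
    for i, s in enumerate(seqs):
        sp = (species or [f"GenA sp{i}"] * len(seqs))[i]
        entries.append((f"r{i}", s, make_lineage("FamA", genus="GenA",
                                                 species=sp)))
    return make_db(entries)


class TestEntropy:
    def test_uniform_distinct_sequences_attain_log_n(self, rng):
        db = db_with_sequences([random_seq(rng, 50) for _ in range(4)])
        assert entropy_profile(db).sequence_entropy == pytest.approx(math.log(4))

    def test_single_species_label_zero_entropy(self, rng):
        db = db_with_sequences([random_seq(rng, 50) for _ in range(4)],
                               species=["GenA spX"] * 4)
        assert entropy_profile(db).taxonomic_entropy["species"] == 0.0

    def test_mixed_frequencies_closed_form(self, rng):
        seqs = [random_seq(rng, 50) for _ in range(3)]
        db = db_with_sequences([seqs[0], seqs[0], seqs[1], seqs[2]])
        h = entropy_profile(db).sequence_entropy
        assert h == pytest.approx(1.0397, abs=1e-4)

    def test_bounds_and_unique_count(self, rng):
        db = db_with_sequences([random_seq(rng, 50) for _ in range(6)])
        prof = entropy_profile(db)
        assert 0 <= prof.sequence_entropy <= math.log(prof.unique_sequences)
        assert prof.unique_sequences <= prof.total_sequences

    def test_missing_rank_excluded(self, rng):
        db = db_with_sequences([random_seq(rng, 50) for _ in range(3)])
        from dataclasses import replace
        db.taxonomy["r0"] = replace(db.taxonomy["r0"], species=None)
        # two remaining records, two distinct species labels -> ln 2
        assert entropy_profile(db).taxonomic_entropy["species"] == \
            pytest.approx(math.log(2))


class TestLengthSummary:
    def test_median(self, rng):
        db = db_with_sequences([random_seq(rng, n) for n in (100, 200, 300)])
        assert length_summary(db)["median"] == 200

    def test_single_record_degenerate(self, rng):
        s = length_summary(db_with_sequences([random_seq(rng, 80)]))
        assert s["min"] == s["median"] == s["max"] == 80

    def test_histogram_bins(self, rng):
        db = db_with_sequences([random_seq(rng, n) for n in range(1, 101)])
        hist = length_summary(db)["histogram"]
        assert hist == {1: 50, 51: 50}


class TestClassifier:
    def test_single_class_always_predicted(self, rng):
        db = db_with_sequences([random_seq(rng, 60)], species=["GenA spX"])
        clf = fit_classifier(db)
        pred = classify(clf, db.sequences)
        assert pred["r0"] == db.taxonomy["r0"]

    def test_disjoint_kmer_classes_separable(self):
        # two classes whose sequences share no 7-mer
        a, b = "ACGTACG" * 6, "TTTGGGC" * 6
        db = make_db([
            ("a0", a, make_lineage("FamA", species="GenFamA spA")),
            ("b0", b, make_lineage("FamB", species="GenFamB spB")),
        ])
        clf = fit_classifier(db)
        pred = classify(clf, db.sequences)
        assert pred["a0"].species == "GenFamA spA"
        assert pred["b0"].species == "GenFamB spB"

    def test_posterior_tie_broken_lexicographically(self):
        # symmetric training: the query carries one k-mer from each class
        db = make_db([
            ("a0", "A" * 20, make_lineage("FamA", species="GenFamA spA")),
            ("b0", "T" * 20, make_lineage("FamB", species="GenFamB spB")),
        ])
        from barcodedb.evaluate import _kmer_matrix
        from barcodedb.store import SequenceRecord
        clf = fit_classifier(db, k=7)
        query_rec = SequenceRecord("q", "A" * 7 + "C" + "T" * 7)
        jll = clf.model.predict_joint_log_proba(
            _kmer_matrix([query_rec], 7, clf.vocabulary, grow=False))
        assert jll[0][0] == pytest.approx(jll[0][1])  # genuine posterior tie
        pred = classify(clf, [query_rec])["q"]
        assert str(pred) == min(clf.classes)

    def test_short_record_flagged_and_classified_from_priors(self, rng):
        db = db_with_sequences([random_seq(rng, 60) for _ in range(3)],
                               species=["GenA spX"] * 3)
        clf = fit_classifier(db)
        with pytest.warns(UserWarning, match="shorter than k"):
            pred = classify(clf, [db.sequences[0].__class__("tiny", "ACG")])
        assert pred["tiny"].species == "GenA spX"


class TestEvaluate:
    def lineages(self, labels):
        return {f"r{i}": make_lineage("FamA", genus="GenA",
                                      species=(f"GenA {lab}" if lab else None))
                if lab is not None else
                Lineage(kingdom="K")
                for i, lab in enumerate(labels)}

    def test_hand_tallied_counts(self):
        expected = {f"r{i}": make_lineage("FamA", species=f"sp{i}")
                    for i in range(10)}
        predicted = {}
        for i in range(10):
            if i < 7:      # correct
                predicted[f"r{i}"] = expected[f"r{i}"]
            elif i < 9:    # wrong species
                predicted[f"r{i}"] = make_lineage("FamA", species="wrong sp")
            else:          # no species prediction
                from dataclasses import replace
                predicted[f"r{i}"] = replace(expected[f"r{i}"], species=None)
        m = evaluate(predicted, expected)["species"]
        assert (m.tp, m.fp, m.fn) == (7, 2, 3)
        assert m.precision == pytest.approx(7 / 9)
        assert m.recall == pytest.approx(0.7)
        assert m.f_measure == pytest.approx(2 * (7 / 9) * 0.7 / (7 / 9 + 0.7))

    def test_all_correct(self):
        expected = {f"r{i}": make_lineage("FamA", species=f"sp{i}")
                    for i in range(5)}
        m = evaluate(expected, expected)["species"]
        assert m.precision == m.recall == m.f_measure == 1.0

    def test_none_predicted_degenerate(self):
        from dataclasses import replace
        expected = {f"r{i}": make_lineage("FamA", species=f"sp{i}")
                    for i in range(5)}
        predicted = {k: replace(v, species=None) for k, v in expected.items()}
        m = evaluate(predicted, expected)["species"]
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)

    def test_permutation_symmetric(self):
        expected = {f"r{i}": make_lineage("FamA", species=f"sp{i % 3}")
                    for i in range(6)}
        predicted = {f"r{i}": make_lineage("FamA", species=f"sp{(i + 1) % 3}")
                    for i in range(6)}
        m1 = evaluate(predicted, expected)
        shuffled_exp = dict(reversed(list(expected.items())))
        m2 = evaluate(predicted, shuffled_exp)
        assert {r: (m.tp, m.fp, m.fn) for r, m in m1.items()} == \
            {r: (m.tp, m.fp, m.fn) for r, m in m2.items()}

    def test_identifier_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identifier"):
            evaluate({"a": Lineage()}, {"b": Lineage()})


@pytest.fixture(scope="module")
def separable():
    return generate(FixtureSpec(n_families=6, seqs_per_family=6,
                                species_per_family=2, seed=0)).database


class TestCrossValidate:

    def test_leaked_perfect_on_separable(self, separable):
        res = cross_validate(separable, CVConfig(mode="leaked"))
        assert res.pooled["species"].f_measure == 1.0

    def test_kfold_not_above_leaked(self, separable):
        leaked = cross_validate(separable, CVConfig(mode="leaked"))
        kfold = cross_validate(separable, CVConfig(mode="kfold", K=5, seed=0))
        assert kfold.pooled["species"].f_measure <= \
            leaked.pooled["species"].f_measure

    def test_singleton_species_truncated_out(self):
        # every species has one record: after truncation, no fold retains
        # species-rank expectations
        db = generate(FixtureSpec(n_families=4, seqs_per_family=1,
                                  intra_family_divergence=0.01,
                                  seed=3)).database
        res = cross_validate(db, CVConfig(mode="kfold", K=2, seed=0))
        m = res.pooled["species"]
        assert (m.tp, m.fp, m.fn) == (0, 0, 0)
        assert m.f_measure is None

    def test_pooled_invariant_to_fold_order(self, separable):
        res = cross_validate(separable, CVConfig(mode="kfold", K=4, seed=5))
        pooled = {(m.tp, m.fp, m.fn) for m in [res.pooled["species"]]}
        total = np.array([0, 0, 0])
        for fold in res.per_fold:
            m = fold["species"]
            total += (m.tp, m.fp, m.fn)
        assert pooled == {tuple(total)}

    def test_k_exceeding_records_rejected(self, separable):
        with pytest.raises(ValueError, match="K="):
            cross_validate(separable, CVConfig(mode="kfold", K=1000))
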