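"""Database benchmarking: entropy and length profiles, a k-mer multinomial
naive-Bayes taxonomic classifier, and leaked / k-fold cross-validated
per-rank precision, recall and F-measure.

Two evaluation regimes are offered.  *Leaked* cross-validation trains and
tests on the full database — every query has an exact match, so it measures
the best-case accuracy the database can support.  *k-fold* cross-validation
(default K=5) holds each fold out of training, a pseudo-realistic regime in
which a query's taxon may be absent from training; each test record's expected
lineage is therefore truncated to the deepest rank whose label occurs in that
fold's training set before scoring.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.naive_bayes import MultinomialNB

from .store import ReferenceDatabase, SequenceRecord
from .taxonomy import RANKS, Lineage

__all__ = [
    "EntropyProfile",
    "NBClassifier",
    "RankMetrics",
    "CVResult",
    "entropy_profile",
    "length_summary",
    "fit_classifier",
    "classify",
    "evaluate",
    "cross_validate",
]


def _shannon(counts) -> float:
    """Shannon entropy (nats) of a frequency distribution given as counts."""
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


@dataclass
class EntropyProfile:
    sequence_entropy: float
    taxonomic_entropy: dict[str, float]
    unique_sequences: int
    total_sequences: int

    def to_json(self) -> dict:
        return {
            "sequence_entropy_nats": self.sequence_entropy,
            "taxonomic_entropy_nats": dict(self.taxonomic_entropy),
            "unique_sequences": self.unique_sequences,
            "total_sequences": self.total_sequences,
        }


def entropy_profile(db: ReferenceDatabase) -> EntropyProfile:
    """Sequence entropy (over distinct sequence strings) and per-rank
    taxonomic entropy (over labels; records missing the rank excluded)."""
    if len(db) == 0:
        raise ValueError("entropy of an empty database")
    seq_counts = Counter(r.sequence for r in db.sequences)
    tax_entropy = {}
    for rank in RANKS:
        labels = Counter(
            lin.label_at(rank) for lin in db.taxonomy.values()
            if lin.label_at(rank) is not None
        )
        tax_entropy[rank] = _shannon(labels.values())
    return EntropyProfile(
        sequence_entropy=_shannon(seq_counts.values()),
        taxonomic_entropy=tax_entropy,
        unique_sequences=len(seq_counts),
        total_sequences=len(db),
    )


def length_summary(db: ReferenceDatabase, bin_width: int = 50) -> dict:
    """Five-number length summary plus a fixed-width histogram.

    Histogram bins cover ``[i*bin_width + 1, (i+1)*bin_width]`` and are keyed
    by their lower bound.
    """
    if len(db) == 0:
        raise ValueError("length summary of an empty database")
    lengths = np.array([len(r) for r in db.sequences])
    hist = Counter((int(l) - 1) // bin_width for l in lengths)
    return {
        "min": int(lengths.min()),
        "q1": float(np.percentile(lengths, 25)),
        "median": float(np.median(lengths)),
        "q3": float(np.percentile(lengths, 75)),
        "max": int(lengths.max()),
        "histogram": {idx * bin_width + 1: hist[idx] for idx in sorted(hist)},
        "bin_width": bin_width,
    }


@dataclass
class NBClassifier:
    """Multinomial naive Bayes over k-mer counts of full serialized lineages."""

    k: int
    alpha: float
    vocabulary: dict[str, int]
    classes: list[str]
    model: MultinomialNB = field(repr=False, default=None)


def _kmer_matrix(records, k: int, vocabulary: dict[str, int],
                 grow: bool) -> sparse.csr_matrix:
    rows, cols, data = [], [], []
    for row, rec in enumerate(records):
        counts: Counter = Counter()
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            word = seq[i:i + k]
            if grow and word not in vocabulary:
                if all(c in "ACGT" for c in word):
                    vocabulary[word] = len(vocabulary)
            idx = vocabulary.get(word)
            if idx is not None:
                counts[idx] += 1
        for idx, c in counts.items():
            rows.append(row)
            cols.append(idx)
            data.append(c)
    return sparse.csr_matrix(
        (data, (rows, cols)),
        shape=(len(records), max(len(vocabulary), 1)),
        dtype=np.float64,
    )


def fit_classifier(db: ReferenceDatabase, k: int = 7,
                   alpha: float = 0.001) -> NBClassifier:
    """Train the k-mer naive-Bayes classifier; classes are the distinct
    serialized lineages of the training database."""
    if len(db) == 0:
        raise ValueError("cannot train on an empty database")
    vocabulary: dict[str, int] = {}
    X = _kmer_matrix(db.sequences, k, vocabulary, grow=True)
    y = np.array([str(db.taxonomy[r.identifier]) for r in db.sequences])
    model = MultinomialNB(alpha=alpha)
    model.fit(X, y)
    # sklearn sorts classes_, and predict's argmax takes the first maximum,
    # which realises the lexicographically-smallest tie-break.
    return NBClassifier(k=k, alpha=alpha, vocabulary=vocabulary,
                        classes=list(model.classes_), model=model)


def classify(clf: NBClassifier, records) -> dict[str, Lineage]:
    """Maximum-posterior lineage per record (deterministic; posterior ties go
    to the lexicographically smallest class).  Records shorter than k carry an
    empty k-mer profile, fall back to the class priors, and are flagged with a
    warning."""
    records = list(records)
    if not records:
        return {}
    X = _kmer_matrix(records, clf.k, clf.vocabulary, grow=False)
    predictions = clf.model.predict(X)
    short = [r.identifier for r in records if len(r) < clf.k]
    if short:
        warnings.warn(
            f"{len(short)} record(s) shorter than k={clf.k} classified from "
            f"priors alone: {short[:5]}",
            stacklevel=2,
        )
    return {
        rec.identifier: Lineage.parse(pred)
        for rec, pred in zip(records, predictions)
    }


@dataclass
class RankMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        if self.tp + self.fp + self.fn == 0:
            return None
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float | None:
        if self.tp + self.fp + self.fn == 0:
            return None
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_measure(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0

    def to_json(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f_measure": self.f_measure}


def evaluate(predicted: dict[str, Lineage],
             expected: dict[str, Lineage]) -> dict[str, RankMetrics]:
    """Per-rank precision/recall/F of predictions against expectations.

    At each rank, only records with a non-missing expected label are scored:
    a matching prediction is a true positive; a present-but-wrong prediction
    counts as both a false positive and a false negative; a missing prediction
    is a false negative.  Metrics over zero scored records are ``None``.
    """
    if set(predicted) != set(expected):
        raise ValueError("predicted and expected identifier sets differ")
    metrics = {rank: RankMetrics() for rank in RANKS}
    for ident, exp in expected.items():
        pred = predicted[ident]
        for rank in RANKS:
            want = exp.label_at(rank)
            if want is None:
                continue
            got = pred.label_at(rank)
            m = metrics[rank]
            if got is None:
                m.fn += 1
            elif got == want:
                m.tp += 1
            else:
                m.fp += 1
                m.fn += 1
    return metrics


@dataclass
class CVConfig:
    K: int = 5
    seed: int = 0
    mode: str = "kfold"

    def __post_init__(self) -> None:
        if self.mode not in ("kfold", "leaked"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.mode == "kfold" and self.K < 2:
            raise ValueError("kfold requires K >= 2")


@dataclass
class CVResult:
    mode: str
    per_fold: list[dict[str, RankMetrics]]
    pooled: dict[str, RankMetrics]

    def to_json(self) -> dict:
        return {
            "mode": self.mode,
            "pooled": {r: m.to_json() for r, m in self.pooled.items()},
            "per_fold": [
                {r: m.to_json() for r, m in fold.items()}
                for fold in self.per_fold
            ],
        }


def _truncate_to_training(lineage: Lineage, training_labels) -> Lineage:
    """Truncate an expected lineage at the first rank whose label is absent
    from the fold's training set (deeper ranks become missing)."""
    depth = -1
    for i, rank in enumerate(RANKS):
        label = lineage.label_at(rank)
        if label is None or label not in training_labels[rank]:
            break
        depth = i
    return lineage.truncate(depth)


def _pool(folds) -> dict[str, RankMetrics]:
    pooled = {rank: RankMetrics() for rank in RANKS}
    for fold in folds:
        for rank, m in fold.items():
            pooled[rank].tp += m.tp
            pooled[rank].fp += m.fp
            pooled[rank].fn += m.fn
    return pooled


def cross_validate(db: ReferenceDatabase, cfg: CVConfig = CVConfig(),
                   k: int = 7, alpha: float = 0.001) -> CVResult:
    """Leaked or K-fold cross-validated classification accuracy."""
    if cfg.mode == "leaked":
        clf = fit_classifier(db, k=k, alpha=alpha)
        predicted = classify(clf, db.sequences)
        expected = {r.identifier: db.taxonomy[r.identifier] for r in db.sequences}
        fold = evaluate(predicted, expected)
        return CVResult("leaked", [fold], _pool([fold]))

    if cfg.K > len(db):
        raise ValueError(f"K={cfg.K} exceeds record count {len(db)}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(db))
    fold_assignments = np.array_split(order, cfg.K)

    folds = []
    for test_idx in fold_assignments:
        test_set = set(int(i) for i in test_idx)
        train_recs = [r for i, r in enumerate(db.sequences) if i not in test_set]
        test_recs = [r for i, r in enumerate(db.sequences) if i in test_set]
        train_db = ReferenceDatabase(
            train_recs,
            {r.identifier: db.taxonomy[r.identifier] for r in train_recs},
        )
        clf = fit_classifier(train_db, k=k, alpha=alpha)
        predicted = classify(clf, test_recs)
        training_labels = {
            rank: {
                lin.label_at(rank)
                for lin in train_db.taxonomy.values()
                if lin.label_at(rank) is not None
            }
            for rank in RANKS
        }
        expected = {
            r.identifier: _truncate_to_training(
                db.taxonomy[r.identifier], training_labels)
            for r in test_recs
        }
        folds.append(evaluate(predicted, expected))
    return CVResult("kfold", folds, _pool(folds))
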