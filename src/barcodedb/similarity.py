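"""Seeded pairwise nucleotide similarity search — the in-package blastn stand-in.

Subjects are indexed by exact k-mer words (default word size 11, ACGT words
only).  A query's candidate subjects are those sharing at least one word with
either query strand; each candidate is scored by affine-gap local alignment
(match +2, mismatch -3, gap open 5, gap extend 2 — megablast-style defaults),
and hits report percent identity (matches / alignment columns) and query
coverage (aligned query span / query length).  Subjects shorter than the word
size are always candidates, so tiny references behave sensibly.

Both curation filters (contaminant removal, mislabel detection) are built on
:func:`search`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import encode, local_align, revcomp
from .store import SequenceRecord

__all__ = [
    "AlignmentHit",
    "SearchIndex",
    "build_index",
    "search",
    "hits_to_outfmt6",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-subject local alignment result."""

    query_id: str
    subject_id: str
    identity_pct: float
    query_coverage_pct: float
    score: int
    strand: str = "+"
    aln_columns: int = 0


@dataclass
class SearchIndex:
    """k-mer postings over a subject set, plus encoded subject sequences."""

    k: int
    postings: dict[str, list[int]]
    subjects: list[SequenceRecord]
    short_subjects: list[int] = field(default_factory=list)
    _encoded: list = field(default_factory=list, repr=False)


def _kmers(seq: str, k: int):
    """Yield (position, word) for every ACGT-only window of length k."""
    acgt = frozenset("ACGT")
    for i in range(len(seq) - k + 1):
        word = seq[i:i + k]
        if set(word) <= acgt:
            yield i, word


def build_index(subjects, k: int = 11) -> SearchIndex:
    """Index ``subjects`` by their forward-strand k-mers.

    Words containing ambiguity codes are not indexed; subjects shorter than
    ``k`` are recorded for exhaustive fallback alignment.
    """
    if k < 4:
        raise ValueError(f"word size k={k} too small; need k >= 4")
    subjects = list(subjects)
    if not subjects:
        raise ValueError("cannot index an empty subject set")
    postings: dict[str, list[int]] = {}
    short: list[int] = []
    encoded = []
    for idx, rec in enumerate(subjects):
        encoded.append(encode(rec.sequence))
        if len(rec.sequence) < k:
            short.append(idx)
            continue
        seen_words = set()
        for _pos, word in _kmers(rec.sequence, k):
            if word not in seen_words:
                postings.setdefault(word, []).append(idx)
                seen_words.add(word)
    return SearchIndex(k=k, postings=postings, subjects=subjects,
                       short_subjects=short, _encoded=encoded)


def search(query: SequenceRecord, index: SearchIndex, max_hits: int = 5,
           min_identity_pct: float = 0.0,
           min_query_cov_pct: float = 0.0) -> list[AlignmentHit]:
    """Top local-alignment hits of ``query`` against the indexed subjects.

    Candidates are subjects sharing a seed word with the query on either
    strand (aligned on the strand(s) the seeds indicate); short subjects are
    aligned on both strands.  Hits below the identity/coverage floors are
    dropped, the rest sorted by descending score, then descending identity,
    then subject identifier, and truncated to ``max_hits``.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    if not index.subjects:
        raise ValueError("search against an empty index")

    qseq = query.sequence
    qrc = revcomp(qseq)
    plus: set[int] = set()
    minus: set[int] = set()
    for _pos, word in _kmers(qseq, index.k):
        plus.update(index.postings.get(word, ()))
    for _pos, word in _kmers(qrc, index.k):
        minus.update(index.postings.get(word, ()))
    for idx in index.short_subjects:
        plus.add(idx)
        minus.add(idx)

    q_enc = encode(qseq)
    qrc_enc = encode(qrc)
    qlen = len(qseq)
    hits: list[AlignmentHit] = []
    for idx in sorted(plus | minus):
        s_enc = index._encoded[idx]
        best = None
        strand = "+"
        if idx in plus:
            best = local_align(q_enc, s_enc)
        if idx in minus:
            res_m = local_align(qrc_enc, s_enc)
            if best is None or res_m.score > best.score:
                best = res_m
                strand = "-"
        if best is None or best.score <= 0:
            continue
        identity = best.identity_pct
        coverage = best.query_coverage_pct(qlen)
        if identity < min_identity_pct or coverage < min_query_cov_pct:
            continue
        hits.append(AlignmentHit(
            query_id=query.identifier,
            subject_id=index.subjects[idx].identifier,
            identity_pct=identity,
            query_coverage_pct=coverage,
            score=best.score,
            strand=strand,
            aln_columns=best.columns,
        ))
    hits.sort(key=lambda h: (-h.score, -h.identity_pct, h.subject_id))
    return hits[:max_hits]


def hits_to_outfmt6(hits) -> str:
    """Render hits in the BLAST outfmt-6 column spirit (subset of columns):
    qseqid, sseqid, pident, length, score, qcovs, strand."""
    lines = []
    for h in hits:
        lines.append(
            f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t"
            f"{h.aln_columns}\t{h.score}\t{h.query_coverage_pct:.2f}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
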