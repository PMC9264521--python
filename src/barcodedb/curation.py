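"""Database curation filters: quality culling, taxonomy-aware dereplication,
contaminant removal and mislabel (misidentification) removal.

All filters are monotone (output identifiers are a subset of the input),
preserve input record order, are idempotent, and append one provenance entry
recording parameters and the removed identifiers with reasons.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import groupby

from .similarity import build_index, search
from .store import ReferenceDatabase

__all__ = [
    "CullParams",
    "ContaminantParams",
    "MisidParams",
    "cull_sequences",
    "dereplicate",
    "filter_contaminants",
    "filter_misidentified",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CullParams:
    """Quality-cull thresholds.

    A record is discarded when it has ``max_degenerate`` or more degenerate
    (non-ACGT IUPAC) bases, or a homopolymer run of ``max_homopolymer`` or more
    identical A/C/G/T bases.
    """

    max_degenerate: int = 5
    max_homopolymer: int = 12

    def __post_init__(self) -> None:
        if self.max_degenerate < 1 or self.max_homopolymer < 1:
            raise ValueError("cull thresholds must be >= 1")


@dataclass(frozen=True)
class ContaminantParams:
    """Floors for calling a record a contaminant from its best hit."""

    min_identity_pct: float = 90.0
    min_query_cov_pct: float = 95.0

    def __post_init__(self) -> None:
        for v in (self.min_identity_pct, self.min_query_cov_pct):
            if not (0 < v <= 100):
                raise ValueError("contaminant floors must lie in (0, 100]")


@dataclass(frozen=True)
class MisidParams:
    """Mislabel-detection parameters: how many best self-hits to inspect and
    how often the record's own label at ``rank`` must appear among them."""

    n_best: int = 5
    rank: str = "family"
    min_rank_occurrences: int = 2

    def __post_init__(self) -> None:
        if self.n_best < 2:
            raise ValueError("n_best must be >= 2")


def count_degenerate(sequence: str) -> int:
    return sum(1 for c in sequence if c not in _ACGT)


def longest_homopolymer(sequence: str) -> int:
    """Longest run of a single A/C/G/T base (ambiguity runs do not count)."""
    best = 0
    for base, run in groupby(sequence):
        if base in _ACGT:
            best = max(best, sum(1 for _ in run))
    return best


def cull_sequences(db: ReferenceDatabase,
                   params: CullParams = CullParams()) -> ReferenceDatabase:
    """Remove low-quality records per :class:`CullParams`."""
    removed = []
    keep = []
    for rec in db.sequences:
        n_deg = count_degenerate(rec.sequence)
        run = longest_homopolymer(rec.sequence)
        if n_deg >= params.max_degenerate:
            removed.append({"identifier": rec.identifier, "reason": "degenerate",
                            "evidence": f"{n_deg} degenerate bases"})
        elif run >= params.max_homopolymer:
            removed.append({"identifier": rec.identifier, "reason": "homopolymer",
                            "evidence": f"run of {run}"})
        else:
            keep.append(rec.identifier)
    return db.subset(keep, "cull", {
        "max_degenerate": params.max_degenerate,
        "max_homopolymer": params.max_homopolymer,
        "removed": removed,
    })


def dereplicate(db: ReferenceDatabase, mode: str = "uniq") -> ReferenceDatabase:
    """Collapse byte-identical sequences, taxonomy-aware.

    ``uniq``
        keep one representative per distinct (sequence, lineage) pair — the
        record with the lexicographically smallest identifier — so identical
        sequences carrying different taxonomies are all conserved and the set
        of represented species is unchanged.
    ``majority``
        keep exactly one record per sequence group (smallest identifier),
        relabeled with the group's most frequent lineage (ties broken by the
        lexicographically smallest serialized lineage).  Majority relabeling
        can silently propagate mislabels for low-divergence markers and is
        emitted with a warning.
    """
    if mode not in ("uniq", "majority"):
        raise ValueError(f"unknown dereplication mode {mode!r}")
    if mode == "majority":
        warnings.warn(
            "majority-mode dereplication relabels identical sequences with the "
            "modal taxonomy; for low-divergence markers this can increase the "
            "proportion of mislabeled records",
            stacklevel=2,
        )

    groups: dict[str, list[str]] = {}
    for rec in db.sequences:
        groups.setdefault(rec.sequence, []).append(rec.identifier)

    keep: list[str] = []
    relabel = {}
    removed = []
    for seq, ids in groups.items():
        if mode == "uniq":
            by_lineage: dict[str, list[str]] = {}
            for ident in ids:
                by_lineage.setdefault(str(db.taxonomy[ident]), []).append(ident)
            kept_here = {min(members) for members in by_lineage.values()}
        else:
            rep = min(ids)
            kept_here = {rep}
            counts = Counter(str(db.taxonomy[i]) for i in ids)
            top = max(counts.values())
            modal = min(lin for lin, c in counts.items() if c == top)
            from .taxonomy import Lineage
            relabel[rep] = Lineage.parse(modal)
        keep.extend(kept_here)
        for ident in ids:
            if ident not in kept_here:
                removed.append({"identifier": ident, "reason": "replicate",
                                "evidence": f"kept {sorted(kept_here)}"})
    return db.subset(keep, "dereplicate",
                     {"mode": mode, "removed": removed}, relabel=relabel)


def filter_contaminants(db: ReferenceDatabase, contaminant_refs,
                        params: ContaminantParams = ContaminantParams(),
                        label: str = "contaminants") -> ReferenceDatabase:
    """Remove records similar enough to a contaminant reference set.

    A record is discarded when its best contaminant hit has identity >=
    ``min_identity_pct`` and query coverage >= ``min_query_cov_pct``.  Apply
    sequentially for multiple contaminant sets; ``label`` names the set in the
    provenance log.
    """
    refs = list(contaminant_refs)
    if not refs:
        raise ValueError("contaminant reference set is empty")
    index = build_index(refs)
    keep = []
    removed = []
    for rec in db.sequences:
        hits = search(rec, index, max_hits=1,
                      min_identity_pct=params.min_identity_pct,
                      min_query_cov_pct=params.min_query_cov_pct)
        if hits:
            h = hits[0]
            removed.append({
                "identifier": rec.identifier, "reason": "contaminant",
                "evidence": (f"{h.subject_id} identity={h.identity_pct:.1f} "
                             f"coverage={h.query_coverage_pct:.1f}"),
            })
        else:
            keep.append(rec.identifier)
    return db.subset(keep, f"filter-contaminants[{label}]", {
        "min_identity_pct": params.min_identity_pct,
        "min_query_cov_pct": params.min_query_cov_pct,
        "reference_set": label,
        "removed": removed,
    })


def filter_misidentified(db: ReferenceDatabase,
                         params: MisidParams = MisidParams(),
                         exempt_singleton_families: bool = False
                         ) -> ReferenceDatabase:
    """Remove records whose taxonomy is not corroborated by their neighbours.

    Each record is searched against the whole database (itself included); a
    record is discarded when its own label at ``params.rank`` appears fewer
    than ``min_rank_occurrences`` times among the ``n_best`` best hits — i.e.
    no hit besides the self-hit shares the label.  Records with a missing
    label at the rank are kept and reported.  With
    ``exempt_singleton_families`` the sole representative of a label is kept
    even when uncorroborated (collateral-loss protection).
    """
    if len(db) < 2:
        raise ValueError("mislabel filtering needs at least 2 records")
    index = build_index(db.sequences)
    rank = params.rank
    label_counts = Counter(
        lin.label_at(rank) for lin in db.taxonomy.values()
        if lin.label_at(rank) is not None
    )
    keep = []
    removed = []
    missing_rank = []
    for rec in db.sequences:
        own = db.taxonomy[rec.identifier].label_at(rank)
        if own is None:
            missing_rank.append(rec.identifier)
            keep.append(rec.identifier)
            continue
        hits = search(rec, index, max_hits=params.n_best)
        n_same = sum(
            1 for h in hits
            if db.taxonomy[h.subject_id].label_at(rank) == own
        )
        if n_same >= params.min_rank_occurrences:
            keep.append(rec.identifier)
        elif exempt_singleton_families and label_counts[own] == 1:
            keep.append(rec.identifier)
        else:
            removed.append({
                "identifier": rec.identifier, "reason": "misidentified",
                "evidence": (f"{rank}={own} seen {n_same}x in top "
                             f"{len(hits)} hits"),
            })
    return db.subset(keep, "filter-misidentified", {
        "n_best": params.n_best,
        "rank": rank,
        "min_rank_occurrences": params.min_rank_occurrences,
        "exempt_singleton_families": exempt_singleton_families,
        "missing_rank_label": missing_rank,
        "removed": removed,
    })
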