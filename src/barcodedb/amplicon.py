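"""Restrict reference sequences to the region a PCR primer pair amplifies.

Primer sites are located by an ungapped sliding alignment of each primer over
the template (indels at the primer site are not modeled); a site is valid when
the fraction of matching positions reaches ``min_primer_identity`` (default
0.8).  IUPAC codes on either side match whenever their base sets intersect.
Both template orientations are scanned; the extracted inter-primer region is
reported in the forward-primer orientation with the primers themselves
trimmed off, so extraction is symmetric under reverse complement of the
template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import encode, revcomp
from .store import ReferenceDatabase, SequenceRecord

__all__ = ["PrimerPair", "extract_amplicons"]


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both written 5'->3' as ordered for PCR."""

    forward: str
    reverse: str
    min_primer_identity: float = 0.8
    min_len: int | None = None
    max_len: int | None = None

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < 10:
                raise ValueError(f"{name} primer shorter than 10 nt")
            try:
                encode(primer.upper())
            except ValueError as exc:
                raise ValueError(f"{name} primer is not valid IUPAC: {exc}") from exc
        if not (0 < self.min_primer_identity <= 1):
            raise ValueError("min_primer_identity must lie in (0, 1]")
        if (self.min_len is not None and self.max_len is not None
                and self.min_len > self.max_len):
            raise ValueError("min_len exceeds max_len")


def _best_site(template: np.ndarray, primer: np.ndarray, start: int,
               threshold: float) -> tuple[int, float] | None:
    """Best ungapped primer placement at offset >= ``start``.

    Returns (offset, identity) of the highest-identity valid placement,
    leftmost on ties, or None when no placement reaches ``threshold``.
    Matching is IUPAC bit-set intersection on both sides.
    """
    plen = len(primer)
    tlen = len(template)
    if start + plen > tlen:
        return None
    window = np.lib.stride_tricks.sliding_window_view(template[start:], plen)
    matches = ((window & primer) != 0).sum(axis=1)
    identities = matches / plen
    best = int(np.argmax(identities))  # argmax returns the leftmost maximum
    ident = float(identities[best])
    if ident < threshold:
        return None
    return start + best, ident


def _extract_one(seq: str, fwd: np.ndarray, rev_rc: np.ndarray,
                 threshold: float) -> tuple[str, float] | None:
    """Extract the inter-primer region from one orientation of a template.

    Returns (amplicon, combined identity) or None if either site is missing.
    """
    template = encode(seq)
    fwd_site = _best_site(template, fwd, 0, threshold)
    if fwd_site is None:
        return None
    f_off, f_ident = fwd_site
    insert_start = f_off + len(fwd)
    rev_site = _best_site(template, rev_rc, insert_start, threshold)
    if rev_site is None:
        return None
    r_off, r_ident = rev_site
    return seq[insert_start:r_off], f_ident + r_ident


def extract_amplicons(db: ReferenceDatabase,
                      primers: PrimerPair) -> ReferenceDatabase:
    """Trim every record to its amplified region; drop records without one.

    Each record is scanned in both orientations; when both yield a valid
    primer pair the orientation with the higher combined primer identity wins
    (ties by the lexicographically smaller amplicon, so the choice does not
    depend on the strand the template was deposited on).  Records whose
    extracted region is empty or violates the length bounds are dropped.
    """
    fwd = encode(primers.forward.upper())
    rev_rc = encode(revcomp(primers.reverse.upper()))
    threshold = primers.min_primer_identity

    keep = []
    removed = []
    new_seqs = {}
    for rec in db.sequences:
        candidates = []
        for oriented in (rec.sequence, revcomp(rec.sequence)):
            result = _extract_one(oriented, fwd, rev_rc, threshold)
            if result is not None:
                candidates.append(result)
        if not candidates:
            removed.append({"identifier": rec.identifier,
                            "reason": "no-primer-match", "evidence": ""})
            continue
        candidates.sort(key=lambda c: (-c[1], c[0]))
        amplicon = candidates[0][0]
        if not amplicon:
            removed.append({"identifier": rec.identifier,
                            "reason": "empty-amplicon", "evidence": ""})
            continue
        if primers.min_len is not None and len(amplicon) < primers.min_len:
            removed.append({"identifier": rec.identifier, "reason": "too-short",
                            "evidence": f"{len(amplicon)} nt"})
            continue
        if primers.max_len is not None and len(amplicon) > primers.max_len:
            removed.append({"identifier": rec.identifier, "reason": "too-long",
                            "evidence": f"{len(amplicon)} nt"})
            continue
        keep.append(rec.identifier)
        new_seqs[rec.identifier] = amplicon

    out = db.subset(keep, "extract-amplicons", {
        "forward": primers.forward,
        "reverse": primers.reverse,
        "min_primer_identity": threshold,
        "min_len": primers.min_len,
        "max_len": primers.max_len,
        "removed": removed,
    })
    out.sequences = [
        SequenceRecord(r.identifier, new_seqs[r.identifier], r.description)
        for r in out.sequences
    ]
    return out
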