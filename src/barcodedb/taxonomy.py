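"""Accession-to-taxid and taxid-to-lineage resolution.

Reference entries arrive as bare sequence accessions; classifying against them
requires a seven-rank taxonomic lineage (kingdom, phylum, class, order, family,
genus, species) per entry.  This module maps accessions to NCBI taxids via the
``nucl_gb.accession2taxid`` table and taxids to lineages via the ``new_taxdump``
``rankedlineage.dmp`` file, and joins the two for a set of sequence records.

Lineages are serialized with Greengenes/QIIME-style rank prefixes
(``k__; p__; c__; o__; f__; g__; s__``) so the output taxonomy TSV can be
imported directly as a taxonomy artifact by downstream classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "Lineage",
    "TaxidMap",
    "LineageTable",
    "TaxonomyFormatError",
    "load_accession2taxid",
    "load_lineages",
    "resolve",
]

#: Rank attribute names in fixed kingdom-to-species order.
RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")

#: Serialization prefix for each rank, in the same order as :data:`RANKS`.
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

_A2T_HEADER = ("accession", "accession.version", "taxid", "gi")


class TaxonomyFormatError(ValueError):
    """Raised when a taxonomy input file does not match its expected dialect."""


@dataclass(frozen=True)
class Lineage:
    """A seven-rank taxonomic lineage; ``None`` marks a missing rank.

    The species label, when present, carries the genus as its first token
    (e.g. genus ``"Quercus"``, species ``"Quercus robur"``).
    """

    kingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def labels(self) -> tuple[str | None, ...]:
        """Rank labels in kingdom-to-species order."""
        return tuple(getattr(self, r) for r in RANKS)

    def label_at(self, rank: str) -> str | None:
        """Label at ``rank`` (one of :data:`RANKS`, ``class`` accepted)."""
        rank = "class_" if rank == "class" else rank
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, rank)

    def truncate(self, depth: int) -> "Lineage":
        """Copy with every rank deeper than index ``depth`` (0-based) missing."""
        kept = {r: getattr(self, r) for i, r in enumerate(RANKS) if i <= depth}
        return Lineage(**kept)

    def __str__(self) -> str:
        parts = [
            pref + (lab if lab is not None else "")
            for pref, lab in zip(RANK_PREFIXES, self.labels())
        ]
        return "; ".join(parts)

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        """Parse the ``k__...; p__...`` serialized form back into a lineage."""
        parts = [p.strip() for p in text.split(";")]
        if len(parts) != len(RANKS):
            raise TaxonomyFormatError(
                f"expected {len(RANKS)} rank fields, got {len(parts)}: {text!r}"
            )
        kwargs: dict[str, str | None] = {}
        for rank, prefix, part in zip(RANKS, RANK_PREFIXES, parts):
            if not part.startswith(prefix):
                raise TaxonomyFormatError(
                    f"rank field {part!r} lacks prefix {prefix!r}"
                )
            label = part[len(prefix):]
            kwargs[rank] = label if label else None
        return cls(**kwargs)


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix from an accession, if present."""
    head, dot, tail = accession.rpartition(".")
    if dot and tail.isdigit():
        return head
    return accession


@dataclass
class TaxidMap:
    """Accession -> taxid mapping; versioned and bare accessions both resolve."""

    entries: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    def get(self, accession: str) -> int | None:
        taxid = self.entries.get(accession)
        if taxid is None:
            taxid = self.entries.get(strip_version(accession))
        return taxid

    def __len__(self) -> int:
        # count distinct version-stripped accessions
        return len({strip_version(a) for a in self.entries})

    def __contains__(self, accession: str) -> bool:
        return self.get(accession) is not None


@dataclass
class LineageTable:
    """Taxid -> :class:`Lineage`, iterated in sorted-taxid order."""

    entries: dict[int, Lineage] = field(default_factory=dict)
    n_duplicates: int = 0

    def get(self, taxid: int) -> Lineage | None:
        return self.entries.get(taxid)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(sorted(self.entries))


def load_accession2taxid(path, restrict_to=None) -> TaxidMap:
    """Load a ``nucl_gb.accession2taxid``-dialect TSV.

    Parameters
    ----------
    path : str or path-like
        TSV with header ``accession  accession.version  taxid  gi``.
    restrict_to : collection of str, optional
        Keep only rows whose accession (either form) is in this collection;
        bounds memory when the table is large.

    Malformed rows are counted on the returned map's ``n_skipped``, not fatal.
    """
    wanted = None
    if restrict_to is not None:
        wanted = {strip_version(a) for a in restrict_to}
    taxid_map = TaxidMap()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _A2T_HEADER:
            raise TaxonomyFormatError(
                f"unexpected header {header!r}; expected columns {_A2T_HEADER}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                taxid_map.n_skipped += 1
                continue
            acc, acc_ver, taxid_s, _gi = cols
            try:
                taxid = int(taxid_s)
            except ValueError:
                taxid_map.n_skipped += 1
                continue
            if taxid <= 0 or not acc:
                taxid_map.n_skipped += 1
                continue
            if wanted is not None and strip_version(acc_ver or acc) not in wanted:
                continue
            taxid_map.entries[acc] = taxid
            if acc_ver:
                taxid_map.entries[acc_ver] = taxid
    return taxid_map


# rankedlineage.dmp column order after the taxid:
# tax_name, species, genus, family, order, class, phylum, kingdom, superkingdom
_RANKEDLINEAGE_NCOLS = 10


def load_lineages(rankedlineage_path) -> LineageTable:
    """Parse an NCBI ``rankedlineage.dmp`` file into a :class:`LineageTable`.

    The dmp dialect separates fields with ``\\t|\\t`` and terminates lines with
    ``\\t|``.  Empty fields become missing ranks.  When the species column is
    empty but the row's own name is a species-level binomial (first token equals
    the genus), the name fills the species slot.
    """
    table = LineageTable()
    with open(rankedlineage_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            if "\t|\t" not in line:
                raise TaxonomyFormatError(
                    f"line {lineno} is not '\\t|\\t'-delimited dmp format"
                )
            cols = line.split("\t|\t")
            if len(cols) != _RANKEDLINEAGE_NCOLS:
                raise TaxonomyFormatError(
                    f"line {lineno}: expected {_RANKEDLINEAGE_NCOLS} dmp fields,"
                    f" got {len(cols)}"
                )
            try:
                taxid = int(cols[0])
            except ValueError as exc:
                raise TaxonomyFormatError(f"line {lineno}: bad taxid {cols[0]!r}") from exc
            name, species, genus, family, order, class_, phylum, kingdom = (
                c.strip() or None for c in cols[1:9]
            )
            if species is None and genus is not None and name is not None:
                if name.split(" ", 1)[0] == genus and " " in name:
                    species = name
            if taxid in table.entries:
                table.n_duplicates += 1
            table.entries[taxid] = Lineage(
                kingdom=kingdom,
                phylum=phylum,
                class_=class_,
                order=order,
                family=family,
                genus=genus,
                species=species,
            )
    if table.n_duplicates:
        warnings.warn(
            f"{table.n_duplicates} duplicate taxid rows (last occurrence kept)",
            stacklevel=2,
        )
    return table


def resolve(records, taxid_map: TaxidMap, lineages: LineageTable, supplemental=None):
    """Attach (taxid, lineage) to each record; report unresolvable accessions.

    Parameters
    ----------
    records : iterable of SequenceRecord
    taxid_map : TaxidMap
    lineages : LineageTable
    supplemental : mapping accession -> Lineage, optional
        Offline fallback for accessions missing from ``taxid_map`` or whose
        taxid lacks a lineage (queried with and without version suffix).

    Returns
    -------
    resolved : dict identifier -> (taxid or None, Lineage)
    unresolved : list of identifiers, in input order

    The identifier sets of the two return values partition the input set.
    """
    supplemental = supplemental or {}
    resolved: dict[str, tuple[int | None, Lineage]] = {}
    unresolved: list[str] = []
    for rec in records:
        acc = rec.identifier
        taxid = taxid_map.get(acc)
        lineage = lineages.get(taxid) if taxid is not None else None
        if lineage is None:
            supp = supplemental.get(acc)
            if supp is None:
                supp = supplemental.get(strip_version(acc))
            if supp is not None:
                resolved[acc] = (taxid, supp)
                continue
            unresolved.append(acc)
            continue
        resolved[acc] = (taxid, lineage)
    return resolved, unresolved
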