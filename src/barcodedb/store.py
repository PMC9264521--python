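"""Sequence records, the reference-database container, and its file formats.

A reference database is a paired FASTA (sequences) + TSV (taxonomy, columns
``Feature ID`` / ``Taxon``) with equal identifier sets — the format taxonomy
classifiers import directly.  Every curation stage consumes and returns a
:class:`ReferenceDatabase` and appends one provenance entry, so the stage-by-
stage sequence/species count report can be rebuilt from the log alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .taxonomy import Lineage

__all__ = [
    "IUPAC_CODES",
    "SequenceRecord",
    "ProvenanceEntry",
    "ReferenceDatabase",
    "DatabaseFormatError",
    "read_fasta",
    "write_database",
    "read_database",
    "read_taxonomy_tsv",
    "assemble",
]

#: Allowed nucleotide characters (IUPAC, after U->T normalization).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

TAXONOMY_HEADER = ("Feature ID", "Taxon")


class DatabaseFormatError(ValueError):
    """Raised for malformed sequence or taxonomy inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    """One reference entry: identifier, uppercase IUPAC sequence, description."""

    identifier: str
    sequence: str
    description: str = ""

    def validate(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise DatabaseFormatError(
                f"invalid identifier {self.identifier!r} (empty or whitespace)"
            )
        if not self.sequence:
            raise DatabaseFormatError(f"record {self.identifier!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise DatabaseFormatError(
                f"record {self.identifier!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProvenanceEntry:
    """One pipeline stage: name, parameters, record counts in and out."""

    stage: str
    params: dict
    n_in: int
    n_out: int

    def to_json(self) -> dict:
        return {
            "stage": self.stage,
            "params": self.params,
            "records_in": self.n_in,
            "records_out": self.n_out,
        }


@dataclass
class ReferenceDatabase:
    """Ordered sequence records + identifier->lineage taxonomy + provenance."""

    sequences: list[SequenceRecord]
    taxonomy: dict[str, Lineage]
    provenance_log: list[ProvenanceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.identifier for r in self.sequences]
        if len(set(ids)) != len(ids):
            raise DatabaseFormatError("duplicate identifiers in database")
        if set(ids) != set(self.taxonomy):
            missing = set(ids) ^ set(self.taxonomy)
            raise DatabaseFormatError(
                f"sequence/taxonomy identifier mismatch: {sorted(missing)[:5]}..."
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def identifiers(self) -> list[str]:
        return [r.identifier for r in self.sequences]

    def lineage_of(self, identifier: str) -> Lineage:
        return self.taxonomy[identifier]

    def species_labels(self) -> set[str]:
        """Distinct non-missing species labels."""
        return {
            lin.species for lin in self.taxonomy.values() if lin.species is not None
        }

    @property
    def n_species(self) -> int:
        return len(self.species_labels())

    def subset(self, keep_ids, stage: str, params: dict,
               relabel: dict[str, Lineage] | None = None) -> "ReferenceDatabase":
        """New database keeping ``keep_ids`` (input order preserved), with one
        appended provenance entry; ``relabel`` overrides lineages by id."""
        keep = set(keep_ids)
        seqs = [r for r in self.sequences if r.identifier in keep]
        relabel = relabel or {}
        tax = {
            r.identifier: relabel.get(r.identifier, self.taxonomy[r.identifier])
            for r in seqs
        }
        log = list(self.provenance_log)
        log.append(ProvenanceEntry(stage, params, len(self.sequences), len(seqs)))
        return ReferenceDatabase(seqs, tax, log)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Lowercase is uppercased, U becomes T; gap characters and non-IUPAC symbols
    are rejected with the offending record named; duplicate identifiers and
    empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace("U", "T")
        if "-" in seq or "." in seq:
            raise DatabaseFormatError(
                f"record {entry.id!r}: gap characters are not allowed"
            )
        rec = SequenceRecord(
            identifier=entry.id,
            sequence=seq,
            description=entry.description[len(entry.id):].strip(),
        )
        rec.validate()
        if rec.identifier in seen:
            raise DatabaseFormatError(f"duplicate identifier {rec.identifier!r}")
        seen.add(rec.identifier)
        records.append(rec)
    if not records:
        raise DatabaseFormatError(f"no FASTA records found in {path}")
    return records


def write_database(db: ReferenceDatabase, out_dir) -> tuple[Path, Path]:
    """Write ``sequences.fasta`` (one unwrapped line per record) and
    ``taxonomy.tsv`` (``Feature ID<TAB>Taxon``) into ``out_dir``.

    Refuses to write an empty database.  Returns the two paths.
    """
    if len(db) == 0:
        raise DatabaseFormatError("refusing to write an empty reference database")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_path = out / "sequences.fasta"
    tsv_path = out / "taxonomy.tsv"
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for rec in db.sequences:
            header = rec.identifier
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n{rec.sequence}\n")
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TAXONOMY_HEADER) + "\n")
        for rec in db.sequences:
            fh.write(f"{rec.identifier}\t{db.taxonomy[rec.identifier]}\n")
    return fasta_path, tsv_path


def read_taxonomy_tsv(path) -> dict[str, Lineage]:
    """Read a ``Feature ID<TAB>Taxon`` TSV into an identifier->lineage map."""
    taxonomy: dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TAXONOMY_HEADER:
            raise DatabaseFormatError(
                f"unexpected taxonomy header {header!r}; expected {TAXONOMY_HEADER}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                identifier, taxon = line.split("\t")
            except ValueError as exc:
                raise DatabaseFormatError(f"bad taxonomy row {line!r}") from exc
            if identifier in taxonomy:
                raise DatabaseFormatError(f"duplicate identifier {identifier!r}")
            taxonomy[identifier] = Lineage.parse(taxon)
    if not taxonomy:
        raise DatabaseFormatError(f"no taxonomy rows found in {path}")
    return taxonomy


def read_database(fasta_path, taxonomy_path) -> ReferenceDatabase:
    """Read a FASTA + taxonomy TSV pair back into a :class:`ReferenceDatabase`."""
    records = read_fasta(fasta_path)
    taxonomy = read_taxonomy_tsv(taxonomy_path)
    return ReferenceDatabase(records, taxonomy)


def assemble(records, resolved) -> ReferenceDatabase:
    """Join sequence records with their resolved lineages (the global table).

    ``resolved`` maps identifier -> (taxid, Lineage) as returned by
    :func:`barcodedb.taxonomy.resolve`.  Records without a resolved lineage are
    dropped; the count is noted in the seeded provenance entry.
    """
    records = list(records)
    ids = [r.identifier for r in records]
    if len(set(ids)) != len(ids):
        raise DatabaseFormatError("duplicate accession across assembled inputs")
    kept = [r for r in records if r.identifier in resolved]
    if not kept:
        raise DatabaseFormatError("no records could be resolved; empty database")
    taxonomy = {r.identifier: resolved[r.identifier][1] for r in kept}
    log = [
        ProvenanceEntry(
            "assemble",
            {"dropped_unresolved": len(records) - len(kept)},
            len(records),
            len(kept),
        )
    ]
    return ReferenceDatabase(kept, taxonomy, log)


def write_provenance(db: ReferenceDatabase, path, tool_version: str = "") -> None:
    """Dump the provenance log (plus species counts) as JSON."""
    payload = {
        "tool_version": tool_version,
        "stages": [e.to_json() for e in db.provenance_log],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
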