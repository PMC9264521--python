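"""Self-contained synthetic inputs for every pipeline stage.

The generator emulates the structure the curation filters assume: sequence
families descended from per-family ancestors (substitution-only mutation, so
identity arithmetic stays exact), coherent synthetic seven-rank lineages (one
genus per family), planted mislabels, planted contaminants, exact duplicates,
degenerate-base / homopolymer targets for the quality cull, and primer-flanked
amplicon templates — together with matching accession2taxid and rankedlineage
files and a truth manifest naming every planted artefact.

All label strings are synthetic (``f__Fam03`` style); nothing implies real
taxa.  Every output is a pure function of ``FixtureSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._align import revcomp
from .amplicon import PrimerPair
from .store import (ProvenanceEntry, ReferenceDatabase, SequenceRecord,
                    write_database)
from .taxonomy import Lineage, strip_version

__all__ = ["FixtureSpec", "TruthManifest", "FixtureBundle", "generate", "PRESETS"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic database.

    Divergences are per-site substitution probabilities: each family ancestor
    mutates away from a common root at ``inter_family_divergence``, each record
    from its family ancestor at ``intra_family_divergence``.
    """

    n_families: int = 20
    seqs_per_family: int = 8
    ancestor_length: int = 300
    intra_family_divergence: float = 0.02
    inter_family_divergence: float = 0.30
    n_mislabeled: int = 0
    n_contaminants: int = 0
    n_exact_contaminants: int = 0
    n_duplicates: int = 0
    species_per_family: int | None = None  # None: one species per record
    primer_pair: PrimerPair | None = None
    primer_site_mismatches: tuple[int, int] = (0, 0)
    degenerate_injection: tuple[int, int] | None = None  # (N count, run length)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_family_divergence <= self.intra_family_divergence:
            raise ValueError(
                "inter-family divergence must exceed intra-family divergence"
            )
        for name in ("n_families", "seqs_per_family", "ancestor_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_mislabeled", "n_contaminants", "n_exact_contaminants",
                     "n_duplicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = self.n_families * self.seqs_per_family
        if self.n_mislabeled > total:
            raise ValueError("more mislabels requested than records")


@dataclass
class TruthManifest:
    """What was planted where: the key for recovery tests."""

    mislabeled: list[dict] = field(default_factory=list)
    contaminant_copies: list[dict] = field(default_factory=list)
    duplicates: list[dict] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)
    homopolymer: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "mislabeled": self.mislabeled,
            "contaminant_copies": self.contaminant_copies,
            "duplicates": self.duplicates,
            "degenerate": self.degenerate,
            "homopolymer": self.homopolymer,
        }


@dataclass
class FixtureBundle:
    """In-memory fixture plus writers for the on-disk input formats."""

    database: ReferenceDatabase
    accession2taxid_tsv: str
    rankedlineage_dmp: str
    contaminants: list[SequenceRecord]
    truth: TruthManifest

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        fasta, tsv = write_database(self.database, out)
        paths["sequences"] = fasta
        paths["taxonomy"] = tsv
        paths["accession2taxid"] = out / "accession2taxid.tsv"
        paths["accession2taxid"].write_text(self.accession2taxid_tsv)
        paths["rankedlineage"] = out / "rankedlineage.dmp"
        paths["rankedlineage"].write_text(self.rankedlineage_dmp)
        if self.contaminants:
            paths["contaminants"] = out / "contaminants.fasta"
            with open(paths["contaminants"], "w") as fh:
                for rec in self.contaminants:
                    fh.write(f">{rec.identifier}\n{rec.sequence}\n")
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(
            json.dumps(self.truth.to_json(), indent=2) + "\n")
        return paths


def _mutate(rng: np.random.Generator, seq: np.ndarray,
            rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` (always to a new base)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def _lineage_for(family: int, species: int) -> Lineage:
    genus = f"Gen{family:02d}"
    return Lineage(
        kingdom="Synthviridae",
        phylum="Synthophyta",
        class_="Synthopsida",
        order=f"Ord{family:02d}",
        family=f"Fam{family:02d}",
        genus=genus,
        species=f"{genus} sp{species:03d}",
    )


def _concrete(rng: np.random.Generator, primer: str) -> str:
    """Instantiate a concrete ACGT site from an IUPAC primer."""
    from ._align import _CODE
    site = []
    for c in primer.upper():
        bases = [b for b in "ACGT" if _CODE[b] & _CODE[c]]
        site.append(bases[rng.integers(len(bases))])
    return "".join(site)


def _mismatch_site(rng: np.random.Generator, primer: str, site: str,
                   n_mismatches: int) -> str:
    """Substitute ``n_mismatches`` positions of a primer site to bases outside
    the primer's IUPAC set at that position."""
    from ._align import _CODE
    site_l = list(site)
    positions = rng.choice(len(site_l), size=n_mismatches, replace=False)
    for p in positions:
        outside = [b for b in "ACGT" if not (_CODE[b] & _CODE[primer[p].upper()])]
        if not outside:  # N-position: every base matches, cannot force mismatch
            continue
        site_l[p] = outside[rng.integers(len(outside))]
    return "".join(site_l)


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a complete fixture bundle from ``spec`` (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    truth = TruthManifest()

    root = rng.choice(_BASES, size=spec.ancestor_length)
    species_per_family = spec.species_per_family or spec.seqs_per_family

    records: list[SequenceRecord] = []
    taxonomy: dict[str, Lineage] = {}
    counter = 0
    for fam in range(spec.n_families):
        ancestor = _mutate(rng, root, spec.inter_family_divergence)
        for j in range(spec.seqs_per_family):
            counter += 1
            acc = f"SYN{counter:05d}.1"
            seq = "".join(_mutate(rng, ancestor, spec.intra_family_divergence))
            records.append(SequenceRecord(acc, seq))
            taxonomy[acc] = _lineage_for(fam, j % species_per_family)

    # plant mislabels: swap a record's lineage to another family's.  No two
    # records of one true family are planted into the same family, so planted
    # errors cannot corroborate each other and each one stays recoverable.
    if spec.n_mislabeled:
        all_ids = [r.identifier for r in records]
        chosen = rng.choice(len(all_ids), size=spec.n_mislabeled, replace=False)
        used_pairs: set[tuple[str, int]] = set()
        for idx in sorted(int(i) for i in chosen):
            ident = all_ids[idx]
            true_fam = taxonomy[ident].family
            true_fam_idx = int(true_fam.removeprefix("Fam"))
            candidates = [f for f in range(spec.n_families)
                          if f != true_fam_idx
                          and (true_fam, f) not in used_pairs]
            if not candidates:
                candidates = [f for f in range(spec.n_families)
                              if f != true_fam_idx]
            other = candidates[int(rng.integers(len(candidates)))]
            used_pairs.add((true_fam, other))
            planted = _lineage_for(other, int(rng.integers(species_per_family)))
            taxonomy[ident] = planted
            truth.mislabeled.append({
                "identifier": ident,
                "true_family": true_fam,
                "planted_family": planted.family,
            })

    mislabeled_ids = {m["identifier"] for m in truth.mislabeled}
    clean_ids = [r.identifier for r in records
                 if r.identifier not in mislabeled_ids]

    # exact duplicates (same sequence + lineage, fresh accession)
    for d in range(spec.n_duplicates):
        src = clean_ids[int(rng.integers(len(clean_ids)))]
        source = next(r for r in records if r.identifier == src)
        counter += 1
        acc = f"SYN{counter:05d}.1"
        records.append(SequenceRecord(acc, source.sequence))
        taxonomy[acc] = taxonomy[src]
        truth.duplicates.append({"identifier": acc, "copy_of": src})

    # degenerate / homopolymer cull targets injected into clean records
    if spec.degenerate_injection is not None:
        n_deg, run_len = spec.degenerate_injection
        picks = rng.choice(len(clean_ids), size=2, replace=False)
        deg_id, run_id = clean_ids[int(picks[0])], clean_ids[int(picks[1])]
        for i, rec in enumerate(records):
            if rec.identifier == deg_id and n_deg > 0:
                pos = rng.choice(len(rec.sequence), size=n_deg, replace=False)
                s = list(rec.sequence)
                for p in pos:
                    s[p] = "N"
                records[i] = SequenceRecord(rec.identifier, "".join(s))
                truth.degenerate.append(rec.identifier)
            elif rec.identifier == run_id and run_len > 0:
                s = rec.sequence
                start = int(rng.integers(max(len(s) - run_len, 1)))
                s = s[:start] + "A" * run_len + s[start + run_len:]
                records[i] = SequenceRecord(rec.identifier, s)
                truth.homopolymer.append(rec.identifier)

    # contaminants: GC-skewed random sequences, plus exact copies of records
    contaminants: list[SequenceRecord] = []
    for c in range(spec.n_contaminants):
        seq = "".join(rng.choice(_BASES, size=spec.ancestor_length,
                                 p=[0.1, 0.4, 0.4, 0.1]))
        contaminants.append(SequenceRecord(f"CONT{c:03d}", seq))
    for c in range(spec.n_exact_contaminants):
        src = clean_ids[int(rng.integers(len(clean_ids)))]
        source = next(r for r in records if r.identifier == src)
        contaminants.append(
            SequenceRecord(f"CONTCOPY{c:03d}", source.sequence))
        truth.contaminant_copies.append(
            {"contaminant": f"CONTCOPY{c:03d}", "copy_of": src})

    # wrap records as primerF + core + revcomp(primerR)
    if spec.primer_pair is not None:
        fwd_mm, rev_mm = spec.primer_site_mismatches
        wrapped = []
        for rec in records:
            fsite = _mismatch_site(
                rng, spec.primer_pair.forward,
                _concrete(rng, spec.primer_pair.forward), fwd_mm)
            rsite = _mismatch_site(
                rng, spec.primer_pair.reverse,
                _concrete(rng, spec.primer_pair.reverse), rev_mm)
            wrapped.append(SequenceRecord(
                rec.identifier, fsite + rec.sequence + revcomp(rsite)))
        records = wrapped
        if spec.n_exact_contaminants:
            # keep exact-copy contaminants identical to the wrapped records
            by_id = {r.identifier: r for r in records}
            copy_of = {m["contaminant"]: m["copy_of"]
                       for m in truth.contaminant_copies}
            contaminants = [
                SequenceRecord(c.identifier, by_id[copy_of[c.identifier]].sequence)
                if c.identifier in copy_of else c
                for c in contaminants
            ]

    # matching taxonomy source files
    species_taxids: dict[str, int] = {}
    for lin in taxonomy.values():
        species_taxids.setdefault(lin.species, 1000 + len(species_taxids))
    a2t_lines = ["accession\taccession.version\ttaxid\tgi"]
    for rec in records:
        acc_ver = rec.identifier
        taxid = species_taxids[taxonomy[acc_ver].species]
        a2t_lines.append(f"{strip_version(acc_ver)}\t{acc_ver}\t{taxid}\t0")
    dmp_lines = []
    lineage_by_species = {lin.species: lin for lin in taxonomy.values()}
    for species, taxid in sorted(species_taxids.items(), key=lambda kv: kv[1]):
        lin = lineage_by_species[species]
        fields_ = [str(taxid), lin.species, lin.species, lin.genus, lin.family,
                   lin.order, lin.class_, lin.phylum, lin.kingdom, ""]
        dmp_lines.append("\t|\t".join(fields_) + "\t|")

    db = ReferenceDatabase(
        records, dict(taxonomy),
        [ProvenanceEntry("generate", {"seed": spec.seed}, len(records),
                         len(records))],
    )
    return FixtureBundle(
        database=db,
        accession2taxid_tsv="\n".join(a2t_lines) + "\n",
        rankedlineage_dmp="\n".join(dmp_lines) + "\n",
        contaminants=contaminants,
        truth=truth,
    )


#: Named presets for the ``fixtures`` CLI subcommand.
PRESETS: dict[str, FixtureSpec] = {
    "clean": FixtureSpec(n_families=6, seqs_per_family=5, seed=1),
    "mislabeled": FixtureSpec(n_families=20, seqs_per_family=8,
                              n_mislabeled=10, seed=1),
    "contaminated": FixtureSpec(n_families=6, seqs_per_family=5,
                                n_contaminants=5, n_exact_contaminants=2,
                                seed=1),
    "amplicon": FixtureSpec(
        n_families=6, seqs_per_family=5,
        primer_pair=PrimerPair("ACGGATCGTAGCTAGCCTAG", "TGCCAGTTGGAACCTTGCAC"),
        seed=1),
    "cull": FixtureSpec(n_families=6, seqs_per_family=5,
                        degenerate_injection=(6, 14), seed=1),
    "mixed": FixtureSpec(
        n_families=10, seqs_per_family=8, n_mislabeled=4,
        n_contaminants=5, n_exact_contaminants=1, n_duplicates=2,
        degenerate_injection=(6, 14),
        primer_pair=PrimerPair("ACGGATCGTAGCTAGCCTAG", "TGCCAGTTGGAACCTTGCAC"),
        seed=1),
}


def preset(name: str, seed: int | None = None) -> FixtureSpec:
    """Look up a preset, optionally reseeded."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec
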