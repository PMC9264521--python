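"""End-to-end pipeline: resolve -> assemble -> cull -> [dereplicate] ->
decontaminate -> mislabel filter -> [amplicon extraction].

Stage order is fixed; dereplication and amplicon restriction are the two
optional stages.  Every stage writes its FASTA/TSV pair under
``out_dir/stages/<NN-stage>/`` so reported counts can be recounted
independently, and the run emits a machine-readable provenance JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .amplicon import PrimerPair, extract_amplicons
from .curation import (ContaminantParams, CullParams, MisidParams,
                       cull_sequences, dereplicate, filter_contaminants,
                       filter_misidentified)
from .store import (ReferenceDatabase, assemble, read_fasta, write_database,
                    write_provenance)
from .taxonomy import (Lineage, load_accession2taxid, load_lineages, resolve)

__all__ = ["PipelineConfig", "StageCount", "run_pipeline", "load_config"]


@dataclass
class StageCount:
    """One row of the stage report: counts after the stage ran."""

    stage: str
    n_sequences: int
    n_species: int

    def to_json(self) -> dict:
        return {"stage": self.stage, "sequences": self.n_sequences,
                "species": self.n_species}


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (flat; see ``load_config``)."""

    sequences: Path
    accession2taxid: Path
    rankedlineage: Path
    out_dir: Path
    supplemental_taxonomy: Path | None = None
    cull: CullParams = field(default_factory=CullParams)
    derep_mode: str = "skip"  # uniq | majority | skip
    contaminant_refs: list[Path] = field(default_factory=list)
    contaminant_params: ContaminantParams = field(
        default_factory=ContaminantParams)
    misid: MisidParams = field(default_factory=MisidParams)
    exempt_singleton_families: bool = False
    primers: PrimerPair | None = None  # None: skip extraction
    write_stage_outputs: bool = True

    def validate(self) -> None:
        for path in [self.sequences, self.accession2taxid, self.rankedlineage,
                     self.supplemental_taxonomy, *self.contaminant_refs]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input missing: {path}")
        if self.derep_mode not in ("uniq", "majority", "skip"):
            raise ValueError(f"derep_mode must be uniq|majority|skip, "
                             f"got {self.derep_mode!r}")


def load_config(path) -> PipelineConfig:
    """Read a flat YAML config file into a :class:`PipelineConfig`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    primers = None
    if raw.get("primers"):
        primers = PrimerPair(**raw["primers"])
    return PipelineConfig(
        sequences=Path(raw["sequences"]),
        accession2taxid=Path(raw["accession2taxid"]),
        rankedlineage=Path(raw["rankedlineage"]),
        out_dir=Path(raw["out_dir"]),
        supplemental_taxonomy=(Path(raw["supplemental_taxonomy"])
                               if raw.get("supplemental_taxonomy") else None),
        cull=CullParams(**raw.get("cull", {})),
        derep_mode=raw.get("derep_mode", "skip"),
        contaminant_refs=[Path(p) for p in raw.get("contaminant_refs", [])],
        contaminant_params=ContaminantParams(**raw.get("contaminant_params", {})),
        misid=MisidParams(**raw.get("misid", {})),
        exempt_singleton_families=raw.get("exempt_singleton_families", False),
        primers=primers,
        write_stage_outputs=raw.get("write_stage_outputs", True),
    )


def _read_supplemental(path) -> dict[str, Lineage]:
    from .store import read_taxonomy_tsv
    return read_taxonomy_tsv(path)


def run_pipeline(config: PipelineConfig):
    """Run the full pipeline; returns (final database, stage report).

    A stage failure aborts the run but the report rows accumulated so far are
    written to ``out_dir/stage_report.json`` before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: list[StageCount] = []
    stage_no = 0

    def checkpoint(db: ReferenceDatabase, stage: str) -> None:
        nonlocal stage_no
        stage_no += 1
        report.append(StageCount(stage, len(db), db.n_species))
        if config.write_stage_outputs:
            write_database(db, out / "stages" / f"{stage_no:02d}-{stage}")

    def flush_report() -> None:
        with open(out / "stage_report.json", "w", encoding="utf-8") as fh:
            json.dump([r.to_json() for r in report], fh, indent=2)
            fh.write("\n")

    try:
        records = read_fasta(config.sequences)
        taxid_map = load_accession2taxid(
            config.accession2taxid,
            restrict_to=[r.identifier for r in records])
        lineages = load_lineages(config.rankedlineage)
        supplemental = (_read_supplemental(config.supplemental_taxonomy)
                        if config.supplemental_taxonomy else None)
        resolved, unresolved = resolve(records, taxid_map, lineages,
                                       supplemental=supplemental)
        stage_no += 1
        report.append(StageCount(
            "resolve", len(resolved),
            len({lin.species for _t, lin in resolved.values()
                 if lin.species is not None})))

        db = assemble(records, resolved)
        checkpoint(db, "assemble")

        db = cull_sequences(db, config.cull)
        checkpoint(db, "cull")

        if config.derep_mode != "skip":
            db = dereplicate(db, mode=config.derep_mode)
            checkpoint(db, "dereplicate")

        if config.contaminant_refs:
            for ref_path in config.contaminant_refs:
                refs = read_fasta(ref_path)
                db = filter_contaminants(db, refs, config.contaminant_params,
                                         label=Path(ref_path).name)
            checkpoint(db, "decontaminate")

        db = filter_misidentified(
            db, config.misid,
            exempt_singleton_families=config.exempt_singleton_families)
        checkpoint(db, "filter-misidentified")

        if config.primers is not None:
            db = extract_amplicons(db, config.primers)
            checkpoint(db, "extract-amplicons")
    finally:
        flush_report()

    write_database(db, out)
    write_provenance(db, out / "provenance.json", tool_version=__version__)
    return db, report
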