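"""End-to-end pipeline orchestration from a single structured config.

Stages (dependency order): simulate -> classify -> phylo -> primers ->
inventory.  Each stage reads the previous stage's artifacts from the
output directory, writes TSV/JSON/newick/FASTA artifacts of its own, and
the run ends with a manifest (config hash, seeds, package version) that
suffices to re-run any stage in isolation.  Identical config plus seeds
give byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, nirk_features, phylogeny, primer_analysis, sequence_io
from .nirk_features import DEFAULT_INDEL_REGIONS, IndelRegion
from .pathway_inventory import (
    pairwise_gene_screen,
    read_inventory_tsv,
    summarize_cohort,
    write_inventory_tsv,
)
from .primer_analysis import Primer
from .reference_mapping import ReferenceSequence, Scoring, map_to_reference, stack_alignment
from .sequence_io import SequenceRecord, read_fasta, write_fasta, write_metadata
from .synthetic_data import (
    SequenceGenConfig,
    backtranslate,
    generate_inventory,
    generate_nirk_set,
    plant_primer_sites,
    surrogate_reference,
)

log = logging.getLogger("nirktools")

ALL_STAGES = ("simulate", "classify", "phylo", "primers", "inventory")


@dataclass
class PipelineConfig:
    """Validated run configuration; every seed is explicit."""

    outdir: Path
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    reference: str = "bundled"  # or a FASTA path
    fasta: str | None = None
    metadata: str | None = None
    inventory_tsv: str | None = None
    indel_regions: tuple[IndelRegion, ...] = DEFAULT_INDEL_REGIONS
    phylo: dict = field(default_factory=lambda: {
        "method": "count_differences",
        "deletion_policy": "complete",
        "replicates": 1000,
    })
    primers: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        if raw.get("fasta") and raw.get("synthetic"):
            raise ValueError("config must use real inputs or a synthetic block, not both")
        regions = tuple(
            IndelRegion(**r) for r in raw.get("indel_regions", [])
        ) or DEFAULT_INDEL_REGIONS
        cfg = cls(
            outdir=Path(raw.get("outdir", "nirktools_out")),
            seed=int(raw.get("seed", 0)),
            synthetic=dict(raw.get("synthetic") or {}),
            reference=raw.get("reference", "bundled"),
            fasta=raw.get("fasta"),
            metadata=raw.get("metadata"),
            inventory_tsv=raw.get("inventory_tsv"),
            indel_regions=regions,
            phylo={**{"method": "count_differences", "deletion_policy": "complete",
                      "replicates": 1000}, **(raw.get("phylo") or {})},
            primers=dict(raw.get("primers") or {}),
            raw=dict(raw),
        )
        return cfg

    def load_reference(self) -> ReferenceSequence:
        if self.reference == "bundled":
            return surrogate_reference()
        recs = read_fasta(self.reference, alphabet="protein")
        return ReferenceSequence(record=recs[0], canonical_length=len(recs[0]))

    def portable_raw(self) -> dict:
        """Config dict without the output path, so bundles are relocatable."""
        return {k: v for k, v in self.raw.items() if k != "outdir"}

    def config_hash(self) -> str:
        blob = json.dumps(self.portable_raw(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_log(stage: str, msg: str) -> None:
    log.info("[%s] %s", stage, msg)


def run_simulate(cfg: PipelineConfig) -> None:
    out = cfg.outdir
    gen_kwargs = dict(cfg.synthetic)
    gen_kwargs.setdefault("seed", cfg.seed)
    primer_blocks = cfg.primers.get("sets", [])
    plant_spec = gen_kwargs.pop("primer_mismatch_spec", None)
    gcfg = SequenceGenConfig(indel_regions=cfg.indel_regions, **gen_kwargs)
    records, truth, ref = generate_nirk_set(gcfg)
    write_fasta(records, out / "synthetic_protein.fasta")
    write_metadata(records, out / "synthetic_metadata.tsv")
    truth.to_csv(out / "synthetic_truth.tsv", sep="\t", index=False)
    write_fasta([ref.record], out / "reference.fasta")
    nt = backtranslate(records, seed=gcfg.seed + 1)
    if primer_blocks and plant_spec:
        clade_of = dict(zip(truth["id"], truth["clade"]))
        primer = Primer(**primer_blocks[0])
        nt, planted = plant_primer_sites(
            nt, primer, plant_spec, clade_of, seed=gcfg.seed + 2
        )
        planted.to_csv(out / "synthetic_primer_truth.tsv", sep="\t", index=False)
    write_fasta(nt, out / "synthetic_nucleotide.fasta")
    inv, inv_truth = generate_inventory(seed=gcfg.seed + 3)
    write_inventory_tsv(inv, out / "synthetic_inventory.tsv")
    _stage_log("simulate", f"wrote {len(records)} sequences and {len(inv)} genome inventories")


def _load_proteins(cfg: PipelineConfig) -> list[SequenceRecord]:
    if cfg.fasta:
        return read_fasta(cfg.fasta, "protein", metadata=cfg.metadata)
    return read_fasta(
        cfg.outdir / "synthetic_protein.fasta",
        "protein",
        metadata=cfg.outdir / "synthetic_metadata.tsv",
    )


def run_classify(cfg: PipelineConfig) -> None:
    out = cfg.outdir
    ref = cfg.load_reference()
    records = _load_proteins(cfg)
    records, removal_log = nirk_features.filter_redundant(records)
    profiles = []
    for rec in records:
        rmap = map_to_reference(rec, ref)
        profiles.append(
            nirk_features.build_profile(rec, rmap, regions=cfg.indel_regions)
        )
    frame = nirk_features.profiles_to_frame(profiles)
    accepted = frame[frame.is_nirk]
    rejected = frame[~frame.is_nirk]
    frame.to_csv(out / "profiles.tsv", sep="\t", index=False)
    rejected.to_csv(out / "rejects.tsv", sep="\t", index=False)
    pd.DataFrame(removal_log).to_csv(out / "redundancy_removed.tsv", sep="\t", index=False)
    with open(out / "profiles.json", "w") as fh:
        json.dump(frame.to_dict(orient="records"), fh, indent=1)
    _stage_log(
        "classify",
        f"{len(accepted)} validated NirK, {len(rejected)} rejected, "
        f"{len(removal_log)} redundant strains removed",
    )


def run_phylo(cfg: PipelineConfig) -> None:
    out = cfg.outdir
    ref = cfg.load_reference()
    records = _load_proteins(cfg)
    maps = [map_to_reference(rec, ref) for rec in records]
    aln = stack_alignment(records, maps, trim_to_reference=True)
    dm = phylogeny.distance_matrix(
        aln, cfg.phylo["method"], cfg.phylo["deletion_policy"]
    )
    phylogeny.write_distance_tsv(dm, out / "distances.tsv")
    tree = phylogeny.bootstrap_support(
        aln,
        cfg.phylo["method"],
        cfg.phylo["deletion_policy"],
        replicates=int(cfg.phylo["replicates"]),
        seed=cfg.seed,
    )
    (out / "tree.nwk").write_text(phylogeny.to_newick(tree) + "\n")
    _stage_log("phylo", f"NJ tree over {len(dm)} sequences written")


def run_primers(cfg: PipelineConfig) -> None:
    out = cfg.outdir
    sets = cfg.primers.get("sets", [])
    if not sets:
        _stage_log("primers", "no primer sets configured; skipping")
        return
    nt = read_fasta(out / "synthetic_nucleotide.fasta", "nucleotide") if not cfg.fasta else read_fasta(cfg.fasta, "nucleotide")
    profiles_path = out / "profiles.tsv"
    group_of: dict[str, str] = {}
    if profiles_path.exists():
        prof = pd.read_csv(profiles_path, sep="\t")
        group_of = dict(zip(prof["id"], prof["clade"]))
    for block in sets:
        primer = Primer(**block)
        profile = primer_analysis.mismatch_profile(primer, nt, group_of)
        profile.to_csv(out / f"mismatch_profile_{primer.name}.tsv", sep="\t")
        logo = primer_analysis.binding_region_logo(nt, primer)
        logo.frequencies.assign(IC_bits=logo.information_content).to_csv(
            out / f"logo_{primer.name}.tsv", sep="\t"
        )
    _stage_log("primers", f"evaluated {len(sets)} primer(s) on {len(nt)} sequences")


def run_inventory(cfg: PipelineConfig) -> None:
    out = cfg.outdir
    path = cfg.inventory_tsv or out / "synthetic_inventory.tsv"
    table = read_inventory_tsv(path)
    summary = summarize_cohort(table)
    summary.to_csv(out / "pathway_summary.tsv", sep="\t")
    screen = pairwise_gene_screen(table)
    screen.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
    _stage_log("inventory", f"classified {len(table)} genomes")


_RUNNERS = {
    "simulate": run_simulate,
    "classify": run_classify,
    "phylo": run_phylo,
    "primers": run_primers,
    "inventory": run_inventory,
}

_DEPENDENCIES = {
    "classify": ["synthetic_protein.fasta"],
    "phylo": ["synthetic_protein.fasta"],
    "primers": ["synthetic_nucleotide.fasta"],
    "inventory": ["synthetic_inventory.tsv"],
}


def run(cfg: PipelineConfig, stages: Sequence[str] = ALL_STAGES) -> int:
    """Run the requested stages in dependency order; 0 on success."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in ALL_STAGES if s in stages]
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    for stage in ordered:
        if stage != "simulate" and not cfg.fasta and not cfg.inventory_tsv:
            missing = [
                f
                for f in _DEPENDENCIES.get(stage, [])
                if not (cfg.outdir / f).exists()
            ]
            if missing and "simulate" not in ordered[: ordered.index(stage)]:
                log.error("[%s] missing upstream artifact(s): %s", stage, missing)
                return 2
        try:
            _RUNNERS[stage](cfg)
        except Exception as exc:  # surface which stage failed
            log.error("[%s] failed: %s", stage, exc)
            return 1
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": list(ordered),
        "config": cfg.portable_raw(),
    }
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return 0
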