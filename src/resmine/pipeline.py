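"""End-to-end mining pipeline: configuration and the run_mine orchestrator.

Stages, in order: read genomes -> detect core enzymes -> assemble candidate
regions -> resistance screen (hook homologue + duplication rule) ->
multi-genome boundary trimming -> family clustering -> refinement -> genus
filter -> taxonomy summary. Every stage's outputs are written under the run's
output directory and enumerated in a MANIFEST; report.json is deterministic
for identical inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from . import __version__
from . import families as fam_mod
from . import genome_io, mining
from .homology import ScoringScheme, build_duplication_index
from .hook_panel import HookPanel, builtin_panel, load_panel

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one mining run.

    ``genomes`` is a list of dicts with keys ``fasta``, ``gff3`` and
    optionally ``assembly_id``; ``taxa_tsv`` is the sidecar taxon table. When
    ``panel_fasta``/``core_reference`` are omitted the bundled synthetic panel
    and core references are used.
    """

    genomes: list[dict]
    out_dir: str
    taxa_tsv: Optional[str] = None
    panel_fasta: Optional[str] = None
    panel_tsv: Optional[str] = None
    core_reference: Optional[str] = None
    seed: int = 0
    # alignment
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    # hook search / duplication rule
    hook_min_identity: float = 50.0
    hook_min_coverage: float = 0.7
    # core detection
    core_min_identity: float = 30.0
    core_min_coverage: float = 0.5
    # region assembly
    max_intergenes: int = 4
    max_gap_bp: int = 10000
    # occurrence / boundary trimming
    occurrence_min_identity: float = 50.0
    occurrence_min_coverage: float = 0.6
    widely_distributed_cutoff: float = 0.5
    # family clustering
    family_weights: tuple[float, float, float] = (0.3, 0.2, 0.5)
    family_distance_cutoff: float = 0.3
    family_match_min_identity: float = 40.0

    def validate(self) -> None:
        if not self.genomes:
            raise ValueError("no input genomes configured")
        for entry in self.genomes:
            for key in ("fasta", "gff3"):
                if key not in entry:
                    raise ValueError(f"genome entry missing {key!r}: {entry}")
                if not os.path.exists(entry[key]):
                    raise ValueError(f"missing file: {entry[key]}")
        for path in (self.taxa_tsv, self.panel_fasta, self.panel_tsv,
                     self.core_reference):
            if path is not None and not os.path.exists(path):
                raise ValueError(f"missing file: {path}")
        for name, value, lo, hi in (
            ("hook_min_identity", self.hook_min_identity, 0, 100),
            ("core_min_identity", self.core_min_identity, 0, 100),
            ("occurrence_min_identity", self.occurrence_min_identity, 0, 100),
            ("family_match_min_identity", self.family_match_min_identity, 0, 100),
            ("hook_min_coverage", self.hook_min_coverage, 0, 1),
            ("core_min_coverage", self.core_min_coverage, 0, 1),
            ("occurrence_min_coverage", self.occurrence_min_coverage, 0, 1),
            ("widely_distributed_cutoff", self.widely_distributed_cutoff, 0, 1),
            ("family_distance_cutoff", self.family_distance_cutoff, 0, 1),
        ):
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if abs(sum(self.family_weights) - 1.0) > 1e-9:
            raise ValueError("family_weights must sum to 1")

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.matrix_name, self.gap_open, self.gap_extend)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["family_weights"] = list(self.family_weights)
        return d

    @staticmethod
    def from_yaml(path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "family_weights" in raw:
            raw["family_weights"] = tuple(raw["family_weights"])
        return RunConfig(**raw)


@dataclass
class RunReport:
    """In-memory result of run_mine; ``report`` is the serializable dict."""

    regions: list[mining.BGCRegion]
    families_prefilter: list
    families: list
    report: dict
    notices: list[str] = field(default_factory=list)
    out_dir: str = ""


def _load_panel(config: RunConfig) -> HookPanel:
    if config.panel_fasta:
        if not config.panel_tsv:
            raise ValueError("panel_fasta given without panel_tsv")
        return load_panel(config.panel_fasta, config.panel_tsv)
    return builtin_panel()


def run_mine(config: RunConfig) -> RunReport:
    """Execute the full pipeline; artifacts land in ``config.out_dir``."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []
    notices: list[str] = []
    try:
        report = _run_stages(config, written, notices)
    except Exception:
        _write_manifest(config.out_dir, written, complete=False)
        raise
    _write_manifest(config.out_dir, written, complete=True)
    return report


def _run_stages(config: RunConfig, written: list[str], notices: list[str]):
    from .report import report_to_html, report_to_json

    scheme = config.scheme()
    panel = _load_panel(config)
    core_ref = config.core_reference or mining.builtin_core_reference_path()
    taxa = (
        genome_io.read_taxon_metadata(config.taxa_tsv) if config.taxa_tsv else {}
    )

    genomes = []
    for entry in config.genomes:
        genome = genome_io.read_genome(
            entry["fasta"], entry["gff3"], taxa,
            assembly_id=entry.get("assembly_id"),
        )
        genomes.append(genome)
    genomes.sort(key=lambda g: g.assembly_id)

    all_regions: list[mining.BGCRegion] = []
    for genome in genomes:
        cores = mining.detect_core_genes(
            genome, core_ref, config.core_min_identity,
            config.core_min_coverage, scheme,
        )
        regions = mining.assemble_regions(
            genome, cores, config.max_intergenes, config.max_gap_bp
        )
        dup_index = build_duplication_index(
            genome, panel, scheme, config.hook_min_identity,
            config.hook_min_coverage,
        )
        regions = [
            mining.resistance_screen(r, genome, panel, dup_index)
            for r in regions
        ]
        all_regions.extend(regions)

    if len(genomes) >= 2:
        member_ids = {gid for r in all_regions for gid in r.genes}
        occurrence = mining.build_occurrence_index(
            genomes, config.occurrence_min_identity,
            config.occurrence_min_coverage, scheme, gene_ids=member_ids,
        )
        all_regions = [
            mining.delineate_boundaries(
                r, occurrence, config.widely_distributed_cutoff
            )
            for r in all_regions
        ]
    else:
        notices.append(
            "single-genome run: boundary trimming skipped (occurrence "
            "statistics need >=2 genomes)"
        )

    for region in all_regions:
        region.validate()

    flagged = [r for r in all_regions if r.flagged]
    if flagged:
        raw_families = fam_mod.cluster_families(
            flagged, config.family_distance_cutoff, config.family_weights,
            scheme,
        )
        families_prefilter = fam_mod.refine_families(raw_families)
        families = fam_mod.drop_single_genus(families_prefilter)
    else:
        families_prefilter = []
        families = []
        notices.append("no regions flagged; family stages skipped")

    tax_table, tax_totals = fam_mod.taxonomy_summary(families)

    # ---- artifacts -------------------------------------------------------
    out = config.out_dir
    regions_tsv = os.path.join(out, "regions.tsv")
    mining.region_table(all_regions).to_csv(regions_tsv, sep="\t", index=False)
    written.append(regions_tsv)

    by_assembly = {g.assembly_id: g for g in genomes}
    gbk_dir = os.path.join(out, "regions")
    os.makedirs(gbk_dir, exist_ok=True)
    for region in flagged:
        gbk = os.path.join(gbk_dir, f"{region.region_id}.gbk")
        genome_io.write_bgc_genbank(by_assembly[region.assembly_id], region, gbk)
        written.append(gbk)

    pre_tsv = os.path.join(out, "families_prefilter.tsv")
    fam_mod.family_table(families_prefilter).to_csv(pre_tsv, sep="\t", index=False)
    written.append(pre_tsv)
    fam_tsv = os.path.join(out, "families.tsv")
    fam_mod.family_table(families).to_csv(fam_tsv, sep="\t", index=False)
    written.append(fam_tsv)
    tax_tsv = os.path.join(out, "taxonomy.tsv")
    tax_table.to_csv(tax_tsv, sep="\t")
    written.append(tax_tsv)

    hook_annotations = {h.hook_id: h.annotation for h in panel.hooks}
    report_dict = _build_report_dict(
        config, genomes, all_regions, families_prefilter, families,
        tax_totals, notices, hook_annotations,
    )
    json_path = os.path.join(out, "report.json")
    report_to_json(report_dict, json_path)
    written.append(json_path)
    html_path = os.path.join(out, "report.html")
    report_to_html(report_dict, html_path)
    written.append(html_path)

    return RunReport(
        regions=all_regions,
        families_prefilter=families_prefilter,
        families=families,
        report=report_dict,
        notices=notices,
        out_dir=out,
    )


def _region_dict(region: mining.BGCRegion) -> dict:
    return {
        "region_id": region.region_id,
        "assembly_id": region.assembly_id,
        "contig": region.contig_id,
        "start": region.interval[0],
        "end": region.interval[1],
        "genes": [
            {
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
            }
            for g in region.gene_models
        ],
        "core_classes": {
            gid: sig.core_class for gid, sig in sorted(region.cores.items())
        },
        "hooks": [
            {
                "gene_id": gid,
                "hook_id": hh.hook_id,
                "percent_identity": round(hh.hit.percent_identity, 2),
                "outside_copies": hh.outside_copies,
            }
            for gid, hh in sorted(region.hook_hits.items())
        ],
        "flagged": region.flagged,
        "genus": region.genus,
        "taxonomic_class": region.taxonomic_class,
    }


def _family_dict(family) -> dict:
    return {
        "family_id": family.family_id,
        "members": [r.region_id for r in family.members],
        "core_signature": list(family.core_signature or ()),
        "hook_id": family.hook_signature,
        "genera": sorted(family.genera),
        "class_counts": dict(sorted(family.class_counts.items())),
    }


def _build_report_dict(
    config, genomes, regions, families_prefilter, families, tax_totals,
    notices, hook_annotations,
) -> dict:
    flagged = [r for r in regions if r.flagged]
    return {
        "schema_version": 1,
        "provenance": {
            "tool": "resmine",
            "version": __version__,
            "config": config.echo(),
        },
        "notices": list(notices),
        "hook_annotations": dict(sorted(hook_annotations.items())),
        "genomes": [
            {
                "assembly_id": g.assembly_id,
                "organism": g.organism,
                "genus": g.genus,
                "taxonomic_class": g.taxonomic_class,
                "n_contigs": len(g.contigs),
                "n_genes": len(g.genes),
            }
            for g in genomes
        ],
        "regions": [_region_dict(r) for r in sorted(regions, key=lambda r: r.region_id)],
        "n_flagged": len(flagged),
        "families_prefilter": [_family_dict(f) for f in families_prefilter],
        "families": [_family_dict(f) for f in families],
        "taxonomy_totals": {k: int(v) for k, v in tax_totals.items()},
    }


def _write_manifest(out_dir: str, written: Sequence[str], complete: bool) -> None:
    import datetime

    path = os.path.join(out_dir, "MANIFEST.txt")
    with open(path, "w") as fh:
        fh.write(f"status: {'COMPLETE' if complete else 'INCOMPLETE'}\n")
        fh.write(f"written_at: {datetime.datetime.now().isoformat()}\n")
        for p in written:
            fh.write(os.path.relpath(p, out_dir) + "\n")
        fh.write("MANIFEST.txt\n")
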