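"""Candidate BGC detection, boundary trimming, and the resistance screen.

The stages here take an annotated genome to a set of flagged candidate
clusters:

1. ``detect_core_genes`` — find scaffold-building core enzymes (PKSs, NRPSs,
   terpene synthases, prenyltransferases) by similarity to a curated core
   reference FASTA.
2. ``assemble_regions`` — grow a gene window around each core and merge
   overlapping windows into candidate regions.
3. ``build_occurrence_index`` / ``delineate_boundaries`` — genuine cluster
   genes show restricted occurrence across genomes while flanking genes are
   widely distributed; flanks above an occurrence cutoff are trimmed.
4. ``resistance_screen`` — a region is flagged when it encodes a close
   homologue of a hook protein and that homologue has at least one additional
   copy in the genome outside the region (the duplication rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from Bio import SeqIO

from .genome_io import GeneModel, GenomeRecord
from .homology import (
    AlignmentHit,
    DuplicationEntry,
    ScoringScheme,
    count_outside_copies,
    smith_waterman,
)

log = logging.getLogger(__name__)

CORE_CLASSES = (
    "HR-PKS",
    "NR-PKS",
    "PKS-NRPS",
    "NRPS",
    "NRPS-like",
    "terpene_synthase",
    "prenyltransferase",
)

#: classes whose references count as the PKS / NRPS halves of a hybrid
_PKS_GROUP = {"HR-PKS", "NR-PKS"}
_NRPS_GROUP = {"NRPS"}

#: query-segment overlap (fraction of either segment) below which two hits are
#: treated as distinct domains of a fusion protein
_FUSION_MAX_OVERLAP = 0.2


@dataclass(frozen=True)
class CoreSignature:
    """Core-enzyme call for one gene: class plus supporting alignments."""

    core_class: str
    evidence: tuple[AlignmentHit, ...]

    def __post_init__(self) -> None:
        if self.core_class not in CORE_CLASSES:
            raise ValueError(f"unknown core class {self.core_class!r}")
        if not self.evidence:
            raise ValueError("core signature requires >=1 evidence hit")


@dataclass(frozen=True)
class HookHit:
    """A member gene's best hook homology plus its outside-copy count."""

    hook_id: str
    hit: AlignmentHit
    outside_copies: int


@dataclass
class BGCRegion:
    """A candidate cluster: member genes, core calls, hook evidence, flag."""

    region_id: str
    assembly_id: str
    contig_id: str
    interval: tuple[int, int]
    genes: list[str]
    gene_models: list[GeneModel]
    cores: dict[str, CoreSignature]
    hook_hits: dict[str, HookHit] = field(default_factory=dict)
    flagged: bool = False
    genus: str = "unknown"
    taxonomic_class: str = "unknown"

    def validate(self) -> None:
        if not self.cores:
            raise ValueError(f"region {self.region_id}: no core gene")
        starts = [g.start for g in self.gene_models]
        if starts != sorted(starts):
            raise ValueError(f"region {self.region_id}: genes not sorted by start")
        if self.gene_models:
            lo = min(g.start for g in self.gene_models)
            hi = max(g.end for g in self.gene_models)
            s, e = self.interval
            if s > lo or e < hi:
                raise ValueError(
                    f"region {self.region_id}: interval does not cover members"
                )
        if self.flagged and not any(
            h.outside_copies >= 1 for h in self.hook_hits.values()
        ):
            raise ValueError(
                f"region {self.region_id}: flagged without a duplicated hook"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def best_hook(self) -> Optional[HookHit]:
        """Highest-scoring hook hit (ties by hook id), or None."""
        if not self.hook_hits:
            return None
        return min(
            self.hook_hits.values(), key=lambda h: (-h.hit.score, h.hook_id)
        )

    def core_class_multiset(self) -> tuple[str, ...]:
        """Sorted multiset of member core classes (the family core signature)."""
        return tuple(sorted(sig.core_class for sig in self.cores.values()))


def read_core_reference(path) -> list[tuple[str, str, str]]:
    """Read the core reference FASTA; headers carry ``class=`` tags.

    Returns (ref_id, core_class, sequence) triples; an unlabeled or
    unknown-class header is a hard error.
    """
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        core_class = None
        for token in rec.description.split():
            if token.startswith("class="):
                core_class = token[len("class="):]
        if core_class is None:
            raise ValueError(f"core reference {rec.id}: header lacks class= tag")
        if core_class not in CORE_CLASSES:
            raise ValueError(
                f"core reference {rec.id}: unknown class {core_class!r}"
            )
        refs.append((rec.id, core_class, str(rec.seq).upper()))
    return refs


def builtin_core_reference_path() -> str:
    from importlib import resources

    return str(resources.files("resmine") / "data" / "core_reference.fasta")


def _segment_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length as a fraction of the shorter segment."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if hi <= lo:
        return 0.0
    return (hi - lo) / min(a[1] - a[0], b[1] - b[0])


def detect_core_genes(
    genome: GenomeRecord,
    core_reference,
    min_identity: float = 30.0,
    min_coverage: float = 0.5,
    scheme: ScoringScheme | None = None,
) -> list[tuple[str, CoreSignature]]:
    """Classify genes by their best-scoring qualifying core reference.

    ``core_reference`` is a path to a ``class=``-tagged FASTA or a list of
    (ref_id, class, sequence) triples. Coverage is tested on the reference
    side. A gene with PKS and NRPS reference hits on nearly disjoint query
    segments (overlap < 20% of either) is called a PKS-NRPS hybrid.
    """
    if isinstance(core_reference, (str, bytes)) or hasattr(core_reference, "__fspath__"):
        refs = read_core_reference(core_reference)
    else:
        refs = list(core_reference)
    scheme = scheme or ScoringScheme()
    out: list[tuple[str, CoreSignature]] = []
    for gene in genome.genes:
        qualifying: list[tuple[str, AlignmentHit]] = []
        for ref_id, core_class, seq in refs:
            hit = smith_waterman(
                gene.protein, seq, scheme, query_id=gene.gene_id, target_id=ref_id
            )
            if hit is None:
                continue
            if hit.percent_identity < min_identity or hit.target_coverage < min_coverage:
                continue
            qualifying.append((core_class, hit))
        if not qualifying:
            continue
        qualifying.sort(key=lambda ch: (-ch[1].score, ch[1].target_id))
        best_class, best_hit = qualifying[0]
        fusion = _find_fusion(qualifying)
        if fusion is not None:
            out.append((gene.gene_id, fusion))
        else:
            out.append((gene.gene_id, CoreSignature(best_class, (best_hit,))))
    return out


def _find_fusion(
    qualifying: list[tuple[str, AlignmentHit]]
) -> Optional[CoreSignature]:
    pks_hits = [h for c, h in qualifying if c in _PKS_GROUP]
    nrps_hits = [h for c, h in qualifying if c in _NRPS_GROUP]
    for ph in pks_hits:
        for nh in nrps_hits:
            if _segment_overlap(ph.query_interval, nh.query_interval) < _FUSION_MAX_OVERLAP:
                return CoreSignature("PKS-NRPS", (ph, nh))
    return None


def assemble_regions(
    genome: GenomeRecord,
    core_genes: Sequence[tuple[str, CoreSignature]],
    max_intergenes: int = 4,
    max_gap_bp: int = 10000,
) -> list[BGCRegion]:
    """Grow a window of neighbours around each core gene; merge overlaps.

    From each core the window extends gene-by-gene in both directions while at
    most ``max_intergenes`` genes have been added on that side and the bp gap
    to the next gene is <= ``max_gap_bp``. Overlapping windows on a contig are
    merged. Region ids are deterministic: assembly, contig, ordinal by start.
    """
    core_map = dict(sorted(core_genes))
    by_contig: dict[str, list[GeneModel]] = {}
    for gene in genome.genes:
        by_contig.setdefault(gene.contig_id, []).append(gene)
    for genes in by_contig.values():
        genes.sort(key=lambda g: (g.start, g.gene_id))

    regions: list[BGCRegion] = []
    counter = 0
    for contig_id in sorted(by_contig):
        genes = by_contig[contig_id]
        idx_of = {g.gene_id: i for i, g in enumerate(genes)}
        windows: list[tuple[int, int]] = []
        for gene_id in core_map:
            if gene_id not in idx_of:
                continue
            i = idx_of[gene_id]
            lo = i
            added = 0
            while lo > 0 and added < max_intergenes:
                gap = genes[lo].start - genes[lo - 1].end
                if gap > max_gap_bp:
                    break
                lo -= 1
                added += 1
            hi = i
            added = 0
            while hi < len(genes) - 1 and added < max_intergenes:
                gap = genes[hi + 1].start - genes[hi].end
                if gap > max_gap_bp:
                    break
                hi += 1
                added += 1
            windows.append((lo, hi))
        if not windows:
            continue
        windows.sort()
        merged: list[list[int]] = []
        for lo, hi in windows:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            counter += 1
            members = genes[lo : hi + 1]
            cores = {
                g.gene_id: core_map[g.gene_id]
                for g in members
                if g.gene_id in core_map
            }
            region = BGCRegion(
                region_id=f"{genome.assembly_id}.{contig_id}.r{counter}",
                assembly_id=genome.assembly_id,
                contig_id=contig_id,
                interval=(members[0].start, max(g.end for g in members)),
                genes=[g.gene_id for g in members],
                gene_models=list(members),
                cores=cores,
                genus=genome.genus,
                taxonomic_class=genome.taxonomic_class,
            )
            region.validate()
            regions.append(region)
    return regions


def build_occurrence_index(
    genomes: Sequence[GenomeRecord],
    min_identity: float = 50.0,
    min_coverage: float = 0.6,
    scheme: ScoringScheme | None = None,
    gene_ids: Optional[set[str]] = None,
) -> dict[str, float]:
    """Fraction of *other* genomes carrying a homologue of each gene.

    Coverage is required on both sequences. ``gene_ids`` restricts the
    computation to the genes of interest (e.g. region members); all other
    genomes' genes are always candidates as homology targets.
    """
    if len(genomes) < 2:
        raise ValueError(
            "occurrence index needs >=2 genomes; for single-genome runs skip "
            "boundary trimming"
        )
    scheme = scheme or ScoringScheme()
    index: dict[str, float] = {}
    for gi, genome in enumerate(genomes):
        others = [g for gj, g in enumerate(genomes) if gj != gi]
        for gene in genome.genes:
            if gene_ids is not None and gene.gene_id not in gene_ids:
                continue
            present = 0
            for other in others:
                found = False
                for cand in other.genes:
                    hit = smith_waterman(
                        gene.protein, cand.protein, scheme,
                        query_id=gene.gene_id, target_id=cand.gene_id,
                    )
                    if hit is None:
                        continue
                    if (
                        hit.percent_identity >= min_identity
                        and hit.query_coverage >= min_coverage
                        and hit.target_coverage >= min_coverage
                    ):
                        found = True
                        break
                if found:
                    present += 1
            index[gene.gene_id] = present / len(others)
    return index


def delineate_boundaries(
    region: BGCRegion,
    occurrence_index: Mapping[str, float],
    widely_distributed_cutoff: float = 0.5,
) -> BGCRegion:
    """Trim widely distributed flanking genes off a region.

    From each flank inward, genes with occurrence >= the cutoff are removed
    until the first gene below the cutoff; core genes and hook-hit genes are
    never removed and stop trimming. Idempotent.
    """
    def trimmable(gene_id: str) -> bool:
        if gene_id in region.cores or gene_id in region.hook_hits:
            return False
        return occurrence_index.get(gene_id, 0.0) >= widely_distributed_cutoff

    lo, hi = 0, len(region.genes) - 1
    while lo <= hi and trimmable(region.genes[lo]):
        lo += 1
    while hi >= lo and trimmable(region.genes[hi]):
        hi -= 1
    members = region.gene_models[lo : hi + 1]
    if not members:
        log.warning("region %s: trimming removed all genes; keeping as-is",
                    region.region_id)
        return region
    trimmed = replace(
        region,
        genes=[g.gene_id for g in members],
        gene_models=members,
        interval=(members[0].start, max(g.end for g in members)),
        cores={k: v for k, v in region.cores.items()
               if k in {g.gene_id for g in members}},
        hook_hits={k: v for k, v in region.hook_hits.items()
                   if k in {g.gene_id for g in members}},
    )
    trimmed.validate()
    return trimmed


def resistance_screen(
    region: BGCRegion,
    genome: GenomeRecord,
    panel,
    duplication_index: Mapping[str, list[DuplicationEntry]],
) -> BGCRegion:
    """Apply the duplication rule to one region.

    Every member gene with a qualifying panel hit (taken from the duplication
    index, which was built at the panel-search thresholds) gets a hook hit
    with its outside-copy count; the region is flagged iff some hook homologue
    has at least one copy outside the region.
    """
    member_ids = set(region.genes)
    best_per_gene: dict[str, tuple[str, AlignmentHit]] = {}
    for hook_id, entries in duplication_index.items():
        for entry in entries:
            if entry.gene_id not in member_ids:
                continue
            cur = best_per_gene.get(entry.gene_id)
            if cur is None or (-entry.hit.score, hook_id) < (-cur[1].score, cur[0]):
                best_per_gene[entry.gene_id] = (hook_id, entry.hit)
    hook_hits: dict[str, HookHit] = {}
    for gene_id, (hook_id, hit) in sorted(best_per_gene.items()):
        outside = count_outside_copies(
            hook_id, region.contig_id, region.interval, duplication_index
        )
        hook_hits[gene_id] = HookHit(hook_id, hit, outside)
    screened = replace(
        region,
        hook_hits=hook_hits,
        flagged=any(h.outside_copies >= 1 for h in hook_hits.values()),
    )
    screened.validate()
    return screened


def region_table(regions: Sequence[BGCRegion]):
    """Summary table of regions (one row each) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for r in regions:
        bh = r.best_hook()
        rows.append(
            {
                "region_id": r.region_id,
                "assembly_id": r.assembly_id,
                "contig": r.contig_id,
                "start": r.interval[0],
                "end": r.interval[1],
                "n_genes": r.n_genes,
                "core_classes": ";".join(r.core_class_multiset()),
                "hook_id": bh.hook_id if bh else "",
                "hook_identity": round(bh.hit.percent_identity, 2) if bh else "",
                "outside_copies": bh.outside_copies if bh else "",
                "flagged": r.flagged,
                "genus": r.genus,
                "taxonomic_class": r.taxonomic_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "assembly_id", "contig", "start", "end", "n_genes",
            "core_classes", "hook_id", "hook_identity", "outside_copies",
            "flagged", "genus", "taxonomic_class",
        ],
    )
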