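"""Synthetic multi-genome inputs with planted resistant BGCs and ground truth.

The generator emulates the inputs the mining pipeline expects — several
annotated fungal genomes (FASTA + GFF3 + taxon TSV) — with features planted at
known locations so every pipeline stage can be tested offline:

* ``true_resistant_bgc`` — a cluster with a core enzyme, a hook homologue at a
  chosen identity, and >=1 extra hook copy elsewhere in the genome (the
  essential housekeeping copy). Must be flagged.
* ``decoy_no_duplicate`` — hook homologue in the cluster but no outside copy.
* ``decoy_no_hook`` — core enzyme but no hook homologue at all.
* ``decoy_duplicate_outside_only`` — hook copies outside the cluster only.

All decoys must survive region assembly but fail the resistance screen.
Planted clusters are bracketed by "common" genes present in (almost) all
genomes, giving the high-occurrence flanks that boundary trimming removes,
and are isolated from the rest of the contig by large intergenic spacers.
Clusters sharing a ``family_label`` are mutated copies of one prototype
cluster, so they co-cluster into a gene-cluster family downstream.

All randomness flows from the single config seed; identical configs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import genome_io
from .hook_panel import HookPanel, builtin_panel
from .mining import BGCRegion, read_core_reference, builtin_core_reference_path

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PLANT_KINDS = (
    "true_resistant_bgc",
    "decoy_no_duplicate",
    "decoy_no_hook",
    "decoy_duplicate_outside_only",
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


@dataclass(frozen=True)
class PlantSpec:
    """One planted cluster (or decoy) in one genome."""

    kind: str
    genome_index: int
    core_class: str
    family_label: str
    hook_id: Optional[str] = None
    identity_to_hook: Optional[float] = None
    outside_copies: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.kind == "true_resistant_bgc" and self.outside_copies < 1:
            raise ValueError("true_resistant_bgc requires outside_copies >= 1")
        if self.kind == "decoy_no_duplicate" and self.outside_copies != 0:
            raise ValueError("decoy_no_duplicate requires outside_copies == 0")
        if self.kind == "decoy_duplicate_outside_only" and self.outside_copies < 1:
            raise ValueError(
                "decoy_duplicate_outside_only requires outside_copies >= 1"
            )
        if self.kind == "decoy_no_hook":
            if self.hook_id is not None:
                raise ValueError("decoy_no_hook must not carry a hook_id")
        elif self.hook_id is None:
            raise ValueError(f"{self.kind} requires a hook_id")

    @property
    def has_in_cluster_hook(self) -> bool:
        return self.kind in ("true_resistant_bgc", "decoy_no_duplicate")

    @property
    def expected_flagged(self) -> bool:
        return self.kind == "true_resistant_bgc"


@dataclass
class SimConfig:
    """Study conditions for one synthetic run; the seed fixes all randomness."""

    seed: int
    n_genomes: int = 5
    taxon_plan: list[tuple[str, str]] = field(default_factory=list)
    genes_per_genome: int = 16
    plants: list[PlantSpec] = field(default_factory=list)
    n_common_genes: int = 4
    common_in_genomes: Optional[list[int]] = None
    filler_identity: float = 90.0
    core_identity_range: tuple[float, float] = (60.0, 80.0)
    outside_copy_identity_range: tuple[float, float] = (70.0, 85.0)

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes >= 1 required")
        if not self.taxon_plan:
            self.taxon_plan = [("Genus", "Class")] * self.n_genomes
        if len(self.taxon_plan) != self.n_genomes:
            raise ValueError("taxon_plan length must equal n_genomes")
        for p in self.plants:
            if not (0 <= p.genome_index < self.n_genomes):
                raise ValueError(f"plant genome_index {p.genome_index} out of range")
        # one family, one hook and one core class (members are homologous)
        fam_hook: dict[str, tuple] = {}
        for p in self.plants:
            key = (p.hook_id, p.core_class)
            prev = fam_hook.setdefault(p.family_label, key)
            if prev != key:
                raise ValueError(
                    f"family {p.family_label}: members disagree on hook/core "
                    f"({prev} vs {key})"
                )
        # hooks with and without outside copies must not collide in one genome
        for gi in range(self.n_genomes):
            hooks = [
                p.hook_id
                for p in self.plants
                if p.genome_index == gi and p.hook_id is not None
            ]
            if len(hooks) != len(set(hooks)):
                raise ValueError(
                    f"genome {gi}: a hook is used by more than one plant; "
                    "outside-copy counts would be ambiguous"
                )

    def run_id(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_config(seed: int) -> SimConfig:
    """The default study conditions: 5 genomes, 3 genera across 2 classes,
    4 true resistant BGCs (hook identity 60-80%) in two families, and 3 decoys
    of each decoy kind."""
    taxa = [
        ("Aspergillus", "Eurotiomycetes"),
        ("Aspergillus", "Eurotiomycetes"),
        ("Hypoxylon", "Sordariomycetes"),
        ("Hypoxylon", "Sordariomycetes"),
        ("Calonectria", "Sordariomycetes"),
    ]
    rng = np.random.default_rng(seed)

    def ident() -> float:
        return float(np.round(rng.uniform(60.0, 80.0), 1))

    plants = [
        # family A spans Aspergillus + Hypoxylon -> survives the genus filter
        PlantSpec("true_resistant_bgc", 0, "HR-PKS", "famA", "HK01", ident(), 2),
        PlantSpec("true_resistant_bgc", 2, "HR-PKS", "famA", "HK01", ident(), 1),
        # family B is Aspergillus-only -> dropped by the genus filter
        PlantSpec("true_resistant_bgc", 0, "NRPS", "famB", "HK02", ident(), 1),
        PlantSpec("true_resistant_bgc", 1, "NRPS", "famB", "HK02", ident(), 2),
        PlantSpec("decoy_no_duplicate", 0, "NR-PKS", "dnd1", "HK03", ident(), 0),
        PlantSpec("decoy_no_duplicate", 2, "terpene_synthase", "dnd2", "HK04", ident(), 0),
        PlantSpec("decoy_no_duplicate", 3, "NRPS-like", "dnd3", "HK05", ident(), 0),
        PlantSpec("decoy_no_hook", 1, "prenyltransferase", "dnh1"),
        PlantSpec("decoy_no_hook", 3, "NR-PKS", "dnh2"),
        PlantSpec("decoy_no_hook", 4, "terpene_synthase", "dnh3"),
        PlantSpec("decoy_duplicate_outside_only", 1, "HR-PKS", "doo1", "HK07",
                  None, 2),
        PlantSpec("decoy_duplicate_outside_only", 2, "NRPS", "doo2", "HK08",
                  None, 1),
        PlantSpec("decoy_duplicate_outside_only", 4, "NRPS-like", "doo3", "HK06",
                  None, 1),
    ]
    return SimConfig(seed=seed, n_genomes=5, taxon_plan=taxa, plants=plants)


@dataclass
class PlantTruth:
    """Ground truth for one planted cluster."""

    plant_id: str
    assembly_id: str
    contig_id: str
    interval: tuple[int, int]
    kind: str
    core_class: str
    hook_id: Optional[str]
    family_label: str
    gene_ids: list[str]
    expected_flagged: bool
    outside_copy_gene_ids: list[str]


@dataclass
class SimTruth:
    run_id: str
    genomes: list[dict]
    plants: list[PlantTruth]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "run_id": self.run_id,
                    "genomes": self.genomes,
                    "plants": [dataclasses.asdict(p) for p in self.plants],
                },
                fh,
                indent=1,
                default=list,
            )

    @staticmethod
    def from_json(path) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)
        plants = [
            PlantTruth(**{**p, "interval": tuple(p["interval"])})
            for p in raw["plants"]
        ]
        return SimTruth(raw["run_id"], raw["genomes"], plants)


def mutate_protein(sequence: str, target_identity: float, seed: int) -> str:
    """Substitute exactly round((1 - t/100) * L) positions, each to a
    different residue; realized identity equals the target within rounding."""
    if not (0 < target_identity <= 100):
        raise ValueError("target_identity must be in (0, 100]")
    if target_identity < 5:
        raise ValueError("target identity below 5% is meaningless")
    if len(sequence) < 20:
        raise ValueError("sequence shorter than 20 residues")
    rng = np.random.default_rng(seed)
    n_sub = int(round((1.0 - target_identity / 100.0) * len(sequence)))
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    out = list(sequence)
    for pos in sorted(positions):
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length - 1)
    )
    return "M" + body


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein -> CDS with uniformly random synonymous codons plus a stop."""
    codons = []
    for aa in protein:
        options = _CODONS_FOR[aa]
        codons.append(options[int(rng.integers(len(options)))])
    codons.append(_STANDARD.stop_codons[int(rng.integers(len(_STANDARD.stop_codons)))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


class _ContigBuilder:
    """Append genes and spacers left to right, tracking gene coordinates."""

    def __init__(self, contig_id: str, rng: np.random.Generator):
        self.contig_id = contig_id
        self.rng = rng
        self.parts: list[str] = []
        self.cursor = 0
        self.genes: list[dict] = []

    def spacer(self, length: int) -> None:
        self.parts.append(_random_nt(self.rng, length))
        self.cursor += length

    def add_gene(
        self,
        gene_id: str,
        protein: str,
        strand: str,
        n_introns: int = 0,
        product: str = "",
    ) -> dict:
        cds = reverse_translate(protein, self.rng)
        n_exons = n_introns + 1
        # split the CDS at codon boundaries into n_exons coding pieces
        n_codons = len(cds) // 3
        if n_exons > 1:
            cuts = sorted(
                self.rng.choice(np.arange(1, n_codons), size=n_exons - 1,
                                replace=False)
            )
        else:
            cuts = []
        bounds = [0] + [3 * c for c in cuts] + [len(cds)]
        pieces = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [
            "GT" + _random_nt(self.rng, int(self.rng.integers(56, 86))) + "AG"
            for _ in range(n_introns)
        ]
        if strand == "+":
            genomic_pieces = pieces
        else:
            genomic_pieces = [
                str(Seq(p).reverse_complement()) for p in reversed(pieces)
            ]
        exons: list[tuple[int, int]] = []
        pos = self.cursor
        for k, piece in enumerate(genomic_pieces):
            exons.append((pos, pos + len(piece)))
            self.parts.append(piece)
            pos += len(piece)
            if k < len(introns):
                self.parts.append(introns[k])
                pos += len(introns[k])
        self.cursor = pos
        info = {
            "gene_id": gene_id,
            "contig_id": self.contig_id,
            "interval": (exons[0][0], exons[-1][1]),
            "strand": strand,
            "exons": exons,
            "protein": protein,
            "product": product,
        }
        self.genes.append(info)
        return info

    def sequence(self) -> str:
        return "".join(self.parts)


def _write_gff3(path, contigs: Sequence[_ContigBuilder]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cb in contigs:
            fh.write(
                f"##sequence-region {cb.contig_id} 1 {len(cb.sequence())}\n"
            )
        for cb in contigs:
            for g in cb.genes:
                s, e = g["interval"]
                gid = g["gene_id"]
                strand = g["strand"]
                attrs = f"ID={gid}"
                fh.write(
                    f"{cb.contig_id}\tresmine_synth\tgene\t{s + 1}\t{e}\t.\t"
                    f"{strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{cb.contig_id}\tresmine_synth\tmRNA\t{s + 1}\t{e}\t.\t"
                    f"{strand}\t.\tID={gid}.t1;Parent={gid}"
                    + (f";product={g['product']}" if g["product"] else "")
                    + "\n"
                )
                exons = g["exons"]
                coding_order = exons if strand == "+" else list(reversed(exons))
                cum = 0
                phases = {}
                for a, b in coding_order:
                    phases[(a, b)] = (3 - cum % 3) % 3
                    cum += b - a
                for a, b in exons:
                    fh.write(
                        f"{cb.contig_id}\tresmine_synth\tCDS\t{a + 1}\t{b}\t.\t"
                        f"{strand}\t{phases[(a, b)]}\t"
                        f"ID={gid}.cds;Parent={gid}.t1\n"
                    )


def _write_fasta(path, contigs: Sequence[_ContigBuilder]) -> None:
    with open(path, "w") as fh:
        for cb in contigs:
            seq = cb.sequence()
            fh.write(f">{cb.contig_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def generate_genomes(
    config: SimConfig,
    out_dir,
    panel: Optional[HookPanel] = None,
    core_reference=None,
    audit: bool = True,
) -> tuple[list[dict], SimTruth]:
    """Emit FASTA + GFF3 + taxa.tsv + truth.json for every genome in the plan.

    Returns (genome file manifest, SimTruth). With ``audit`` (default), every
    generated genome is re-read through :mod:`resmine.genome_io` and planted
    protein sequences are verified to round-trip exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    panel = panel or builtin_panel()
    refs = (
        read_core_reference(core_reference or builtin_core_reference_path())
    )
    ref_by_class = {}
    for ref_id, core_class, seq in refs:
        ref_by_class.setdefault(core_class, (ref_id, seq))
    rng = np.random.default_rng(config.seed)

    common_proteins = [
        random_protein(rng, int(rng.integers(180, 260)))
        for _ in range(config.n_common_genes)
    ]
    common_targets = (
        set(config.common_in_genomes)
        if config.common_in_genomes is not None
        else set(range(config.n_genomes))
    )

    # one prototype cluster per family label, shared by all its plants
    prototypes: dict[str, dict] = {}
    for plant in config.plants:
        if plant.family_label in prototypes:
            continue
        prototypes[plant.family_label] = {
            "fillers": [
                random_protein(rng, int(rng.integers(150, 300))) for _ in range(4)
            ],
        }
    plant_hook, plant_core = _family_homolog_chains(config, panel, ref_by_class, rng)

    genome_manifest: list[dict] = []
    truths: list[PlantTruth] = []
    taxa_rows = []
    for gi in range(config.n_genomes):
        assembly_id = f"SYN{gi + 1:02d}"
        genus, tclass = config.taxon_plan[gi]
        taxa_rows.append(
            {
                "assembly_id": assembly_id,
                "organism": f"{genus} synthetica {assembly_id}",
                "genus": genus,
                "class": tclass,
            }
        )
        ctg1 = _ContigBuilder(f"{assembly_id}_ctg1", rng)
        ctg2 = _ContigBuilder(f"{assembly_id}_ctg2", rng)
        counter = 0

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{assembly_id}_g{counter:04d}"

        outside_queue: list[tuple[str, str]] = []  # (protein, product)
        plants_here = [
            (idx, p) for idx, p in enumerate(config.plants)
            if p.genome_index == gi
        ]
        ctg1.spacer(2000)
        for pi, (plant_idx, plant) in enumerate(plants_here):
            proto = prototypes[plant.family_label]
            core_prot = plant_core[plant_idx]
            fillers = [
                mutate_protein(f, config.filler_identity, int(rng.integers(2**31)))
                for f in proto["fillers"]
            ]
            if plant.has_in_cluster_hook:
                hook_prot = plant_hook[plant_idx]
                proper = [
                    (fillers[0], "hypothetical protein", 0),
                    (fillers[1], "hypothetical protein", 0),
                    (core_prot, f"{plant.core_class} core enzyme", 1),
                    (hook_prot, "hook homologue", 1),
                    (fillers[2], "hypothetical protein", 0),
                ]
            else:
                proper = [
                    (fillers[0], "hypothetical protein", 0),
                    (fillers[1], "hypothetical protein", 0),
                    (core_prot, f"{plant.core_class} core enzyme", 1),
                    (fillers[3], "hypothetical protein", 0),
                    (fillers[2], "hypothetical protein", 0),
                ]
            if plant.outside_copies and plant.hook_id is not None:
                hook_seq = panel.get(plant.hook_id).sequence
                for _ in range(plant.outside_copies):
                    ident = float(
                        np.round(
                            rng.uniform(*config.outside_copy_identity_range), 1
                        )
                    )
                    outside_queue.append(
                        (
                            mutate_protein(
                                hook_seq, ident, int(rng.integers(2**31))
                            ),
                            f"housekeeping copy of {plant.hook_id}",
                        )
                    )
            # left common flank, proper genes, right common flank
            if pi > 0:
                ctg1.spacer(15000)
            flank_l = mutate_protein(
                common_proteins[0], 90.0, int(rng.integers(2**31))
            )
            flank_r = mutate_protein(
                common_proteins[1 % len(common_proteins)], 90.0,
                int(rng.integers(2**31)),
            )
            ctg1.add_gene(next_id(), flank_l, "+", 0, "conserved flank protein")
            gene_ids = []
            interval_start = None
            for prot, product, introns in proper:
                ctg1.spacer(int(rng.integers(300, 800)))
                strand = "+" if rng.random() < 0.5 else "-"
                info = ctg1.add_gene(next_id(), prot, strand, introns, product)
                gene_ids.append(info["gene_id"])
                if interval_start is None:
                    interval_start = info["interval"][0]
                interval_end = info["interval"][1]
            ctg1.spacer(int(rng.integers(300, 800)))
            ctg1.add_gene(next_id(), flank_r, "-", 0, "conserved flank protein")
            truths.append(
                PlantTruth(
                    plant_id=f"{assembly_id}_p{pi + 1}",
                    assembly_id=assembly_id,
                    contig_id=ctg1.contig_id,
                    interval=(interval_start, interval_end),
                    kind=plant.kind,
                    core_class=plant.core_class,
                    hook_id=plant.hook_id,
                    family_label=plant.family_label,
                    gene_ids=gene_ids,
                    expected_flagged=plant.expected_flagged,
                    outside_copy_gene_ids=[],
                )
            )
        ctg1.spacer(60000)

        # distal zone: background genes, standalone common genes, hook copies
        distal: list[tuple[str, str]] = []
        n_bg = config.genes_per_genome
        for _ in range(n_bg):
            distal.append(
                (
                    random_protein(rng, int(rng.integers(100, 450))),
                    "hypothetical protein",
                )
            )
        if gi in common_targets:
            for cp in common_proteins:
                distal.append(
                    (
                        mutate_protein(cp, 90.0, int(rng.integers(2**31))),
                        "conserved housekeeping-like protein",
                    )
                )
        order = rng.permutation(len(distal))
        distal = [distal[i] for i in order]
        outside_gene_ids: list[str] = []
        items_ctg1 = distal[: (2 * len(distal)) // 3]
        items_ctg2 = distal[(2 * len(distal)) // 3 :]
        for k, (prot, product) in enumerate(outside_queue):
            (items_ctg1 if k % 2 == 0 else items_ctg2).append((prot, product))
        for prot, product in items_ctg1:
            ctg1.spacer(int(rng.integers(2000, 4000)))
            strand = "+" if rng.random() < 0.5 else "-"
            info = ctg1.add_gene(next_id(), prot, strand, 0, product)
            if product.startswith("housekeeping copy"):
                outside_gene_ids.append(info["gene_id"])
        ctg1.spacer(1000)
        ctg2.spacer(1500)
        for prot, product in items_ctg2:
            strand = "+" if rng.random() < 0.5 else "-"
            info = ctg2.add_gene(next_id(), prot, strand, 0, product)
            if product.startswith("housekeeping copy"):
                outside_gene_ids.append(info["gene_id"])
            ctg2.spacer(int(rng.integers(2000, 4000)))
        for t in truths:
            if t.assembly_id == assembly_id and t.hook_id is not None:
                # all of this genome's outside hook copies, for the audit
                t.outside_copy_gene_ids = outside_gene_ids

        fasta = os.path.join(out_dir, f"{assembly_id}.fna")
        gff = os.path.join(out_dir, f"{assembly_id}.gff3")
        _write_fasta(fasta, [ctg1, ctg2])
        _write_gff3(gff, [ctg1, ctg2])
        genome_manifest.append(
            {
                "assembly_id": assembly_id,
                "fasta": fasta,
                "gff3": gff,
                "genus": genus,
                "class": tclass,
            }
        )
        if audit:
            _audit_genome(fasta, gff, assembly_id, [ctg1, ctg2], taxa_rows[-1])

    import pandas as pd

    taxa_path = os.path.join(out_dir, "taxa.tsv")
    pd.DataFrame(taxa_rows).to_csv(taxa_path, sep="\t", index=False)
    truth = SimTruth(config.run_id(), genome_manifest, truths)
    truth.to_json(os.path.join(out_dir, "truth.json"))
    return genome_manifest, truth


def _family_homolog_chains(
    config: SimConfig, panel: HookPanel, ref_by_class, rng: np.random.Generator
) -> tuple[dict[int, str], dict[int, str]]:
    """Per-plant hook and core proteins, coherent within each family.

    Members of one family descend from a common ancestral cluster: the member
    with the highest identity-to-hook target is mutated from the hook itself,
    each further member from the previous one, by just enough substitutions to
    reach its own target. Cross-member identity therefore stays high (roughly
    the ratio of the two targets) while each member still sits at its planted
    distance from the hook. Core enzymes are chained the same way from the
    class reference, at identities drawn from ``core_identity_range``.
    """
    by_family: dict[str, list[int]] = {}
    for idx, plant in enumerate(config.plants):
        by_family.setdefault(plant.family_label, []).append(idx)
    plant_hook: dict[int, str] = {}
    plant_core: dict[int, str] = {}
    for label in sorted(by_family):
        idxs = by_family[label]
        hook_members = [
            i for i in idxs if config.plants[i].has_in_cluster_hook
        ]
        hook_members.sort(
            key=lambda i: -(config.plants[i].identity_to_hook or 70.0)
        )
        cur_seq: Optional[str] = None
        cur_ident = 100.0
        for i in hook_members:
            plant = config.plants[i]
            target = plant.identity_to_hook or 70.0
            if cur_seq is None:
                cur_seq = panel.get(plant.hook_id).sequence
            rel = min(100.0, 100.0 * target / cur_ident)
            cur_seq = mutate_protein(cur_seq, rel, int(rng.integers(2**31)))
            cur_ident = target
            plant_hook[i] = cur_seq
        core_members = sorted(idxs)
        targets = sorted(
            (
                float(np.round(rng.uniform(*config.core_identity_range), 1))
                for _ in core_members
            ),
            reverse=True,
        )
        cur_seq = None
        cur_ident = 100.0
        for i, target in zip(core_members, targets):
            if cur_seq is None:
                cur_seq = _core_seq_for(
                    config.plants[i].core_class, ref_by_class
                )[1]
            rel = min(100.0, 100.0 * target / cur_ident)
            cur_seq = mutate_protein(cur_seq, rel, int(rng.integers(2**31)))
            cur_ident = target
            plant_core[i] = cur_seq
    return plant_hook, plant_core


def _core_seq_for(core_class: str, ref_by_class) -> tuple[str, str]:
    if core_class == "PKS-NRPS":
        # hybrid: PKS reference N-half fused to NRPS reference C-half
        pid, pseq = ref_by_class["HR-PKS"]
        nid, nseq = ref_by_class["NRPS"]
        return (f"{pid}+{nid}", pseq + nseq)
    if core_class not in ref_by_class:
        raise ValueError(f"no core reference for class {core_class!r}")
    return ref_by_class[core_class]


def _audit_genome(fasta, gff, assembly_id, builders, taxon_row) -> None:
    genome = genome_io.read_genome(
        fasta, gff, {assembly_id: taxon_row}, assembly_id=assembly_id
    )
    by_id = {g.gene_id: g for g in genome.genes}
    for cb in builders:
        for planted in cb.genes:
            gene = by_id.get(planted["gene_id"])
            if gene is None:
                raise AssertionError(
                    f"audit: planted gene {planted['gene_id']} missing after "
                    "re-reading"
                )
            if gene.protein != planted["protein"]:
                raise AssertionError(
                    f"audit: protein mismatch for {planted['gene_id']}"
                )


@dataclass
class RecoveryReport:
    """Recovery of planted truth by the pipeline, all rates in [0, 1]."""

    flag_recall: float
    flag_precision: float
    boundary_exactness: float
    family_pair_agreement: float
    n_truth_positive: int
    n_flagged: int
    notices: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_recovery(
    regions: Sequence[BGCRegion],
    families,
    truth: SimTruth,
    run_id: Optional[str] = None,
) -> RecoveryReport:
    """Score pipeline output against planted truth.

    ``families`` should be the refined families *before* genus filtering, so
    that single-genus planted families still count toward pair agreement.
    Precision with zero flagged regions is reported as 1.0 with a notice.
    """
    if run_id is not None and run_id != truth.run_id:
        raise ValueError(
            f"run id mismatch: output {run_id} vs truth {truth.run_id}"
        )
    notices: list[str] = []
    positives = [p for p in truth.plants if p.expected_flagged]
    flagged = [r for r in regions if r.flagged]

    def overlaps(region: BGCRegion, plant: PlantTruth) -> bool:
        if region.assembly_id != plant.assembly_id:
            return False
        if region.contig_id != plant.contig_id:
            return False
        rs, re_ = region.interval
        ps, pe = plant.interval
        return rs < pe and ps < re_

    match: dict[str, BGCRegion] = {}
    for plant in positives:
        for region in flagged:
            if overlaps(region, plant):
                match[plant.plant_id] = region
                break
    recall = len(match) / len(positives) if positives else 1.0
    if not positives:
        notices.append("no truth positives")

    true_flagged = sum(
        1 for r in flagged if any(overlaps(r, p) for p in positives)
    )
    if flagged:
        precision = true_flagged / len(flagged)
    else:
        precision = 1.0
        notices.append("no regions flagged; precision reported as 1.0")

    exact = sum(
        1
        for pid, region in match.items()
        if set(region.genes)
        == set(next(p for p in positives if p.plant_id == pid).gene_ids)
    )
    boundary = exact / len(match) if match else 0.0
    if not match:
        notices.append("no recovered plants; boundary exactness reported as 0.0")

    fam_of: dict[str, str] = {}
    for fam in families or []:
        for region in fam.members:
            fam_of[region.region_id] = fam.family_id
    pairs = 0
    agree = 0
    for i, p1 in enumerate(positives):
        for p2 in positives[i + 1:]:
            if p1.family_label != p2.family_label:
                continue
            pairs += 1
            r1 = match.get(p1.plant_id)
            r2 = match.get(p2.plant_id)
            if (
                r1 is not None
                and r2 is not None
                and fam_of.get(r1.region_id) is not None
                and fam_of.get(r1.region_id) == fam_of.get(r2.region_id)
            ):
                agree += 1
    agreement = agree / pairs if pairs else 1.0
    if not pairs:
        notices.append("no same-family truth pairs")

    return RecoveryReport(
        flag_recall=recall,
        flag_precision=precision,
        boundary_exactness=boundary,
        family_pair_agreement=agreement,
        n_truth_positive=len(positives),
        n_flagged=len(flagged),
        notices=notices,
    )
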