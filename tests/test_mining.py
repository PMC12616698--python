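"""Core-enzyme detection, region assembly, boundary trimming, resistance screen."""

import random

import numpy as np
import pytest

from resmine.genome_io import Contig, GeneModel, GenomeRecord
from resmine.homology import build_duplication_index
from resmine.mining import (
    BGCRegion,
    assemble_regions,
    build_occurrence_index,
    delineate_boundaries,
    detect_core_genes,
    read_core_reference,
    builtin_core_reference_path,
    resistance_screen,
)
from resmine.synth import mutate_protein, random_protein


@pytest.fixture(scope="module")
def core_refs():
    return read_core_reference(builtin_core_reference_path())


def make_genome(protein_plan, assembly="asm", gap=3000):
    """One-contig genome; protein_plan is [(gene_id, protein)] in order."""
    genes = []
    pos = 1000
    for gid, prot in protein_plan:
        end = pos + 3 * len(prot) + 3
        genes.append(GeneModel(gid, "c1", (pos, end), "+", [(pos, end)], prot))
        pos = end + gap
    return GenomeRecord(
        assembly, "org", "Genus", "Class", [Contig("c1", "A" * (pos + 1000))],
        genes,
    )


class TestDetectCoreGenes:
    def test_mutated_core_is_detected_with_its_class(self, core_refs):
        ref = next(r for r in core_refs if r[1] == "HR-PKS")
        rng = np.random.default_rng(1)
        genome = make_genome(
            [("core1", mutate_protein(ref[2], 70.0, 4)),
             ("bg1", random_protein(rng, 250))]
        )
        found = dict(detect_core_genes(genome, core_refs))
        assert set(found) == {"core1"}
        assert found["core1"].core_class == "HR-PKS"

    def test_fusion_gene_is_called_pks_nrps(self, core_refs):
        pks = next(r for r in core_refs if r[1] == "HR-PKS")[2]
        nrps = next(r for r in core_refs if r[1] == "NRPS")[2]
        genome = make_genome([("fusion", mutate_protein(pks + nrps, 80.0, 5))])
        found = dict(detect_core_genes(genome, core_refs))
        assert found["fusion"].core_class == "PKS-NRPS"
        assert len(found["fusion"].evidence) == 2

    def test_unlabeled_reference_header_is_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">ref1 no class tag here\n" + "M" * 60 + "\n")
        with pytest.raises(ValueError, match="class="):
            read_core_reference(path)


class TestAssembleRegions:
    def _core_sig(self, core_refs, genome, gene_id):
        return dict(detect_core_genes(genome, core_refs))[gene_id]

    def test_core_with_three_tight_neighbors_each_side(self, core_refs):
        ref = next(r for r in core_refs if r[1] == "NRPS")
        rng = np.random.default_rng(2)
        plan = [(f"n{i}", random_protein(rng, 150)) for i in range(3)]
        plan += [("core", mutate_protein(ref[2], 75.0, 6))]
        plan += [(f"m{i}", random_protein(rng, 150)) for i in range(3)]
        genome = make_genome(plan, gap=500)
        cores = detect_core_genes(genome, core_refs)
        regions = assemble_regions(genome, cores)
        assert len(regions) == 1
        assert regions[0].genes == ["n0", "n1", "n2", "core", "m0", "m1", "m2"]

    def test_two_nearby_cores_merge_into_one_region(self, core_refs):
        ref = next(r for r in core_refs if r[1] == "NRPS")
        rng = np.random.default_rng(3)
        plan = [
            ("coreA", mutate_protein(ref[2], 75.0, 7)),
            ("x0", random_protein(rng, 150)),
            ("x1", random_protein(rng, 150)),
            ("coreB", mutate_protein(ref[2], 75.0, 8)),
        ]
        genome = make_genome(plan, gap=500)
        cores = detect_core_genes(genome, core_refs)
        regions = assemble_regions(genome, cores)
        assert len(regions) == 1
        assert set(regions[0].cores) == {"coreA", "coreB"}

    def test_large_gap_blocks_extension(self, core_refs):
        ref = next(r for r in core_refs if r[1] == "NRPS")
        rng = np.random.default_rng(4)
        genome = make_genome(
            [("far", random_protein(rng, 150)),
             ("core", mutate_protein(ref[2], 75.0, 9))],
            gap=20000,
        )
        cores = detect_core_genes(genome, core_refs)
        regions = assemble_regions(genome, cores, max_gap_bp=10000)
        assert regions[0].genes == ["core"]

    def test_cores_on_different_contigs_stay_separate(self, core_refs):
        ref = next(r for r in core_refs if r[1] == "NRPS")
        c1 = make_genome([("coreA", mutate_protein(ref[2], 75.0, 10))])
        gene_b = GeneModel(
            "coreB", "c2", (1000, 1000 + 3 * len(c1.genes[0].protein) + 3), "+",
            [(1000, 1000 + 3 * len(c1.genes[0].protein) + 3)],
            mutate_protein(ref[2], 75.0, 11),
        )
        genome = GenomeRecord(
            "asm", "org", "Genus", "Class",
            c1.contigs + [Contig("c2", "A" * 10000)],
            c1.genes + [gene_b],
        )
        cores = detect_core_genes(genome, core_refs)
        regions = assemble_regions(genome, cores)
        assert len(regions) == 2
        assert {r.contig_id for r in regions} == {"c1", "c2"}

    def test_output_independent_of_core_input_order(self, core_refs):
        ref = next(r for r in core_refs if r[1] == "NRPS")
        rng = np.random.default_rng(5)
        plan = [(f"g{i}", random_protein(rng, 150)) for i in range(4)]
        plan.insert(1, ("coreA", mutate_protein(ref[2], 75.0, 12)))
        plan.insert(4, ("coreB", mutate_protein(ref[2], 75.0, 13)))
        genome = make_genome(plan, gap=500)
        cores = detect_core_genes(genome, core_refs)
        shuffled = list(cores)
        random.Random(0).shuffle(shuffled)
        a = assemble_regions(genome, cores)
        b = assemble_regions(genome, shuffled)
        assert [(r.region_id, r.genes) for r in a] == [
            (r.region_id, r.genes) for r in b
        ]


class TestOccurrenceIndex:
    def _genomes(self, rng):
        shared = random_protein(rng, 200)
        partial = random_protein(rng, 220)
        genomes = []
        for i in range(5):
            plan = [(f"a{i}_shared", mutate_protein(shared, 90.0, 50 + i))]
            if i < 3:  # partial in genomes 0..2
                plan.append((f"a{i}_part", mutate_protein(partial, 90.0, 60 + i)))
            plan.append((f"a{i}_uniq", random_protein(rng, 180)))
            genomes.append(make_genome(plan, assembly=f"asm{i}"))
        return genomes

    def test_fractions_match_planted_presence(self):
        rng = np.random.default_rng(6)
        genomes = self._genomes(rng)
        index = build_occurrence_index(genomes)
        assert index["a0_shared"] == 1.0  # in all 4 other genomes
        assert index["a0_uniq"] == 0.0
        assert index["a0_part"] == pytest.approx(0.5)  # 2 of 4 others

    def test_single_genome_is_hard_error(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="boundary trimming"):
            build_occurrence_index([make_genome([("g", random_protein(rng, 100))])])


def region_from(genome, gene_ids, cores=None, hook_hits=None):
    models = [g for g in genome.genes if g.gene_id in set(gene_ids)]
    models.sort(key=lambda g: g.start)
    return BGCRegion(
        region_id="r1",
        assembly_id=genome.assembly_id,
        contig_id=models[0].contig_id,
        interval=(models[0].start, max(g.end for g in models)),
        genes=[g.gene_id for g in models],
        gene_models=models,
        cores=cores or {},
        hook_hits=hook_hits or {},
    )


class TestDelineateBoundaries:
    def _setup(self, core_refs):
        ref = next(r for r in core_refs if r[1] == "NRPS")
        rng = np.random.default_rng(8)
        plan = [
            ("flankL", random_protein(rng, 150)),
            ("inner1", random_protein(rng, 150)),
            ("core", mutate_protein(ref[2], 75.0, 14)),
            ("inner2", random_protein(rng, 150)),
            ("flankR", random_protein(rng, 150)),
        ]
        genome = make_genome(plan, gap=500)
        cores = dict(detect_core_genes(genome, core_refs))
        return genome, {"core": cores["core"]}

    def test_ubiquitous_flanks_are_trimmed(self, core_refs):
        genome, cores = self._setup(core_refs)
        region = region_from(genome, [g.gene_id for g in genome.genes], cores)
        occ = {"flankL": 1.0, "inner1": 0.1, "core": 0.2, "inner2": 0.0,
               "flankR": 1.0}
        trimmed = delineate_boundaries(region, occ)
        assert trimmed.genes == ["inner1", "core", "inner2"]
        assert trimmed.interval[0] > region.interval[0]

    def test_all_rare_genes_leave_region_unchanged(self, core_refs):
        genome, cores = self._setup(core_refs)
        region = region_from(genome, [g.gene_id for g in genome.genes], cores)
        occ = {g: 0.1 for g in region.genes}
        assert delineate_boundaries(region, occ).genes == region.genes

    def test_trimming_is_idempotent_and_stops_at_rare_gene(self, core_refs):
        genome, cores = self._setup(core_refs)
        region = region_from(genome, [g.gene_id for g in genome.genes], cores)
        occ = {"flankL": 0.8, "inner1": 0.2, "core": 0.9, "inner2": 0.9,
               "flankR": 0.8}
        once = delineate_boundaries(region, occ)
        # widely distributed inner2 is trimmed too; the core stops trimming
        assert once.genes == ["inner1", "core"]
        twice = delineate_boundaries(once, occ)
        assert twice.genes == once.genes

    def test_core_and_hook_genes_are_protected(self, core_refs):
        genome, cores = self._setup(core_refs)
        region = region_from(genome, [g.gene_id for g in genome.genes], cores)
        occ = {g: 1.0 for g in region.genes}
        trimmed = delineate_boundaries(region, occ)
        assert "core" in trimmed.genes


class TestResistanceScreen:
    def _genome_with_hook(self, panel, core_refs, outside_copies):
        ref = next(r for r in core_refs if r[1] == "HR-PKS")
        hook = panel.hooks[0]
        rng = np.random.default_rng(9)
        plan = [
            ("f1", random_protein(rng, 150)),
            ("core", mutate_protein(ref[2], 70.0, 15)),
            ("hookgene", mutate_protein(hook.sequence, 70.0, 16)),
            ("f2", random_protein(rng, 150)),
        ]
        for k in range(outside_copies):
            plan.append((f"dup{k}", mutate_protein(hook.sequence, 80.0, 20 + k)))
        genome = make_genome(plan, gap=500)
        cores = dict(detect_core_genes(genome, core_refs))
        region = region_from(
            genome, ["f1", "core", "hookgene", "f2"], {"core": cores["core"]}
        )
        index = build_duplication_index(genome, panel)
        return genome, region, index

    def test_hook_plus_outside_copy_flags_region(self, panel, core_refs):
        genome, region, index = self._genome_with_hook(panel, core_refs, 1)
        out = resistance_screen(region, genome, panel, index)
        assert out.flagged
        assert out.hook_hits["hookgene"].outside_copies == 1
        assert out.hook_hits["hookgene"].hook_id == panel.hooks[0].hook_id

    def test_hook_without_outside_copy_is_not_flagged(self, panel, core_refs):
        genome, region, index = self._genome_with_hook(panel, core_refs, 0)
        out = resistance_screen(region, genome, panel, index)
        assert not out.flagged
        assert out.hook_hits["hookgene"].outside_copies == 0

    def test_two_outside_copies_counted(self, panel, core_refs):
        genome, region, index = self._genome_with_hook(panel, core_refs, 2)
        out = resistance_screen(region, genome, panel, index)
        assert out.hook_hits["hookgene"].outside_copies == 2

    def test_flagged_region_invariant_holds(self, panel, core_refs):
        genome, region, index = self._genome_with_hook(panel, core_refs, 1)
        out = resistance_screen(region, genome, panel, index)
        out.validate()  # flagged => some hook hit with outside_copies >= 1
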