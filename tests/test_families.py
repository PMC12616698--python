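"""BGC similarity, single-linkage families, refinement, genus filter, taxonomy."""

import random

import numpy as np
import pytest

from resmine.families import (
    Family,
    bgc_similarity,
    cluster_families,
    drop_single_genus,
    family_table,
    families_from_assignments,
    refine_families,
    taxonomy_summary,
)
from resmine.genome_io import Contig, GeneModel, GenomeRecord
from resmine.mining import BGCRegion, CoreSignature, HookHit
from resmine.homology import AlignmentHit
from resmine.synth import mutate_protein, random_protein


def make_region(region_id, proteins, genus="Aspergillus",
                tclass="Eurotiomycetes", hook_id=None, core_classes=("NRPS",),
                assembly="asm"):
    """Region with one gene per protein; first len(core_classes) genes are cores."""
    models = []
    pos = 1000
    for i, prot in enumerate(proteins):
        end = pos + 3 * len(prot)
        models.append(
            GeneModel(f"{region_id}_g{i}", "c1", (pos, end), "+", [(pos, end)],
                      prot)
        )
        pos = end + 500
    fake_hit = AlignmentHit(
        "q", "t", 100, 80.0, 1.0, 1.0, (0, 10), (0, 10)
    )
    cores = {
        models[i].gene_id: CoreSignature(cc, (fake_hit,))
        for i, cc in enumerate(core_classes)
    }
    hook_hits = {}
    if hook_id is not None:
        hook_hits[models[-1].gene_id] = HookHit(hook_id, fake_hit, 1)
    return BGCRegion(
        region_id=region_id,
        assembly_id=assembly,
        contig_id="c1",
        interval=(models[0].start, models[-1].end),
        genes=[m.gene_id for m in models],
        gene_models=models,
        cores=cores,
        hook_hits=hook_hits,
        flagged=bool(hook_hits),
        genus=genus,
        taxonomic_class=tclass,
    )


@pytest.fixture(scope="module")
def base_proteins():
    rng = np.random.default_rng(2718)
    return [random_protein(rng, 120) for _ in range(6)]


class TestBgcSimilarity:
    def test_region_vs_itself_is_one(self, base_proteins):
        r = make_region("ra", base_proteins[:4])
        sim = bgc_similarity(r, r)
        assert sim.combined == pytest.approx(1.0)
        assert sim.jaccard == 1.0 and sim.adjacency == 1.0 and sim.identity == 1.0

    def test_disjoint_regions_score_zero(self, base_proteins):
        rng = np.random.default_rng(11)
        r1 = make_region("ra", base_proteins[:3])
        r2 = make_region("rb", [random_protein(rng, 110) for _ in range(3)])
        sim = bgc_similarity(r1, r2)
        assert sim.combined == 0.0

    def test_reversed_gene_order_is_still_perfect(self, base_proteins):
        r1 = make_region("ra", base_proteins[:4])
        r2 = make_region("rb", list(reversed(base_proteins[:4])))
        sim = bgc_similarity(r1, r2)
        assert sim.jaccard == 1.0
        assert sim.adjacency == 1.0  # unordered adjacent pairs preserved
        assert sim.combined == pytest.approx(1.0)

    def test_weights_must_sum_to_one(self, base_proteins):
        r = make_region("ra", base_proteins[:3])
        with pytest.raises(ValueError, match="sum to 1"):
            bgc_similarity(r, r, weights=(0.5, 0.5, 0.5))


class TestClusterFamilies:
    def test_similar_pair_forms_one_family(self, base_proteins):
        r1 = make_region("ra", base_proteins[:4])
        r2 = make_region(
            "rb", [mutate_protein(p, 90.0, i) for i, p in
                   enumerate(base_proteins[:4])]
        )
        fams = cluster_families([r1, r2])
        assert len(fams) == 1
        assert len(fams[0]) == 2

    def test_chain_a_b_c_coclusters_via_single_linkage(self, base_proteins):
        """a~b and b~c pass the cutoff, a~c does not; the chain still joins."""
        p = base_proteins
        rb = make_region("rb", p[:6])
        ra = make_region(
            "ra", [mutate_protein(x, 95.0, i) for i, x in enumerate(p[:4])]
        )
        rc = make_region(
            "rc", [mutate_protein(x, 95.0, 10 + i) for i, x in enumerate(p[2:6])]
        )
        sim_ab = bgc_similarity(ra, rb).combined
        sim_bc = bgc_similarity(rb, rc).combined
        sim_ac = bgc_similarity(ra, rc).combined
        assert sim_ab >= 0.7 and sim_bc >= 0.7 and sim_ac < 0.7
        fams = cluster_families([ra, rb, rc], distance_cutoff=0.3)
        assert len(fams) == 1
        assert len(fams[0]) == 3

    def test_dissimilar_regions_stay_singletons(self, base_proteins):
        rng = np.random.default_rng(13)
        regions = [
            make_region(f"r{i}", [random_protein(rng, 100) for _ in range(3)])
            for i in range(3)
        ]
        fams = cluster_families(regions)
        assert len(fams) == 3
        assert all(len(f) == 1 for f in fams)

    def test_invariant_under_input_permutation(self, base_proteins):
        p = base_proteins
        regions = [
            make_region("ra", p[:4]),
            make_region("rb", [mutate_protein(x, 90.0, i) for i, x in
                               enumerate(p[:4])]),
            make_region("rc", p[3:6]),
        ]
        fams1 = cluster_families(regions)
        shuffled = list(regions)
        random.Random(1).shuffle(shuffled)
        fams2 = cluster_families(shuffled)
        sig1 = [(f.family_id, [r.region_id for r in f.members]) for f in fams1]
        sig2 = [(f.family_id, [r.region_id for r in f.members]) for f in fams2]
        assert sig1 == sig2


class TestRefineFamilies:
    def test_mixed_core_classes_split(self, base_proteins):
        r1 = make_region("ra", base_proteins[:3], core_classes=("HR-PKS",),
                         hook_id="HK01")
        r2 = make_region("rb", base_proteins[:3], core_classes=("NRPS",),
                         hook_id="HK01")
        fams = refine_families([Family.from_members("fam001", [r1, r2])])
        assert len(fams) == 2

    def test_mixed_hooks_split(self, base_proteins):
        r1 = make_region("ra", base_proteins[:3], hook_id="HK_ALS")
        r2 = make_region("rb", base_proteins[:3], hook_id="HK_IMPDH")
        fams = refine_families([Family.from_members("fam001", [r1, r2])])
        assert len(fams) == 2
        assert {f.hook_signature for f in fams} == {"HK_ALS", "HK_IMPDH"}

    def test_homogeneous_family_unchanged_and_idempotent(self, base_proteins):
        rs = [
            make_region(f"r{i}", base_proteins[:3], hook_id="HK01")
            for i in range(3)
        ]
        fams = [Family.from_members("fam001", rs)]
        once = refine_families(fams)
        assert len(once) == 1
        assert [r.region_id for r in once[0].members] == [
            r.region_id for r in rs
        ]
        twice = refine_families(once)
        assert [(f.family_id, len(f)) for f in twice] == [
            (f.family_id, len(f)) for f in once
        ]

    def test_refinement_never_merges(self, base_proteins):
        f1 = Family.from_members(
            "fam001", [make_region("ra", base_proteins[:3], hook_id="HK01")]
        )
        f2 = Family.from_members(
            "fam002", [make_region("rb", base_proteins[:3], hook_id="HK01")]
        )
        assert len(refine_families([f1, f2])) == 2


class TestGenusFilterAndTaxonomy:
    def test_single_genus_family_dropped(self, base_proteins):
        fam = Family.from_members(
            "fam001",
            [make_region(f"r{i}", base_proteins[:3], genus="Aspergillus")
             for i in range(3)],
        )
        assert drop_single_genus([fam]) == []

    def test_multi_genus_family_kept(self, base_proteins):
        fam = Family.from_members(
            "fam001",
            [
                make_region("ra", base_proteins[:3], genus="Aspergillus"),
                make_region("rb", base_proteins[:3], genus="Hypoxylon",
                            tclass="Sordariomycetes"),
            ],
        )
        kept = drop_single_genus([fam])
        assert len(kept) == 1
        assert kept[0].genera == {"Aspergillus", "Hypoxylon"}

    def test_taxonomy_counts_and_conservation(self, base_proteins):
        members = [
            make_region(f"s{i}", base_proteins[:3], genus="Fusarium",
                        tclass="Sordariomycetes")
            for i in range(4)
        ] + [
            make_region(f"e{i}", base_proteins[:3], genus="Aspergillus",
                        tclass="Eurotiomycetes")
            for i in range(2)
        ]
        fams = [
            Family.from_members("fam001", members[:3]),
            Family.from_members("fam002", members[3:]),
        ]
        table, totals = taxonomy_summary(fams)
        assert totals["Sordariomycetes"] == 4
        assert totals["Eurotiomycetes"] == 2
        assert table.values.sum() == sum(len(f) for f in fams)

    def test_family_table_and_external_assignments(self, base_proteins):
        r1 = make_region("ra", base_proteins[:3], hook_id="HK01")
        r2 = make_region("rb", base_proteins[:3], hook_id="HK01")
        fams = families_from_assignments([r1, r2], {"ra": "F1", "rb": "F1"})
        assert len(fams) == 1
        tab = family_table(fams)
        assert tab.loc[0, "n_members"] == 2
        with pytest.raises(ValueError, match="ra"):
            families_from_assignments([r1], {})
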