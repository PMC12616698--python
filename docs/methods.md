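# Methods

## The self-resistance screen

Secondary-metabolite BGCs that encode a resistant variant of their product's
target protein tend to carry that variant *in addition to* the genome's
essential housekeeping copy. `resmine` operationalizes this as two
requirements on a candidate region: (i) some member gene is a close homologue
of a hook (conserved housekeeping) protein, and (ii) the genome carries at
least one further qualifying homologue of that hook outside the region. The
in-cluster copy itself does not count toward duplication — the biological
argument needs an essential copy *beyond* the cluster, and counting the
cluster copy would flag every hook homologue trivially. Whether the original
tool counts the in-cluster copy is not documented; this package's rule is the
stricter reading and is stated here as its own design choice.

"Close homologue" is ≥ 50% identity with ≥ 70% coverage of the hook; both
thresholds are configuration (`hook_min_identity`, `hook_min_coverage`), not
biological constants, and were chosen so that planted homologues at 60–80%
identity pass comfortably while unrelated proteins and generic paralogs do
not.

## Alignment engine

Local alignment is Gotoh's affine-gap Smith–Waterman over BLOSUM62 (BLOSUM45
selectable, or any NCBI-format matrix file). A gap of length *k* costs
`gap_open + (k−1)·gap_extend`, defaults 11/1. The unknown residue `X`
(ambiguous codons) scores 0 against everything, so it neither rewards nor
punishes. The traceback is fully deterministic: ties prefer the diagonal
move, then a gap in the target, then a gap in the query, and among equal-
scoring end cells the smallest row, then column, wins. Percent identity is
identical columns over all alignment columns (gaps included); coverage is
aligned span over sequence length, per side. The fill runs as a numba kernel;
correctness is pinned in the tests against a plain-Python full-matrix oracle
(200 random pairs, exact score equality) and against Biopython's
`PairwiseAligner` in local mode with the same gap convention.

An optional 4-mer shared-seed prefilter exists for panel search but is off by
default (and in all tests): it is not guaranteed lossless at low identity.

## Core-enzyme detection and region assembly

Core scaffold-building enzymes are detected by similarity to a shipped
reference FASTA whose headers carry `class=` tags (HR-PKS, NR-PKS, NRPS,
NRPS-like, terpene_synthase, prenyltransferase), at defaults 30% identity and
50% reference coverage. A gene with qualifying hits to both a PKS and an NRPS
reference on query segments overlapping < 20% of either segment is called a
PKS–NRPS hybrid. The bundled references are synthetic sequences sized like
the fungal enzymes they stand for (300–430 aa); real mining should substitute
curated references. Profile/HMM detection is a possible later extension; the
original tool's detection models are unpublished, so this similarity rule is
a declared substitute, not a reconstruction.

Each core seeds a window extended gene-by-gene in both directions, adding at
most `max_intergenes = 4` genes per side and never across an intergenic gap
larger than `max_gap_bp = 10 kb`; overlapping windows merge. The defaults
keep typical fungal clusters (≤ ~15 genes) intact while preventing runaway
windows through gene-dense background; both are configuration.

## Boundary trimming by cross-genome occurrence

Genuine cluster genes occur in few genomes; flanking housekeeping genes occur
in most. For each region member gene the occurrence index is the fraction of
the *other* input genomes containing a homologue at 50% identity and 60%
coverage of both sequences. From each region flank inward, genes at
occurrence ≥ 0.5 are removed until the first gene below the cutoff; core
genes and hook-hit genes are never removed and stop trimming. The operation
is idempotent. Single-genome runs skip trimming (occurrence is undefined) and
say so in the report. The index is computed only for region member genes —
computing it for every gene in every genome would be quadratic waste.

## Gene-cluster families

Two regions are compared on genes matched by reciprocal best hits at ≥ 40%
identity: `combined = 0.3·Jaccard + 0.2·adjacency + 0.5·identity`, where
Jaccard is over matched genes, adjacency is the Jaccard of unordered adjacent
matched pairs (so gene-order reversal is still a perfect match), and identity
is the mean matched-pair identity. Families are single-linkage components at
distance `1 − combined ≤ 0.3`. Weights and cutoff are configuration; they are
this package's in-repo replacement for external cluster-family tools, and an
adapter imports an externally computed assignment for parity runs. Families
are then partitioned so every family shares one core-class multiset and one
best hook, and families whose members all come from one genus are dropped as
probable lineage-specific false positives. Family numbering is deterministic
(ordered by smallest member region id) and run-specific.

Degenerate cases: two single-gene regions have no adjacent pairs; adjacency
is defined as 1 when both regions are fully matched, else 0. Regions with no
matched genes score 0 overall.

## Synthetic studies

The generator emits FASTA + GFF3 + taxon TSV + truth JSON per genome, fully
determined by one seed. Planted clusters are five genes — two fillers, a core
enzyme, a hook homologue (true/no-duplicate kinds), one more filler —
bracketed by two "common" genes present in (almost) all genomes, which give
the high-occurrence flanks that boundary trimming should remove, and isolated
by ≥ 15 kb spacers so window extension stops at the cluster edge. Outside
hook copies are placed ≥ 50 kb downstream or on a second contig, guaranteeing
non-overlap with any assembled region under default window parameters. Decoy
kinds cover the three failure modes of the screen: hook without duplicate,
duplicate without in-cluster hook, and no hook at all.

Members of one planted family descend from a common ancestral cluster:
fillers are 90%-identity mutants of a family prototype, and the hook and core
homologues form a descent chain — the member with the highest
identity-to-hook target is mutated from the hook itself, each further member
from the previous one by just enough substitutions to reach its own target.
This keeps cross-member identity high (roughly the ratio of the targets), as
it is between homologous clusters in real congeneric genomes, while each
member sits at its planted distance from the hook.

The default study is 5 genomes across three genera and two taxonomic classes
(2× *Aspergillus*/Eurotiomycetes, 2× *Hypoxylon*/Sordariomycetes, 1×
*Calonectria*/Sordariomycetes), 16 background genes per genome plus 4 common
genes, 4 true resistant BGCs with hook identities drawn from 60–80% (one
two-genus family, one single-genus family that the genus filter should drop),
and 3 decoys of each kind. Proteins are reverse-translated with uniformly
random synonymous codons; planted core and hook genes carry one intron each
to exercise spliced translation; background genes are intron-free. A
self-audit re-reads every generated genome through the package's own readers
and verifies planted proteins round-trip exactly.

What the generator does *not* emulate: codon bias, nucleotide-level mutation
processes, synteny decay, transposons, pseudogenes, annotation errors, and
hook families with deep paralog structure. Perfect recovery on synthetic
studies therefore demonstrates that the rules are implemented correctly and
separate the planted signal classes, not that the thresholds are optimal for
real Pezizomycotina assemblies.

## Determinism and problem sizes

All randomness flows from explicit seeds (one per synthetic config; the
pipeline itself is deterministic). Reports carry no timestamps in
`report.json` — timestamps live in the MANIFEST — so identical runs are
byte-identical, which the tests assert. The shipped study sizes (5–6 genomes,
~45 genes per genome, proteins ≤ ~850 aa) were chosen so a full end-to-end
run completes in seconds on a single CPU while still exercising every stage
on multi-copy, multi-contig, multi-genus inputs.

## Known limitations

* Annotated assemblies only; no ab initio gene prediction, no isoform
  handling (first transcript per gene wins).
* Similarity-based core detection will miss core enzymes diverged below the
  identity threshold and cannot distinguish subclasses the reference set
  lacks.
* The duplication rule counts gene copies, not functionality: a pseudogenized
  outside copy still satisfies it.
* Occurrence-based trimming assumes the input genome set is taxonomically
  broad enough that housekeeping flanks really are widespread; with few,
  closely related genomes it under-trims.
* E-value statistics, profile search, and RiPP cluster detection are out of
  scope.
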