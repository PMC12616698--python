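# resmine — resistance-gene-guided mining of fungal biosynthetic gene clusters

Fungi that synthesize a toxic natural product often protect themselves by
carrying, *inside* the product's biosynthetic gene cluster (BGC), an extra
copy of the very housekeeping gene the product inhibits — a **self-resistance
gene**. That genetic signature can be read the other way around: if a BGC
encodes a close homologue of a conserved housekeeping protein, *and* the
genome carries at least one additional copy of that protein elsewhere (the
cell's essential copy), the cluster likely produces an inhibitor of that
protein. Finding such clusters turns genome sequence directly into bioactivity
hypotheses: the resistance gene names the drug target before any compound has
been isolated.

`resmine` implements this screen for annotated fungal genome assemblies:

1. **Genome I/O** — FASTA + GFF3 pairs or GenBank flat files in, per-region
   GenBank out (`resmine.genome_io`).
2. **Hook panel** — the conserved housekeeping "bait" proteins
   (`resmine.hook_panel`); a panel can also be *built* from a reference
   proteome by reciprocal-best-hit conservation across comparator proteomes.
3. **Homology** — affine-gap Smith–Waterman local alignment (BLOSUM62 by
   default) with a genome-wide duplication index (`resmine.homology`).
4. **Mining** — core-enzyme detection (HR-PKS, NR-PKS, PKS–NRPS, NRPS,
   NRPS-like, terpene synthase, prenyltransferase), cluster-window assembly,
   occurrence-based boundary trimming, and the resistance screen
   (`resmine.mining`).
5. **Families** — flagged BGCs are grouped across genomes into gene-cluster
   families by gene content, adjacency and identity, refined to share one
   core signature and one hook, and filtered to families spanning ≥2 genera
   (`resmine.families`).
6. **Synthetic studies** — a deterministic generator that plants true
   resistant BGCs and three kinds of decoys into simulated genomes, with
   machine-readable ground truth (`resmine.synth`).

## The screen, precisely

For a candidate region *R* on contig *c* and a hook protein *h*, let
*S(g, h)* be the optimal local alignment (affine gaps: a gap of length *k*
costs `gap_open + (k−1)·gap_extend`, defaults 11/1). Gene *g* is a **hook
homologue** when percent identity ≥ 50 and the aligned span covers ≥ 70% of
*h*. *R* is **flagged** iff it contains a hook homologue *g* of some *h* and
the genome contains ≥ 1 further homologue of *h* whose gene interval lies
outside *R* (a different contig always counts as outside).

Families use the similarity
`combined = 0.3·Jaccard + 0.2·adjacency + 0.5·identity` over genes matched
between two regions by reciprocal best hits at ≥ 40% identity, with
single-linkage components at distance `1 − combined ≤ 0.3`.

## Worked example

Simulate the default five-genome study (three genera, four true resistant
BGCs at 60–80% hook identity, nine decoys), mine it, and score recovery:

```bash
resmine simulate --seed 3 --out sim/
resmine mine --config run.yaml        # points at sim/*.fna, sim/*.gff3
resmine evaluate --report run/report.json --truth sim/truth.json
```

`mine` prints:

```
13 regions, 4 flagged, 1 families after filtering -> run/
```

All 13 planted clusters are assembled as candidate regions; exactly the 4
true resistant BGCs pass the duplication rule (none of the 9 decoys does),
and after refinement and genus filtering one family survives — the planted
two-genus family. The first flagged row of `run/regions.tsv`:

```
region_id            n_genes core_classes hook_id hook_identity outside_copies flagged genus
SYN01.SYN01_ctg1.r1  5       HR-PKS       HK01    62.11         2              True    Aspergillus
```

reads: a five-gene cluster with an HR-PKS core encodes a homologue of hook
HK01 (a synthetic acetolactate-synthase bait) at 62% identity, and the genome
carries two more HK01 copies outside the cluster — the self-resistance
signature. `evaluate` reports flag recall 1.0, flag precision 1.0, boundary
exactness 1.0 and family-pair agreement 1.0 for this run.

`run/report.html` renders the surviving families as cards with gene-arrow
diagrams (cores red, hook homologues blue) and the hook annotation text.

## Scope and caveats

The bundled hook panel and core-enzyme references are **synthetic** sequences
for offline, self-contained operation; for real mining supply your own panel
FASTA + metadata TSV (e.g. a conserved-proteome panel built with
`resmine build-panel`) and curated core-enzyme references. Input genomes must
be annotated — `resmine` does no gene prediction. See `docs/methods.md` for
the model, parameter defaults, and known limitations.
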