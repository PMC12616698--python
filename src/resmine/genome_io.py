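"""Annotated-genome input/output.

Reads FASTA+GFF3 pairs or GenBank flat files into an in-memory genome model
(contigs, gene models, proteins, taxon labels) and writes flagged BGC
subregions back out as GenBank records. Coordinates are 0-based half-open
internally; GFF3 and GenBank I/O convert from/to the 1-based inclusive
conventions of those formats.

Only the first transcript per gene is used (fungal annotations in this
problem are effectively one-isoform); genes whose spliced CDS length is not a
multiple of 3 are skipped with a warning rather than aborting a whole-genome
run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_NUC = set("ACGTN")


@dataclass
class Contig:
    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _NUC
        if bad:
            raise ValueError(
                f"contig {self.contig_id}: illegal nucleotides {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One protein-coding gene: genomic interval, exon structure, protein."""

    gene_id: str
    contig_id: str
    interval: tuple[int, int]
    strand: str
    exons: list[tuple[int, int]]
    protein: str
    product: str = ""

    def __post_init__(self) -> None:
        s, e = self.interval
        if not (0 <= s < e):
            raise ValueError(f"gene {self.gene_id}: bad interval {self.interval}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exons = sorted(self.exons)
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if b1 > a2:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for a, b in exons:
            if a < s or b > e:
                raise ValueError(f"gene {self.gene_id}: exon outside interval")
        self.exons = exons
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein")

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]


@dataclass
class GenomeRecord:
    """One assembly: contigs, gene models, and taxon labels."""

    assembly_id: str
    organism: str
    genus: str
    taxonomic_class: str
    contigs: list[Contig] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.assembly_id}: duplicate gene ids")
        known = {c.contig_id for c in self.contigs}
        for g in self.genes:
            if g.contig_id not in known:
                raise ValueError(
                    f"{self.assembly_id}: gene {g.gene_id} references unknown "
                    f"contig {g.contig_id}"
                )
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


def spliced_cds(contig_seq: str, exons: list[tuple[int, int]], strand: str) -> str:
    """Concatenate exon sequences in genomic order; reverse-complement for '-'."""
    seq = "".join(contig_seq[a:b] for a, b in sorted(exons))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_cds(cds: str, phase: int = 0) -> str:
    """Translate a spliced CDS (standard table), trimming one trailing stop.

    ``phase`` bases are trimmed from the 5' end (GFF3 phase of the first
    translated segment). Ambiguous codons translate to X.
    """
    trimmed = cds[phase:]
    if len(trimmed) % 3 != 0:
        raise ValueError(f"CDS length {len(trimmed)} not divisible by 3")
    protein = str(Seq(trimmed).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def _taxon_for(assembly_id: str, taxon_metadata: Mapping[str, Mapping[str, str]]):
    meta = taxon_metadata.get(assembly_id, {})
    return (
        meta.get("organism", assembly_id),
        meta.get("genus", "unknown"),
        meta.get("class", "unknown"),
    )


def read_taxon_metadata(path) -> dict[str, dict[str, str]]:
    """Read the sidecar taxon TSV (assembly_id, organism, genus, class)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"assembly_id", "organism", "genus", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxon metadata {path}: missing columns {sorted(missing)}")
    return {
        row["assembly_id"]: {
            "organism": row["organism"],
            "genus": row["genus"],
            "class": row["class"],
        }
        for _, row in df.iterrows()
    }


def read_genome(
    fasta_path,
    gff_path,
    taxon_metadata: Mapping[str, Mapping[str, str]] | None = None,
    assembly_id: str | None = None,
) -> GenomeRecord:
    """Read a FASTA + GFF3 pair into a GenomeRecord.

    One GeneModel per gene, from its first mRNA (or the gene's own CDS children
    for bare gene+CDS annotations). The protein is derived by splicing CDS
    segments in genomic order, reverse-complementing on the minus strand and
    translating with the standard codon table, honouring the phase of the
    first translated segment.
    """
    taxon_metadata = taxon_metadata or {}
    contigs = [
        Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    contig_seqs = {c.contig_id: c.sequence for c in contigs}
    if assembly_id is None:
        import os

        assembly_id = os.path.splitext(os.path.basename(str(fasta_path)))[0]

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in contig_seqs:
            raise ValueError(
                f"feature {gene.id}: contig {gene.seqid} absent from FASTA"
            )
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            parent = mrnas[0]  # transcripts beyond the first are ignored
        else:
            parent = gene
        cds_feats = list(db.children(parent, featuretype="CDS", order_by="start"))
        if not cds_feats:
            continue
        exons = [(f.start - 1, f.end) for f in cds_feats]  # GFF3 is 1-based incl.
        strand = gene.strand if gene.strand in "+-" else "+"
        # phase of the 5'-most translated segment (last CDS for minus strand)
        phase_feat = cds_feats[0] if strand == "+" else cds_feats[-1]
        try:
            phase = int(phase_feat.frame)
        except (TypeError, ValueError):
            phase = 0
        cds = spliced_cds(contig_seqs[gene.seqid], exons, strand)
        try:
            protein = translate_cds(cds, phase)
        except ValueError as exc:
            log.warning("skipping gene %s: %s", gene.id, exc)
            continue
        if not protein:
            log.warning("skipping gene %s: empty translation", gene.id)
            continue
        product = ""
        attrs = parent.attributes if parent is not gene else gene.attributes
        if "product" in attrs:
            product = attrs["product"][0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                interval=(gene.start - 1, gene.end),
                strand=strand,
                exons=exons,
                protein=protein,
                product=product,
            )
        )
    organism, genus, tclass = _taxon_for(assembly_id, taxon_metadata)
    return GenomeRecord(assembly_id, organism, genus, tclass, contigs, genes)


def read_genbank(
    path,
    taxon_metadata: Mapping[str, Mapping[str, str]] | None = None,
    assembly_id: str | None = None,
) -> GenomeRecord:
    """Read a GenBank flat file into a GenomeRecord.

    A stored /translation qualifier is preferred over re-translation; CDS
    features lacking both a translation and a parsable location are skipped
    with a warning.
    """
    taxon_metadata = taxon_metadata or {}
    contigs: list[Contig] = []
    genes: list[GeneModel] = []
    records = list(SeqIO.parse(str(path), "genbank"))
    if assembly_id is None:
        import os

        assembly_id = os.path.splitext(os.path.basename(str(path)))[0]
    n = 0
    for rec in records:
        contigs.append(Contig(rec.id, str(rec.seq)))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            gene_id = (
                feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("gene", [None])[0]
                or f"cds_{n}"
            )
            if feat.location is None:
                log.warning("skipping CDS %s: no location", gene_id)
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            exons = sorted(
                (int(part.start), int(part.end)) for part in feat.location.parts
            )
            translation = feat.qualifiers.get("translation", [None])[0]
            if translation is None:
                cds = spliced_cds(str(rec.seq), exons, strand)
                try:
                    phase = int(feat.qualifiers.get("codon_start", ["1"])[0]) - 1
                    translation = translate_cds(cds, phase)
                except ValueError as exc:
                    log.warning("skipping CDS %s: %s", gene_id, exc)
                    continue
            if not translation:
                log.warning("skipping CDS %s: empty translation", gene_id)
                continue
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    interval=(exons[0][0], exons[-1][1]),
                    strand=strand,
                    exons=exons,
                    protein=translation,
                    product=feat.qualifiers.get("product", [""])[0],
                )
            )
    organism, genus, tclass = _taxon_for(assembly_id, taxon_metadata)
    return GenomeRecord(assembly_id, organism, genus, tclass, contigs, genes)


def extract_proteome(genome: GenomeRecord) -> dict[str, str]:
    """gene_id -> protein, one entry per gene, ordered by contig then start."""
    return {
        g.gene_id: g.protein
        for g in sorted(genome.genes, key=lambda g: (g.contig_id, g.start))
    }


def write_bgc_genbank(genome: GenomeRecord, region, path) -> None:
    """Write one BGC region as a GenBank record with re-based coordinates.

    Every member gene becomes a CDS feature with translation and product;
    core-class and hook-hit evidence, when present on the region, is emitted
    as /note qualifiers (``core_class=...``, ``hook=...``).
    """
    contig = genome.contig(region.contig_id)
    rs, re_ = region.interval
    if rs < 0 or re_ > contig.length:
        raise ValueError(
            f"region {region.region_id} interval {region.interval} outside "
            f"contig {contig.contig_id} (length {contig.length})"
        )
    sub = Seq(contig.sequence[rs:re_])
    rec = SeqRecord(
        sub,
        id=region.region_id[:16],
        name=region.region_id[:16],
        description=f"{genome.assembly_id} {region.contig_id}:{rs}-{re_}",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    by_id = {g.gene_id: g for g in genome.genes}
    cores = getattr(region, "cores", {}) or {}
    hook_hits = getattr(region, "hook_hits", {}) or {}
    for gene_id in region.genes:
        gene = by_id[gene_id]
        parts = [
            FeatureLocation(a - rs, b - rs, strand=1 if gene.strand == "+" else -1)
            for a, b in gene.exons
        ]
        if gene.strand == "-":
            parts = parts[::-1]
        location = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals = {
            "locus_tag": [gene.gene_id],
            "translation": [gene.protein],
            "codon_start": ["1"],
        }
        if gene.product:
            quals["product"] = [gene.product]
        notes = []
        if gene_id in cores:
            notes.append(f"core_class={cores[gene_id].core_class}")
        if gene_id in hook_hits:
            hh = hook_hits[gene_id]
            notes.append(
                f"hook={hh.hook_id} identity={hh.hit.percent_identity:.1f} "
                f"outside_copies={hh.outside_copies}"
            )
        if notes:
            quals["note"] = notes
        rec.features.append(SeqFeature(location, type="CDS", qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")
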