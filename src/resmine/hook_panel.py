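"""The hook-protein panel: conserved housekeeping baits for resistance mining.

A "hook" is a conserved housekeeping protein (or, optionally, a human drug
target / disease-related protein) used as a query bait: a BGC becomes a
self-resistance candidate when it encodes a close homologue of a hook. The
panel ships as an amino-acid FASTA plus a metadata TSV (hook_id, source_locus,
category, annotation); a small synthetic built-in panel is bundled for offline
runs and tests.

``build_panel`` operationalizes "highly conserved" as reciprocal-best-hit
conservation across comparator proteomes; the thresholds are configuration,
not fixed truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .homology import ScoringScheme, reciprocal_best_hits

log = logging.getLogger(__name__)

CATEGORIES = ("housekeeping", "fda_drug_target", "disease_related")

#: hooks shorter than this are rejected; identity/coverage thresholds are
#: meaningless on very short baits
MIN_HOOK_LENGTH = 50


@dataclass(frozen=True)
class HookProtein:
    hook_id: str
    source_locus: str
    category: str
    annotation: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"hook {self.hook_id}: empty sequence")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"hook {self.hook_id}: category {self.category!r} not in "
                f"{CATEGORIES}"
            )


@dataclass
class HookPanel:
    hooks: list[HookProtein]
    panel_id: str = "panel"

    def __post_init__(self) -> None:
        ids = [h.hook_id for h in self.hooks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"panel {self.panel_id}: duplicate hook ids")
        seqs = [h.sequence for h in self.hooks]
        if len(seqs) != len(set(seqs)):
            raise ValueError(f"panel {self.panel_id}: duplicate hook sequences")

    def __len__(self) -> int:
        return len(self.hooks)

    def get(self, hook_id: str) -> HookProtein:
        for h in self.hooks:
            if h.hook_id == hook_id:
                return h
        raise KeyError(hook_id)


def load_panel(fasta_path, metadata_tsv, panel_id: str = "panel") -> HookPanel:
    """Load and validate a panel from FASTA + metadata TSV.

    Every FASTA record must have a metadata row and vice versa (hard error
    listing the offending ids). Records with identical sequences are collapsed
    keeping the first id, with a logged warning. Hooks shorter than
    ``MIN_HOOK_LENGTH`` residues are rejected.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str).fillna("")
    required = {"hook_id", "source_locus", "category", "annotation"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"panel metadata: missing columns {sorted(missing_cols)}")
    meta_ids = list(meta["hook_id"])
    no_seq = [i for i in meta_ids if i not in seqs]
    no_meta = [i for i in seqs if i not in set(meta_ids)]
    if no_seq or no_meta:
        raise ValueError(
            f"panel mismatch: metadata rows without sequence {no_seq}; "
            f"sequences without metadata {no_meta}"
        )
    hooks: list[HookProtein] = []
    seen: dict[str, str] = {}
    for _, row in meta.iterrows():
        hook_id = row["hook_id"]
        seq = seqs[hook_id]
        if len(seq) < MIN_HOOK_LENGTH:
            raise ValueError(
                f"hook {hook_id}: length {len(seq)} < {MIN_HOOK_LENGTH}"
            )
        if seq in seen:
            log.warning(
                "panel %s: hook %s duplicates sequence of %s; keeping the first",
                panel_id, hook_id, seen[seq],
            )
            continue
        seen[seq] = hook_id
        hooks.append(
            HookProtein(
                hook_id=hook_id,
                source_locus=row["source_locus"],
                category=row["category"],
                annotation=row["annotation"],
                sequence=seq,
            )
        )
    return HookPanel(hooks, panel_id)


def serialize_panel(panel: HookPanel, fasta_path, metadata_tsv) -> None:
    """Write a panel back to FASTA + metadata TSV (inverse of load_panel)."""
    with open(fasta_path, "w") as fh:
        for h in panel.hooks:
            fh.write(f">{h.hook_id}\n{h.sequence}\n")
    pd.DataFrame(
        [
            {
                "hook_id": h.hook_id,
                "source_locus": h.source_locus,
                "category": h.category,
                "annotation": h.annotation,
            }
            for h in panel.hooks
        ]
    ).to_csv(metadata_tsv, sep="\t", index=False)


def builtin_panel() -> HookPanel:
    """The bundled synthetic hook panel (see data/builtin_panel.fasta)."""
    data = resources.files("resmine") / "data"
    return load_panel(
        str(data / "builtin_panel.fasta"),
        str(data / "builtin_panel.tsv"),
        panel_id="builtin-synthetic",
    )


def build_panel(
    reference_proteome: Mapping[str, str],
    comparator_proteomes: Sequence[Mapping[str, str]],
    min_identity: float = 40.0,
    min_coverage: float = 0.6,
    min_fraction: float = 0.8,
    scheme: ScoringScheme | None = None,
    panel_id: str = "built-panel",
    annotations: Mapping[str, str] | None = None,
) -> HookPanel:
    """Select conserved reference proteins as hooks by RBH conservation.

    A reference protein is kept iff it has a reciprocal best hit at
    >= ``min_identity`` percent identity and >= ``min_coverage`` coverage of
    both sequences in at least ``ceil(min_fraction * n_comparators)``
    comparator proteomes. Category is ``housekeeping``.
    """
    if not reference_proteome:
        raise ValueError("empty reference proteome")
    if not comparator_proteomes:
        raise ValueError("need at least one comparator proteome")
    annotations = annotations or {}
    scheme = scheme or ScoringScheme()
    needed = math.ceil(min_fraction * len(comparator_proteomes))
    conserved_in: dict[str, int] = {pid: 0 for pid in reference_proteome}
    for comparator in comparator_proteomes:
        rbh = reciprocal_best_hits(
            reference_proteome,
            comparator,
            scheme=scheme,
            min_identity=min_identity,
            min_coverage=min_coverage,
            coverage_both=True,
        )
        for pid in rbh:
            conserved_in[pid] += 1
    hooks = []
    seen_seqs: set[str] = set()
    for pid in sorted(reference_proteome):
        if conserved_in[pid] < needed:
            continue
        seq = reference_proteome[pid].upper()
        if len(seq) < MIN_HOOK_LENGTH or seq in seen_seqs:
            continue
        seen_seqs.add(seq)
        hooks.append(
            HookProtein(
                hook_id=pid,
                source_locus=pid,
                category="housekeeping",
                annotation=annotations.get(pid, ""),
                sequence=seq,
            )
        )
    return HookPanel(hooks, panel_id)
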