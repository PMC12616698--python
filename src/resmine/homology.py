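"""Pairwise protein homology: affine-gap Smith-Waterman, panel search, duplication index.

This module provides the alignment engine behind the resistance rule: a BGC is
interesting when one of its genes is a close homologue of a housekeeping "hook"
protein AND that homologue has at least one additional copy elsewhere in the
genome (the cell's essential copy). Alignment is local, affine-gap, BLOSUM62 by
default, with a deterministic traceback so that identity/coverage figures are
reproducible run to run.

Scoring conventions
-------------------
A gap of length ``k`` costs ``gap_open + (k - 1) * gap_extend``; the opening
penalty covers the first gapped residue. ``X`` (unknown residue, e.g. from an
ambiguous codon) scores 0 against every residue including itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

log = logging.getLogger(__name__)

#: residues accepted in query/target sequences
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

_PTR_STOP, _PTR_DIAG, _PTR_UP, _PTR_LEFT = 0, 1, 2, 3


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``matrix_name`` may be ``BLOSUM62`` (default) or ``BLOSUM45``; alternatively
    ``matrix_path`` points at an NCBI-format plain-text matrix file which takes
    precedence. Gap cost for a gap of length k is ``gap_open + (k-1)*gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    matrix_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError(
                f"require gap_open >= gap_extend >= 1, got "
                f"open={self.gap_open} extend={self.gap_extend}"
            )


_MATRIX_CACHE: dict = {}


def _encoded_matrix(scheme: ScoringScheme) -> np.ndarray:
    """Dense int32 score matrix over PROTEIN_ALPHABET, X row/column zeroed."""
    key = (scheme.matrix_name, scheme.matrix_path)
    cached = _MATRIX_CACHE.get(key)
    if cached is not None:
        return cached
    if scheme.matrix_path is not None:
        mat = substitution_matrices.read(scheme.matrix_path)
    else:
        if scheme.matrix_name not in ("BLOSUM62", "BLOSUM45"):
            raise ValueError(f"unsupported matrix {scheme.matrix_name!r}")
        mat = substitution_matrices.load(scheme.matrix_name)
    n = len(PROTEIN_ALPHABET)
    dense = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            if a == "X" or b == "X":
                dense[i, j] = 0
            else:
                dense[i, j] = int(mat[a, b])
    _MATRIX_CACHE[key] = dense
    return dense


_CODE = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}


def encode_protein(seq: str, label: str = "sequence") -> np.ndarray:
    """Map a protein string to integer codes; reject illegal characters."""
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    out = np.empty(len(seq), dtype=np.int8)
    for pos, ch in enumerate(seq.upper()):
        code = _CODE.get(ch)
        if code is None:
            raise ValueError(
                f"{label}: illegal character {ch!r} at position {pos}"
            )
        out[pos] = code
    return out


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment above the reporting threshold.

    Coverages are aligned-span / sequence-length, in (0, 1]; intervals are
    0-based half-open on each sequence. ``percent_identity`` counts identical
    columns over all alignment columns (gap columns included).
    """

    query_id: str
    target_id: str
    score: int
    percent_identity: float
    query_coverage: float
    target_coverage: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]


@njit(cache=True)
def _sw_fill(a, b, S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), -(1 << 60), dtype=np.int64)
    F = np.full((n + 1, m + 1), -(1 << 60), dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pe = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 -> extended
    pf = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
                pe[i, j] = 0
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
                pf[i, j] = 0
            diag = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            # tie-break preference: diagonal > up > left > stop
            h = 0
            p = _PTR_STOP
            if diag >= h and diag > 0:
                h = diag
                p = _PTR_DIAG
            if F[i, j] > h:
                h = F[i, j]
                p = _PTR_UP
            if E[i, j] > h:
                h = E[i, j]
                p = _PTR_LEFT
            H[i, j] = h
            ptr[i, j] = p
            if h > best:  # strict: keeps smallest row, then column
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr, pe, pf


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> Optional[AlignmentHit]:
    """Optimal local alignment of ``a`` (query) vs ``b`` (target).

    Returns ``None`` when the best local score is 0 (no positively scoring
    alignment exists). The traceback is deterministic: at score ties the
    diagonal move is preferred over a gap in the target ("up") over a gap in
    the query ("left"), and among equally scoring cells the one with the
    smallest row, then column, is chosen.
    """
    scheme = scheme or ScoringScheme()
    ea = encode_protein(a, "query")
    eb = encode_protein(b, "target")
    S = _encoded_matrix(scheme)
    best, bi, bj, ptr, pe, pf = _sw_fill(
        ea, eb, S, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0:
        return None
    # traceback
    i, j = bi, bj
    columns = 0
    identical = 0
    state = "H"
    while True:
        if state == "H":
            p = ptr[i, j]
            if p == _PTR_STOP:
                break
            if p == _PTR_DIAG:
                columns += 1
                if ea[i - 1] == eb[j - 1]:
                    identical += 1
                i -= 1
                j -= 1
            elif p == _PTR_UP:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            columns += 1
            ext = pf[i, j]
            i -= 1
            if not ext:
                state = "H"
        else:  # E
            columns += 1
            ext = pe[i, j]
            j -= 1
            if not ext:
                state = "H"
    qs, qe = i, bi
    ts, te = j, bj
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        score=int(best),
        percent_identity=100.0 * identical / columns,
        query_coverage=(qe - qs) / len(a),
        target_coverage=(te - ts) / len(b),
        query_interval=(qs, qe),
        target_interval=(ts, te),
    )


def _shared_kmers(a: str, b: str, k: int = 4) -> int:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)


def search_panel(
    protein: str,
    panel,
    scheme: ScoringScheme | None = None,
    min_identity: float = 50.0,
    min_coverage: float = 0.7,
    protein_id: str = "query",
    prefilter: bool = False,
) -> Optional[AlignmentHit]:
    """Best hook hit for one protein, or ``None``.

    Both thresholds must pass: percent identity >= ``min_identity`` and
    coverage of the hook (target) side >= ``min_coverage``. Ties on score are
    broken by lexicographic hook id. The optional 4-mer shared-seed prefilter
    skips hooks with no shared 4-mer; it is OFF by default because it is not
    guaranteed lossless at low identity.
    """
    scheme = scheme or ScoringScheme()
    best: Optional[AlignmentHit] = None
    for hook in sorted(panel.hooks, key=lambda h: h.hook_id):
        if prefilter and _shared_kmers(protein, hook.sequence) < 1:
            continue
        hit = smith_waterman(
            protein, hook.sequence, scheme, query_id=protein_id, target_id=hook.hook_id
        )
        if hit is None:
            continue
        if hit.percent_identity < min_identity or hit.target_coverage < min_coverage:
            continue
        if best is None or hit.score > best.score:
            best = hit
    return best


@dataclass(frozen=True)
class DuplicationEntry:
    """One genome gene hitting a hook: location plus the alignment evidence."""

    gene_id: str
    contig_id: str
    interval: tuple[int, int]
    hit: AlignmentHit


def build_duplication_index(
    genome,
    panel,
    scheme: ScoringScheme | None = None,
    min_identity: float = 50.0,
    min_coverage: float = 0.7,
    prefilter: bool = False,
) -> dict[str, list[DuplicationEntry]]:
    """All qualifying hook homologues in a genome, per hook, best score first."""
    scheme = scheme or ScoringScheme()
    index: dict[str, list[DuplicationEntry]] = {h.hook_id: [] for h in panel.hooks}
    for gene in genome.genes:
        for hook in panel.hooks:
            if prefilter and _shared_kmers(gene.protein, hook.sequence) < 1:
                continue
            hit = smith_waterman(
                gene.protein, hook.sequence, scheme,
                query_id=gene.gene_id, target_id=hook.hook_id,
            )
            if hit is None:
                continue
            if (
                hit.percent_identity < min_identity
                or hit.target_coverage < min_coverage
            ):
                continue
            index[hook.hook_id].append(
                DuplicationEntry(gene.gene_id, gene.contig_id, gene.interval, hit)
            )
    for entries in index.values():
        entries.sort(key=lambda e: (-e.hit.score, e.gene_id))
    return index


def count_outside_copies(
    hook_id: str,
    region_contig: str,
    region_interval: tuple[int, int],
    duplication_index: Mapping[str, list[DuplicationEntry]],
) -> int:
    """Qualifying copies of a hook's homologue outside a region's interval.

    A gene on a different contig always counts as outside; on the same contig
    it counts when its interval does not overlap the region's.
    """
    entries = duplication_index.get(hook_id)
    if not entries:
        return 0
    rs, re_ = region_interval
    count = 0
    for entry in entries:
        if entry.contig_id != region_contig:
            count += 1
            continue
        gs, ge = entry.interval
        if ge <= rs or gs >= re_:
            count += 1
    return count


def reciprocal_best_hits(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    min_identity: float = 40.0,
    min_coverage: float = 0.0,
    coverage_both: bool = True,
) -> dict[str, tuple[str, AlignmentHit]]:
    """Reciprocal best hits between two proteomes.

    Best hits are by alignment score (ties by id); a pair is reported when each
    side is the other's best hit, identity >= ``min_identity`` and, when
    ``coverage_both``, coverage of both sequences >= ``min_coverage``.
    """
    scheme = scheme or ScoringScheme()
    hits: dict[tuple[str, str], AlignmentHit] = {}
    best_ab: dict[str, tuple[int, str]] = {}
    best_ba: dict[str, tuple[int, str]] = {}
    for aid, aseq in proteins_a.items():
        for bid, bseq in proteins_b.items():
            hit = smith_waterman(aseq, bseq, scheme, query_id=aid, target_id=bid)
            if hit is None:
                continue
            hits[(aid, bid)] = hit
            cur = best_ab.get(aid)
            if cur is None or (-hit.score, bid) < cur:
                best_ab[aid] = (-hit.score, bid)
            cur = best_ba.get(bid)
            if cur is None or (-hit.score, aid) < cur:
                best_ba[bid] = (-hit.score, aid)
    out: dict[str, tuple[str, AlignmentHit]] = {}
    for aid, (_, bid) in best_ab.items():
        if best_ba.get(bid, (0, None))[1] != aid:
            continue
        hit = hits[(aid, bid)]
        if hit.percent_identity < min_identity:
            continue
        covs = (hit.query_coverage, hit.target_coverage)
        cov_ok = min(covs) if coverage_both else max(covs)
        if cov_ok < min_coverage:
            continue
        out[aid] = (bid, hit)
    return out


def write_hits_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """Export alignment hits as a TSV table."""
    import pandas as pd

    rows = [
        {
            "query": h.query_id,
            "target": h.target_id,
            "score": h.score,
            "percent_identity": round(h.percent_identity, 2),
            "query_coverage": round(h.query_coverage, 4),
            "target_coverage": round(h.target_coverage, 4),
            "query_start": h.query_interval[0],
            "query_end": h.query_interval[1],
            "target_start": h.target_interval[0],
            "target_end": h.target_interval[1],
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query", "target", "score", "percent_identity", "query_coverage",
            "target_coverage", "query_start", "query_end", "target_start",
            "target_end",
        ],
    ).to_csv(path, sep="\t", index=False)
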