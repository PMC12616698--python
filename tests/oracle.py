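"""Independent brute-force oracles used only by the tests.

Kept deliberately naive (dict lookups, plain Python loops, full matrices) and
separate from the package's own implementations.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")

# standard codon table, hardcoded so translation is checked against an
# independent source rather than the library the reader itself uses
CODON_TABLE = {}
_bases = "TCAG"
_aa = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_i = 0
for b1 in _bases:
    for b2 in _bases:
        for b3 in _bases:
            CODON_TABLE[b1 + b2 + b3] = _aa[_i]
            _i += 1

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aas.append(CODON_TABLE.get(codon, "X"))
    prot = "".join(aas)
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def blosum62(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return 0
    return int(_B62[a, b])


def sw_affine_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Local affine-gap alignment score; gap of length k costs
    gap_open + (k-1)*gap_extend. Full-matrix DP, no shortcuts."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + blosum62(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)
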