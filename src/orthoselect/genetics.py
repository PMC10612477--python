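"""Universal genetic code, sense-codon indexing, and translation.

Everything downstream (input validation, back-translation, the codon
substitution engine, the simulator) shares this one table so a codon index
means the same thing everywhere: the 61 sense codons of the universal code,
sorted lexicographically over the alphabet A < C < G < T.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: The 61 sense codons in lexicographic order; indices into this list are the
#: state space of the substitution models.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if _CODON_TABLE[c] != "*"
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

#: Amino acid encoded by each sense codon, aligned with SENSE_CODONS.
CODON_AA: tuple[str, ...] = tuple(_CODON_TABLE[c] for c in SENSE_CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-nucleotide neighbours, transitions, synonymy."""
    single = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    transition = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    synonymous = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diffs[0] in _TRANSITIONS
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous


SINGLE_STEP, IS_TRANSITION, IS_SYNONYMOUS = _pair_structure()


def translate(cds: str) -> str:
    """Translate a CDS with the universal code; codons containing N give 'X'.

    Raises ValueError on length not divisible by 3 or on characters outside
    {A,C,G,T,N} (case-insensitive).
    """
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    out = []
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(_CODON_TABLE[codon])
    return "".join(out)


def codon_indices(cds: str) -> np.ndarray:
    """Map an in-frame, gap-free CDS to sense-codon indices.

    Raises KeyError (via dict lookup) for stop or ambiguous codons; callers
    are expected to have validated/cleaned the sequence first.
    """
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    return np.array([CODON_INDEX[seq[k : k + 3]] for k in range(0, len(seq), 3)],
                    dtype=np.int64)
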