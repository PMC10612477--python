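"""Protein alignment, codon back-translation, and column cleaning.

The aligner is a deterministic progressive method: pairwise affine-gap
global alignments give distances for a neighbor-joining guide tree, and
profiles are merged bottom-up with profile-profile dynamic programming
(BLOSUM62, gap open -10 / extend -0.5). It deliberately does not reproduce
phylogeny-aware gap placement; an externally produced protein alignment in
FASTA can be supplied instead and back-translated the same way.

Back-translation maps each aligned residue to its source codon ('-' becomes
'---'), so degapping any codon-alignment row reproduces the validated CDS
byte-exactly. Before likelihood work, codon columns containing a gap or an
ambiguous (N) codon in any taxon are removed (complete deletion), keeping a
site-index map so selected sites are reported in original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .gene_tree import GeneTree, TreeNode, nj_tree
from .genetics import translate

GAP_OPEN = -10.0
GAP_EXTEND = -0.5
MIN_CODON_COLUMNS = 10

_AA = "ARNDCQEGHILKMFPSTWYVX"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


def _blosum62_matrix() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(_AA), len(_AA)))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            out[i, j] = m[a, b]
    return out


_B62 = _blosum62_matrix()


@dataclass
class ProteinAlignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class CodonAlignment:
    taxa: list[str]
    rows: list[str]
    #: maps current codon-column index -> 1-based codon position in the
    #: original (pre-cleaning) alignment
    site_map: list[int] | None = None

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.n_codon_columns * 3 != len(self.rows[0]):
            raise ValueError("row length is not a multiple of 3")
        if self.site_map is None:
            self.site_map = list(range(1, self.n_codon_columns + 1))

    @property
    def n_codon_columns(self) -> int:
        return len(self.rows[0]) // 3

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def codon(self, row_idx: int, col: int) -> str:
        return self.rows[row_idx][3 * col : 3 * col + 3]


class TooShortError(ValueError):
    """Cleaning left fewer codon columns than the minimum for a stable fit."""


# ---------------------------------------------------------------------------
# progressive protein alignment
# ---------------------------------------------------------------------------

def _pairwise_global(a: str, b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def _profile(rows: list[str]) -> np.ndarray:
    """Residue-frequency profile, one row per column over the 21-letter set."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, len(_AA)))
    for r in rows:
        for c, aa in enumerate(r):
            if aa != "-":
                prof[c, _AA_INDEX[aa]] += 1.0
    tot = prof.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return prof / tot


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap Needleman–Wunsch on two profiles (average-of-pairs scores)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    S = pa @ _B62 @ pb.T  # (la, lb) expected substitution score per column pair

    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    # traceback: 0=M,1=X,2=Y per matrix
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        mi, xi, yi = M[i - 1], X[i - 1], Y[i - 1]  # previous row views
        for j in range(1, lb + 1):
            cand = (mi[j - 1], xi[j - 1], yi[j - 1])
            k = int(np.argmax(cand))
            M[i, j] = cand[k] + S[i - 1, j - 1]
            tb_m[i, j] = k
            cand = (M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                    Y[i - 1, j] + GAP_OPEN)
            k = int(np.argmax(cand))
            X[i, j] = cand[k]
            tb_x[i, j] = k
            cand = (M[i, j - 1] + GAP_OPEN, X[i, j - 1] + GAP_OPEN,
                    Y[i, j - 1] + GAP_EXTEND)
            k = int(np.argmax(cand))
            Y[i, j] = cand[k]
            tb_y[i, j] = k

    i, j = la, lb
    state = int(np.argmax((M[i, j], X[i, j], Y[i, j])))
    out_a: list[str] = []
    out_b: list[str] = []
    gap_a = "-" * len(rows_a)
    gap_b = "-" * len(rows_b)
    cols_a = ["".join(r[c] for r in rows_a) for c in range(la)]
    cols_b = ["".join(r[c] for r in rows_b) for c in range(lb)]
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append(cols_a[i - 1]); out_b.append(cols_b[j - 1])
            state = int(tb_m[i, j]); i -= 1; j -= 1
        elif state == 1 and i > 0:
            out_a.append(cols_a[i - 1]); out_b.append(gap_b)
            state = int(tb_x[i, j]); i -= 1
        elif state == 2 and j > 0:
            out_a.append(gap_a); out_b.append(cols_b[j - 1])
            state = int(tb_y[i, j]); j -= 1
        elif i > 0:
            out_a.append(cols_a[i - 1]); out_b.append(gap_b); i -= 1
        else:
            out_a.append(gap_a); out_b.append(cols_b[j - 1]); j -= 1
    out_a.reverse(); out_b.reverse()
    new_a = ["".join(col[r] for col in out_a) for r in range(len(rows_a))]
    new_b = ["".join(col[r] for col in out_b) for r in range(len(rows_b))]
    return new_a, new_b


def _guide_tree(names: list[str], seqs: list[str]) -> GeneTree:
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = _pairwise_global(seqs[i], seqs[j])
            shared = [(a, b) for a, b in zip(sa, sb) if a != "-" and b != "-"]
            p = (sum(a != b for a, b in shared) / len(shared)) if shared else 1.0
            dist[i, j] = dist[j, i] = p
    return nj_tree(dist, names)


def align_proteins(peptides: Mapping[str, str]) -> ProteinAlignment:
    """Progressive multiple alignment of one cluster's peptides.

    Deterministic given its input; requires >= 3 non-empty sequences (the
    cluster invariant).
    """
    names = list(peptides)
    seqs = [peptides[n] for n in names]
    if len(names) < 3:
        raise ValueError("need at least 3 sequences")
    if any(not s for s in seqs):
        raise ValueError("empty peptide sequence")
    guide = _guide_tree(names, seqs)

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [peptides[node.name]]
        parts = [merge(c) for c in node.children]
        names_acc, rows_acc = parts[0]
        for nxt_names, nxt_rows in parts[1:]:
            rows_acc, nxt_rows = _align_profiles(rows_acc, nxt_rows)
            names_acc = names_acc + nxt_names
            rows_acc = rows_acc + nxt_rows
        return names_acc, rows_acc

    out_names, out_rows = merge(guide.root)
    order = [out_names.index(n) for n in names]
    return ProteinAlignment(taxa=names, rows=[out_rows[k] for k in order])


# ---------------------------------------------------------------------------
# back-translation and cleaning
# ---------------------------------------------------------------------------

def back_translate(pa: ProteinAlignment, cds: Mapping[str, str]) -> CodonAlignment:
    """Thread each CDS onto its aligned peptide row; '-' becomes '---'."""
    rows = []
    for taxon, prow in zip(pa.taxa, pa.rows):
        seq = cds[taxon]
        expected = translate(seq)
        degapped = prow.replace("-", "")
        if len(expected) != len(degapped):
            raise ValueError(
                f"{taxon}: CDS translates to {len(expected)} residues but aligned "
                f"row has {len(degapped)}")
        out = []
        k = 0
        for pos, aa in enumerate(prow):
            if aa == "-":
                out.append("---")
                continue
            have = expected[k]
            if have != aa and have != "X" and aa != "X":
                raise ValueError(
                    f"{taxon}: translation mismatch at residue {k + 1} "
                    f"(CDS gives {have!r}, alignment has {aa!r})")
            out.append(seq[3 * k : 3 * k + 3])
            k += 1
        rows.append("".join(out))
    return CodonAlignment(taxa=list(pa.taxa), rows=rows)


def clean_columns(ca: CodonAlignment, policy: str = "complete_deletion",
                  min_columns: int = MIN_CODON_COLUMNS) -> CodonAlignment:
    """Remove codon columns with gaps or N in any taxon (complete deletion).

    ``policy="keep_all"`` returns the alignment unchanged. Raises
    :class:`TooShortError` when fewer than ``min_columns`` codon columns
    survive.
    """
    if policy == "keep_all":
        return ca
    if policy != "complete_deletion":
        raise ValueError(f"unknown column policy {policy!r}")
    keep: list[int] = []
    for col in range(ca.n_codon_columns):
        codons = [r[3 * col : 3 * col + 3] for r in ca.rows]
        if any("-" in c or "N" in c for c in codons):
            continue
        keep.append(col)
    if len(keep) < min_columns:
        raise TooShortError(
            f"only {len(keep)} codon columns survive cleaning (< {min_columns})")
    rows = ["".join(r[3 * c : 3 * c + 3] for c in keep) for r in ca.rows]
    site_map = [ca.site_map[c] for c in keep]
    return CodonAlignment(taxa=list(ca.taxa), rows=rows, site_map=site_map)


def write_phylip(ca: CodonAlignment, path) -> None:
    """Sequential PHYLIP with padded names (PAML-compatible layout)."""
    with open(path, "w") as fh:
        fh.write(f" {len(ca.taxa)} {len(ca.rows[0])}\n")
        for taxon, row in zip(ca.taxa, ca.rows):
            fh.write(f"{taxon.ljust(30)}  {row}\n")
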