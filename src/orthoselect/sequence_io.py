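"""Reading, pairing and validating per-species CDS/peptide FASTA inputs.

Each species contributes two FASTA files — coding sequences and the
corresponding peptides — whose header sets must be identical (a hard input
requirement). Individual records that fail translation consistency are
excluded with a machine-readable reason rather than aborting a genome-scale
run; a mismatch between the two files' header sets is fatal.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .genetics import STOP_CODONS, translate

log = logging.getLogger(__name__)


class FastaError(ValueError):
    """Malformed FASTA input (duplicate headers, no records, parse failure)."""


class HeaderMismatchError(ValueError):
    """CDS and peptide files of one species disagree on headers/counts."""


@dataclass(frozen=True)
class GeneRecord:
    """A validated CDS/peptide pair for one gene.

    Invariants (enforced by :func:`pair_and_validate`): the stored ``cds`` has
    any terminal stop codon stripped, translates exactly to ``peptide`` under
    the universal code (codons containing N translate to X; X in the peptide
    matches anything), and contains no internal stop codon.
    """

    header: str
    cds: str
    peptide: str


@dataclass
class ProteomePair:
    """One species' validated records plus the per-record rejection log."""

    species_id: str
    records: list[GeneRecord] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def as_dict(self) -> dict[str, GeneRecord]:
        return {r.header: r for r in self.records}


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records in file order as (first-token header, upper-case seq).

    Multi-line sequences are concatenated; empty sequences and duplicate
    headers raise :class:`FastaError`; a missing file raises FileNotFoundError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FastaError(f"{path}: sequence data before first '>' header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.id  # first whitespace-delimited token
            seq = str(rec.seq).upper()
            if header in seen:
                raise FastaError(f"{path}: duplicate header {header!r}")
            if not seq:
                raise FastaError(f"{path}: empty sequence for {header!r}")
            seen.add(header)
            records.append((header, seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def _validate_record(header: str, cds: str, peptide: str) -> tuple[GeneRecord | None, str | None]:
    """Validate one CDS/peptide pair; returns (record, None) or (None, reason)."""
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if set(cds) - set("ACGTN"):
        return None, "invalid_nucleotides"
    if len(cds) % 3 != 0:
        return None, "length_not_multiple_of_3"
    if len(cds) != 3 * len(peptide):
        return None, "length_mismatch"
    aa = translate(cds)
    if "*" in aa:
        return None, "internal_stop"
    for got, want in zip(aa, peptide):
        if got != want and got != "X" and want != "X":
            return None, "translation_mismatch"
    return GeneRecord(header=header, cds=cds, peptide=peptide), None


def pair_and_validate(cds_path: str | Path, pep_path: str | Path,
                      species_id: str | None = None) -> ProteomePair:
    """Pair a species' CDS and peptide FASTA files and validate each record.

    The two files must contribute identical header sets and record counts
    (fatal otherwise). Terminal stop codons are stripped before the 3x length
    check. Records failing validation are moved to ``rejected`` with a reason.
    """
    if species_id is None:
        species_id = Path(cds_path).name.split(".")[0]
    cds_recs = read_fasta(cds_path)
    pep_recs = read_fasta(pep_path)
    if len(cds_recs) != len(pep_recs):
        raise HeaderMismatchError(
            f"{species_id}: record counts differ "
            f"({len(cds_recs)} CDS vs {len(pep_recs)} peptides)")
    cds_map = dict(cds_recs)
    pep_map = dict(pep_recs)
    if set(cds_map) != set(pep_map):
        only_cds = sorted(set(cds_map) - set(pep_map))[:5]
        only_pep = sorted(set(pep_map) - set(cds_map))[:5]
        raise HeaderMismatchError(
            f"{species_id}: header sets differ between CDS and peptide files "
            f"(CDS-only e.g. {only_cds}, peptide-only e.g. {only_pep})")

    pair = ProteomePair(species_id=species_id)
    for header, _ in cds_recs:
        rec, reason = _validate_record(header, cds_map[header], pep_map[header])
        if rec is None:
            log.warning("%s: rejecting %s (%s)", species_id, header, reason)
            pair.rejected.append((header, reason))
        else:
            pair.records.append(rec)
    return pair


def discover_inputs(cds_dir: str | Path, pep_dir: str | Path) -> list[tuple[str, Path, Path]]:
    """Match CDS and peptide files across two directories by file-name stem."""
    cds_dir, pep_dir = Path(cds_dir), Path(pep_dir)
    exts = (".fa", ".fasta", ".fna", ".faa", ".fa.gz", ".fasta.gz")
    def stem(p: Path) -> str:
        return p.name.split(".")[0]
    cds_files = {stem(p): p for p in sorted(cds_dir.iterdir())
                 if p.name.endswith(exts)}
    pep_files = {stem(p): p for p in sorted(pep_dir.iterdir())
                 if p.name.endswith(exts)}
    common = sorted(set(cds_files) & set(pep_files))
    if not common:
        raise FileNotFoundError(
            f"no species with matching file stems in {cds_dir} and {pep_dir}")
    return [(s, cds_files[s], pep_files[s]) for s in common]


def read_manifest(path: str | Path) -> list[tuple[str, Path, Path]]:
    """Read an explicit TSV manifest: species_id, cds_path, pep_path."""
    out = []
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sp, cds, pep = line.split("\t")[:3]
            out.append((sp, base / cds if not Path(cds).is_absolute() else Path(cds),
                        base / pep if not Path(pep).is_absolute() else Path(pep)))
    return out


def load_proteomes(entries: Iterable[tuple[str, Path, Path]]) -> list[ProteomePair]:
    return [pair_and_validate(cds, pep, sp) for sp, cds, pep in entries]


def write_validation_report(proteomes: Iterable[ProteomePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\theader\tstatus\treason\n")
        for p in proteomes:
            for r in p.records:
                fh.write(f"{p.species_id}\t{r.header}\taccepted\t.\n")
            for header, reason in p.rejected:
                fh.write(f"{p.species_id}\t{header}\trejected\t{reason}\n")
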