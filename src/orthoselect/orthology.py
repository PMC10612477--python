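"""One-to-one orthologous gene cluster (OGC) prediction.

All-vs-all Smith–Waterman protein similarity feeds a reciprocal-best-hit
(RBH) graph; connected components become OGCs only if they span at least
``min_species`` species (default 3) and contain exactly one gene per
species. Components carrying within-species paralogs are rejected wholesale
rather than trimmed — a cluster must consist exclusively of one-to-one
orthologs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import ProteomePair

log = logging.getLogger(__name__)

Gene = tuple[str, str]  # (species_id, header)


@dataclass(frozen=True)
class ScoringConfig:
    """BLAST-like local-alignment scoring for the native similarity search."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 50.0
    min_identity: float = 0.25


@dataclass(frozen=True)
class SimilarityHit:
    query: Gene
    subject: Gene
    score: float
    identity_fraction: float


@dataclass(frozen=True)
class OGC:
    """A one-to-one orthologous gene cluster spanning >= 3 species."""

    ogc_id: str
    members: dict[str, str]  # species_id -> gene header

    @property
    def n_species(self) -> int:
        return len(self.members)

    def __hash__(self) -> int:
        return hash((self.ogc_id, tuple(sorted(self.members.items()))))


def _aligner(scoring: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _identity(alignment) -> float:
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    return counts.identities / aligned if aligned else 0.0


def all_pairs_similarity(proteomes: Sequence[ProteomePair],
                         scoring: ScoringConfig | None = None) -> list[SimilarityHit]:
    """Local-align every cross-species protein pair; emit hits above threshold.

    Scores are symmetric (score(a,b) == score(b,a)); both orientations of a
    passing pair are emitted so best-hit selection can run per ordered pair.
    """
    if len(proteomes) < 2:
        raise ValueError("orthology prediction needs at least 2 species")
    scoring = scoring or ScoringConfig()
    aligner = _aligner(scoring)
    hits: list[SimilarityHit] = []
    for ai in range(len(proteomes)):
        for bi in range(ai + 1, len(proteomes)):
            pa, pb = proteomes[ai], proteomes[bi]
            for ra in pa.records:
                for rb in pb.records:
                    score = aligner.score(ra.peptide, rb.peptide)
                    if score < scoring.min_score:
                        continue
                    ident = _identity(aligner.align(ra.peptide, rb.peptide)[0])
                    if ident < scoring.min_identity:
                        continue
                    ga: Gene = (pa.species_id, ra.header)
                    gb: Gene = (pb.species_id, rb.header)
                    hits.append(SimilarityHit(ga, gb, float(score), ident))
                    hits.append(SimilarityHit(gb, ga, float(score), ident))
    return hits


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    """Load a precomputed hit table: qspecies qgene sspecies sgene pident score."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            qs, qg, ss, sg, pid, score = line.split("\t")[:6]
            hits.append(SimilarityHit((qs, qg), (ss, sg),
                                      float(score), float(pid) / 100.0))
    return hits


def reciprocal_best_hits(hits: Iterable[SimilarityHit],
                         sim_factor: float = 0.95) -> nx.Graph:
    """Build the undirected reciprocal-(near-)best-hit graph.

    For each ordered (query gene, subject species) pair, the near-best set
    holds every hit whose score is at least ``sim_factor`` times the best
    score for that pair (ProteinOrtho's similarity semantics; ``sim_factor=1``
    is strict best-hits-with-ties). An undirected edge exists iff the
    near-best relation holds in both directions — so a recent within-species
    duplicate joins its family's component and trips the one-to-one filter
    instead of being silently dropped.
    """
    if not 0.0 < sim_factor <= 1.0:
        raise ValueError("sim_factor must lie in (0, 1]")
    best_score: dict[tuple[Gene, str], float] = {}
    for h in hits:
        key = (h.query, h.subject[0])
        if h.score > best_score.get(key, 0.0):
            best_score[key] = h.score
    near_best: dict[tuple[Gene, str], set[Gene]] = {}
    for h in hits:
        key = (h.query, h.subject[0])
        if h.score >= sim_factor * best_score[key]:
            near_best.setdefault(key, set()).add(h.subject)
    graph = nx.Graph()
    for (query, subj_sp), subjects in near_best.items():
        for subject in subjects:
            if query in near_best.get((subject, query[0]), ()):
                graph.add_edge(query, subject)
    return graph


def cluster_and_filter(graph: nx.Graph, min_species: int = 3,
                       allow_small: bool = False) -> list[OGC]:
    """Connected components -> OGCs, applying the two eligibility rules.

    A component is emitted iff it spans >= min_species species and has at
    most one gene per species; paralog-bearing components are discarded
    entirely. Cluster ids are assigned in sorted member-list order.
    """
    if min_species < 3 and not allow_small:
        raise ValueError("min_species < 3 requires allow_small=True")
    eligible: list[dict[str, str]] = []
    for comp in nx.connected_components(graph):
        species = [g[0] for g in comp]
        if len(set(species)) < min_species:
            continue
        if len(species) != len(set(species)):
            log.info("discarding %d-gene component with within-species paralogs",
                     len(comp))
            continue
        # sort: component sets iterate in a hash-dependent order, and member
        # order propagates into alignment/tree order downstream
        eligible.append(dict(sorted(comp)))
    eligible.sort(key=lambda m: sorted(m.items()))
    width = max(4, len(str(len(eligible))))
    return [OGC(ogc_id=f"OGC{str(i + 1).zfill(width)}", members=m)
            for i, m in enumerate(eligible)]


def predict_ogcs(proteomes: Sequence[ProteomePair],
                 scoring: ScoringConfig | None = None,
                 min_species: int = 3) -> list[OGC]:
    hits = all_pairs_similarity(proteomes, scoring)
    return cluster_and_filter(reciprocal_best_hits(hits), min_species)


def write_orthology_table(ogcs: Sequence[OGC], species_ids: Sequence[str],
                          path: str | Path) -> None:
    """ProteinOrtho-like TSV: one OGC per row, '*' for absent species."""
    with open(path, "w") as fh:
        cols = "\t".join(species_ids)
        fh.write(f"ogc_id\tn_species\tspecies\t{cols}\n")
        for ogc in ogcs:
            present = ",".join(sorted(ogc.members))
            cells = "\t".join(ogc.members.get(sp, "*") for sp in species_ids)
            fh.write(f"{ogc.ogc_id}\t{ogc.n_species}\t{present}\t{cells}\n")
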