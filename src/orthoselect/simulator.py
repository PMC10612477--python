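"""Codon-sequence simulator: ground-truth data for every pipeline stage.

Sequences evolve along a tree under exactly the engine's distributional
assumptions: a site draws its omega class from the model mixture, the root
codon comes from the equilibrium frequencies, and each branch applies the
class's transition-probability matrix (matrix-exponential method, no
explicit event simulation). Alignments are gap-free by construction; gap
handling is exercised separately with synthetic gap injection.

``emit_pipeline_inputs`` turns gene families into per-species CDS/peptide
FASTA files, optionally simulating gene losses and within-species paralogs
(short 0.05-substitution duplicate branches) so the one-to-one and
minimum-three-species orthology filters can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import CodonAlignment
from .codon_engine import (
    CodonFrequencies, _eigen, _mean_rate, _p_from_eigen, _unscaled_generator,
    model_classes,
)
from .gene_tree import GeneTree, parse_newick
from .genetics import N_SENSE, SENSE_CODONS, translate
from .sequence_io import write_fasta

PARALOG_BRANCH = 0.05

#: Balanced default topologies; terminal branches 0.3, internal 0.15
#: expected substitutions per codon — a moderately divergent clade in which
#: both tree estimation and selection tests are well informed.
DEFAULT_TREES = {
    3: "(spA:0.3,spB:0.3,spC:0.3);",
    4: "((spA:0.3,spB:0.3):0.15,spC:0.3,spD:0.3);",
    5: "((spA:0.3,spB:0.3):0.15,(spC:0.3,spD:0.3):0.15,spE:0.3);",
    6: "((spA:0.3,spB:0.3):0.15,(spC:0.3,spD:0.3):0.15,(spE:0.3,spF:0.3):0.15);",
}

#: Default true parameters per model for simulation studies.
DEFAULT_PARAMS = {
    "M0": {"kappa": 2.0, "omega": 0.3},
    "M1a": {"kappa": 2.0, "p0": 0.7, "omega0": 0.2},
    "M2a": {"kappa": 2.0, "q0": 0.6, "q1": 0.5, "omega0": 0.2, "omega2": 4.0},
    "BR2": {"kappa": 2.0, "omega_bg": 0.2, "omega_fg": 3.0},
    "BSA": {"kappa": 2.0, "q0": 0.6, "q1": 0.5, "omega0": 0.2, "omega2": 4.0},
}


def default_tree(n_taxa: int = 5) -> GeneTree:
    return parse_newick(DEFAULT_TREES[n_taxa])


def toy_dataset(out_dir: str | Path, seed: int = 0) -> dict:
    """The bundled 3-species example: three 300-codon families, one of them
    under strong episodic positive selection (M2a, half the mass split
    between neutral and omega=6 classes) so the branch/branch-site stage is
    exercised; the other two evolve under purifying one-ratio conditions."""
    scenario = SimScenario(tree=default_tree(3), model="M0",
                           params=dict(DEFAULT_PARAMS["M0"]),
                           n_codons=300, n_families=3, seed=seed)
    positive = ("M2a", {"kappa": 2.0, "q0": 0.5, "q1": 0.5,
                        "omega0": 0.15, "omega2": 6.0})
    return emit_pipeline_inputs(scenario, out_dir, family_overrides={1: positive})


@dataclass
class SimScenario:
    """One simulation condition: tree, true model, sizes, family-level rates."""

    tree: GeneTree
    model: str = "M0"
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS["M0"]))
    n_codons: int = 300
    n_families: int = 5
    paralog_rate: float = 0.0
    loss_rate: float = 0.0
    seed: int = 0
    ncat: int = 10

    def __post_init__(self) -> None:
        if self.n_codons < 1 or self.n_families < 1:
            raise ValueError("n_codons and n_families must be >= 1")
        for r in (self.paralog_rate, self.loss_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _uniform_freqs() -> CodonFrequencies:
    return CodonFrequencies("equal", np.full(N_SENSE, 1.0 / N_SENSE))


def _sample_step(P: np.ndarray, states: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P[states], axis=1)
    u = rng.random(len(states)) * cum[:, -1]
    return (cum > u[:, None]).argmax(axis=1)


def evolve_alignment(scenario: SimScenario,
                     rng: np.random.Generator | None = None,
                     freqs: CodonFrequencies | None = None
                     ) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate one gap-free codon alignment; returns (alignment, site classes).

    Site classes index the model's mixture (in ``model_classes`` order).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    freqs = freqs or _uniform_freqs()
    pi = freqs.pi
    classes = model_classes(scenario.model, scenario.params, scenario.ncat)
    props = np.array([p for p, _, _ in classes])
    props = props / props.sum()
    omegas = sorted({w for _, wb, wf in classes for w in (wb, wf)})
    eigs, rates = {}, {}
    for w in omegas:
        Q = _unscaled_generator(scenario.params["kappa"], w, pi)
        rates[w] = _mean_rate(Q, pi)
        eigs[w] = _eigen(Q, pi)
    factor = sum(p * rates[wb] for p, wb, _ in classes)

    n = scenario.n_codons
    site_class = rng.choice(len(classes), size=n, p=props)
    root_states = _sample_step(np.tile(pi, (N_SENSE, 1)),
                               np.zeros(n, dtype=int), rng)

    tree = scenario.tree
    fg = tree.foreground
    states_at: dict[int, np.ndarray] = {}
    seq_rows: dict[str, np.ndarray] = {}

    def walk(node, states):
        for child in node.children:
            is_fg = child.is_leaf and child.name == fg
            child_states = states.copy()
            t = child.length / factor
            for k, (_, wb, wfg) in enumerate(classes):
                mask = site_class == k
                if not mask.any():
                    continue
                w = wfg if is_fg else wb
                P = _p_from_eigen(eigs[w], t)
                child_states[mask] = _sample_step(P, states[mask], rng)
            if child.is_leaf:
                seq_rows[child.name] = child_states
            else:
                walk(child, child_states)

    walk(tree.root, root_states)
    taxa = tree.leaves()
    rows = ["".join(SENSE_CODONS[s] for s in seq_rows[t]) for t in taxa]
    return CodonAlignment(taxa=taxa, rows=rows), site_class


def _evolve_extra_branch(row: str, scenario: SimScenario, length: float,
                         rng: np.random.Generator,
                         freqs: CodonFrequencies) -> str:
    """Evolve one sequence further along a short branch (paralog divergence)."""
    pi = freqs.pi
    kappa = scenario.params["kappa"]
    classes = model_classes(scenario.model, scenario.params, scenario.ncat)
    w_mean = sum(p * wb for p, wb, _ in classes)
    Q = _unscaled_generator(kappa, w_mean, pi)
    P = _p_from_eigen(_eigen(Q, pi), length / _mean_rate(Q, pi))
    states = np.array([SENSE_CODONS.index(row[k:k + 3])
                       for k in range(0, len(row), 3)])
    out = _sample_step(P, states, rng)
    return "".join(SENSE_CODONS[s] for s in out)


def emit_pipeline_inputs(scenario: SimScenario, out_dir: str | Path,
                         family_overrides: dict[int, tuple[str, dict]] | None = None
                         ) -> dict:
    """Write per-species CDS/peptide FASTA files plus a ground-truth table.

    Each family contributes one gene per species, minus simulated losses
    (``loss_rate`` per species) and plus within-species duplicates
    (``paralog_rate`` per family, one extra copy on a short branch).
    ``family_overrides`` replaces (model, params) for selected family indices.
    Returns a manifest dict with per-family truth.
    """
    out_dir = Path(out_dir)
    cds_dir = out_dir / "cds"
    pep_dir = out_dir / "pep"
    cds_dir.mkdir(parents=True, exist_ok=True)
    pep_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    freqs = _uniform_freqs()
    species = scenario.tree.leaves()
    per_species: dict[str, list[tuple[str, str]]] = {sp: [] for sp in species}
    truth_rows = []

    for fam in range(scenario.n_families):
        model, params = scenario.model, scenario.params
        if family_overrides and fam in family_overrides:
            model, params = family_overrides[fam]
        fam_scn = SimScenario(tree=scenario.tree, model=model, params=dict(params),
                              n_codons=scenario.n_codons, seed=scenario.seed)
        aln, site_class = evolve_alignment(fam_scn, rng=rng, freqs=freqs)
        lost = [sp for sp in species if rng.random() < scenario.loss_rate]
        dup_family = rng.random() < scenario.paralog_rate
        dup_species = species[rng.integers(len(species))] if dup_family else None
        for sp in species:
            if sp in lost:
                continue
            header = f"{sp}_g{fam + 1:03d}"
            row = aln.row(sp)
            per_species[sp].append((header, row))
            truth_rows.append((fam + 1, sp, header, model, "ortholog"))
            if sp == dup_species:
                dup = _evolve_extra_branch(row, fam_scn, PARALOG_BRANCH, rng, freqs)
                per_species[sp].append((header + "p", dup))
                truth_rows.append((fam + 1, sp, header + "p", model, "paralog"))

    for sp in species:
        cds_records = per_species[sp]
        write_fasta(cds_records, cds_dir / f"{sp}.fa")
        write_fasta([(h, translate(s)) for h, s in cds_records],
                    pep_dir / f"{sp}.fa")
    with open(out_dir / "ground_truth.tsv", "w") as fh:
        fh.write("family\tspecies\theader\tmodel\trole\n")
        for r in truth_rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return {
        "cds_dir": str(cds_dir), "pep_dir": str(pep_dir),
        "species": species, "n_families": scenario.n_families,
        "truth": truth_rows,
    }
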