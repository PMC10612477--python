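import numpy as np
import pytest

from orthoselect.gene_tree import parse_newick
from orthoselect.simulator import DEFAULT_PARAMS, SimScenario, evolve_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def five_taxon_tree():
    return parse_newick("((spA:0.3,spB:0.3):0.15,(spC:0.3,spD:0.3):0.15,spE:0.3);")


@pytest.fixture
def small_m0_alignment(five_taxon_tree):
    """A 200-codon alignment simulated under one-ratio purifying selection."""
    scn = SimScenario(tree=five_taxon_tree, model="M0",
                      params=dict(DEFAULT_PARAMS["M0"]), n_codons=200, seed=42)
    ca, _ = evolve_alignment(scn)
    return ca


def write_fasta_text(path, records):
    with open(path, "w") as fh:
        for h, s in records:
            fh.write(f">{h}\n{s}\n")
    return path
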