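import numpy as np
import pytest

from clovermap import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """A small two-pair (4-group) simulated dataset with full truth."""
    rng = np.random.default_rng(7)
    genome = sim.SimGenome.regular(n_pairs=2, length_cm=100,
                                   markers_per_group=14)
    design = sim.SimDesign(n_progeny=188, n_biparental=16, n_female=20,
                           n_male=20, multi_locus_fraction=0.2,
                           missing_rate=0.05, error_rate=0.01)
    haplos = {p: sim.simulate_gametes(genome, design, p, rng)
              for p in ("P1", "P2")}
    loci = sim.assign_loci(genome, design, rng)
    table, truth = sim.render_genotype_table(haplos, loci, design, genome,
                                             rng)
    return table, truth


def strip_suffix(locus_id: str) -> str:
    return locus_id[:-3] if locus_id.endswith(("_P1", "_P2")) else locus_id
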