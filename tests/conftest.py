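"""Shared fixtures: small synthetic panels, families and cohorts."""

import numpy as np
import pytest

from paleokin import simdata as sd


@pytest.fixture(scope="session")
def two_pop_graph():
    return sd.AdmixtureGraphSpec(
        nodes=["R", "O", "POP"],
        edges={"O": ("R", 0.2), "POP": ("R", 0.05)})


@pytest.fixture(scope="session")
def pop_freqs(two_pop_graph):
    freqs, panel = sd.simulate_graph_frequencies(two_pop_graph, 30_000, 11)
    return freqs, panel


@pytest.fixture(scope="session")
def family_truth(pop_freqs):
    """Nuclear family with three children, plus X panel."""
    freqs, panel = pop_freqs
    xpanel = sd.make_panel(6000, 77, "X", prefix="x")
    xfreqs, xpanel = sd.simulate_graph_frequencies(
        sd.AdmixtureGraphSpec(nodes=["R", "POP"], edges={"POP": ("R", 0.05)}),
        6000, 78, panel=xpanel)
    ped = sd.nuclear_family(3)
    truth = sd.gene_drop(ped, {"POP": freqs["POP"]}, panel, 21,
                         x_panel=xpanel, x_freqs={"POP": xfreqs["POP"]})
    return truth, ped


@pytest.fixture(scope="session")
def family_store(family_truth, pop_freqs):
    """Called genotypes for the family at moderate coverage with damage."""
    from paleokin import genocall as gc
    truth, ped = family_truth
    spec = sd.SequencingSpec(mean_depth=4.0, base_error=0.002,
                             deamination_rate=0.15, seed=31)
    piles = sd.sequence(truth, spec)
    store = gc.build_store(piles, gc.DamageProfile.terminal(0.15), seed=32,
                           sexes=truth.sex)
    return store, truth
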