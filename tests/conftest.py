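"""Shared fixtures.

The expensive scenario pipelines (lattice replicates + model fits) are
session-scoped so several tests can interrogate one run.  Sizes follow
the reduced-scale study design: side-40 lattice, 20 replicates for the
cell-to-cell-only scenarios, 12 for the mixed/cell-free ones.
"""

import numpy as np
import pytest

import focusdyn as fd

SEED = 1


@pytest.fixture(scope="session")
def small_lattice():
    return fd.build_hex_lattice(8)


@pytest.fixture(scope="session")
def lattice40():
    return fd.build_hex_lattice(40)


@pytest.fixture(scope="session")
def single_focus_report():
    """CC-only growth from one central cell, fitted with all four variants."""
    cfg = fd.ScenarioConfig(side=40, n_replicates=20, seed=SEED,
                            n_restarts=4, models=("CC", "aCC", "aCC-dI"))
    return fd.run_single_focus(cfg)


@pytest.fixture(scope="session")
def multifocus_report():
    """Inoculated CC-only growth, fitted from the 17 h sample onward."""
    cfg = fd.ScenarioConfig(side=40, n_replicates=20, seed=SEED,
                            n_restarts=4, models=("CC", "aCC", "aCC-dI"))
    return fd.run_multifocus(cfg)


@pytest.fixture(scope="session")
def mixed_slow_report():
    cfg = fd.ScenarioConfig(side=40, n_replicates=12, seed=SEED,
                            n_restarts=4, models=("CCF", "aCCF"))
    return fd.run_mixed_transmission(cfg, diffusion="slow")


@pytest.fixture(scope="session")
def mixed_fast_report():
    cfg = fd.ScenarioConfig(side=40, n_replicates=12, seed=SEED,
                            n_restarts=4, models=("CCF", "aCCF"))
    return fd.run_mixed_transmission(cfg, diffusion="fast")
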