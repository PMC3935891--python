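"""Shared fixtures: desk-scale synthetic datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest

import telobind as tb
from telobind.constants import KB

KT300 = KB * 300.0


@pytest.fixture(scope="session")
def funnel():
    """Default Gaussian-well binding landscape."""
    return tb.ModelPotential.gaussian_funnel()


@pytest.fixture(scope="session")
def small_umbrella(funnel):
    """16-window dataset at reduced sampling (10^4 saved samples/window).

    Enough for consistency checks within a few seconds; the full-scale run
    lives in the acceptance tests.
    """
    windows = tb.make_windows(1.5, 4.5, 0.2, 700.0)
    params = tb.LangevinParams(kT=KT300, n_steps=100_000, stride=10,
                               seed=11, n_walkers=16)
    samples, report = tb.generate_umbrella_dataset(funnel, windows, params)
    return samples, report, params


@pytest.fixture(scope="session")
def small_pmf(small_umbrella):
    samples, _, _ = small_umbrella
    return tb.wham_solve(samples)


@pytest.fixture()
def single_atom_ensemble():
    atoms = pd.DataFrame([dict(name="C1", element="C", resid=1, resname="LIG",
                               chain="A", charge=0.0, sigma=0.34,
                               epsilon=0.36, donor=False, acceptor=False)])
    return tb.FrameEnsemble(atoms=atoms, coords=np.zeros((1, 1, 3)))


def make_atoms(specs):
    """specs: iterable of (name, element, resid, chain, charge, donor, acceptor)."""
    rows = []
    for name, element, resid, chain, charge, donor, acceptor in specs:
        rows.append(dict(name=name, element=element, resid=resid,
                         resname="X", chain=chain, charge=charge,
                         sigma=0.3, epsilon=0.5, donor=donor,
                         acceptor=acceptor))
    return pd.DataFrame(rows)
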