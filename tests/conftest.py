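"""Shared fixtures: packaged data, prepared molecules, a small aligned ensemble."""

from __future__ import annotations

import numpy as np
import pytest

from cptqsar import structures as st
from cptqsar.datasets import load_paper_fixture
from cptqsar.fields import GridSpec


@pytest.fixture(scope="session")
def paper_fixture():
    return load_paper_fixture()


@pytest.fixture(scope="session")
def prep_config():
    return st.PrepConfig()


def _prepare(smiles: str, cid: str, cfg: st.PrepConfig) -> st.Molecule3D:
    mol = st.parse_molecule(smiles, "smiles", mol_id=cid)
    mol = st.prepare_conformer(mol, cfg)
    return st.assign_charges(mol)


@pytest.fixture(scope="session")
def prepared_template(paper_fixture, prep_config):
    """Compound 4d (the alignment template), embedded, minimized, charged."""
    return _prepare(paper_fixture.compounds["4d"], "4d", prep_config)


@pytest.fixture(scope="session")
def prepared_4a(paper_fixture, prep_config):
    return _prepare(paper_fixture.compounds["4a"], "4a", prep_config)


@pytest.fixture(scope="session")
def mini_ensemble(paper_fixture, prep_config, prepared_template):
    """Four derivatives aligned onto the 4d template (fast subset)."""
    aligned = []
    for cid in ("4d", "4a", "4c", "4l"):
        mol = (
            prepared_template
            if cid == "4d"
            else _prepare(paper_fixture.compounds[cid], cid, prep_config)
        )
        corr = st.match_scaffold(mol, prepared_template, paper_fixture.scaffold_smarts)
        moved, _ = st.superpose(mol, prepared_template, corr)
        aligned.append(moved)
    return aligned


@pytest.fixture(scope="session")
def qsar_results():
    """One full pipeline run on the packaged compound set, shared by tests."""
    from cptqsar.pipeline import RunConfig, run_qsar

    return run_qsar(RunConfig())


@pytest.fixture()
def small_grid():
    return GridSpec(origin=(0.0, 0.0, 0.0), spacing=2.0, shape=(4, 4, 4))


@pytest.fixture()
def rng():
    return np.random.default_rng(20150513 % 2**31)


def random_rotation(rng) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
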