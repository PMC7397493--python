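"""Shared fixtures: small synthetic structures and reflection sets."""

import numpy as np
import pytest

from microshred.model_io import StructureModel


def build_chain(n_res, chain="A", res_name="GLY", offset=(0.0, 0.0, 0.0),
                first_res=1, spacing=3.8):
    """Straight full-backbone chain: N, CA, C, O per residue."""
    rows = {k: [] for k in ("element", "name", "res_id", "res_name",
                            "chain", "xyz", "occ", "b")}
    offset = np.asarray(offset, dtype=float)
    deltas = [("N", "N", (-1.2, 0.5, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
              ("C", "C", (1.3, 0.4, 0.0)), ("O", "O", (1.5, 1.6, 0.0))]
    for i in range(n_res):
        base = np.array([i * spacing, 0.0, 0.0]) + offset
        for name, el, d in deltas:
            rows["element"].append(el)
            rows["name"].append(name)
            rows["res_id"].append(first_res + i)
            rows["res_name"].append(res_name)
            rows["chain"].append(chain)
            rows["xyz"].append(base + d)
            rows["occ"].append(1.0)
            rows["b"].append(10.0)
    return StructureModel(element=rows["element"], name=rows["name"],
                          res_id=rows["res_id"], res_name=rows["res_name"],
                          chain=rows["chain"], xyz=np.array(rows["xyz"]),
                          occ=rows["occ"], b_factor=rows["b"])


def random_blob(n_atoms, seed=0, elements=("C", "N", "O", "S"),
                extent=10.0, b_range=(2.0, 20.0)):
    """Random pseudo-atoms labelled as CA for quick diffraction tests."""
    rng = np.random.default_rng(seed)
    return StructureModel(
        element=rng.choice(elements, n_atoms),
        name=np.array(["CA"] * n_atoms, dtype=object),
        res_id=np.arange(1, n_atoms + 1),
        res_name=np.array(["ALA"] * n_atoms, dtype=object),
        chain=np.array(["A"] * n_atoms, dtype=object),
        xyz=rng.uniform(0.0, extent, (n_atoms, 3)),
        occ=rng.uniform(0.4, 1.0, n_atoms),
        b_factor=rng.uniform(*b_range, n_atoms))


@pytest.fixture
def chain30():
    return build_chain(30)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
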