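"""Shared fixtures and oracle helpers.

SDF fixtures are generated at test time from SMILES via RDKit, so no
binary data ships with the package.  The helpers here are deliberately
independent of the implementation paths they check (brute-force
neighbour search, central finite differences).
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from druglike.moldata import MoleculeRecord


def smiles_to_sdf_text(smiles_list) -> str:
    """V2000 SDF text with one $$$$-delimited entry per SMILES."""
    blocks = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None, f"fixture SMILES failed to parse: {smi}"
        blocks.append(Chem.MolToMolBlock(mol) + "$$$$\n")
    return "".join(blocks)


CORRUPT_SDF_ENTRY = "this is not a molecule\n\n\n  1  0\nnonsense\nM  END\n$$$$\n"


@pytest.fixture
def write_sdf_file(tmp_path):
    def _write(smiles_list, name="mols.sdf", corrupt_entries=0):
        text = smiles_to_sdf_text(smiles_list) + CORRUPT_SDF_ENTRY * corrupt_entries
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def records_from_smiles(smiles_list, source_set="positive"):
    """Build MoleculeRecords directly, bypassing file I/O."""
    out = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None
        out.append(MoleculeRecord(record_id=i, mol=mol,
                                  canonical_id=Chem.MolToInchi(mol),
                                  source_set=source_set))
    return out


# --------------------------------------------------------------------------
# independent oracles

def numerical_gradients(loss_fn, arrays, h=1e-6):
    """Central finite differences of ``loss_fn()`` w.r.t. each array entry.

    ``loss_fn`` must read the (mutated in place) arrays on every call.
    """
    grads = []
    for arr in arrays:
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            up = loss_fn()
            flat[i] = orig - h
            down = loss_fn()
            flat[i] = orig
            gflat[i] = (up - down) / (2 * h)
        grads.append(g)
    return grads


def check_smote_geometry(minority, synthetic, k, atol=1e-9):
    """Verify each synthetic row solves x_new = x_i + u (x_nn - x_i) for some
    minority row x_i, one of its k nearest minority neighbours x_nn
    (brute-force search, self excluded), and u in [0, 1]."""
    minority = np.asarray(minority, dtype=float)
    d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    neigh = np.argsort(d2, axis=1, kind="stable")[:, :k]
    for x_new in np.asarray(synthetic, dtype=float):
        ok = False
        for i in range(len(minority)):
            for j in neigh[i]:
                d = minority[j] - minority[i]
                rel = x_new - minority[i]
                dd = float(d @ d)
                if dd == 0:
                    if np.allclose(rel, 0, atol=atol):
                        ok = True
                        break
                    continue
                u = float(rel @ d) / dd
                if -1e-12 <= u <= 1 + 1e-12 and np.allclose(
                        minority[i] + u * d, x_new, atol=atol):
                    ok = True
                    break
            if ok:
                break
        assert ok, f"synthetic point {x_new} is not on an admissible SMOTE segment"
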