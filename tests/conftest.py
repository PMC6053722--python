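"""Shared fixtures: tiny PDB texts, synthetic helices, graph builders."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from rincompare.structure_io import AtomSite, ResidueSite, StructureModel, read_pdb
from rincompare.synthetic_structures import HelixSpec, PerturbationSpec, make_ideal_helix, perturb_residues

MINIMAL_GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  7.38           N
ATOM      2  CA  GLY A   1      10.523   5.590  -5.292  1.00  7.05           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA ASER A   1       1.500   0.000   0.000  0.60 10.00           C
ATOM      3  CA BSER A   1       1.600   0.100   0.000  0.40 10.00           C
ATOM      4  OG  SER A   1       2.000   1.300   0.000  1.00 10.00           O
END
"""

#: Real-structure inputs (not distributable with the package): place the
#: wild-type and variant lysozyme coordinate files here to enable the
#: crystal-structure reproductions.
LYSOZYME_DIR = Path(__file__).resolve().parents[1] / "data" / "pdb"


def load_lysozyme(pdb_id: str) -> StructureModel:
    """Load a user-supplied lysozyme structure or fail the calling test."""
    path = LYSOZYME_DIR / f"{pdb_id.lower()}.pdb"
    if not path.exists():
        pytest.fail(
            f"requires the {pdb_id.upper()} crystal structure at {path}. "
            "This file is not distributable with the package and the pipeline "
            "never fetches from the network; download it from the Protein "
            "Data Bank and re-run."
        )
    return read_pdb(str(path), model_id=pdb_id.lower())


def ca_only_model(positions, chain_id="A", model_id="points") -> StructureModel:
    """A bare model with one CA per residue at the given coordinates."""
    residues = [
        ResidueSite(
            chain_id,
            i + 1,
            "",
            "GLY",
            [AtomSite(i + 1, "CA", "C", np.asarray(p, float))],
        )
        for i, p in enumerate(positions)
    ]
    return StructureModel(id=model_id, chains={chain_id: residues})


@pytest.fixture
def minimal_model():
    return read_pdb(MINIMAL_GLY_PDB, model_id="mini")


@pytest.fixture
def helix30():
    model = make_ideal_helix(HelixSpec(n_residues=30))
    model.id = "ref"
    return model


@pytest.fixture
def displaced_variants(helix30):
    """Two variants with planted displacement sets {5, 9} and {9, 14}."""
    v1 = perturb_residues(
        helix30,
        PerturbationSpec(target_residues={5, 9}, displacement=2.5, direction=(0.0, 0.0, 1.0)),
    )
    v1.id = "var1"
    v2 = perturb_residues(
        helix30,
        PerturbationSpec(target_residues={9, 14}, displacement=2.5, direction=(1.0, 0.0, 0.0)),
    )
    v2.id = "var2"
    return v1, v2
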