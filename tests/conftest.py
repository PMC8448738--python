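"""Shared fixtures: small synthetic assemblies with planted ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pbsnet import AssemblyModel, annotate_subunits, extract_chromophores, load_structure
from pbsnet.chromophore import Chromophore
from pbsnet.fixtures import (
    ChromophoreSite,
    DecoySite,
    FixtureSpec,
    annotation_config_from_manifest,
    make_assembly,
)
from pbsnet.regions import Region, Role
from pbsnet.structure_io import ATOM_COLUMNS


def point_chromophore(label: str, position, role: Role = Role.OTHER) -> Chromophore:
    """Single-atom chromophore for graph-level tests (distance = Euclidean)."""
    x, y, z = (float(v) for v in position)
    atoms = pd.DataFrame(
        [(label, "TBL", 301, "", "NA", "N", x, y, z, False, 1)], columns=ATOM_COLUMNS
    )
    return Chromophore(
        chain_id=label,
        residue_number=301,
        component_code="TBL",
        atoms=atoms,
        ring_map={"A": ["NA"]},
        conjugated_atoms=["NA"],
        parent_role=role,
        region=Region(),
    )


def build_fixture(tmp_path, spec: FixtureSpec, basename: str = "fixture"):
    """Realize a spec, reload from the written mmCIF, annotate, extract."""
    result = make_assembly(spec, tmp_path, basename)
    model = load_structure(result.cif_path)
    model = annotate_subunits(model, annotation_config_from_manifest(result.manifest))
    chromophores = extract_chromophores(model, ["TBL"])
    return result, model, chromophores


@pytest.fixture(scope="session")
def env_fixture(tmp_path_factory):
    """Two-bilin assembly with decoy residues at engineered distances."""
    spec = FixtureSpec(
        chromophores=[
            ChromophoreSite(
                center=(0, 0, 0),
                role="ApcD",
                region={"compartment": "core", "cylinder": "A", "layer": 4},
            ),
            ChromophoreSite(
                center=(30, 0, 0),
                role="ApcF",
                region={"compartment": "core", "cylinder": "A", "layer": 3},
            ),
        ],
        decoys=[
            DecoySite("TYR", 0, 5.0, "D"),
            DecoySite("TYR", 0, 8.5, "D"),
            DecoySite("PHE", 0, 4.5, "A"),
            DecoySite("ARG", 1, 4.0, "B"),
            DecoySite("TRP", 1, 9.0, "C"),
            DecoySite("ALA", 1, 6.0, None),
        ],
        seed=11,
    )
    tmp = tmp_path_factory.mktemp("env_fixture")
    return build_fixture(tmp, spec, "env")


def random_positions(rng: np.random.Generator, n: int, scale: float = 60.0) -> np.ndarray:
    return rng.uniform(0, scale, size=(n, 3))
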