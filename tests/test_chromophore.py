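"""Ring partition, chromophore extraction and distance metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from pbsnet import (
    chromophore_distance,
    extract_chromophores,
    partition_rings,
    residue_ring_distance,
)
from pbsnet.chromophore import DistanceMetric
from pbsnet.errors import EmptySelectionError, MetricUndefinedError, NomenclatureError
from pbsnet.fixtures import ChromophoreSite, DecoySite, FixtureSpec, make_toy_chromophore
from pbsnet.structure_io import ATOM_COLUMNS

from conftest import build_fixture, point_chromophore


def _atoms_df(names):
    rows = [
        ("X", "CYC", 1, "", name, name[0], float(i), 0.0, 0.0, False, 1)
        for i, name in enumerate(names)
    ]
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


class TestPartitionRings:
    @pytest.mark.parametrize(
        "name,where",
        [
            ("C2A", "A"),   # ring-core carbon of ring A
            ("NA", "A"),    # pyrrole nitrogen
            ("C4D", "D"),
            ("CHB", "HB"),  # methine bridge
            ("CHD", "HD"),
        ],
    )
    def test_name_routing(self, name, where):
        ring_map = partition_rings(_atoms_df([name, "C1A"]))
        assert name in ring_map[where]

    @pytest.mark.parametrize("name", ["CBA", "CMA", "O1A", "CAB", "CAC", "CBD"])
    def test_side_chain_excluded(self, name):
        """Propionate/methyl/vinyl branch atoms stay out of rings."""
        ring_map = partition_rings(_atoms_df([name, "C1A"]))
        assigned = {a for atoms in ring_map.values() for a in atoms}
        assert name not in assigned

    def test_no_bilin_names_raises(self):
        with pytest.raises(NomenclatureError):
            partition_rings(_atoms_df(["CA", "CB", "OXT"]))

    def test_toy_chromophore_partition(self):
        """The toy tetrapyrrole yields four 5-atom rings and three bridges."""
        atoms = make_toy_chromophore((0, 0, 0))
        assert len(atoms) == 23
        df = _atoms_df([n for n, _, _ in atoms])
        ring_map = partition_rings(df)
        for ring in "ABCD":
            assert len(ring_map[ring]) == 5
        for bridge in ("HB", "HC", "HD"):
            assert len(ring_map[bridge]) == 1


class TestChromophoreDistance:
    def test_zero_self_distance(self):
        c = point_chromophore("A", (1, 2, 3))
        for metric in DistanceMetric:
            assert chromophore_distance(c, c, metric) == 0.0

    def test_three_four_five(self):
        c1 = point_chromophore("A", (0, 0, 0))
        c2 = point_chromophore("B", (3, 4, 0))
        for metric in DistanceMetric:
            assert chromophore_distance(c1, c2, metric) == pytest.approx(5.0)

    def test_min_atom_equals_bruteforce(self):
        """min metrics equal the exhaustive minimum over the atom cross product."""
        rng = np.random.default_rng(42)

        def random_chromo(label, offset):
            names = [f"C{j}{L}" for L in "ABCD" for j in range(1, 5)] + ["NA", "NB", "NC", "ND"]
            coords = rng.normal(0, 4, size=(20, 3)) + offset
            rows = [
                (label, "TBL", 301, "", names[i], "C", *coords[i], False, 1)
                for i in range(20)
            ]
            atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
            from pbsnet.chromophore import chromophore_from_atoms

            return chromophore_from_atoms(atoms), coords

        c1, xyz1 = random_chromo("A", 0.0)
        c2, xyz2 = random_chromo("B", 15.0)
        expected = cdist(xyz1, xyz2).min()
        assert chromophore_distance(c1, c2, DistanceMetric.MIN_ANY_ATOM) == pytest.approx(expected, abs=1e-9)
        assert chromophore_distance(c1, c2, DistanceMetric.MIN_CONJUGATED_ATOM) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_superset_monotonicity(self, seed):
        """d(a,b)=d(b,a); min over all atoms never exceeds min over conjugated."""
        rng = np.random.default_rng(seed)
        atoms1 = make_toy_chromophore(rng.uniform(-20, 20, 3))
        atoms2 = make_toy_chromophore(rng.uniform(-20, 20, 3))

        def to_chromo(label, atoms):
            rows = [(label, "TBL", 301, "", n, e, *p, False, 1) for n, e, p in atoms]
            df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
            from pbsnet.chromophore import chromophore_from_atoms
            return chromophore_from_atoms(df)

        c1, c2 = to_chromo("A", atoms1), to_chromo("B", atoms2)
        for metric in DistanceMetric:
            assert chromophore_distance(c1, c2, metric) == chromophore_distance(c2, c1, metric)
        assert chromophore_distance(c1, c2, DistanceMetric.MIN_ANY_ATOM) <= (
            chromophore_distance(c1, c2, DistanceMetric.MIN_CONJUGATED_ATOM) + 1e-12
        )

    def test_rigid_motion_invariance(self):
        """One rotation+translation applied to both changes nothing (1e-6 Å)."""
        rng = np.random.default_rng(3)
        R = Rotation.random(random_state=9).as_matrix()
        t = rng.uniform(-50, 50, 3)

        def pair(transform):
            out = []
            for label, center in (("A", np.zeros(3)), ("B", np.array([18.0, 5.0, -2.0]))):
                atoms = make_toy_chromophore(center)
                rows = []
                for n, e, p in atoms:
                    q = R @ p + t if transform else p
                    rows.append((label, "TBL", 301, "", n, e, *q, False, 1))
                df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
                from pbsnet.chromophore import chromophore_from_atoms
                out.append(chromophore_from_atoms(df))
            return out

        (a0, b0), (a1, b1) = pair(False), pair(True)
        for metric in DistanceMetric:
            d0 = chromophore_distance(a0, b0, metric)
            d1 = chromophore_distance(a1, b1, metric)
            assert d1 == pytest.approx(d0, abs=1e-6)

    def test_empty_conjugated_set_raises(self):
        c = point_chromophore("A", (0, 0, 0))
        c.conjugated_atoms = []
        with pytest.raises(MetricUndefinedError):
            chromophore_distance(c, c, DistanceMetric.MIN_CONJUGATED_ATOM)


class TestExtraction:
    def test_counts_and_parent_roles(self, tmp_path):
        spec = FixtureSpec(
            chromophores=[
                ChromophoreSite(center=(0, 0, 0), role="ApcA"),
                ChromophoreSite(center=(40, 0, 0), role="ApcB"),
                ChromophoreSite(center=(80, 0, 0), role="CpcA",
                                region={"compartment": "rod", "rod_name": "R1"}),
            ],
            seed=1,
        )
        _, model, chromos = build_fixture(tmp_path, spec)
        assert len(chromos) == 3
        assert [c.parent_role.value for c in chromos] == ["ApcA", "ApcB", "CpcA"]

    def test_empty_codes_empty_list(self, env_fixture):
        _, model, _ = env_fixture
        assert extract_chromophores(model, []) == []

    def test_no_matches_is_empty_not_error(self, env_fixture):
        _, model, _ = env_fixture
        assert extract_chromophores(model, ["ZZZ"]) == []


class TestResidueRingDistance:
    def test_engineered_five_angstrom_contact(self, env_fixture):
        """A Tyr planted 5.0 Å from ring D measures 5.0 Å from the file."""
        result, model, chromos = env_fixture
        decoy = result.manifest["decoys"][0]
        target = next(c for c in chromos if c.label == decoy["target_id"])
        d = residue_ring_distance(model, decoy["chain_id"], 1, target, "D")
        assert d == pytest.approx(5.0, abs=0.01)

    def test_absent_ring_raises(self, env_fixture):
        _, model, chromos = env_fixture
        c = chromos[0]
        degenerate = point_chromophore("Z", (0, 0, 0))
        with pytest.raises(MetricUndefinedError):
            residue_ring_distance(model, "A", 1, degenerate, "D")

    def test_backbone_only_selection_raises(self, env_fixture):
        _, model, chromos = env_fixture
        import pandas as pd
        from pbsnet.structure_io import ATOM_COLUMNS
        gly = pd.DataFrame(
            [("ZG", "GLY", 1, "", n, n[0], 0.0, 0.0, 0.0, True, 1)
             for n in ("N", "CA", "C", "O")],
            columns=ATOM_COLUMNS,
        )
        model2 = model.with_atoms(pd.concat([model.atoms, gly], ignore_index=True))
        with pytest.raises(EmptySelectionError):
            residue_ring_distance(model2, "ZG", 1, chromos[0], "D")
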