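"""Residue contacts, π–π / cation–π geometry, aromatic censuses."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from pbsnet import (
    aromatic_census,
    chromophore_neighborhood,
    classify_cation_pi,
    classify_contacts,
    classify_pi_interaction,
)
from pbsnet.errors import DegenerateGeometryError, EmptySelectionError
from pbsnet.fixtures import ChromophoreSite, DecoySite, FixtureSpec
from pbsnet.microenvironment import interplanar_angle, linker_polarization, ring_plane
from pbsnet.structure_io import ATOM_COLUMNS

from conftest import build_fixture


def hexagon(center=(0.0, 0.0, 0.0), radius=1.39, normal_z=True):
    cx, cy, cz = center
    pts = []
    for k in range(6):
        a = 2 * np.pi * k / 6
        pts.append((cx + radius * np.cos(a), cy + radius * np.sin(a), cz))
    return np.array(pts)


class TestRingGeometry:
    def test_plane_normal_of_flat_ring(self):
        centroid, normal = ring_plane(hexagon())
        np.testing.assert_allclose(centroid, [0, 0, 0], atol=1e-12)
        assert abs(abs(normal[2]) - 1.0) < 1e-12

    def test_collinear_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            ring_plane(pts)

    def test_known_angle_recovered(self):
        """Two planes constructed 30° apart give 30° to closed-form accuracy."""
        r1 = hexagon()
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        r2 = hexagon() @ R.T + np.array([0, 0, 4.0])
        _, n1 = ring_plane(r1)
        _, n2 = ring_plane(r2)
        assert interplanar_angle(n1, n2) == pytest.approx(30.0, abs=1e-6)

    def test_angle_folded_to_quadrant(self):
        n1 = np.array([0.0, 0.0, 1.0])
        n2 = -n1  # antiparallel normals are the same plane
        assert interplanar_angle(n1, n2) == pytest.approx(0.0, abs=1e-9)


class TestPiClassification:
    def test_parallel_stack(self):
        r1 = hexagon()
        r2 = hexagon(center=(0.5, 0.0, 3.5))
        ann = classify_pi_interaction(r1, r2)
        assert ann.kind == "pi_pi_parallel"
        assert ann.interplanar_angle == pytest.approx(0.0, abs=1e-9)

    def test_t_shaped(self):
        r1 = hexagon()
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        r2 = hexagon() @ R.T + np.array([0, 0, 5.0])
        ann = classify_pi_interaction(r2, r1)
        assert ann.kind == "pi_pi_tshaped"
        assert ann.interplanar_angle == pytest.approx(90.0, abs=1e-9)
        assert ann.centroid_distance == pytest.approx(5.0, abs=1e-9)

    def test_far_apart_is_none(self):
        ann = classify_pi_interaction(hexagon(), hexagon(center=(0, 0, 12.0)))
        assert ann.kind == "none"

    def test_invariance_under_permutation_and_rigid_motion(self):
        """Atom order and global motion leave distance/angle unchanged."""
        rng = np.random.default_rng(21)
        r1 = hexagon()
        R30 = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        r2 = hexagon() @ R30.T + np.array([1.0, 0.5, 4.0])
        base = classify_pi_interaction(r1, r2)
        perm = rng.permutation(6)
        moved = Rotation.random(random_state=4).as_matrix()
        t = rng.uniform(-30, 30, 3)
        ann = classify_pi_interaction(r1[perm] @ moved.T + t, r2 @ moved.T + t)
        assert ann.kind == base.kind
        assert ann.centroid_distance == pytest.approx(base.centroid_distance, abs=1e-6)
        assert ann.interplanar_angle == pytest.approx(base.interplanar_angle, abs=1e-6)


class TestCationPi:
    def _arg(self, dz):
        rows = [
            ("R", "ARG", 1, "", name, name[0], x, y, dz, True, 1)
            for name, x, y in (
                ("N", -3.0, 1.0), ("CA", -3.0, 0.0), ("C", -4.0, -1.0), ("O", -5.0, -1.0),
                ("NE", -1.2, 0.0), ("CZ", 0.0, 0.0), ("NH1", 0.6, 1.04), ("NH2", 0.6, -1.04),
            )
        ]
        return pd.DataFrame(rows, columns=ATOM_COLUMNS)

    def test_guanidinium_over_ring(self):
        ann = classify_cation_pi(self._arg(4.0), hexagon())
        assert ann.kind == "cation_pi"
        assert ann.centroid_distance == pytest.approx(4.0, abs=0.01)

    def test_far_away_is_none(self):
        assert classify_cation_pi(self._arg(12.0), hexagon()).kind == "none"

    def test_missing_group_raises(self):
        df = self._arg(4.0)
        df = df[df["atom_name"].isin(["N", "CA", "C", "O"])]
        with pytest.raises(EmptySelectionError):
            classify_cation_pi(df, hexagon(), residue_name="ARG")


class TestNeighborhood:
    def test_cutoff_below_nearest_contact_is_empty(self, env_fixture):
        _, model, chromos = env_fixture
        assert chromophore_neighborhood(model, chromos[0], cutoff=2.0) == []

    def test_matches_bruteforce_over_all_residues(self, env_fixture):
        """The KD-tree neighborhood equals a direct scan of every residue."""
        _, model, chromos = env_fixture
        cutoff = 10.0
        for chromo in chromos:
            got = {
                (c.chain_id, c.residue_number): c.min_distance
                for c in chromophore_neighborhood(model, chromo, cutoff)
            }
            chromo_xyz = chromo.atom_coords()
            expected = {}
            poly = model.atoms[model.atoms["is_polymer"]]
            for (cid, num), res in poly.groupby(["chain_id", "residue_number"]):
                side = res[~res["atom_name"].isin(("N", "CA", "C", "O", "OXT"))]
                if len(side) == 0:
                    continue
                d = cdist(side[["x", "y", "z"]].to_numpy(), chromo_xyz).min()
                if d <= cutoff:
                    expected[(cid, int(num))] = d
            assert set(got) == set(expected)
            for key in got:
                assert got[key] == pytest.approx(expected[key], abs=1e-9)

    def test_contacts_sorted_and_ring_attributed(self, env_fixture):
        result, model, chromos = env_fixture
        contacts = chromophore_neighborhood(model, chromos[0], 10.0)
        dists = [c.min_distance for c in contacts]
        assert dists == sorted(dists)
        tyr = [c for c in contacts if c.residue_name == "TYR"]
        assert tyr and tyr[0].nearest_ring == "D"

    def test_classified_table_echoes_thresholds(self, env_fixture):
        _, model, chromos = env_fixture
        contacts = chromophore_neighborhood(model, chromos[1], 10.0)
        table = classify_contacts(model, chromos[1], contacts)
        assert "pi_parallel_max_dist" in table.columns
        assert (table["pi_parallel_max_dist"] == 5.5).all()


class TestAromaticCensus:
    def test_planted_counts_and_polarization(self, tmp_path):
        """4 Tyr near one bilin and none near another count as (4, 0)."""
        spec = FixtureSpec(
            chromophores=[
                ChromophoreSite(center=(0, 0, 0), role="CpcB",
                                region={"compartment": "rod", "rod_name": "R1", "hexamer_index": 1}),
                ChromophoreSite(center=(60, 0, 0), role="CpcB",
                                region={"compartment": "rod", "rod_name": "R1", "hexamer_index": 2}),
            ],
            decoys=[DecoySite("TYR", 0, 5.0, ring, chain_id="L")
                    for ring in ("A", "B", "C", "D")],
            seed=2,
        )
        result, model, chromos = build_fixture(tmp_path, spec, "census")
        census = aromatic_census(model, chromos, cutoff=8.0, grouping="chain")
        row = census.set_index("group").loc["L"]
        assert row["n_tyr"] == 4
        assert row["n_trp"] == 0
        pol = linker_polarization(model, "L", chromos[0], chromos, cutoff=8.0)
        assert pol == pytest.approx(1.0)

    def test_census_monotone_in_cutoff(self, env_fixture):
        _, model, chromos = env_fixture
        totals = []
        for cutoff in (4.0, 6.0, 9.0, 12.0):
            census = aromatic_census(model, chromos, cutoff, grouping="chain")
            totals.append(census["n_aromatic"].sum() if len(census) else 0)
        assert totals == sorted(totals)

    def test_rarest_type_identified(self, env_fixture):
        """With one planted Trp and several Tyr/Phe, Trp is the rarest present."""
        _, model, chromos = env_fixture
        census = aromatic_census(model, chromos, cutoff=12.0, grouping="role")
        counts = census[["n_phe", "n_tyr", "n_trp"]].sum()
        assert counts["n_trp"] <= counts["n_tyr"]
        assert counts["n_trp"] <= counts["n_phe"] + 1
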