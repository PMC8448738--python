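"""Synthetic bilin-bearing assemblies with fully controlled geometry.

Real phycobilisome depositions are hundreds of thousands of atoms; every
pipeline stage here is instead exercised on small generated assemblies in
which the ground truth — chromophore positions, planted transfer chains,
decoy-residue distances, subunit roles — is known by construction and
recorded in a manifest.

A *toy chromophore* is a planar four-ring tetrapyrrole mimic: four regular
pentagons named with bilin nomenclature (``NA``/``C1A``-``C4A`` ... suffix
A-D) joined by methine carbons ``CHB``/``CHC``/``CHD``, ~3 Å ring spacing
and ~12 Å total span.  It carries the fictitious component code ``TBL`` so
extraction-by-code is exercised without colliding with real chemistry.
Each chromophore gets a short alanine "stub" chain placed 2.75 Å away as a
covalent-attachment proxy, so parent-role assignment by proximity is
honest.  Decoy residues are idealized side-chain templates (minimal N, CA,
C, O backbone) placed so the realized side-chain-to-target minimum distance
matches the requested distance to 0.01 Å.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chromophore import extract_chromophores
from .errors import FixtureSpecError, InvalidPlacementError
from .regions import Region, Role, parse_role
from .structure_io import ATOM_COLUMNS, AssemblyModel, write_mmcif, write_pdb

#: Fictitious component code of the toy bilin.
TOY_COMPONENT_CODE = "TBL"
#: Residue number under which the toy bilin is stored in its chain.
TOY_LIGAND_RESNUM = 301

STERIC_FLOOR = 2.5  # Å; intended decoy distances below this are rejected
_STUB_CONTACT = 2.75  # Å; realized stub-to-bilin distance (attachment proxy)

_RING_SPACING = 3.0
_PENTAGON_RADIUS = 1.2

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float).reshape(3, 3)
    if np.abs(R @ R.T - np.eye(3)).max() > 1e-6 or np.linalg.det(R) < 0:
        raise InvalidPlacementError("orientation is not a proper rotation matrix")
    return R


def _rotation_from_x(direction: np.ndarray) -> np.ndarray:
    """Proper rotation mapping +x onto ``direction`` (unit)."""
    b = np.asarray(direction, dtype=float)
    b = b / np.linalg.norm(b)
    a = np.array([1.0, 0.0, 0.0])
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s2 = float(np.dot(v, v))
    if s2 < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([-1.0, -1.0, 1.0])  # 180° about z
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s2)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


# ---------------------------------------------------------------------------
# toy chromophore
# ---------------------------------------------------------------------------

def make_toy_chromophore(
    center: Sequence[float], orientation: np.ndarray | None = None
) -> list[tuple[str, str, np.ndarray]]:
    """Atoms of the planar 4-ring tetrapyrrole mimic.

    Returns ``(atom_name, element, position)`` triples: 23 atoms — four
    pentagons of 5 plus three methine bridges — whose centroid equals
    ``center`` to 1e-6 Å.  ``orientation`` rotates the mimic about its
    centroid (identity by default; long axis along +x, ring plane z = 0).
    """
    R = np.eye(3) if orientation is None else _check_rotation(orientation)
    center = np.asarray(center, dtype=float)

    atoms: list[tuple[str, str, np.ndarray]] = []
    ring_letters = "ABCD"
    half_span = 1.5 * _RING_SPACING
    for i, letter in enumerate(ring_letters):
        ring_center = np.array([-half_span + i * _RING_SPACING, 0.0, 0.0])
        names = [f"N{letter}"] + [f"C{j}{letter}" for j in range(1, 5)]
        for k, name in enumerate(names):
            angle = np.pi / 2 + 2 * np.pi * k / 5
            pos = ring_center + _PENTAGON_RADIUS * np.array(
                [np.cos(angle), np.sin(angle), 0.0]
            )
            element = "N" if name.startswith("N") else "C"
            atoms.append((name, element, pos))
    for i, letter in enumerate("BCD"):
        x = -half_span + (i + 0.5) * _RING_SPACING
        atoms.append((f"CH{letter}", "C", np.array([x, -0.9, 0.0])))

    coords = np.array([p for _, _, p in atoms])
    coords -= coords.mean(axis=0)
    coords = coords @ R.T + center
    return [(n, e, coords[i]) for i, (n, e, _) in enumerate(atoms)]


# ---------------------------------------------------------------------------
# residue templates (local frame: CA at origin, side chain along +x)
# ---------------------------------------------------------------------------

_BACKBONE_LOCAL = [
    ("N", "N", (-0.8, 1.2, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (-1.0, -1.1, 0.3)),
    ("O", "O", (-2.2, -1.2, 0.5)),
]


def _hexagon(center_x: float, radius: float = 1.39) -> dict[str, tuple]:
    cx = center_x + radius
    ring = {}
    for name, deg in (
        ("CG", 180), ("CD1", 120), ("CE1", 60), ("CZ", 0), ("CE2", 300), ("CD2", 240)
    ):
        a = np.radians(deg)
        ring[name] = (cx + radius * np.cos(a), radius * np.sin(a), 0.0)
    return ring


def _pentagon_his(center_x: float, radius: float = 1.17) -> dict[str, tuple]:
    cx = center_x + radius
    ring = {}
    for name, deg in (
        ("CG", 180), ("ND1", 108), ("CE1", 36), ("NE2", 324), ("CD2", 252)
    ):
        a = np.radians(deg)
        ring[name] = (cx + radius * np.cos(a), radius * np.sin(a), 0.0)
    return ring


def _side_chain_template(residue_type: str) -> list[tuple[str, str, tuple]]:
    rtype = residue_type.upper()
    side: dict[str, tuple] = {}
    if rtype == "ALA":
        side = {"CB": (1.5, 0.0, 0.0)}
    elif rtype in ("PHE", "TYR"):
        side = {"CB": (1.5, 0.6, 0.0)}
        side.update(_hexagon(2.9))
        if rtype == "TYR":
            cz = side["CZ"]
            side["OH"] = (cz[0] + 1.36, cz[1], cz[2])
    elif rtype == "HIS":
        side = {"CB": (1.5, 0.6, 0.0)}
        side.update(_pentagon_his(2.9))
    elif rtype == "TRP":
        side = {
            "CB": (1.5, 0.6, 0.0),
            "CG": (2.9, 0.0, 0.0),
            "CD1": (3.6, 1.1, 0.0),
            "NE1": (4.9, 0.85, 0.0),
            "CE2": (5.1, -0.5, 0.0),
            "CD2": (3.9, -1.2, 0.0),
            "CE3": (3.9, -2.6, 0.0),
            "CZ3": (5.1, -3.3, 0.0),
            "CH2": (6.3, -2.6, 0.0),
            "CZ2": (6.35, -1.2, 0.0),
        }
    elif rtype == "ARG":
        side = {
            "CB": (1.5, 0.0, 0.0),
            "CG": (2.9, 0.4, 0.0),
            "CD": (4.2, -0.3, 0.0),
            "NE": (5.5, 0.4, 0.0),
            "CZ": (6.8, -0.1, 0.0),
            "NH1": (7.0, -1.4, 0.0),
            "NH2": (7.9, 0.7, 0.0),
        }
    elif rtype == "LYS":
        side = {
            "CB": (1.5, 0.0, 0.0),
            "CG": (2.8, 0.7, 0.0),
            "CD": (4.1, -0.1, 0.0),
            "CE": (5.4, 0.6, 0.0),
            "NZ": (6.7, -0.1, 0.0),
        }
    else:
        raise FixtureSpecError(f"no template for residue type {residue_type!r}")
    atoms = list(_BACKBONE_LOCAL)
    for name, pos in side.items():
        atoms.append((name, name[0], pos))
    return atoms


# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------

@dataclass
class ChromophoreSite:
    """Placement of one toy chromophore and its parent-chain labels."""

    center: tuple[float, float, float]
    orientation: Optional[np.ndarray] = None
    role: str = "ApcA"
    region: Optional[dict] = None
    chain_id: Optional[str] = None


@dataclass
class DecoySite:
    """A decoy residue planted at a known distance from a chromophore ring."""

    residue_type: str
    target_index: int
    distance: float
    target_ring: Optional[str] = "D"
    role: str = "other"
    chain_id: Optional[str] = None


@dataclass
class FixtureSpec:
    """Complete recipe for a synthetic assembly."""

    chromophores: list[ChromophoreSite] = field(default_factory=list)
    decoys: list[DecoySite] = field(default_factory=list)
    seed: int = 0
    jitter: float = 0.0

    def validate(self) -> None:
        if not self.chromophores:
            raise FixtureSpecError("fixture needs at least one chromophore")
        for d in self.decoys:
            if d.distance <= STERIC_FLOOR:
                raise FixtureSpecError(
                    f"intended decoy distance {d.distance} Å is below the steric "
                    f"floor {STERIC_FLOOR} Å"
                )
            if not 0 <= d.target_index < len(self.chromophores):
                raise FixtureSpecError(
                    f"decoy targets chromophore {d.target_index}, but only "
                    f"{len(self.chromophores)} exist"
                )
            parse_role(d.role)
        for site in self.chromophores:
            parse_role(site.role)
        if self.jitter < 0:
            raise FixtureSpecError("jitter must be >= 0")


@dataclass
class FixtureResult:
    """Written files plus the planted ground truth."""

    cif_path: Path
    pdb_path: Path
    manifest_path: Path
    manifest: dict
    model: AssemblyModel


# ---------------------------------------------------------------------------
# assembly construction
# ---------------------------------------------------------------------------

def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(a, b).min())


def _place_template_at_distance(
    template: list[tuple[str, str, tuple]],
    anchor: np.ndarray,
    direction: np.ndarray,
    target_coords: np.ndarray,
    intended: float,
) -> list[tuple[str, str, np.ndarray]]:
    """Position a residue template along ``direction`` from ``anchor`` so the
    min side-chain-heavy-atom distance to ``target_coords`` equals
    ``intended`` (converged to < 1e-4 Å)."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    R = _rotation_from_x(-u)  # side chain (+x locally) points back toward target
    local = np.array([p for _, _, p in template], dtype=float)
    names = [n for n, _, _ in template]
    side_mask = np.array([n not in ("N", "CA", "C", "O") for n in names])
    span = float(np.max(np.abs(local))) + 1.0

    s = intended + span
    for _ in range(100):
        coords = local @ R.T + (anchor + s * u)
        d = _min_distance(coords[side_mask], target_coords)
        if abs(d - intended) < 1e-4:
            break
        s += intended - d
        if s < 0.1:
            s = 0.1
    coords = local @ R.T + (anchor + s * u)
    return [(n, e, coords[i]) for i, (n, e, _) in enumerate(template)]


def make_assembly(
    spec: FixtureSpec, out_dir: str | Path, basename: str = "fixture"
) -> FixtureResult:
    """Realize a :class:`FixtureSpec` as mmCIF + PDB files and a manifest.

    Deterministic given the spec (including its seed): the same spec written
    twice produces byte-identical files.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    rows: list[tuple] = []
    chain_counter = 0

    def next_chain() -> str:
        nonlocal chain_counter
        if chain_counter >= len(_CHAIN_ALPHABET):
            raise FixtureSpecError("too many chains for single-character chain ids")
        cid = _CHAIN_ALPHABET[chain_counter]
        chain_counter += 1
        return cid

    manifest: dict = {
        "seed": spec.seed,
        "jitter": spec.jitter,
        "component_code": TOY_COMPONENT_CODE,
        "chromophores": [],
        "decoys": [],
    }

    chromo_info: list[dict] = []
    for idx, site in enumerate(spec.chromophores):
        cid = site.chain_id or next_chain()
        R = np.eye(3) if site.orientation is None else _check_rotation(site.orientation)
        center = np.asarray(site.center, dtype=float)
        bilin_atoms = make_toy_chromophore(center, R)
        bilin_coords = np.array([p for _, _, p in bilin_atoms])

        # attachment stub: two alanines approached from beyond ring A
        u_stub = R @ np.array([-1.0, 0.0, 0.0])
        stub_atoms = _place_template_at_distance(
            _side_chain_template("ALA"), center, u_stub, bilin_coords, _STUB_CONTACT
        )
        second = [
            (n, e, p + u_stub * 4.0 + R @ np.array([0.0, 1.5, 0.0]))
            for n, e, p in stub_atoms
        ]
        for resnum, res_atoms in ((1, stub_atoms), (2, second)):
            for name, element, pos in res_atoms:
                rows.append((cid, "ALA", resnum, "", name, element, *pos, True, 1))
        for name, element, pos in bilin_atoms:
            rows.append(
                (cid, TOY_COMPONENT_CODE, TOY_LIGAND_RESNUM, "", name, element, *pos, False, 1)
            )
        info = {
            "index": idx,
            "chain_id": cid,
            "id": f"{cid}/{TOY_LIGAND_RESNUM}/{TOY_COMPONENT_CODE}",
            "center": [float(x) for x in center],
            "role": site.role,
            "region": site.region or {},
        }
        chromo_info.append(
            {"center": center, "R": R, "coords": bilin_coords, "chain": cid}
        )
        manifest["chromophores"].append(info)

    ring_seen: dict[tuple[int, Optional[str]], int] = {}
    decoy_resnum: dict[str, int] = {}  # decoys sharing a chain get 1, 2, ...
    half_span = 1.5 * _RING_SPACING
    ring_offsets = {"A": -half_span, "B": -0.5 * _RING_SPACING,
                    "C": 0.5 * _RING_SPACING, "D": half_span}
    for decoy in spec.decoys:
        target = chromo_info[decoy.target_index]
        center, R, bilin_coords = target["center"], target["R"], target["coords"]
        if decoy.target_ring:
            offset = ring_offsets[decoy.target_ring.upper()]
            anchor = center + R @ np.array([offset, 0.0, 0.0])
            letters = "ABCD"
            letter = decoy.target_ring.upper()
            ring_names = {f"N{letter}"} | {f"C{j}{letter}" for j in range(1, 5)}
            mask = [n in ring_names for n, _, _ in make_toy_chromophore(center, R)]
            target_coords = bilin_coords[np.array(mask)]
        else:
            anchor = center
            target_coords = bilin_coords
        # approach along the ring-plane normal so the target ring really is
        # the nearest part of the bilin; successive decoys on the same target
        # alternate faces and tilt away to avoid piling up
        key = (decoy.target_index, decoy.target_ring)
        k = ring_seen.get(key, 0)
        ring_seen[key] = k + 1
        face = 1.0 if k % 2 == 0 else -1.0
        tilt = np.radians(0.0 if k < 2 else 30.0)
        azimuth = np.radians(45.0 + 60.0 * k)
        direction = R @ np.array(
            [
                np.sin(tilt) * np.cos(azimuth),
                np.sin(tilt) * np.sin(azimuth),
                face * np.cos(tilt),
            ]
        )
        atoms = _place_template_at_distance(
            _side_chain_template(decoy.residue_type),
            anchor,
            direction,
            target_coords,
            decoy.distance,
        )
        cid = decoy.chain_id or next_chain()
        resnum = decoy_resnum.get(cid, 0) + 1
        decoy_resnum[cid] = resnum
        for name, element, pos in atoms:
            rows.append((cid, decoy.residue_type.upper(), resnum, "", name, element, *pos, True, 1))
        manifest["decoys"].append(
            {
                "chain_id": cid,
                "residue_number": resnum,
                "residue_type": decoy.residue_type.upper(),
                "target_index": decoy.target_index,
                "target_id": manifest["chromophores"][decoy.target_index]["id"],
                "target_ring": decoy.target_ring,
                "intended_distance": decoy.distance,
                "role": decoy.role,
            }
        )

    atoms_df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    if spec.jitter > 0:
        noise = rng.uniform(-spec.jitter, spec.jitter, size=(len(atoms_df), 3))
        atoms_df[["x", "y", "z"]] = atoms_df[["x", "y", "z"]].to_numpy() + noise
    # fixed decimal precision keeps mmCIF and PDB output in exact agreement
    atoms_df[["x", "y", "z"]] = atoms_df[["x", "y", "z"]].round(3)

    model = AssemblyModel(atoms=atoms_df, format="memory")
    cif_path = write_mmcif(model, out_dir / f"{basename}.cif")
    pdb_path = write_pdb(model, out_dir / f"{basename}.pdb")

    manifest_path = out_dir / f"{basename}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return FixtureResult(
        cif_path=cif_path,
        pdb_path=pdb_path,
        manifest_path=manifest_path,
        manifest=manifest,
        model=model,
    )


def annotation_config_from_manifest(manifest: dict) -> dict:
    """Role-mapping config (for ``annotate_subunits``) from a manifest."""
    chains: dict[str, dict] = {}
    for info in manifest["chromophores"]:
        chains[info["chain_id"]] = {"role": info["role"], "region": info["region"] or None}
    for decoy in manifest["decoys"]:
        chains[decoy["chain_id"]] = {"role": decoy.get("role", "other")}
    return {"chains": chains, "patterns": []}


# ---------------------------------------------------------------------------
# planted transfer chains
# ---------------------------------------------------------------------------

def plant_path(
    n: int,
    step: float = 25.0,
    cutoff: float = 40.0,
    seed: int = 0,
    clearance: float = 5.0,
) -> tuple[FixtureSpec, list[str]]:
    """Chromophores on a smooth arc forming a unique sub-cutoff chain.

    Consecutive centroids are ``step`` Å apart; all non-consecutive pairs
    are farther than ``cutoff`` + ``clearance`` so the chain remains unique
    under min-atom metrics too (toy chromophores extend ~6 Å from their
    centroids).  The last site is labelled ApcD (terminal emitter), the
    rest are rod phycocyanin sites.  Returns the spec and the expected path
    as the ordered chromophore id list.

    By the triangle inequality a second neighbour can be at most ``2*step``
    away, so ``cutoff + clearance >= 2*step`` is geometrically infeasible
    and raises :class:`~pbsnet.errors.FixtureSpecError`.
    """
    if n < 2:
        raise FixtureSpecError("plant_path needs n >= 2")
    if step >= cutoff:
        raise FixtureSpecError(f"step ({step}) must be below the cutoff ({cutoff})")
    margin = cutoff + clearance
    if margin >= 2 * step:
        raise FixtureSpecError(
            f"cannot separate second neighbours beyond {margin:.1f} Å with "
            f"step {step:.1f} Å (triangle inequality caps them at {2 * step:.1f} Å); "
            f"increase step above {(margin / 2):.1f} Å or lower the cutoff"
        )
    # circle arc: chord(k) = 2R sin(k·theta/2); keep chords monotone in k by
    # bounding the total turn, and push chord(2) beyond cutoff + clearance
    theta_max = 2 * np.arccos(margin / (2 * step))
    theta = min(0.95 * theta_max, np.pi / max(n - 1, 1))
    radius = step / (2 * np.sin(theta / 2))

    # long axis perpendicular to the arc plane keeps min-atom distances
    # close to centroid distances
    orientation = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    sites = []
    for i in range(n):
        angle = i * theta
        center = (radius * np.cos(angle), radius * np.sin(angle), 0.0)
        if i == n - 1:
            role, region = "ApcD", {"compartment": "core", "cylinder": "A", "layer": 4}
        else:
            role = "CpcB"
            region = {"compartment": "rod", "rod_name": "R1", "hexamer_index": None}
        sites.append(
            ChromophoreSite(center=center, orientation=orientation, role=role, region=region)
        )
    spec = FixtureSpec(chromophores=sites, seed=seed)

    centers = np.array([s.center for s in sites])
    for i in range(n):
        for j in range(i + 2, n):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d <= margin:
                raise FixtureSpecError(
                    f"planted arc failed verification: centroids {i},{j} at "
                    f"{d:.2f} Å <= {margin:.2f} Å; use a larger step or smaller n"
                )
    expected = [
        f"{_CHAIN_ALPHABET[i]}/{TOY_LIGAND_RESNUM}/{TOY_COMPONENT_CODE}" for i in range(n)
    ]
    return spec, expected


def verify_planted_path(result: FixtureResult, cutoff: float = 40.0) -> list[str]:
    """Re-verify a planted chain from the *written* file.

    Reloads the mmCIF, re-extracts chromophores and checks from coordinates
    that consecutive centroid spacings are under the cutoff and all other
    pairs above it.  Returns the chain as chromophore ids in planted order.
    """
    from .structure_io import load_structure

    model = load_structure(result.cif_path)
    chromos = extract_chromophores(model, [TOY_COMPONENT_CODE])
    order = {info["id"]: info["index"] for info in result.manifest["chromophores"]}
    chromos.sort(key=lambda c: order[c.label])
    centers = np.array([c.centroid for c in chromos])
    n = len(centers)
    for i in range(n - 1):
        d = float(np.linalg.norm(centers[i] - centers[i + 1]))
        if d > cutoff:
            raise FixtureSpecError(f"consecutive pair {i},{i + 1} at {d:.2f} Å > cutoff")
    for i in range(n):
        for j in range(i + 2, n):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d <= cutoff:
                raise FixtureSpecError(
                    f"non-consecutive pair {i},{j} at {d:.2f} Å <= cutoff"
                )
    return [c.label for c in chromos]
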