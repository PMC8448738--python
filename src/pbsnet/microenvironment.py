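"""Residue microenvironment of bilins: contacts, π–π and cation–π geometry.

The light-harvesting efficiency of a phycobilisome depends not only on
inter-bilin distances but on the protein cage around each bilin: aromatic
side chains (Tyr/Phe, rarely Trp, plus His) stack against the tetrapyrrole
rings and cationic groups (Arg guanidinium, Lys amine) sit over ring faces.
This module enumerates residues near each chromophore and classifies the
candidate interactions from geometry alone — centroid separations and
interplanar angles — without any energetic scoring.

Default geometric thresholds follow common structural-biology practice:
parallel (stacked) π–π at centroid distance ≤ 5.5 Å and interplanar angle
< 30°, T-shaped π–π at ≤ 6.0 Å and > 60°, cation–π at cation-to-ring
centroid distance ≤ 6.0 Å.  All thresholds are configurable and are echoed
into every output record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .chromophore import BACKBONE_ATOMS, Chromophore
from .errors import (
    AnnotationRequiredError,
    DegenerateGeometryError,
    EmptySelectionError,
)
from .regions import Role
from .structure_io import AssemblyModel

#: Side-chain ring atoms of the aromatic residues.
AROMATIC_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Heavy atoms of the cationic group.
CATIONIC_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
}

AROMATIC_RESIDUES = tuple(AROMATIC_RING_ATOMS)
CATIONIC_RESIDUES = tuple(CATIONIC_GROUP_ATOMS)

#: Default analysis shells (Å): primary contact shell and extended shell.
PRIMARY_SHELL = 5.0
EXTENDED_SHELL = 10.0


@dataclass(frozen=True)
class InteractionThresholds:
    """Geometric classification thresholds (Å / degrees)."""

    pi_parallel_max_dist: float = 5.5
    pi_parallel_max_angle: float = 30.0
    pi_tshaped_max_dist: float = 6.0
    pi_tshaped_min_angle: float = 60.0
    cation_pi_max_dist: float = 6.0

    def to_dict(self) -> dict:
        return {
            "pi_parallel_max_dist": self.pi_parallel_max_dist,
            "pi_parallel_max_angle": self.pi_parallel_max_angle,
            "pi_tshaped_max_dist": self.pi_tshaped_max_dist,
            "pi_tshaped_min_angle": self.pi_tshaped_min_angle,
            "cation_pi_max_dist": self.cation_pi_max_dist,
        }


DEFAULT_THRESHOLDS = InteractionThresholds()


@dataclass
class ResidueContact:
    """A polymer residue within a cutoff of a chromophore."""

    chain_id: str
    residue_number: int
    residue_name: str
    residue_role: Role
    chromophore_id: str
    min_distance: float
    nearest_ring: Optional[str]
    nearest_atom_pair: tuple[str, str]


@dataclass
class InteractionAnnotation:
    """Geometric classification of a residue-bilin interaction."""

    kind: str  # pi_pi_parallel | pi_pi_tshaped | cation_pi | none
    centroid_distance: Optional[float] = None
    interplanar_angle: Optional[float] = None
    offset: Optional[float] = None


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring by principal-plane fit.

    The normal is the smallest-variance principal axis of the atom scatter;
    orientation (sign) is arbitrary.  Collinear input raises
    :class:`~pbsnet.errors.DegenerateGeometryError`.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("a ring plane needs >= 3 atoms")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    if singular[1] <= 1e-9 * max(1.0, singular[0]):
        raise DegenerateGeometryError("ring atoms are collinear; plane undefined")
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two planes in degrees, folded to [0, 90]."""
    cosang = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _lateral_offset(c1: np.ndarray, c2: np.ndarray, normal: np.ndarray) -> float:
    """Displacement of centroid c2 from the axis through c1 along ``normal``."""
    delta = c2 - c1
    along = float(np.dot(delta, normal))
    return float(np.sqrt(max(float(np.dot(delta, delta)) - along * along, 0.0)))


# ---------------------------------------------------------------------------
# neighborhood enumeration
# ---------------------------------------------------------------------------

def _side_chain_atoms(res_df: pd.DataFrame) -> pd.DataFrame:
    return res_df.loc[~res_df["atom_name"].isin(BACKBONE_ATOMS)]


def chromophore_neighborhood(
    model: AssemblyModel,
    chromophore: Chromophore,
    cutoff: float = PRIMARY_SHELL,
    exclude_attachment_cysteine: bool = False,
) -> list[ResidueContact]:
    """All polymer residues whose side chains come within ``cutoff`` Å.

    Distances are minimum side-chain-heavy-atom to any-chromophore-atom;
    ``nearest_ring`` reports the ring (or bridge) assignment of the
    minimising chromophore atom, or ``None`` when that atom is a side-chain
    atom of the bilin.  Results are sorted by ascending distance.
    """
    chromo_coords = chromophore.atom_coords()
    chromo_names = chromophore.atoms["atom_name"].tolist()
    atom_ring: dict[str, str] = {}
    for label, names in chromophore.ring_map.items():
        for name in names:
            atom_ring[name] = label

    poly = model.atoms.loc[model.atoms["is_polymer"]]
    poly = poly.loc[~poly["atom_name"].isin(BACKBONE_ATOMS)]
    if len(poly) == 0:
        return []
    coords = poly[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(coords)
    chromo_tree = cKDTree(chromo_coords)
    pairs = tree.query_ball_tree(chromo_tree, r=cutoff)

    per_residue: dict[tuple[str, int, str], tuple[float, str, str]] = {}
    poly_rows = poly.reset_index(drop=True)
    for i, hits in enumerate(pairs):
        if not hits:
            continue
        row = poly_rows.iloc[i]
        key = (row["chain_id"], int(row["residue_number"]), row["residue_name"])
        d = cdist(coords[i][None, :], chromo_coords[hits]).ravel()
        j = int(np.argmin(d))
        dist = float(d[j])
        if key not in per_residue or dist < per_residue[key][0]:
            per_residue[key] = (dist, row["atom_name"], chromo_names[hits[j]])

    if exclude_attachment_cysteine:
        per_residue = {
            key: val
            for key, val in per_residue.items()
            if not (key[2] == "CYS" and val[0] < 2.5)
        }

    contacts = []
    for (cid, num, rname), (dist, res_atom, chromo_atom) in per_residue.items():
        contacts.append(
            ResidueContact(
                chain_id=cid,
                residue_number=num,
                residue_name=rname,
                residue_role=model.role_of(cid),
                chromophore_id=chromophore.label,
                min_distance=dist,
                nearest_ring=atom_ring.get(chromo_atom),
                nearest_atom_pair=(res_atom, chromo_atom),
            )
        )
    contacts.sort(key=lambda c: (c.min_distance, c.chain_id, c.residue_number))
    return contacts


# ---------------------------------------------------------------------------
# interaction classification
# ---------------------------------------------------------------------------

def classify_pi_interaction(
    residue_ring_coords: np.ndarray,
    bilin_ring_coords: np.ndarray,
    thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
) -> InteractionAnnotation:
    """Classify an aromatic-ring / bilin-ring pair as stacked, T-shaped or none.

    Uses ring centroids and principal-plane normals; the interplanar angle
    is folded to [0, 90]°.
    """
    c1, n1 = ring_plane(np.asarray(residue_ring_coords, dtype=float))
    c2, n2 = ring_plane(np.asarray(bilin_ring_coords, dtype=float))
    dist = float(np.linalg.norm(c1 - c2))
    angle = interplanar_angle(n1, n2)
    offset = _lateral_offset(c2, c1, n2)
    if dist <= thresholds.pi_parallel_max_dist and angle < thresholds.pi_parallel_max_angle:
        kind = "pi_pi_parallel"
    elif dist <= thresholds.pi_tshaped_max_dist and angle > thresholds.pi_tshaped_min_angle:
        kind = "pi_pi_tshaped"
    else:
        kind = "none"
    return InteractionAnnotation(
        kind=kind, centroid_distance=dist, interplanar_angle=angle, offset=offset
    )


def classify_cation_pi(
    residue_atoms: pd.DataFrame,
    bilin_ring_coords: np.ndarray,
    residue_name: Optional[str] = None,
    thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
) -> InteractionAnnotation:
    """Classify a cationic side chain (Arg/Lys) against a bilin ring.

    The cation position is the centroid of the guanidinium heavy atoms
    (Arg) or the terminal amine nitrogen (Lys).  Classification is by
    cation-to-ring-centroid distance; the reported angle is between the
    centroid-to-cation vector and the ring normal.
    """
    rname = residue_name or str(residue_atoms["residue_name"].iloc[0])
    group = CATIONIC_GROUP_ATOMS.get(rname.upper())
    if group is None:
        raise EmptySelectionError(f"{rname} has no defined cationic group (expected Arg/Lys)")
    sel = residue_atoms.loc[residue_atoms["atom_name"].isin(group)]
    if len(sel) == 0:
        raise EmptySelectionError(
            f"residue {rname} is missing its cationic-group atoms {group}"
        )
    cation = sel[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)
    centroid, normal = ring_plane(np.asarray(bilin_ring_coords, dtype=float))
    delta = cation - centroid
    dist = float(np.linalg.norm(delta))
    if dist > 0:
        cosang = abs(float(np.dot(delta, normal)) / dist)
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    else:
        angle = 0.0
    kind = "cation_pi" if dist <= thresholds.cation_pi_max_dist else "none"
    return InteractionAnnotation(
        kind=kind,
        centroid_distance=dist,
        interplanar_angle=angle,
        offset=_lateral_offset(centroid, cation, normal),
    )


def classify_contacts(
    model: AssemblyModel,
    chromophore: Chromophore,
    contacts: Sequence[ResidueContact],
    thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Annotate a contact list with π–π / cation–π classifications.

    Aromatic residues are tested ring-against-ring over all four bilin
    rings (best = smallest centroid distance among non-``none`` hits, else
    the smallest-distance ``none``); Arg/Lys are tested with
    :func:`classify_cation_pi`.  Thresholds are echoed into every row.
    """
    rows = []
    for contact in contacts:
        res_df = model.residue_atoms(contact.chain_id, contact.residue_number)
        annotation = InteractionAnnotation(kind="none")
        rname = contact.residue_name.upper()
        candidates: list[InteractionAnnotation] = []
        if rname in AROMATIC_RING_ATOMS:
            ring_atoms = res_df.loc[
                res_df["atom_name"].isin(AROMATIC_RING_ATOMS[rname])
            ]
            if len(ring_atoms) >= 3:
                res_coords = ring_atoms[["x", "y", "z"]].to_numpy(dtype=float)
                for ring_label in ("A", "B", "C", "D"):
                    bilin_coords = chromophore.ring_coords(ring_label)
                    if len(bilin_coords) < 3:
                        continue
                    candidates.append(
                        classify_pi_interaction(res_coords, bilin_coords, thresholds)
                    )
        elif rname in CATIONIC_GROUP_ATOMS:
            for ring_label in ("A", "B", "C", "D"):
                bilin_coords = chromophore.ring_coords(ring_label)
                if len(bilin_coords) < 3:
                    continue
                try:
                    candidates.append(
                        classify_cation_pi(res_df, bilin_coords, rname, thresholds)
                    )
                except EmptySelectionError:
                    break
        if candidates:
            hits = [c for c in candidates if c.kind != "none"]
            pool = hits if hits else candidates
            annotation = min(pool, key=lambda c: c.centroid_distance)
        row = {
            "chromophore_id": contact.chromophore_id,
            "chain_id": contact.chain_id,
            "residue_number": contact.residue_number,
            "residue_name": contact.residue_name,
            "residue_role": contact.residue_role.value,
            "min_distance": contact.min_distance,
            "nearest_ring": contact.nearest_ring,
            "interaction_kind": annotation.kind,
            "centroid_distance": annotation.centroid_distance,
            "interplanar_angle": annotation.interplanar_angle,
        }
        row.update(thresholds.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aromatic census
# ---------------------------------------------------------------------------

def aromatic_census(
    model: AssemblyModel,
    chromophores: Sequence[Chromophore],
    cutoff: float = EXTENDED_SHELL,
    grouping: str = "region",
) -> pd.DataFrame:
    """Counts of aromatic residues contacting any bilin, per group.

    ``grouping`` is ``"region"`` (the region label of the contacting
    residue's chain), ``"role"``, or ``"chain"``.  A residue is counted once
    per group when any of its side-chain heavy atoms is within ``cutoff`` of
    any bilin atom.  Columns report per-type counts and the fraction of each
    aromatic type among contacting aromatics.
    """
    if grouping not in ("region", "role", "chain"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping == "region" and not model.annotations:
        raise AnnotationRequiredError("grouping by region requires an annotated model")

    seen: dict[tuple[str, int, str], str] = {}  # residue -> name
    for chromo in chromophores:
        for contact in chromophore_neighborhood(model, chromo, cutoff):
            if contact.residue_name.upper() in AROMATIC_RING_ATOMS:
                key = (contact.chain_id, contact.residue_number, contact.residue_name)
                seen[key] = contact.residue_name.upper()

    def group_of(chain_id: str) -> str:
        if grouping == "chain":
            return chain_id
        if grouping == "role":
            return model.role_of(chain_id).value
        return model.region_of(chain_id).label

    counts: dict[str, dict[str, int]] = {}
    for (cid, _num, _rname), name in seen.items():
        grp = group_of(cid)
        counts.setdefault(grp, {r: 0 for r in AROMATIC_RESIDUES})[name] += 1

    rows = []
    for grp in sorted(counts):
        row = {"group": grp}
        total = sum(counts[grp].values())
        for rname in AROMATIC_RESIDUES:
            row[f"n_{rname.lower()}"] = counts[grp][rname]
            row[f"frac_{rname.lower()}"] = counts[grp][rname] / total if total else 0.0
        row["n_aromatic"] = total
        rows.append(row)
    columns = ["group"]
    for rname in AROMATIC_RESIDUES:
        columns += [f"n_{rname.lower()}", f"frac_{rname.lower()}"]
    columns.append("n_aromatic")
    return pd.DataFrame(rows, columns=columns)


def linker_polarization(
    model: AssemblyModel,
    linker_chain: str,
    proximal_bilin: Chromophore,
    all_bilins: Sequence[Chromophore],
    cutoff: float = EXTENDED_SHELL,
) -> float:
    """Fraction of a linker's bilin-contacting aromatics near one bilin.

    Quantifies how strongly a rod-core linker's aromatic residues cluster
    around the core-proximal bilin: (aromatics of ``linker_chain`` within
    ``cutoff`` of ``proximal_bilin``) / (aromatics of ``linker_chain``
    within ``cutoff`` of any bilin).  Returns NaN when the denominator is
    zero.
    """
    def linker_aromatics(chromos: Sequence[Chromophore]) -> set[tuple[str, int, str]]:
        out: set[tuple[str, int, str]] = set()
        for chromo in chromos:
            for contact in chromophore_neighborhood(model, chromo, cutoff):
                if (
                    contact.chain_id == linker_chain
                    and contact.residue_name.upper() in AROMATIC_RING_ATOMS
                ):
                    out.add(
                        (contact.chain_id, contact.residue_number, contact.residue_name)
                    )
        return out

    near_any = linker_aromatics(all_bilins)
    if not near_any:
        return float("nan")
    near_proximal = linker_aromatics([proximal_bilin])
    return len(near_proximal & near_any) / len(near_any)
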