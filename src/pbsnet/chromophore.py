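"""Bilin chromophores: extraction, ring partition, and distance metrics.

Bilins are open-chain tetrapyrroles whose four pyrrole rings are labelled
A-D and joined by methine bridge carbons.  In the chemical-component
nomenclature the ring-core atoms carry the ring letter as a suffix (``NA``,
``C1A`` ... ``C4A`` for ring A) and the bridge carbons are named ``CH`` plus
the letter of the following ring (``CHB`` between rings A and B).  Side
chains — propionates, methyls, vinyl/ethylidene groups — fall outside this
pattern and are excluded from the conjugated system used for distances.

Three inter-chromophore distance conventions are provided; which one a
published figure used is generally not recoverable, so every report records
the metric it was computed with.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import EmptySelectionError, MetricUndefinedError, NomenclatureError
from .regions import Region, Role
from .structure_io import AssemblyModel

#: Chemical-component codes of the PBS bilins: phycocyanobilin, phycoerythro-
#: bilin, phycourobilin, phycoviolobilin.
BILIN_COMPONENT_CODES = frozenset({"CYC", "PEB", "PUB", "PVB"})

RING_LABELS = ("A", "B", "C", "D")
BRIDGE_LABELS = ("HB", "HC", "HD")

_RING_ATOM = re.compile(r"^(?:N|C[1-4])([A-D])$")
_BRIDGE_ATOM = re.compile(r"^CH([B-D])$")

#: Backbone atom names excluded from side-chain selections.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class DistanceMetric(str, Enum):
    """Atom convention for an inter-chromophore distance.

    ``min_any_atom``
        minimum heavy-atom distance over all atom pairs (side chains
        included); a lower bound on the other two.
    ``min_conjugated_atom``
        minimum over the conjugated systems only (ring cores + methine
        bridges); the default for network building — robust to side-chain
        conformers.
    ``centroid``
        distance between conjugated-system centroids; the only metric here
        that satisfies the triangle inequality.
    """

    MIN_ANY_ATOM = "min_any_atom"
    MIN_CONJUGATED_ATOM = "min_conjugated_atom"
    CENTROID = "centroid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DEFAULT_METRIC = DistanceMetric.MIN_CONJUGATED_ATOM


@dataclass
class Chromophore:
    """One bilin ligand instance.

    ``atoms`` is the heavy-atom table of the ligand; ``ring_map`` maps ring
    labels A-D to atom-name lists and bridge labels HB/HC/HD to the methine
    carbons; ``conjugated_atoms`` is the union of ring cores and bridges.
    """

    chain_id: str
    residue_number: int
    component_code: str
    atoms: pd.DataFrame
    ring_map: dict[str, list[str]] = field(default_factory=dict)
    conjugated_atoms: list[str] = field(default_factory=list)
    parent_role: Role = Role.OTHER
    parent_chain: Optional[str] = None
    region: Region = field(default_factory=Region)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.component_code)

    @property
    def label(self) -> str:
        """Stable string id, e.g. ``B/301/CYC``."""
        return f"{self.chain_id}/{self.residue_number}/{self.component_code}"

    def atom_coords(self, atom_names: Optional[Iterable[str]] = None) -> np.ndarray:
        """(n, 3) coordinates of selected atoms (all atoms when None)."""
        df = self.atoms
        if atom_names is not None:
            names = set(atom_names)
            df = df.loc[df["atom_name"].isin(names)]
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def conjugated_coords(self) -> np.ndarray:
        return self.atom_coords(self.conjugated_atoms)

    @property
    def centroid(self) -> np.ndarray:
        """Arithmetic mean of the conjugated-atom positions."""
        coords = self.conjugated_coords
        if len(coords) == 0:
            raise MetricUndefinedError(
                f"chromophore {self.label} has an empty conjugated set"
            )
        return coords.mean(axis=0)

    def ring_coords(self, ring: str) -> np.ndarray:
        names = self.ring_map.get(ring, [])
        return self.atom_coords(names)

    def metric_coords(self, metric: DistanceMetric) -> np.ndarray:
        if metric == DistanceMetric.MIN_ANY_ATOM:
            coords = self.atom_coords()
        elif metric == DistanceMetric.MIN_CONJUGATED_ATOM:
            coords = self.conjugated_coords
        else:
            coords = self.centroid[None, :]
        if len(coords) == 0:
            raise MetricUndefinedError(
                f"chromophore {self.label} has no atoms under metric {metric.value}"
            )
        return coords


def partition_rings(atoms: pd.DataFrame, residue_label: str = "") -> dict[str, list[str]]:
    """Partition bilin atoms into rings A-D and methine bridges by name.

    Atoms named ``N?``/``C1?``-``C4?`` with a ring-letter suffix go to that
    ring; ``CH?`` methine carbons are stored under bridge labels ``HB``,
    ``HC``, ``HD``.  Everything else (side chains) is excluded.  A residue in
    which no atom matches raises :class:`~pbsnet.errors.NomenclatureError`;
    a ring with fewer than 4 matched atoms is kept (partial rings occur in
    incompletely modelled ligands).
    """
    ring_map: dict[str, list[str]] = {label: [] for label in RING_LABELS}
    bridges: dict[str, list[str]] = {label: [] for label in BRIDGE_LABELS}
    matched = 0
    for name in atoms["atom_name"]:
        m = _RING_ATOM.match(name)
        if m:
            ring_map[m.group(1)].append(name)
            matched += 1
            continue
        m = _BRIDGE_ATOM.match(name)
        if m:
            bridges["H" + m.group(1)].append(name)
            matched += 1
    if matched == 0:
        raise NomenclatureError(
            f"no atoms of residue {residue_label or '<bilin>'} follow bilin ring "
            "nomenclature (N?/C1?-C4? with ring-letter suffix)"
        )
    out = {label: sorted(names) for label, names in ring_map.items() if names}
    out.update({label: sorted(names) for label, names in bridges.items() if names})
    return out


def _conjugated_atom_names(ring_map: dict[str, list[str]]) -> list[str]:
    names: list[str] = []
    for label in (*RING_LABELS, *BRIDGE_LABELS):
        names.extend(ring_map.get(label, []))
    return names


def chromophore_from_atoms(
    atoms: pd.DataFrame,
    parent_role: Role = Role.OTHER,
    region: Optional[Region] = None,
) -> Chromophore:
    """Build a Chromophore from a bare ligand atom table.

    Convenience for synthetic inputs: runs :func:`partition_rings` and
    derives the conjugated set; chain id / residue number / component code
    are taken from the first atom row.
    """
    first = atoms.iloc[0]
    ring_map = partition_rings(atoms, f"{first['chain_id']}/{first['residue_number']}")
    return Chromophore(
        chain_id=str(first["chain_id"]),
        residue_number=int(first["residue_number"]),
        component_code=str(first["residue_name"]),
        atoms=atoms.reset_index(drop=True),
        ring_map=ring_map,
        conjugated_atoms=_conjugated_atom_names(ring_map),
        parent_role=parent_role,
        region=region or Region(),
    )


def extract_chromophores(
    model: AssemblyModel,
    component_codes: Optional[Iterable[str]] = None,
) -> list[Chromophore]:
    """Build one :class:`Chromophore` per matching ligand group.

    ``component_codes`` defaults to the PBS bilin codes
    (:data:`BILIN_COMPONENT_CODES`).  The parent chain (hence the parent
    role and region) is the polymer chain with the smallest heavy-atom
    distance to the ligand — a proxy for the covalent thioether attachment
    that is robust to missing connectivity records.  Ordering is stable by
    (chain id, residue number).
    """
    if component_codes is None:
        codes = set(BILIN_COMPONENT_CODES)
    else:
        codes = {str(c).upper() for c in component_codes}
    if not codes:
        return []

    atoms = model.atoms
    poly = atoms.loc[atoms["is_polymer"]]
    poly_coords = poly[["x", "y", "z"]].to_numpy(dtype=float)
    poly_chains = poly["chain_id"].to_numpy()
    tree = cKDTree(poly_coords) if len(poly_coords) else None

    chromophores: list[Chromophore] = []
    for group in model.ligand_groups:
        if group.residue_name.upper() not in codes:
            continue
        lig_atoms = model.residue_atoms(group.chain_id, group.residue_number)
        lig_atoms = lig_atoms.loc[lig_atoms["residue_name"] == group.residue_name]
        if len(lig_atoms) == 0:
            continue
        ring_map = partition_rings(
            lig_atoms, f"{group.chain_id}/{group.residue_number}/{group.residue_name}"
        )
        conjugated = _conjugated_atom_names(ring_map)
        parent_chain: Optional[str] = None
        if tree is not None:
            dists, idx = tree.query(lig_atoms[["x", "y", "z"]].to_numpy(dtype=float))
            parent_chain = str(poly_chains[idx[int(np.argmin(dists))]])
        ann = model.annotations.get(parent_chain) if parent_chain else None
        chromophores.append(
            Chromophore(
                chain_id=group.chain_id,
                residue_number=group.residue_number,
                component_code=group.residue_name,
                atoms=lig_atoms.reset_index(drop=True),
                ring_map=ring_map,
                conjugated_atoms=conjugated,
                parent_role=ann.role if ann else Role.OTHER,
                parent_chain=parent_chain,
                region=ann.region if ann else Region(),
            )
        )
    chromophores.sort(key=lambda c: (c.chain_id, c.residue_number))
    return chromophores


def chromophore_distance(
    c1: Chromophore,
    c2: Chromophore,
    metric: DistanceMetric = DEFAULT_METRIC,
) -> float:
    """Distance in Å between two chromophores under a metric.

    Symmetric in its arguments; ``min_*`` metrics minimise over the atom-set
    cross product, ``centroid`` measures centroid to centroid.
    """
    a = c1.metric_coords(metric)
    b = c2.metric_coords(metric)
    return float(cdist(a, b).min())


def residue_ring_distance(
    model: AssemblyModel,
    chain_id: str,
    residue_number: int,
    chromophore: Chromophore,
    target: str = "conjugated",
    side_chain_only: bool = True,
    insertion_code: str = "",
) -> float:
    """Minimum heavy-atom distance from a residue to part of a bilin.

    ``target`` is a ring label (``"A"``-``"D"``), a bridge label, the string
    ``"conjugated"`` or ``"any"``.  By default only side-chain atoms of the
    residue are used (the published residue-to-bilin distances concern
    aromatic/cationic side chains, not backbone).
    """
    res = model.residue_atoms(chain_id, residue_number, insertion_code)
    if len(res) == 0:
        raise EmptySelectionError(
            f"no residue {residue_number}{insertion_code} in chain {chain_id}"
        )
    if side_chain_only:
        res = res.loc[~res["atom_name"].isin(BACKBONE_ATOMS)]
        if len(res) == 0:
            raise EmptySelectionError(
                f"residue {chain_id}/{residue_number} has no side-chain heavy atoms"
            )
    res_coords = res[["x", "y", "z"]].to_numpy(dtype=float)

    if target == "any":
        tgt = chromophore.atom_coords()
    elif target == "conjugated":
        tgt = chromophore.conjugated_coords
    else:
        tgt = chromophore.ring_coords(target)
    if len(tgt) == 0:
        raise MetricUndefinedError(
            f"chromophore {chromophore.label} has no atoms for target {target!r}"
        )
    return float(cdist(res_coords, tgt).min())


def chromophore_table(chromophores: Sequence[Chromophore]) -> pd.DataFrame:
    """Summary table: one row per chromophore with centroid and ring sizes."""
    rows = []
    for c in chromophores:
        centroid = c.centroid
        row = {
            "id": c.label,
            "chain_id": c.chain_id,
            "residue_number": c.residue_number,
            "component_code": c.component_code,
            "parent_chain": c.parent_chain,
            "parent_role": c.parent_role.value,
            "region": c.region.label,
            "centroid_x": centroid[0],
            "centroid_y": centroid[1],
            "centroid_z": centroid[2],
        }
        for label in RING_LABELS:
            row[f"ring_{label}_size"] = len(c.ring_map.get(label, []))
        rows.append(row)
    return pd.DataFrame(rows)


def distance_table(
    chromophores: Sequence[Chromophore],
    metric: DistanceMetric = DEFAULT_METRIC,
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Long-format pairwise distances (each unordered pair once)."""
    rows = []
    for i, c1 in enumerate(chromophores):
        for c2 in chromophores[i + 1 :]:
            d = chromophore_distance(c1, c2, metric)
            if cutoff is not None and d > cutoff:
                continue
            rows.append(
                {"id1": c1.label, "id2": c2.label, "metric": metric.value, "distance": d}
            )
    return pd.DataFrame(rows, columns=["id1", "id2", "metric", "distance"])
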