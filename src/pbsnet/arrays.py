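"""Inter-complex bilin contacts for stacked phycobilisome arrays.

Adjacent phycobilisomes stacked on the thylakoid membrane can bring bilins
of the outermost trimer layers of one core close to those of the next, and
pairs under ~40 Å are treated as candidates for inter-complex energy
transfer.  This module consumes rigid-body placements (rotation +
translation) of assembly copies — e.g. from fitting into a tomographic
array map, which is itself out of scope — applies them, and enumerates
cross-copy bilin pairs under a cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chromophore import (
    Chromophore,
    DEFAULT_METRIC,
    DistanceMetric,
    chromophore_distance,
    extract_chromophores,
)
from .errors import InvalidPlacementError, PbsnetError
from .network import DEFAULT_CUTOFF
from .structure_io import AssemblyModel

ORTHONORMALITY_TOL = 1e-6


@dataclass(frozen=True)
class Placement:
    """A rigid-body transform x -> R x + t with a copy label."""

    rotation: np.ndarray
    translation: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        residual = float(np.abs(R @ R.T - np.eye(3)).max())
        if residual > ORTHONORMALITY_TOL or np.linalg.det(R) < 0:
            raise InvalidPlacementError(
                f"rotation is not a proper rotation (orthonormality residual "
                f"{residual:.2e}, det {np.linalg.det(R):.6f})"
            )

    @classmethod
    def identity(cls, label: str = "") -> "Placement":
        return cls(np.eye(3), np.zeros(3), label)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def apply_placement(model: AssemblyModel, placement: Placement) -> AssemblyModel:
    """Transform every atom; append the placement label to chain ids.

    Annotations are preserved (re-keyed to the new chain ids when a label is
    given) so that downstream region reporting still works on each copy.
    """
    atoms = model.atoms.copy()
    coords = atoms[["x", "y", "z"]].to_numpy(dtype=float)
    atoms[["x", "y", "z"]] = placement.apply(coords)
    suffix = f"_{placement.label}" if placement.label else ""
    if suffix:
        atoms["chain_id"] = atoms["chain_id"].astype(str) + suffix
    out = model.with_atoms(atoms)
    if suffix:
        out.annotations = {
            cid + suffix: type(ann)(cid + suffix, ann.role, ann.region)
            for cid, ann in model.annotations.items()
        }
        out.chain_descriptions = {
            cid + suffix: d for cid, d in model.chain_descriptions.items()
        }
    return out


def read_placements(path: str | Path) -> list[Placement]:
    """Read placements from a transform file.

    Two formats are accepted:

    * plain text: one placement per line, 12 whitespace-separated numbers
      (row-major 3x3 rotation, then translation), optionally followed by a
      label;
    * JSON: a list of ``{"rotation": [[...]], "translation": [...],
      "label": ...}`` objects.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    placements: list[Placement] = []
    if stripped.startswith("[") or stripped.startswith("{"):
        data = json.loads(text)
        if isinstance(data, dict):
            data = [data]
        for i, entry in enumerate(data):
            placements.append(
                Placement(
                    np.asarray(entry["rotation"], dtype=float),
                    np.asarray(entry["translation"], dtype=float),
                    str(entry.get("label", i)),
                )
            )
        return placements
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 12:
            raise PbsnetError(
                f"{path}:{i + 1}: expected 12 numbers (rotation + translation), "
                f"got {len(parts)}"
            )
        nums = [float(x) for x in parts[:12]]
        label = parts[12] if len(parts) > 12 else str(len(placements))
        placements.append(
            Placement(np.array(nums[:9]).reshape(3, 3), np.array(nums[9:12]), label)
        )
    return placements


@dataclass
class ContactSummary:
    """Cross-copy contact table plus layer involvement flags."""

    table: pd.DataFrame
    cutoff: float
    metric: DistanceMetric
    all_involve_boundary_layer: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "n_contacts": int(len(self.table)),
            "min_distance": float(self.table["distance"].min()) if len(self.table) else None,
            "cutoff": self.cutoff,
            "metric": self.metric.value,
            "all_involve_boundary_layer": self.all_involve_boundary_layer,
        }


def inter_complex_contacts(
    copy_a: AssemblyModel | Sequence[Chromophore],
    copy_b: AssemblyModel | Sequence[Chromophore],
    cutoff: float = DEFAULT_CUTOFF,
    metric: DistanceMetric = DEFAULT_METRIC,
) -> ContactSummary:
    """All cross-copy bilin pairs with distance ≤ cutoff, ascending.

    Accepts assemblies (bilins are extracted with defaults) or pre-extracted
    chromophore lists.  The summary's ``all_involve_boundary_layer`` flag
    records whether every contact involves a layer-1 or layer-4
    basal-cylinder bilin of at least one copy (the geometry through which
    stacked cores meet); it is ``None`` when no contact carries layer
    annotation.
    """
    bilins_a = (
        extract_chromophores(copy_a) if isinstance(copy_a, AssemblyModel) else list(copy_a)
    )
    bilins_b = (
        extract_chromophores(copy_b) if isinstance(copy_b, AssemblyModel) else list(copy_b)
    )
    if not bilins_a or not bilins_b:
        raise PbsnetError("inter_complex_contacts: a copy carries no chromophores")

    rows = []
    for ca in bilins_a:
        for cb in bilins_b:
            d = chromophore_distance(ca, cb, metric)
            if d <= cutoff:
                rows.append(
                    {
                        "bilin_a": ca.label,
                        "bilin_b": cb.label,
                        "distance": d,
                        "region_a": ca.region.label,
                        "region_b": cb.region.label,
                        "layer_a": ca.region.layer,
                        "layer_b": cb.region.layer,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "bilin_a", "bilin_b", "distance",
            "region_a", "region_b", "layer_a", "layer_b",
        ],
    ).sort_values("distance", kind="stable").reset_index(drop=True)

    boundary: Optional[bool]
    if len(table) and table[["layer_a", "layer_b"]].notna().any().any():
        boundary = bool(
            table.apply(
                lambda r: r["layer_a"] in (1, 4) or r["layer_b"] in (1, 4), axis=1
            ).all()
        )
    else:
        boundary = None
    return ContactSummary(
        table=table, cutoff=cutoff, metric=metric, all_involve_boundary_layer=boundary
    )
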