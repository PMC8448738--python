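"""Reading and writing atomic models of phycobilisome assemblies.

The module wraps :mod:`gemmi` for mmCIF/PDB parsing and exposes the parsed
model as an :class:`AssemblyModel`: a flat pandas table of heavy atoms plus
per-chain role/region annotations.  Polymer/ligand separation follows the
chemical-component dictionary: standard amino acids (and nucleotides) are
polymer, every other component — bilins included — is a ligand group.

Conventions
-----------
* Author chain ids and author residue numbering are used throughout, the
  numbering in which published residue names (Tyr88, Arg77, ...) are
  expressed.
* Only one model of a multi-model file is analysed (model 1 by default).
* For alternate locations the highest-occupancy conformer is kept; ties are
  broken by file order.
* Hydrogen and deuterium atoms are dropped on load; all downstream distances
  are heavy-atom distances.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    AmbiguousRoleError,
    AnnotationRequiredError,
    DegenerateGeometryError,
    EmptyModelError,
    FormatError,
    StructureIOError,
)
from .regions import (
    ALPHA_ROLES,
    BETA_ROLES,
    Region,
    Role,
    SubunitAnnotation,
    parse_role,
)

logger = logging.getLogger(__name__)

ATOM_COLUMNS = [
    "chain_id",
    "residue_name",
    "residue_number",
    "insertion_code",
    "atom_name",
    "element",
    "x",
    "y",
    "z",
    "is_polymer",
    "model_number",
]


class AtomRecord(NamedTuple):
    """One heavy atom of the assembly (author numbering)."""

    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str
    atom_name: str
    element: str
    position: np.ndarray
    is_polymer: bool
    model_number: int


class LigandGroup(NamedTuple):
    """One non-polymer residue instance."""

    chain_id: str
    residue_number: int
    residue_name: str


@dataclass
class AssemblyModel:
    """A parsed multi-chain assembly.

    Attributes
    ----------
    atoms:
        Heavy-atom table with columns ``chain_id, residue_name,
        residue_number, insertion_code, atom_name, element, x, y, z,
        is_polymer, model_number``.
    annotations:
        Mapping chain id -> :class:`~pbsnet.regions.SubunitAnnotation`.
    chain_descriptions:
        Best-effort mapping chain id -> entity description string (mmCIF
        ``_entity.pdbx_description``), used by annotation auto-guessing.
    """

    atoms: pd.DataFrame
    source: Optional[Path] = None
    format: str = "memory"
    annotations: dict[str, SubunitAnnotation] = field(default_factory=dict)
    chain_descriptions: dict[str, str] = field(default_factory=dict)

    # -- basic views ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of positions in Å."""
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def polymer_chain_ids(self) -> list[str]:
        mask = self.atoms["is_polymer"]
        return sorted(self.atoms.loc[mask, "chain_id"].unique())

    @property
    def ligand_groups(self) -> list[LigandGroup]:
        lig = self.atoms.loc[~self.atoms["is_polymer"]]
        groups = (
            lig.groupby(["chain_id", "residue_number", "residue_name"], sort=True)
            .size()
            .index.tolist()
        )
        return [LigandGroup(c, int(n), r) for c, n, r in groups]

    def chain_summaries(self) -> pd.DataFrame:
        """Per-chain residue counts and polymer flags."""
        rows = []
        for cid, sub in self.atoms.groupby("chain_id", sort=True):
            poly = sub.loc[sub["is_polymer"]]
            rows.append(
                {
                    "chain_id": cid,
                    "n_residues": sub.groupby(["residue_number", "insertion_code"]).ngroups,
                    "n_polymer_residues": poly.groupby(["residue_number", "insertion_code"]).ngroups
                    if len(poly)
                    else 0,
                    "is_polymer": bool(len(poly)),
                }
            )
        return pd.DataFrame(rows)

    def iter_atoms(self) -> Iterable[AtomRecord]:
        for row in self.atoms.itertuples(index=False):
            yield AtomRecord(
                row.chain_id,
                row.residue_name,
                int(row.residue_number),
                row.insertion_code,
                row.atom_name,
                row.element,
                np.array([row.x, row.y, row.z], dtype=float),
                bool(row.is_polymer),
                int(row.model_number),
            )

    def residue_atoms(
        self, chain_id: str, residue_number: int, insertion_code: str = ""
    ) -> pd.DataFrame:
        """Atom table of one residue (author numbering)."""
        a = self.atoms
        mask = (
            (a["chain_id"] == chain_id)
            & (a["residue_number"] == residue_number)
            & (a["insertion_code"] == insertion_code)
        )
        return a.loc[mask]

    def role_of(self, chain_id: str) -> Role:
        ann = self.annotations.get(chain_id)
        return ann.role if ann is not None else Role.OTHER

    def region_of(self, chain_id: str) -> Region:
        ann = self.annotations.get(chain_id)
        return ann.region if ann is not None else Region()

    def with_atoms(self, atoms: pd.DataFrame) -> "AssemblyModel":
        """Copy of this model carrying a replacement atom table."""
        return AssemblyModel(
            atoms=atoms.reset_index(drop=True),
            source=self.source,
            format=self.format,
            annotations=dict(self.annotations),
            chain_descriptions=dict(self.chain_descriptions),
        )


def _is_polymer_component(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None or not info.found():
        return False
    return bool(info.is_amino_acid() or info.is_nucleic_acid())


def _resolve_format(path: Path, format: str) -> gemmi.CoorFormat:
    fmt = format.lower()
    if fmt == "auto":
        return gemmi.CoorFormat.Detect
    if fmt in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    raise FormatError(f"unknown coordinate format {format!r} (expected mmcif, pdb or auto)")


def _entity_descriptions(path: Path) -> dict[str, str]:
    """Map author chain id -> _entity.pdbx_description (mmCIF only)."""
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        ent_desc: dict[str, str] = {}
        for row in block.find("_entity.", ["id", "?pdbx_description"]):
            if row.has(1):
                ent_desc[row.str(0)] = row.str(1)
        chain_desc: dict[str, str] = {}
        table = block.find("_atom_site.", ["auth_asym_id", "label_entity_id"])
        for row in table:
            cid = row.str(0)
            if cid not in chain_desc:
                desc = ent_desc.get(row.str(1))
                if desc:
                    chain_desc[cid] = desc
        return chain_desc
    except Exception:  # noqa: BLE001 - descriptions are optional metadata
        return {}


def load_structure(
    path: str | Path,
    format: str = "auto",
    model_number: int = 1,
) -> AssemblyModel:
    """Read an mmCIF or PDB file into an :class:`AssemblyModel`.

    Parameters
    ----------
    path:
        Coordinate file.  Gzip-compressed files are handled by gemmi.
    format:
        ``"mmcif"``, ``"pdb"`` or ``"auto"`` (detect from contents/extension).
    model_number:
        Which model of a multi-model file to keep (cryo-EM depositions are
        single-model; the default keeps model 1).
    """
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"cannot read structure: no such file {path}")
    coor_format = _resolve_format(path, format)
    try:
        st = gemmi.read_structure(str(path), format=coor_format)
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise StructureIOError(f"failed to parse {path}: {exc}") from exc

    models = list(st)
    chosen = None
    for i, m in enumerate(models, start=1):
        num = getattr(m, "num", None)
        if num is None:
            try:
                num = int(str(getattr(m, "name", i)))
            except ValueError:
                num = i
        if num == model_number:
            chosen = m
            break
    if chosen is None and models:
        if model_number == 1:
            chosen = models[0]
        else:
            raise StructureIOError(f"{path} has no model numbered {model_number}")

    rows: list[tuple] = []
    if chosen is not None:
        for chain in chosen:
            for residue in chain:
                is_poly = _is_polymer_component(residue.name)
                icode = residue.seqid.icode.strip()
                # alternate locations: keep the highest-occupancy conformer,
                # ties broken by file order
                best: dict[str, tuple[float, int, gemmi.Atom]] = {}
                for order, atom in enumerate(residue):
                    if atom.element.is_hydrogen:
                        continue
                    prev = best.get(atom.name)
                    occ = float(atom.occ)
                    if prev is None or occ > prev[0]:
                        best[atom.name] = (occ, order, atom)
                for _, (_, order, atom) in sorted(
                    best.items(), key=lambda kv: kv[1][1]
                ):
                    rows.append(
                        (
                            chain.name,
                            residue.name,
                            int(residue.seqid.num),
                            icode,
                            atom.name,
                            atom.element.name,
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                            is_poly,
                            model_number,
                        )
                    )
    if not rows:
        raise EmptyModelError(f"{path} parsed to zero atoms")

    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    fmt = "pdb" if coor_format == gemmi.CoorFormat.Pdb else "mmcif"
    if coor_format == gemmi.CoorFormat.Detect:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif"
    descriptions = _entity_descriptions(path) if fmt == "mmcif" else {}
    return AssemblyModel(
        atoms=atoms, source=path, format=fmt, chain_descriptions=descriptions
    )


def to_gemmi(model: AssemblyModel, name: str = "pbsnet") -> gemmi.Structure:
    """Build a gemmi Structure from the atom table (for writing)."""
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model(1)
    for cid, chain_df in model.atoms.groupby("chain_id", sort=False):
        chain = gemmi.Chain(str(cid))
        grouped = chain_df.groupby(
            ["residue_number", "insertion_code", "residue_name"], sort=False
        )
        for (num, icode, rname), res_df in grouped:
            res = gemmi.Residue()
            res.name = str(rname)
            res.seqid = gemmi.SeqId(int(num), icode if icode else " ")
            res.het_flag = "A" if bool(res_df["is_polymer"].iloc[0]) else "H"
            for row in res_df.itertuples(index=False):
                atom = gemmi.Atom()
                atom.name = row.atom_name
                atom.element = gemmi.Element(row.element)
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_mmcif(model: AssemblyModel, path: str | Path) -> Path:
    """Write the model to mmCIF.  Returns the path written."""
    path = Path(path)
    st = to_gemmi(model, name=path.stem)
    st.make_mmcif_document().write_file(str(path))
    return path


def write_pdb(model: AssemblyModel, path: str | Path) -> Path:
    """Write the model to PDB format.  Returns the path written."""
    path = Path(path)
    st = to_gemmi(model, name=path.stem)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# subunit annotation
# ---------------------------------------------------------------------------

def _region_from_mapping(data: Mapping | None) -> Region:
    if not data:
        return Region()
    return Region(
        compartment=data.get("compartment"),
        cylinder=data.get("cylinder"),
        layer=data.get("layer"),
        rod_name=data.get("rod_name"),
        hexamer_index=data.get("hexamer_index"),
    )


def annotate_subunits(model: AssemblyModel, config: Mapping) -> AssemblyModel:
    """Attach role/region annotations from a mapping config.

    ``config`` has two optional sections:

    ``chains``
        mapping chain id -> ``{role: ..., region: {...}}`` (or a bare role
        string).
    ``patterns``
        list of ``{match: <regex>, field: chain_id|description, role: ...,
        region: {...}}`` rules applied to every chain not covered by
        ``chains``.

    Chains matched by no rule are annotated ``role=other`` and logged at
    warning level.  Two pattern rules assigning different roles to one chain
    raise :class:`~pbsnet.errors.AmbiguousRoleError`.
    """
    annotations: dict[str, SubunitAnnotation] = {}
    chain_rules = config.get("chains", {}) or {}
    pattern_rules = config.get("patterns", []) or []

    all_chains = sorted(model.atoms["chain_id"].unique())
    for cid in all_chains:
        rule = chain_rules.get(cid)
        if rule is not None:
            if isinstance(rule, str):
                role, region = parse_role(rule), Region()
            else:
                role = parse_role(rule["role"])
                region = _region_from_mapping(rule.get("region"))
            annotations[cid] = SubunitAnnotation(cid, role, region)
            continue
        matches: list[tuple[str, Role, Region]] = []
        for rule in pattern_rules:
            fieldname = rule.get("field", "chain_id")
            if fieldname == "description":
                subject = model.chain_descriptions.get(cid, "")
            else:
                subject = cid
            if subject and re.search(rule["match"], subject, flags=re.IGNORECASE):
                matches.append(
                    (
                        rule["match"],
                        parse_role(rule["role"]),
                        _region_from_mapping(rule.get("region")),
                    )
                )
        roles = {m[1] for m in matches}
        if len(roles) > 1:
            raise AmbiguousRoleError(
                f"chain {cid!r} matched by conflicting rules: "
                + ", ".join(f"{pat!r} -> {role}" for pat, role, _ in matches)
            )
        if matches:
            _, role, region = matches[0]
            annotations[cid] = SubunitAnnotation(cid, role, region)
        else:
            if bool(model.atoms.loc[model.atoms["chain_id"] == cid, "is_polymer"].any()):
                logger.warning("chain %r matched no annotation rule; role=other", cid)
            annotations[cid] = SubunitAnnotation(cid, Role.OTHER, Region())

    out = model.with_atoms(model.atoms)
    out.annotations = annotations
    return out


#: Substring patterns used by :func:`auto_guess_annotation` against mmCIF
#: entity descriptions (standard UniProt-style naming of PBS subunits).
AUTO_GUESS_PATTERNS: list[tuple[str, str]] = [
    (r"allophycocyanin[- ]?b|apcd", "ApcD"),
    (r"core[- ]membrane linker|apce|l_?cm", "ApcE"),
    (r"apcf|phycobilisome.*beta.*18|beta-18", "ApcF"),
    (r"allophycocyanin.*alpha|apca", "ApcA"),
    (r"allophycocyanin.*beta|apcb", "ApcB"),
    (r"rod[- ]core linker|cpcg|l_?rc", "CpcG"),
    (r"rod linker|cpcc(?!-)|\bl_?r\b", "CpcC"),
    (r"(?:core linker|apcc|l_?c\b|7\.8\s*kda)", "ApcC"),
    (r"phycocyanin.*alpha|cpca", "CpcA"),
    (r"phycocyanin.*beta|cpcb", "CpcB"),
]


def auto_guess_annotation(model: AssemblyModel) -> dict:
    """Propose a role-mapping config from entity description substrings.

    Returns a draft config (the structure :func:`annotate_subunits` accepts)
    intended to be reviewed, corrected and saved by the user — region labels
    in particular cannot be guessed from descriptions and are left empty.
    """
    chains: dict[str, dict] = {}
    for cid in sorted(model.atoms["chain_id"].unique()):
        desc = model.chain_descriptions.get(cid, "")
        role = "other"
        for pattern, candidate in AUTO_GUESS_PATTERNS:
            if re.search(pattern, desc, flags=re.IGNORECASE):
                role = candidate
                break
        chains[cid] = {"role": role, "description": desc}
    return {"chains": chains, "patterns": []}


def _require_annotation(model: AssemblyModel) -> None:
    if not model.annotations:
        raise AnnotationRequiredError(
            "operation requires an annotated model; run annotate_subunits first"
        )


def count_subunits(
    model: AssemblyModel,
    roles: Optional[Sequence[Role | str]] = None,
    compartment: Optional[str] = None,
) -> pd.DataFrame:
    """Raw chain counts by role and region.

    Returns a table with columns ``role, compartment, cylinder, layer,
    rod_name, count``; ``roles``/``compartment`` filter the output.
    """
    _require_annotation(model)
    want_roles = None
    if roles is not None:
        want_roles = {parse_role(r) if isinstance(r, str) else r for r in roles}
    rows = []
    polymer_ids = set(model.polymer_chain_ids)
    for cid, ann in sorted(model.annotations.items()):
        if cid not in polymer_ids:
            continue
        if want_roles is not None and ann.role not in want_roles:
            continue
        comp = ann.compartment
        if compartment is not None and comp != compartment:
            continue
        rows.append(
            {
                "role": ann.role.value,
                "compartment": comp,
                "cylinder": ann.region.cylinder,
                "layer": ann.region.layer,
                "rod_name": ann.region.rod_name,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["role", "compartment", "cylinder", "layer", "rod_name", "count"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(
            ["role", "compartment", "cylinder", "layer", "rod_name"],
            dropna=False,
            sort=True,
        )
        .size()
        .reset_index(name="count")
    )
    return out


def count_monomers(
    model: AssemblyModel, compartment: Optional[str] = None
) -> pd.DataFrame:
    """Count alpha-beta monomers per trimer-layer region.

    A monomer is one (alpha-role chain, beta-role chain) pair within the same
    region group: ``(compartment, cylinder, layer)`` for core chains,
    ``(compartment, rod_name, hexamer_index)`` for rod chains.  Within a
    group the pair count is ``min(n_alpha, n_beta)``.
    """
    _require_annotation(model)
    groups: dict[tuple, list[Role]] = {}
    polymer_ids = set(model.polymer_chain_ids)
    for cid, ann in sorted(model.annotations.items()):
        if cid not in polymer_ids:
            continue
        if ann.role not in ALPHA_ROLES | BETA_ROLES:
            continue
        comp = ann.compartment
        if compartment is not None and comp != compartment:
            continue
        if comp == "rod":
            key = (comp, ann.region.rod_name, ann.region.hexamer_index)
        else:
            key = (comp, ann.region.cylinder, ann.region.layer)
        groups.setdefault(key, []).append(ann.role)
    rows = []
    for key, roles_in_group in sorted(
        groups.items(), key=lambda kv: tuple(str(x) for x in kv[0])
    ):
        n_alpha = sum(1 for r in roles_in_group if r in ALPHA_ROLES)
        n_beta = sum(1 for r in roles_in_group if r in BETA_ROLES)
        rows.append(
            {
                "compartment": key[0],
                "group": "/".join("?" if x is None else str(x) for x in key[1:]),
                "n_alpha": n_alpha,
                "n_beta": n_beta,
                "n_monomers": min(n_alpha, n_beta),
            }
        )
    return pd.DataFrame(
        rows, columns=["compartment", "group", "n_alpha", "n_beta", "n_monomers"]
    )


def assembly_dimensions(model: AssemblyModel) -> tuple[float, float, float]:
    """Extents (length >= height >= thickness, Å) along principal axes.

    The atom cloud is rotated to its principal axes and the axis-aligned
    bounding-box extents of the rotated cloud are returned in decreasing
    order.  Rigid motions of the input change the result only through
    floating-point noise.
    """
    coords = model.coords
    if len(coords) < 3:
        raise DegenerateGeometryError(
            f"assembly_dimensions needs >= 3 atoms, got {len(coords)}"
        )
    centered = coords - coords.mean(axis=0)
    # principal axes of the point cloud
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    if singular[1] <= 1e-9 * max(1.0, singular[0]):
        raise DegenerateGeometryError("atoms are collinear; extents are degenerate")
    projected = centered @ vt.T
    extents = projected.max(axis=0) - projected.min(axis=0)
    length, height, thickness = sorted((float(e) for e in extents), reverse=True)
    return (length, height, thickness)
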