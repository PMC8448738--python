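"""End-to-end analysis pipeline and input validation.

:func:`run_pipeline` chains the stages in the order an analyst reads a
structure: subunit census -> chromophore extraction -> EET network ->
terminal-emitter paths -> microenvironment survey, writing one file per
stage plus a summary JSON that echoes the full effective configuration.
Partial results are preserved on failure: the output directory's MANIFEST
records which stages completed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .chromophore import (
    BILIN_COMPONENT_CODES,
    DistanceMetric,
    chromophore_table,
    extract_chromophores,
)
from .errors import PbsnetError
from .microenvironment import (
    DEFAULT_THRESHOLDS,
    EXTENDED_SHELL,
    PRIMARY_SHELL,
    InteractionThresholds,
    aromatic_census,
    chromophore_neighborhood,
    classify_contacts,
)
from .network import (
    DEFAULT_CUTOFF,
    build_network,
    edge_table,
    terminal_emitter_report,
    to_graphml,
)
from .structure_io import (
    annotate_subunits,
    assembly_dimensions,
    count_monomers,
    count_subunits,
    load_structure,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    input_path: Path
    annotation_config: Optional[Path] = None
    output_dir: Path = Path("pbsnet_out")
    component_codes: tuple[str, ...] = tuple(sorted(BILIN_COMPONENT_CODES))
    metric: DistanceMetric = DistanceMetric.MIN_CONJUGATED_ATOM
    cutoff: float = DEFAULT_CUTOFF
    weight_mode: str = "distance_power6"
    shells: tuple[float, ...] = (PRIMARY_SHELL, EXTENDED_SHELL)
    thresholds: InteractionThresholds = field(default_factory=InteractionThresholds)

    def to_dict(self) -> dict:
        return {
            "input_path": str(self.input_path),
            "annotation_config": str(self.annotation_config)
            if self.annotation_config
            else None,
            "output_dir": str(self.output_dir),
            "component_codes": list(self.component_codes),
            "metric": self.metric.value,
            "cutoff": self.cutoff,
            "weight_mode": self.weight_mode,
            "shells": list(self.shells),
            "thresholds": self.thresholds.to_dict(),
            "version": __version__,
        }


def load_annotation_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise PbsnetError(f"annotation config {path} must be a mapping")
    return config


@dataclass
class Diagnostic:
    severity: str  # error | warning | info
    message: str


def validate_inputs(config: RunConfig) -> list[Diagnostic]:
    """Check inputs without mutating anything; returns diagnostics."""
    diags: list[Diagnostic] = []
    if not Path(config.input_path).exists():
        diags.append(Diagnostic("error", f"input file not found: {config.input_path}"))
        return diags
    try:
        model = load_structure(config.input_path)
    except PbsnetError as exc:
        diags.append(Diagnostic("error", f"cannot parse input: {exc}"))
        return diags
    diags.append(
        Diagnostic(
            "info",
            f"parsed {model.n_atoms} atoms, {len(model.polymer_chain_ids)} polymer "
            f"chains, {len(model.ligand_groups)} ligand groups",
        )
    )
    if config.annotation_config is not None:
        if not Path(config.annotation_config).exists():
            diags.append(
                Diagnostic("error", f"annotation config not found: {config.annotation_config}")
            )
        else:
            cfg = load_annotation_config(config.annotation_config)
            annotated = annotate_subunits(model, cfg)
            n_other = sum(
                1
                for cid in annotated.polymer_chain_ids
                if annotated.role_of(cid).value == "other"
            )
            total = len(annotated.polymer_chain_ids)
            covered = 100.0 * (total - n_other) / total if total else 0.0
            level = "info" if n_other == 0 else "warning"
            diags.append(
                Diagnostic(level, f"annotation covers {covered:.0f}% of polymer chains")
            )
    chromos = extract_chromophores(model, config.component_codes)
    if not chromos:
        diags.append(
            Diagnostic(
                "warning",
                f"no chromophores matched component codes {sorted(config.component_codes)}",
            )
        )
    else:
        diags.append(Diagnostic("info", f"{len(chromos)} chromophores matched"))
    return diags


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written to JSON).

    Output files (TSV unless noted): ``chromophores.tsv``,
    ``census_chains.tsv``, ``census_monomers.tsv``, ``network.graphml``,
    ``network_edges.tsv``, ``paths.json``, ``contacts.tsv``,
    ``aromatic_census.tsv``, ``summary.json``, ``MANIFEST.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest_path = out / "MANIFEST.json"

    def mark(stage: str) -> None:
        completed.append(stage)
        manifest_path.write_text(
            json.dumps({"completed_stages": completed}, indent=2) + "\n"
        )

    summary: dict = {"config": config.to_dict()}
    try:
        stage = "load"
        model = load_structure(config.input_path)
        if config.annotation_config is not None:
            model = annotate_subunits(
                model, load_annotation_config(config.annotation_config)
            )
        summary["n_atoms"] = model.n_atoms
        try:
            dims = assembly_dimensions(model)
            summary["dimensions"] = {
                "length": dims[0], "height": dims[1], "thickness": dims[2]
            }
        except PbsnetError:
            summary["dimensions"] = None
        mark(stage)

        stage = "census"
        if model.annotations:
            chains = count_subunits(model)
            chains.to_csv(out / "census_chains.tsv", sep="\t", index=False)
            monomers = count_monomers(model)
            monomers.to_csv(out / "census_monomers.tsv", sep="\t", index=False)
            summary["census"] = {
                "chains_by_compartment": chains.groupby("compartment", dropna=False)["count"]
                .sum()
                .to_dict(),
                "monomers_by_compartment": monomers.groupby("compartment", dropna=False)[
                    "n_monomers"
                ]
                .sum()
                .to_dict()
                if len(monomers)
                else {},
            }
            mark(stage)

        stage = "extract"
        chromos = extract_chromophores(model, config.component_codes)
        table = chromophore_table(chromos)
        table.to_csv(out / "chromophores.tsv", sep="\t", index=False, float_format="%.2f")
        summary["total_chromophores"] = len(chromos)
        by_comp: dict[str, int] = {}
        for c in chromos:
            comp = c.region.compartment or (
                "core" if c.parent_role.value.startswith("Apc") else
                "rod" if c.parent_role.value.startswith("Cpc") else "unplaced"
            )
            by_comp[comp] = by_comp.get(comp, 0) + 1
        summary["chromophores_by_compartment"] = by_comp
        mark(stage)
        if not chromos:
            summary["note"] = "no chromophores; network and environment stages skipped"
            logger.warning("no chromophores matched; stopping after extraction")
            (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
            return summary

        stage = "network"
        network = build_network(
            chromos,
            cutoff=config.cutoff,
            metric=config.metric,
            weight_mode=config.weight_mode,
        )
        to_graphml(network, out / "network.graphml")
        edge_table(network).to_csv(
            out / "network_edges.tsv", sep="\t", index=False, float_format="%.2f"
        )
        summary["network"] = {
            "n_nodes": network.graph.number_of_nodes(),
            "n_edges": network.graph.number_of_edges(),
            "n_terminal_emitters": len(network.terminal_emitters()),
        }
        mark(stage)

        stage = "paths"
        if network.terminal_emitters():
            report = terminal_emitter_report(network)
            records = report.to_dict(orient="records")
            (out / "paths.json").write_text(json.dumps(records, indent=2, default=str) + "\n")
            summary["paths"] = {
                "n_sources": len(report),
                "recovered": records,
            }
            mark(stage)

        stage = "environment"
        contact_frames = []
        for chromo in chromos:
            contacts = chromophore_neighborhood(model, chromo, max(config.shells))
            if contacts:
                contact_frames.append(
                    classify_contacts(model, chromo, contacts, config.thresholds)
                )
        if contact_frames:
            import pandas as pd

            contacts_df = pd.concat(contact_frames, ignore_index=True)
        else:
            import pandas as pd

            contacts_df = pd.DataFrame()
        contacts_df.to_csv(out / "contacts.tsv", sep="\t", index=False, float_format="%.2f")
        grouping = "region" if model.annotations else "chain"
        census = aromatic_census(model, chromos, max(config.shells), grouping=grouping)
        census.to_csv(out / "aromatic_census.tsv", sep="\t", index=False, float_format="%.3f")
        summary["environment"] = {
            "n_contacts": int(len(contacts_df)),
            "n_classified": int((contacts_df["interaction_kind"] != "none").sum())
            if len(contacts_df)
            else 0,
        }
        mark(stage)
    except PbsnetError as exc:
        summary["error"] = {"stage": stage, "message": str(exc)}
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
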