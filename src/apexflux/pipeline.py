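"""End-to-end runs: structured config, manifests, deterministic outputs.

``run_interactome`` composes quantification, flux classification, arm
overlap, optional GMT enrichment, and QC into one directory of TSV tables
plus a JSON manifest (config echo, package version, seed, config hash).
``run_psi`` does the same for the junction-PSI track. Identical config and
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError
from .flux import (
    classify_flux,
    enrich_categories,
    enrichment_to_frame,
    flux_to_frame,
    hypergeom_overlap_test,
    overlap_to_frame,
    percent_overlap,
    qc_cluster,
)
from .interactome import interactors_to_frame, quantify_interactome
from .io import (
    read_condition_map,
    read_design,
    read_gmt,
    read_junction_counts,
    read_protein_groups,
    write_results,
)
from .junctions import (
    ARJunctionModel,
    call_events,
    class_reports_to_frame,
    classify_ar_junctions,
    events_from_counts,
    events_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Structured configuration for the two analysis tracks.

    Unknown keys in a YAML config are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    # inputs
    protein_groups: str | None = None
    design: str | None = None
    gmt: str | None = None
    junctions: str | None = None
    conditions: str | None = None
    junction_model: str | None = None
    out_dir: str = "apexflux_out"
    # thresholds
    min_unique: int = 2
    min_replicates: int = 2
    min_control_detections: int = 1
    fc_threshold: float = 1.5
    dpsi_threshold: float = 0.2
    alpha: float = 0.05
    # modes
    inclusive_fc: bool = True
    overlap_denominator: str = "union"
    control_condition: str = "control"
    treated_condition: str = "knockdown"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_unique < 1 or self.min_replicates < 1:
            raise ConfigError("min_unique and min_replicates must be >= 1")
        if self.fc_threshold <= 1:
            raise ConfigError("fc_threshold must be > 1")
        if not 0 <= self.dpsi_threshold <= 1:
            raise ConfigError("dpsi_threshold must be in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.overlap_denominator not in ("union", "min", "query"):
            raise ConfigError(
                f"unknown overlap denominator {self.overlap_denominator!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_manifest(
    config: RunConfig, out_dir: Path, extra: dict, name: str = "manifest.json"
) -> None:
    manifest = {
        "apexflux_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **extra,
    }
    with open(out_dir / name, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_interactome(config: RunConfig) -> dict[str, Path]:
    """Run the proteomics track; returns a map of artifact name -> path."""
    if not config.protein_groups or not config.design:
        raise ConfigError("protein_groups and design paths are required")
    for path in (config.protein_groups, config.design):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    design = read_design(config.design)
    rows = read_protein_groups(config.protein_groups, design)
    result = quantify_interactome(
        rows,
        design,
        min_unique=config.min_unique,
        min_replicates=config.min_replicates,
        min_control_detections=config.min_control_detections,
    )
    outputs: dict[str, Path] = {}

    interactors_path = out_dir / "interactors.tsv"
    write_results(interactors_to_frame(result.records), interactors_path, chash)
    outputs["interactors"] = interactors_path

    calls = classify_flux(
        result.records, fc_threshold=config.fc_threshold,
        inclusive=config.inclusive_fc,
    )
    flux_path = out_dir / "flux.tsv"
    write_results(flux_to_frame(calls), flux_path, chash)
    outputs["flux"] = flux_path

    minus = result.ids_in_arm("minus_ir")
    plus = result.ids_in_arm("plus_ir")
    if minus or plus:
        universe = {r.protein_id for r in result.records} | minus | plus
        res = percent_overlap(minus, plus, denominator=config.overlap_denominator)
        with_p = hypergeom_overlap_test(minus, plus, universe)
        res.hypergeom_p = with_p.hypergeom_p
        res.universe_size = with_p.universe_size
        overlap_path = out_dir / "overlap.tsv"
        write_results(overlap_to_frame(res), overlap_path, chash)
        outputs["overlap"] = overlap_path

    if config.gmt:
        gmt = read_gmt(config.gmt)
        universe = {r.protein_id for r in rows if not (r.is_decoy or r.is_flagged_contaminant)}
        query = minus | plus
        enr = enrich_categories(query, gmt, universe, alpha=config.alpha)
        enrich_path = out_dir / "enrichment.tsv"
        write_results(enrichment_to_frame(enr), enrich_path, chash)
        outputs["enrichment"] = enrich_path

    if result.ribaq.values.shape[1] >= 2:
        qc = qc_cluster(result.ribaq)
        pca_df = qc.pca_coords.reset_index(names="sample_id")
        qc_path = out_dir / "qc_pca.tsv"
        write_results(pca_df, qc_path, chash)
        outputs["qc_pca"] = qc_path
        dendro_path = out_dir / "qc_dendrogram.tsv"
        write_results(
            pd.DataFrame(
                {"order": range(1, len(qc.dendrogram_order) + 1),
                 "sample_id": qc.dendrogram_order}
            ),
            dendro_path,
            chash,
        )
        outputs["qc_dendrogram"] = dendro_path

    _write_manifest(
        config, out_dir,
        {"stage_counts": result.stage_counts,
         "n_minus_ir": len(minus), "n_plus_ir": len(plus)},
        name="interactome_manifest.json",
    )
    outputs["manifest"] = out_dir / "interactome_manifest.json"
    return outputs


def run_psi(config: RunConfig) -> dict[str, Path]:
    """Run the junction-PSI track; returns a map of artifact name -> path."""
    if not config.junctions or not config.conditions:
        raise ConfigError("junctions and conditions paths are required")
    for path in (config.junctions, config.conditions):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    rows = read_junction_counts(config.junctions)
    conditions = read_condition_map(config.conditions)
    model = (
        ARJunctionModel.from_table(config.junction_model)
        if config.junction_model
        else ARJunctionModel.default()
    )
    control, treated = config.control_condition, config.treated_condition
    if not rows:
        logger.warning("empty junction table; writing empty outputs")
        events = []
    else:
        events = events_from_counts(rows, conditions, control, treated)
    called = call_events(events, config.dpsi_threshold, config.alpha)
    called_ids = {e.junction_id for e in called}
    events_path = out_dir / "events.tsv"
    write_results(
        events_to_frame(events, control, treated, called_ids), events_path, chash
    )
    outputs = {"events": events_path}

    if rows:
        reports, _ = classify_ar_junctions(rows, model, conditions, control, treated)
    else:
        reports = []
    classes_path = out_dir / "ar_classes.tsv"
    write_results(class_reports_to_frame(reports, control, treated), classes_path, chash)
    outputs["ar_classes"] = classes_path

    _write_manifest(
        config, out_dir,
        {"n_junctions": len(rows), "n_events": len(events),
         "n_called": len(called)},
        name="psi_manifest.json",
    )
    outputs["manifest"] = out_dir / "psi_manifest.json"
    return outputs
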