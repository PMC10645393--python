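"""riBAQ quantification and interactor filtering for the APEX2 design.

The pipeline turns a raw protein-groups table into per-arm interactor lists:

1. drop decoy and flagged-contaminant groups;
2. normalize each sample to relative iBAQ (riBAQ), so each sample's detected
   proteome sums to 1;
3. omit proteins detected in the no-H2O2 control arm (endogenously
   biotinylated / nonspecific background);
4. keep proteins with >=2 unique peptides that are detected in >=2
   replicates of an experimental arm;
5. summarize each retained protein as its mean riBAQ per arm (mean over the
   replicates in which it was detected; no zero-imputation) with per-arm
   abundance ranks.

Detection means a present, strictly positive iBAQ in that sample; nothing is
imputed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, NormalizationError, SchemaError
from .io import EXPERIMENTAL_ARMS, ExperimentDesign, ProteinGroupRow

logger = logging.getLogger(__name__)


@dataclass
class RibaqMatrix:
    """Proteins x samples matrix of riBAQ values.

    ``values`` holds NaN where a protein was not detected in a sample;
    present values lie in (0, 1] and each sample column of present values
    sums to 1. ``denominators`` records the per-sample total iBAQ used for
    normalization.
    """

    values: pd.DataFrame
    denominators: pd.Series

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)


@dataclass
class InteractorRecord:
    """A filtered interactor with per-arm mean riBAQ, support, and rank.

    An arm appears in the per-arm maps only if the protein passed the
    evidence filter for that arm (detected in >= min_replicates replicates).
    """

    protein_id: str
    gene_name: str
    mean_ribaq_by_arm: dict[str, float]
    replicate_support_by_arm: dict[str, int]
    max_unique_peptides: int
    rank_by_arm: dict[str, int] = field(default_factory=dict)

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.mean_ribaq_by_arm)


def drop_decoys_and_flags(
    rows: list[ProteinGroupRow],
) -> list[ProteinGroupRow]:
    """Remove decoy (reverse-database) and flagged-contaminant groups."""
    kept = [r for r in rows if not (r.is_decoy or r.is_flagged_contaminant)]
    logger.info(
        "decoy/flag removal: %d in, %d retained, %d removed",
        len(rows), len(kept), len(rows) - len(kept),
    )
    return kept


def compute_ribaq(
    rows: list[ProteinGroupRow],
    design: ExperimentDesign,
    on_empty: str = "error",
) -> RibaqMatrix:
    """Normalize iBAQ to riBAQ per sample: riBAQ_i = iBAQ_i / sum_j iBAQ_j
    over proteins detected in that sample. Missing stays missing.

    ``on_empty`` controls samples with zero total iBAQ: ``"error"`` raises a
    :class:`NormalizationError` naming the sample, ``"drop"`` excludes the
    column with a warning.
    """
    if on_empty not in ("error", "drop"):
        raise ConfigError(f"on_empty must be 'error' or 'drop', got {on_empty!r}")
    ids = [r.protein_id for r in rows]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate protein_id(s): {dupes}")
    mat = pd.DataFrame(np.nan, index=ids, columns=list(design.sample_ids))
    for r in rows:
        for sid, val in r.ibaq_by_sample.items():
            if val > 0:
                mat.loc[r.protein_id, sid] = val
    totals = mat.sum(axis=0, skipna=True)
    empty = [sid for sid in mat.columns if not totals[sid] > 0]
    if empty:
        if on_empty == "error":
            raise NormalizationError(
                f"sample(s) with zero total iBAQ: {empty}"
            )
        logger.warning("dropping sample(s) with no detections: %s", empty)
        mat = mat.drop(columns=empty)
        totals = totals.drop(index=empty)
    return RibaqMatrix(values=mat / totals, denominators=totals)


def filter_control_contaminants(
    rows: list[ProteinGroupRow],
    design: ExperimentDesign,
    min_control_detections: int = 1,
) -> tuple[list[ProteinGroupRow], set[str]]:
    """Omit proteins detected in the control (no-H2O2) arm.

    A protein counts as control-detected in a sample when it has a present
    iBAQ and >=1 unique peptide there; detection in >=
    ``min_control_detections`` control replicates removes it from
    experimental consideration. Returns (retained rows, removed protein ids).
    """
    control_samples = design.samples_in_arm("control")
    if not control_samples:
        raise ConfigError("design has no control samples; cannot apply "
                          "control-contaminant omission")
    if min_control_detections < 1:
        raise ConfigError("min_control_detections must be >= 1")
    kept: list[ProteinGroupRow] = []
    removed: set[str] = set()
    for r in rows:
        n_det = sum(
            1
            for sid in control_samples
            if r.detected_in(sid) and r.unique_peptides_by_sample.get(sid, 0) >= 1
        )
        if n_det >= min_control_detections:
            removed.add(r.protein_id)
        else:
            kept.append(r)
    logger.info(
        "control-contaminant omission: %d in, %d retained, %d removed",
        len(rows), len(kept), len(removed),
    )
    return kept, removed


def _arm_support(row: ProteinGroupRow, design: ExperimentDesign, arm: str) -> int:
    return sum(1 for sid in design.samples_in_arm(arm) if row.detected_in(sid))


def retained_arms(
    row: ProteinGroupRow,
    design: ExperimentDesign,
    min_unique: int = 2,
    min_replicates: int = 2,
) -> tuple[str, ...]:
    """Experimental arms for which a protein passes the evidence filter:
    max per-sample unique peptides >= min_unique and detection in >=
    min_replicates replicates of that arm."""
    max_pep = max(row.unique_peptides_by_sample.values(), default=0)
    if max_pep < min_unique:
        return ()
    return tuple(
        arm
        for arm in design.experimental_arms
        if _arm_support(row, design, arm) >= min_replicates
    )


def apply_evidence_filters(
    rows: list[ProteinGroupRow],
    design: ExperimentDesign,
    min_unique: int = 2,
    min_replicates: int = 2,
) -> list[ProteinGroupRow]:
    """Keep proteins passing the evidence filter in >=1 experimental arm."""
    if min_unique < 1 or min_replicates < 1:
        raise ConfigError("min_unique and min_replicates must be >= 1")
    for arm in design.experimental_arms:
        n = len(design.samples_in_arm(arm))
        if min_replicates > n:
            raise ConfigError(
                f"min_replicates={min_replicates} exceeds the {n} replicate(s) "
                f"of arm {arm!r}"
            )
    kept = [
        r for r in rows if retained_arms(r, design, min_unique, min_replicates)
    ]
    logger.info(
        "evidence filter (>=%d unique peptides, >=%d replicates): "
        "%d in, %d retained, %d removed",
        min_unique, min_replicates, len(rows), len(kept), len(rows) - len(kept),
    )
    return kept


def summarize_interactors(
    ribaq: RibaqMatrix,
    rows: list[ProteinGroupRow],
    design: ExperimentDesign,
    min_unique: int = 2,
    min_replicates: int = 2,
) -> list[InteractorRecord]:
    """Summarize evidence-filtered proteins as per-arm mean riBAQ records.

    The per-arm mean is the arithmetic mean of riBAQ over the replicates in
    which the protein was detected (2 or 3 of 3, depending on support); ranks
    are assigned per arm by descending mean riBAQ with lexicographic
    protein-id tie-breaks.
    """
    records: list[InteractorRecord] = []
    for r in rows:
        arms = retained_arms(r, design, min_unique, min_replicates)
        if not arms:
            continue
        means: dict[str, float] = {}
        support: dict[str, int] = {}
        for arm in arms:
            sids = [
                sid
                for sid in design.samples_in_arm(arm)
                if sid in ribaq.values.columns and r.detected_in(sid)
            ]
            vals = ribaq.values.loc[r.protein_id, sids].astype(float)
            vals = vals.dropna()
            support[arm] = int(len(vals))
            means[arm] = float(vals.mean())
        records.append(
            InteractorRecord(
                protein_id=r.protein_id,
                gene_name=r.gene_name,
                mean_ribaq_by_arm=means,
                replicate_support_by_arm=support,
                max_unique_peptides=max(
                    r.unique_peptides_by_sample.values(), default=0
                ),
            )
        )
    for arm in design.experimental_arms:
        in_arm = [rec for rec in records if arm in rec.mean_ribaq_by_arm]
        in_arm.sort(key=lambda rec: (-rec.mean_ribaq_by_arm[arm], rec.protein_id))
        for rank, rec in enumerate(in_arm, start=1):
            rec.rank_by_arm[arm] = rank
    records.sort(key=lambda rec: rec.protein_id)
    return records


@dataclass
class InteractomeResult:
    """Bundle returned by :func:`quantify_interactome`."""

    records: list[InteractorRecord]
    ribaq: RibaqMatrix
    removed_contaminant_ids: set[str]
    n_decoys_removed: int
    stage_counts: dict[str, int]

    def ids_in_arm(self, arm: str) -> set[str]:
        return {r.protein_id for r in self.records if arm in r.mean_ribaq_by_arm}


def quantify_interactome(
    rows: list[ProteinGroupRow],
    design: ExperimentDesign,
    min_unique: int = 2,
    min_replicates: int = 2,
    min_control_detections: int = 1,
) -> InteractomeResult:
    """Run the full filter/quantification pipeline in its canonical order:
    decoy removal -> riBAQ normalization -> control omission -> evidence
    filters -> per-arm summaries. Normalization precedes contaminant removal
    so riBAQ reflects each run's full detected proteome."""
    no_decoys = drop_decoys_and_flags(rows)
    ribaq = compute_ribaq(no_decoys, design, on_empty="drop")
    no_contam, removed = filter_control_contaminants(
        no_decoys, design, min_control_detections
    )
    filtered = apply_evidence_filters(no_contam, design, min_unique, min_replicates)
    records = summarize_interactors(
        ribaq, filtered, design, min_unique, min_replicates
    )
    stage_counts = {
        "input": len(rows),
        "after_decoy_flag_removal": len(no_decoys),
        "after_control_omission": len(no_contam),
        "after_evidence_filters": len(filtered),
        "records": len(records),
    }
    return InteractomeResult(
        records=records,
        ribaq=ribaq,
        removed_contaminant_ids=removed,
        n_decoys_removed=len(rows) - len(no_decoys),
        stage_counts=stage_counts,
    )


def interactors_to_frame(records: list[InteractorRecord]) -> pd.DataFrame:
    """Flatten interactor records to a result table (one row per protein)."""
    recs = []
    for r in records:
        rec: dict[str, object] = {
            "protein_id": r.protein_id,
            "gene_name": r.gene_name,
            "max_unique_peptides": r.max_unique_peptides,
        }
        for arm in EXPERIMENTAL_ARMS:
            rec[f"mean_ribaq_{arm}"] = r.mean_ribaq_by_arm.get(arm, np.nan)
            rec[f"support_{arm}"] = r.replicate_support_by_arm.get(arm, 0)
            rec[f"rank_{arm}"] = r.rank_by_arm.get(arm, 0)
        recs.append(rec)
    cols = ["protein_id", "gene_name", "max_unique_peptides"]
    for arm in EXPERIMENTAL_ARMS:
        cols += [f"mean_ribaq_{arm}", f"support_{arm}", f"rank_{arm}"]
    return pd.DataFrame(recs, columns=cols)


def interactors_from_frame(df: pd.DataFrame) -> list[InteractorRecord]:
    """Inverse of :func:`interactors_to_frame`."""
    records = []
    for rec in df.to_dict(orient="records"):
        means: dict[str, float] = {}
        support: dict[str, int] = {}
        ranks: dict[str, int] = {}
        for arm in EXPERIMENTAL_ARMS:
            mean = rec.get(f"mean_ribaq_{arm}", np.nan)
            sup = int(rec.get(f"support_{arm}", 0) or 0)
            if sup > 0 and not pd.isna(mean):
                means[arm] = float(mean)
                support[arm] = sup
                rank = int(rec.get(f"rank_{arm}", 0) or 0)
                if rank:
                    ranks[arm] = rank
        records.append(
            InteractorRecord(
                protein_id=str(rec["protein_id"]),
                gene_name="" if pd.isna(rec.get("gene_name")) else str(rec["gene_name"]),
                mean_ribaq_by_arm=means,
                replicate_support_by_arm=support,
                max_unique_peptides=int(rec["max_unique_peptides"]),
                rank_by_arm=ranks,
            )
        )
    return records
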