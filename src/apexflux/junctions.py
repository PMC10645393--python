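"""Percent-spliced-in (PSI) analysis of splice-junction counts.

PSI of a junction is computed against the competing junctions that share the
same donor exon: inclusion reads are the junction's own counts and exclusion
reads are the pooled counts of its donor-sharing competitors, so for a pair
of junctions competing for one donor the two PSI values sum to exactly 1.
Replicates are pooled by summation within each condition before estimation
(read depth is the information unit); dPSI is treated-minus-control and the
significance of a PSI change is assessed with a two-sided Fisher exact test
on the pooled 2x2 inclusion/exclusion table. That test is a documented
stand-in for the internal tests of dedicated event-annotation tools, which
this package does not reproduce.

The androgen-receptor (AR) junction model maps junctions between named exons
to isoform classes: exon2->exon3 supports full-length AR and the V1/V6/V7/V9
variants, exon3->CE3 (cryptic exon 3) encodes AR-V7, and exon2->CE4 marks a
distinct cryptic-exon-4-containing transcript class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .errors import ConfigError, ModelError, SchemaError, UndefinedPsiError
from .io import JunctionCountRow

logger = logging.getLogger(__name__)


def compute_psi(inclusion: int, exclusion: int) -> float:
    """PSI = inclusion / (inclusion + exclusion); undefined for zero depth."""
    if inclusion < 0 or exclusion < 0:
        raise SchemaError("counts must be nonnegative")
    total = inclusion + exclusion
    if total == 0:
        raise UndefinedPsiError("PSI undefined: inclusion + exclusion == 0")
    return inclusion / total


def test_dpsi(
    inclusion_1: int,
    exclusion_1: int,
    inclusion_2: int,
    exclusion_2: int,
) -> tuple[float, float]:
    """dPSI (condition 2 minus condition 1) and two-sided Fisher exact p on
    the pooled 2x2 inclusion/exclusion table."""
    for c in (inclusion_1, exclusion_1, inclusion_2, exclusion_2):
        if c < 0:
            raise SchemaError("counts must be nonnegative")
    psi1 = compute_psi(inclusion_1, exclusion_1)
    psi2 = compute_psi(inclusion_2, exclusion_2)
    _, p = fisher_exact(
        [[inclusion_1, exclusion_1], [inclusion_2, exclusion_2]],
        alternative="two-sided",
    )
    return psi2 - psi1, float(p)


@dataclass
class JunctionEvent:
    """A junction with pooled inclusion/exclusion counts, PSI per condition,
    dPSI (treated minus control), and Fisher p."""

    junction_id: str
    donor_exon: str
    acceptor_exon: str
    inclusion_by_condition: dict[str, int]
    exclusion_by_condition: dict[str, int]
    psi_by_condition: dict[str, float]
    dpsi: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class ARJunctionModel:
    """Map from (donor_exon, acceptor_exon) to an isoform-class label."""

    classes: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", dict(self.classes))

    @classmethod
    def default(cls) -> "ARJunctionModel":
        return cls(
            {
                ("E2", "E3"): "FL/V1/V6/V7/V9-compatible",
                ("E3", "CE3"): "AR-V7-encoding",
                ("E2", "CE4"): "CE4-containing",
            }
        )

    @classmethod
    def from_table(cls, path: str | Path) -> "ARJunctionModel":
        """Read a model TSV with columns donor_exon, acceptor_exon, class."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"junction model not found: {path}")
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        for col in ("donor_exon", "acceptor_exon", "class"):
            if col not in df.columns:
                raise ModelError(f"junction model missing column {col!r}")
        classes: dict[tuple[str, str], str] = {}
        for rec in df.to_dict(orient="records"):
            key = (str(rec["donor_exon"]).strip(), str(rec["acceptor_exon"]).strip())
            if key in classes:
                raise ModelError(f"duplicate junction key {key} in model")
            classes[key] = str(rec["class"]).strip()
        return cls(classes)

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"donor_exon": d, "acceptor_exon": a, "class": c}
                for (d, a), c in self.classes.items()
            ],
            columns=["donor_exon", "acceptor_exon", "class"],
        ).to_csv(path, sep="\t", index=False)

    def label(self, donor: str, acceptor: str) -> str | None:
        return self.classes.get((donor, acceptor))


def _pooled_counts(
    row: JunctionCountRow,
    condition_by_sample: Mapping[str, str],
    condition: str,
) -> int:
    return sum(
        c
        for sid, c in row.counts_by_sample.items()
        if condition_by_sample.get(sid) == condition
    )


def events_from_counts(
    rows: Sequence[JunctionCountRow],
    condition_by_sample: Mapping[str, str],
    control: str,
    treated: str,
) -> list[JunctionEvent]:
    """Build tested PSI events from junction counts.

    For each junction, exclusion counts in a condition are the pooled counts
    of the other junctions sharing its donor exon. Junctions with zero total
    depth in either condition are skipped with a warning.
    """
    if control == treated:
        raise ConfigError("control and treated conditions must differ")
    groups: dict[str, list[JunctionCountRow]] = {}
    for r in rows:
        groups.setdefault(r.donor_exon, []).append(r)
    events: list[JunctionEvent] = []
    for donor in groups:
        group = groups[donor]
        totals = {
            cond: sum(_pooled_counts(r, condition_by_sample, cond) for r in group)
            for cond in (control, treated)
        }
        for r in group:
            inc = {
                cond: _pooled_counts(r, condition_by_sample, cond)
                for cond in (control, treated)
            }
            exc = {cond: totals[cond] - inc[cond] for cond in (control, treated)}
            if any(inc[c] + exc[c] == 0 for c in (control, treated)):
                logger.warning(
                    "skipping junction %s: zero depth in a condition",
                    r.junction_id,
                )
                continue
            psi = {c: compute_psi(inc[c], exc[c]) for c in (control, treated)}
            dpsi, p = test_dpsi(
                inc[control], exc[control], inc[treated], exc[treated]
            )
            events.append(
                JunctionEvent(
                    junction_id=r.junction_id,
                    donor_exon=r.donor_exon,
                    acceptor_exon=r.acceptor_exon,
                    inclusion_by_condition=inc,
                    exclusion_by_condition=exc,
                    psi_by_condition=psi,
                    dpsi=dpsi,
                    p_value=p,
                )
            )
    events.sort(key=lambda e: e.junction_id)
    return events


def call_events(
    events: Sequence[JunctionEvent],
    dpsi_threshold: float = 0.2,
    alpha: float = 0.05,
) -> list[JunctionEvent]:
    """Select significant splicing changes: |dPSI| strictly greater than the
    threshold and p strictly below alpha (boundary values are not called)."""
    if dpsi_threshold < 0 or alpha < 0:
        raise ConfigError("dpsi_threshold and alpha must be nonnegative")
    return [
        e
        for e in events
        if e.dpsi is not None
        and e.p_value is not None
        and abs(e.dpsi) > dpsi_threshold
        and e.p_value < alpha
    ]


@dataclass
class IsoformClassReport:
    """Aggregated PSI report for one isoform class of the junction model."""

    label: str
    junction_ids: tuple[str, ...]
    inclusion_by_condition: dict[str, int]
    exclusion_by_condition: dict[str, int]
    psi_by_condition: dict[str, float]
    dpsi: float
    p_value: float


def classify_ar_junctions(
    rows: Sequence[JunctionCountRow],
    model: ARJunctionModel,
    condition_by_sample: Mapping[str, str],
    control: str,
    treated: str,
) -> tuple[list[IsoformClassReport], list[JunctionEvent]]:
    """Aggregate junction events into the model's isoform classes.

    Returns (per-class reports, unclassified events). Counts of all
    junctions mapping to a class are summed per condition before PSI/dPSI
    and the Fisher test; model classes with no supporting data are omitted
    with a warning.
    """
    events = events_from_counts(rows, condition_by_sample, control, treated)
    by_class: dict[str, list[JunctionEvent]] = {}
    unclassified: list[JunctionEvent] = []
    for e in events:
        label = model.label(e.donor_exon, e.acceptor_exon)
        if label is None:
            unclassified.append(e)
        else:
            by_class.setdefault(label, []).append(e)
    for label in set(model.classes.values()) - set(by_class):
        logger.warning("isoform class %r has no supporting junctions", label)
    reports: list[IsoformClassReport] = []
    for label in sorted(by_class):
        members = by_class[label]
        inc = {
            c: sum(e.inclusion_by_condition[c] for e in members)
            for c in (control, treated)
        }
        exc = {
            c: sum(e.exclusion_by_condition[c] for e in members)
            for c in (control, treated)
        }
        psi = {c: compute_psi(inc[c], exc[c]) for c in (control, treated)}
        dpsi, p = test_dpsi(inc[control], exc[control], inc[treated], exc[treated])
        reports.append(
            IsoformClassReport(
                label=label,
                junction_ids=tuple(e.junction_id for e in members),
                inclusion_by_condition=inc,
                exclusion_by_condition=exc,
                psi_by_condition=psi,
                dpsi=dpsi,
                p_value=p,
            )
        )
    return reports, unclassified


def events_to_frame(
    events: Sequence[JunctionEvent],
    control: str,
    treated: str,
    called: set[str] | None = None,
) -> pd.DataFrame:
    recs = []
    for e in events:
        recs.append(
            {
                "junction_id": e.junction_id,
                "donor_exon": e.donor_exon,
                "acceptor_exon": e.acceptor_exon,
                f"inclusion_{control}": e.inclusion_by_condition[control],
                f"exclusion_{control}": e.exclusion_by_condition[control],
                f"inclusion_{treated}": e.inclusion_by_condition[treated],
                f"exclusion_{treated}": e.exclusion_by_condition[treated],
                f"psi_{control}": e.psi_by_condition[control],
                f"psi_{treated}": e.psi_by_condition[treated],
                "dpsi": e.dpsi,
                "p_value": e.p_value,
                "called": (e.junction_id in called) if called is not None else None,
            }
        )
    cols = [
        "junction_id", "donor_exon", "acceptor_exon",
        f"inclusion_{control}", f"exclusion_{control}",
        f"inclusion_{treated}", f"exclusion_{treated}",
        f"psi_{control}", f"psi_{treated}", "dpsi", "p_value", "called",
    ]
    return pd.DataFrame(recs, columns=cols)


def class_reports_to_frame(
    reports: Sequence[IsoformClassReport], control: str, treated: str
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.label,
                "junctions": ";".join(r.junction_ids),
                f"inclusion_{control}": r.inclusion_by_condition[control],
                f"exclusion_{control}": r.exclusion_by_condition[control],
                f"inclusion_{treated}": r.inclusion_by_condition[treated],
                f"exclusion_{treated}": r.exclusion_by_condition[treated],
                f"psi_{control}": r.psi_by_condition[control],
                f"psi_{treated}": r.psi_by_condition[treated],
                "dpsi": r.dpsi,
                "p_value": r.p_value,
            }
            for r in reports
        ],
        columns=[
            "class", "junctions",
            f"inclusion_{control}", f"exclusion_{control}",
            f"inclusion_{treated}", f"exclusion_{treated}",
            f"psi_{control}", f"psi_{treated}", "dpsi", "p_value",
        ],
    )
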