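"""Readers and writers for the pipeline's tabular artifacts.

All inputs and outputs are plain tab-separated text: protein-groups tables
in the MaxQuant ``proteinGroups.txt`` dialect (configurable column map),
experiment-design tables, GMT gene-set files, junction-count tables, and
result tables. Every reader validates its schema strictly and never drops a
row silently; every writer produces a deterministic column order so that
repeated runs diff cleanly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import (
    ConfigError,
    DesignMismatchError,
    FormatError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: The three experimental arms of the labeling design. ``control`` is the
#: no-H2O2 labeling reaction used to catalogue endogenously biotinylated and
#: nonspecific background; ``minus_ir``/``plus_ir`` are the unirradiated and
#: irradiated bait arms.
ARMS = ("control", "minus_ir", "plus_ir")
EXPERIMENTAL_ARMS = ("minus_ir", "plus_ir")


class Sample(NamedTuple):
    sample_id: str
    arm: str
    replicate: int


@dataclass(frozen=True)
class ExperimentDesign:
    """Maps samples to arms (control / minus_ir / plus_ir) and replicates.

    Experimental arms must carry at least two replicates each (the evidence
    filter requires detection in >=2 replicates of an arm); a control arm may
    have a single replicate.
    """

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", tuple(Sample(*s) for s in self.samples)
        )
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate sample_id(s) in design: {dupes}")
        for s in self.samples:
            if s.arm not in ARMS:
                raise SchemaError(
                    f"unknown arm {s.arm!r} for sample {s.sample_id!r}; "
                    f"expected one of {ARMS}"
                )
        for arm in EXPERIMENTAL_ARMS:
            n = len(self.samples_in_arm(arm))
            if 0 < n < 2:
                raise SchemaError(
                    f"experimental arm {arm!r} has {n} replicate(s); >=2 required"
                )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    @property
    def arms(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.samples:
            if s.arm not in seen:
                seen.append(s.arm)
        return tuple(seen)

    @property
    def experimental_arms(self) -> tuple[str, ...]:
        return tuple(a for a in self.arms if a != "control")

    def samples_in_arm(self, arm: str) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if s.arm == arm)

    def arm_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.arm
        raise KeyError(sample_id)


@dataclass
class ProteinGroupRow:
    """One protein group with per-sample evidence and iBAQ intensities.

    ``ibaq_by_sample`` holds only *detected* samples: a literal 0 or missing
    value in the input is treated as not-detected and omitted from the map.
    """

    protein_ids: tuple[str, ...]
    gene_name: str
    unique_peptides_by_sample: dict[str, int]
    ibaq_by_sample: dict[str, float]
    is_decoy: bool = False
    is_flagged_contaminant: bool = False

    def __post_init__(self) -> None:
        self.protein_ids = tuple(str(p).strip() for p in self.protein_ids)
        if not self.protein_ids or not self.protein_ids[0]:
            raise SchemaError("protein_ids must be nonempty")
        for s, v in self.ibaq_by_sample.items():
            if v < 0:
                raise SchemaError(f"negative iBAQ for sample {s!r}")

    @property
    def protein_id(self) -> str:
        """Leading accession of the group; used as the row key downstream."""
        return self.protein_ids[0]

    def detected_in(self, sample_id: str) -> bool:
        return self.ibaq_by_sample.get(sample_id, 0.0) > 0


@dataclass
class JunctionCountRow:
    """Raw read counts supporting one splice junction, per sample."""

    junction_id: str
    donor_exon: str
    acceptor_exon: str
    counts_by_sample: dict[str, int]

    def __post_init__(self) -> None:
        for s, c in self.counts_by_sample.items():
            if c != int(c) or c < 0:
                raise SchemaError(
                    f"junction {self.junction_id!r}: count for sample {s!r} "
                    f"must be a nonnegative integer, got {c!r}"
                )
            self.counts_by_sample[s] = int(c)


@dataclass(frozen=True)
class MaxQuantDialect:
    """Column-name map for the protein-groups table.

    Defaults match MaxQuant's ``proteinGroups.txt``. Other upstream tools can
    be accommodated by overriding the prefixes/column names.
    """

    id_col: str = "Protein IDs"
    gene_col: str = "Gene names"
    ibaq_prefix: str = "iBAQ "
    unique_peptides_prefix: str = "Unique peptides "
    reverse_col: str = "Reverse"
    contaminant_col: str = "Potential contaminant"
    decoy_id_prefix: str = "REV__"
    contaminant_id_prefix: str = "CON__"


DEFAULT_DIALECT = MaxQuantDialect()


def read_design(path: str | Path) -> ExperimentDesign:
    """Read an experiment-design TSV with columns sample_id, arm, replicate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"design file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "arm", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"design file {path} missing column {col!r}")
    samples = tuple(
        Sample(str(r.sample_id).strip(), str(r.arm).strip(), int(r.replicate))
        for r in df.itertuples()
    )
    return ExperimentDesign(samples)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    df = pd.DataFrame(design.samples, columns=["sample_id", "arm", "replicate"])
    df.to_csv(path, sep="\t", index=False)


def _flag_truthy(value: object) -> bool:
    if value is None:
        return False
    s = str(value).strip()
    return s not in ("", "nan", "NaN", "0", "False", "false")


def read_protein_groups(
    path: str | Path,
    design: ExperimentDesign,
    dialect: MaxQuantDialect = DEFAULT_DIALECT,
) -> list[ProteinGroupRow]:
    """Parse a protein-groups TSV into rows keyed by the design's samples.

    Decoy ("REV__") and flagged-contaminant ("CON__" / marker column) status
    is parsed into boolean flags; iBAQ values of 0 or blank are recorded as
    not-detected. A per-sample iBAQ column naming a sample absent from the
    design raises :class:`DesignMismatchError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"protein-groups file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)

    if dialect.id_col not in df.columns:
        raise SchemaError(f"missing required column {dialect.id_col!r}")
    if dialect.gene_col not in df.columns:
        raise SchemaError(f"missing required column {dialect.gene_col!r}")
    for sid in design.sample_ids:
        for col in (
            f"{dialect.ibaq_prefix}{sid}",
            f"{dialect.unique_peptides_prefix}{sid}",
        ):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
    for col in df.columns:
        if col.startswith(dialect.ibaq_prefix):
            sid = col[len(dialect.ibaq_prefix) :]
            if sid and sid not in design.sample_ids:
                raise DesignMismatchError(
                    f"sample {sid!r} (column {col!r}) is absent from the design"
                )

    rows: list[ProteinGroupRow] = []
    for rec in df.to_dict(orient="records"):
        raw_ids = str(rec[dialect.id_col])
        protein_ids = tuple(
            p.strip() for p in raw_ids.split(";") if p.strip()
        )
        if not protein_ids:
            raise SchemaError(f"row with empty {dialect.id_col!r}")
        gene = rec.get(dialect.gene_col)
        gene_name = "" if gene is None or str(gene) == "nan" else str(gene).strip()

        is_decoy = any(p.startswith(dialect.decoy_id_prefix) for p in protein_ids)
        is_cont = any(
            p.startswith(dialect.contaminant_id_prefix) for p in protein_ids
        )
        if dialect.reverse_col in df.columns:
            is_decoy = is_decoy or _flag_truthy(rec[dialect.reverse_col])
        if dialect.contaminant_col in df.columns:
            is_cont = is_cont or _flag_truthy(rec[dialect.contaminant_col])

        peptides: dict[str, int] = {}
        ibaq: dict[str, float] = {}
        for sid in design.sample_ids:
            pep_raw = rec[f"{dialect.unique_peptides_prefix}{sid}"]
            try:
                peptides[sid] = int(float(pep_raw)) if str(pep_raw) != "nan" else 0
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"non-integer unique-peptide count {pep_raw!r} "
                    f"for sample {sid!r}"
                ) from exc
            ibaq_raw = rec[f"{dialect.ibaq_prefix}{sid}"]
            if ibaq_raw is None or str(ibaq_raw) in ("", "nan", "NaN"):
                continue
            val = float(ibaq_raw)
            if val < 0:
                raise SchemaError(f"negative iBAQ {val} for sample {sid!r}")
            if val > 0:
                ibaq[sid] = val
        rows.append(
            ProteinGroupRow(
                protein_ids=protein_ids,
                gene_name=gene_name,
                unique_peptides_by_sample=peptides,
                ibaq_by_sample=ibaq,
                is_decoy=is_decoy,
                is_flagged_contaminant=is_cont,
            )
        )
    logger.info("read %d protein groups from %s", len(rows), path)
    return rows


def write_protein_groups(
    rows: Sequence[ProteinGroupRow],
    design: ExperimentDesign,
    path: str | Path,
    dialect: MaxQuantDialect = DEFAULT_DIALECT,
) -> None:
    """Write rows back to the protein-groups dialect (round-trip safe)."""
    records = []
    for r in rows:
        rec: dict[str, object] = {
            dialect.id_col: ";".join(r.protein_ids),
            dialect.gene_col: r.gene_name,
            dialect.reverse_col: "+" if r.is_decoy else "",
            dialect.contaminant_col: "+" if r.is_flagged_contaminant else "",
        }
        for sid in design.sample_ids:
            rec[f"{dialect.unique_peptides_prefix}{sid}"] = (
                r.unique_peptides_by_sample.get(sid, 0)
            )
            rec[f"{dialect.ibaq_prefix}{sid}"] = repr(
                r.ibaq_by_sample[sid]
            ) if sid in r.ibaq_by_sample else 0
        records.append(rec)
    cols = [dialect.id_col, dialect.gene_col, dialect.reverse_col,
            dialect.contaminant_col]
    for sid in design.sample_ids:
        cols.append(f"{dialect.unique_peptides_prefix}{sid}")
    for sid in design.sample_ids:
        cols.append(f"{dialect.ibaq_prefix}{sid}")
    pd.DataFrame(records, columns=cols).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into a map of category name -> member set.

    Each line is ``name<TAB>description<TAB>member...``; duplicate members
    within a category are deduplicated; a repeated category name is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    f">=3 required (name, description, members...)"
                )
            name = fields[0].strip()
            if name in sets:
                raise FormatError(
                    f"{path}:{lineno}: duplicate category name {name!r}"
                )
            members = {m.strip() for m in fields[2:] if m.strip()}
            sets[name] = members
    return sets


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line gene/protein list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


def read_junction_counts(path: str | Path) -> list[JunctionCountRow]:
    """Read a junction-count TSV: junction_id, donor_exon, acceptor_exon,
    then one count column per sample. The (donor, acceptor) pair must be
    unique across rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"junction counts file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("junction_id", "donor_exon", "acceptor_exon")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"junction table missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in required]
    rows: list[JunctionCountRow] = []
    seen_pairs: set[tuple[str, str]] = set()
    for rec in df.to_dict(orient="records"):
        pair = (str(rec["donor_exon"]).strip(), str(rec["acceptor_exon"]).strip())
        if pair in seen_pairs:
            raise SchemaError(f"duplicate junction (donor, acceptor) pair {pair}")
        seen_pairs.add(pair)
        counts: dict[str, int] = {}
        for sid in sample_cols:
            val = rec[sid]
            fval = float(val)
            if fval < 0 or fval != int(fval):
                raise SchemaError(
                    f"junction {rec['junction_id']!r}: count {val!r} for "
                    f"sample {sid!r} is not a nonnegative integer"
                )
            counts[sid] = int(fval)
        rows.append(
            JunctionCountRow(
                junction_id=str(rec["junction_id"]).strip(),
                donor_exon=pair[0],
                acceptor_exon=pair[1],
                counts_by_sample=counts,
            )
        )
    return rows


def write_junction_counts(
    rows: Sequence[JunctionCountRow], path: str | Path
) -> None:
    sample_ids: list[str] = []
    for r in rows:
        for sid in r.counts_by_sample:
            if sid not in sample_ids:
                sample_ids.append(sid)
    records = [
        {
            "junction_id": r.junction_id,
            "donor_exon": r.donor_exon,
            "acceptor_exon": r.acceptor_exon,
            **{sid: r.counts_by_sample.get(sid, 0) for sid in sample_ids},
        }
        for r in rows
    ]
    cols = ["junction_id", "donor_exon", "acceptor_exon", *sample_ids]
    pd.DataFrame(records, columns=cols).to_csv(path, sep="\t", index=False)


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Read a sample -> condition map (TSV columns sample_id, condition)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"condition map not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise SchemaError(f"condition map missing column {col!r}")
    return {
        str(r.sample_id).strip(): str(r.condition).strip()
        for r in df.itertuples()
    }


def write_condition_map(conditions: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(conditions.items()), columns=["sample_id", "condition"]
    ).to_csv(path, sep="\t", index=False)


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write a result table as TSV with deterministic column order and fixed
    float precision; an optional config hash is recorded as a leading comment
    line so every artifact is traceable to the run that produced it."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
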