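"""Synthetic data with planted ground truth for the full pipeline.

The proteomics generator emulates the three-arm APEX2 labeling design
(control without H2O2, unirradiated -IR, irradiated +IR; three replicates
each): planted bait interactors appear only in the two experimental arms,
planted contaminants additionally appear in the control arm (the pipeline's
operational definition of background), and planted IR-responsive subsets
have their +IR intensities multiplied by a true fold change. Intensities
are log-normal; each (protein, sample) is detected independently with a
dropout probability; unique-peptide counts are Poisson-shifted and constant
across the samples of a protein.

The junction generator draws per-replicate inclusion counts from
Binomial(depth, PSI_true) for pairs of junctions competing for one donor
exon, so true PSI values are exactly recoverable in expectation.

Both generators are driven by a single integer seed through independent
named streams, so enlarging one table never perturbs the other.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io import ExperimentDesign, JunctionCountRow, ProteinGroupRow, Sample


def _stream(seed: int, name: str) -> np.random.Generator:
    """A named, independent RNG stream derived from one integer seed."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


@dataclass
class ProteomeSimConfig:
    """Parameters of the synthetic APEX2 protein-groups table.

    ``log10_mu``/``log10_sigma`` parameterize the protein-to-protein
    log-normal base-intensity distribution; ``replicate_log10_sigma`` is the
    within-protein measurement noise per sample (0.05 in log10 units is
    roughly a 12% CV, typical label-free repeatability). ``fc_up`` and
    ``fc_down`` are the true +IR/-IR fold changes of the planted
    IR-responsive subsets and default to 2.0 and 0.5, both beyond the
    pipeline's 1.5-fold classification threshold.
    """

    n_background: int = 1000
    n_contaminants: int = 50
    n_ir_up: int = 40
    n_ir_down: int = 40
    fc_up: float = 2.0
    fc_down: float = 0.5
    log10_mu: float = 6.0
    log10_sigma: float = 0.15
    replicate_log10_sigma: float = 0.05
    detect_prob: float = 0.95
    peptide_lambda: float = 6.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_contaminants", "n_ir_up", "n_ir_down"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.detect_prob <= 1:
            raise ConfigError(
                f"detect_prob must be in (0, 1], got {self.detect_prob}"
            )
        if self.fc_up <= 0 or self.fc_down <= 0:
            raise ConfigError("fold changes must be positive")
        if self.peptide_lambda < 1:
            raise ConfigError("peptide_lambda must be >= 1")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.log10_sigma < 0 or self.replicate_log10_sigma < 0:
            raise ConfigError("sigmas must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth: disjoint ID sets and true fold changes."""

    interactor_ids: frozenset[str]
    contaminant_ids: frozenset[str]
    ir_up_ids: frozenset[str]
    ir_down_ids: frozenset[str]
    true_fc_by_id: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [
            self.interactor_ids, self.contaminant_ids,
            self.ir_up_ids, self.ir_down_ids,
        ]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ConfigError("truth ID sets must be pairwise disjoint")

    @property
    def all_planted_interactors(self) -> frozenset[str]:
        """Everything the filter pipeline should retain (non-contaminant)."""
        return self.interactor_ids | self.ir_up_ids | self.ir_down_ids


def _design(n_replicates: int) -> ExperimentDesign:
    samples = [
        Sample(f"{arm}_r{i + 1}", arm, i + 1)
        for arm in ("control", "minus_ir", "plus_ir")
        for i in range(n_replicates)
    ]
    return ExperimentDesign(tuple(samples))


def generate_proteomics(
    config: ProteomeSimConfig,
) -> tuple[list[ProteinGroupRow], ExperimentDesign, SimTruth]:
    """Generate a protein-groups table, its design, and the planted truth.

    Same config and seed give byte-identical output.
    """
    rng = _stream(config.seed, "proteomics")
    design = _design(config.n_replicates)

    roles: list[tuple[str, str, float]] = []  # (protein_id, role, fold_change)
    roles += [(f"BG{i + 1:05d}", "interactor", 1.0) for i in range(config.n_background)]
    roles += [(f"UP{i + 1:05d}", "ir_up", config.fc_up) for i in range(config.n_ir_up)]
    roles += [(f"DN{i + 1:05d}", "ir_down", config.fc_down) for i in range(config.n_ir_down)]
    roles += [(f"CT{i + 1:05d}", "contaminant", 1.0) for i in range(config.n_contaminants)]

    rows: list[ProteinGroupRow] = []
    for pid, role, fc in roles:
        base = rng.normal(config.log10_mu, config.log10_sigma)
        n_pep = 1 + int(rng.poisson(config.peptide_lambda - 1))
        arms = (
            ("control", "minus_ir", "plus_ir")
            if role == "contaminant"
            else ("minus_ir", "plus_ir")
        )
        ibaq: dict[str, float] = {}
        peptides: dict[str, int] = {}
        for s in design.samples:
            if s.arm not in arms:
                peptides[s.sample_id] = 0
                continue
            detected = rng.random() < config.detect_prob
            if not detected:
                peptides[s.sample_id] = 0
                continue
            log10_fc = np.log10(fc) if s.arm == "plus_ir" else 0.0
            noise = rng.normal(0.0, config.replicate_log10_sigma)
            ibaq[s.sample_id] = float(10 ** (base + log10_fc + noise))
            peptides[s.sample_id] = n_pep
        rows.append(
            ProteinGroupRow(
                protein_ids=(pid,),
                gene_name=f"g{pid}",
                unique_peptides_by_sample=peptides,
                ibaq_by_sample=ibaq,
            )
        )

    truth = SimTruth(
        interactor_ids=frozenset(p for p, r, _ in roles if r == "interactor"),
        contaminant_ids=frozenset(p for p, r, _ in roles if r == "contaminant"),
        ir_up_ids=frozenset(p for p, r, _ in roles if r == "ir_up"),
        ir_down_ids=frozenset(p for p, r, _ in roles if r == "ir_down"),
        true_fc_by_id={p: fc for p, r, fc in roles if r in ("ir_up", "ir_down")},
    )
    return rows, design, truth


@dataclass
class JunctionEventSpec:
    """One simulated splicing event: two junctions competing for a donor.

    ``psi_by_condition`` gives the true inclusion fraction of the
    inclusion-acceptor junction per condition; the competing junction
    receives the complementary reads.
    """

    donor: str
    inclusion_acceptor: str
    exclusion_acceptor: str
    psi_by_condition: Mapping[str, float]

    @property
    def inclusion_id(self) -> str:
        return f"{self.donor}-{self.inclusion_acceptor}"

    @property
    def exclusion_id(self) -> str:
        return f"{self.donor}-{self.exclusion_acceptor}"


def default_ar_events() -> list[JunctionEventSpec]:
    """AR-locus events emulating loss of productive exon2/exon3 splicing:
    the exon2->exon3 junction loses inclusion to exon2->CE4 under knockdown,
    and the AR-V7-defining exon3->CE3 junction is reduced relative to
    exon3->E4."""
    return [
        JunctionEventSpec("E2", "E3", "CE4", {"control": 0.90, "knockdown": 0.55}),
        JunctionEventSpec("E3", "CE3", "E4", {"control": 0.50, "knockdown": 0.20}),
    ]


@dataclass
class JunctionSimConfig:
    """Parameters of the synthetic junction-count table."""

    events: Sequence[JunctionEventSpec] = field(default_factory=default_ar_events)
    depth: int = 200
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        donors_pairs = set()
        for e in self.events:
            for psi in e.psi_by_condition.values():
                if not 0 <= psi <= 1:
                    raise ConfigError(f"PSI {psi} outside [0, 1]")
            key = (e.donor, e.inclusion_acceptor, e.exclusion_acceptor)
            if key in donors_pairs:
                raise ConfigError(f"duplicate event {key}")
            donors_pairs.add(key)


def generate_junction_counts(
    config: JunctionSimConfig,
) -> tuple[list[JunctionCountRow], dict[str, dict[str, float]]]:
    """Generate junction counts and the true PSI map.

    Per event, condition and replicate, the inclusion junction's count is
    drawn Binomial(depth, PSI_true) and the competing junction receives
    depth - inclusion. Sample ids are ``<condition>_r<i>``. Returns
    (rows, {junction_id: {condition: true PSI}}).
    """
    rng = _stream(config.seed, "junctions")
    rows: list[JunctionCountRow] = []
    truth: dict[str, dict[str, float]] = {}
    for ev in config.events:
        inc_counts: dict[str, int] = {}
        exc_counts: dict[str, int] = {}
        for cond, psi in ev.psi_by_condition.items():
            for i in range(config.n_replicates):
                sid = f"{cond}_r{i + 1}"
                inc = int(rng.binomial(config.depth, psi))
                inc_counts[sid] = inc
                exc_counts[sid] = config.depth - inc
        rows.append(
            JunctionCountRow(
                junction_id=ev.inclusion_id,
                donor_exon=ev.donor,
                acceptor_exon=ev.inclusion_acceptor,
                counts_by_sample=inc_counts,
            )
        )
        rows.append(
            JunctionCountRow(
                junction_id=ev.exclusion_id,
                donor_exon=ev.donor,
                acceptor_exon=ev.exclusion_acceptor,
                counts_by_sample=exc_counts,
            )
        )
        truth[ev.inclusion_id] = dict(ev.psi_by_condition)
        truth[ev.exclusion_id] = {
            c: 1.0 - p for c, p in ev.psi_by_condition.items()
        }
    return rows, truth


@dataclass
class FluxRecovery:
    """How well classified flux calls recover the planted truth."""

    n_true_flux: int
    n_called: int
    n_true_positive: int
    sensitivity: float
    fdr: float
    contaminant_removal_rate: float | None = None


def evaluate_flux_recovery(
    truth: SimTruth,
    calls: Sequence,  # Sequence[FluxCall]; untyped to avoid a cycle
    removed_contaminant_ids: set[str] | None = None,
) -> FluxRecovery:
    """Score ir_up/ir_down calls against the planted flux sets.

    A call is a true positive when its direction matches the planted one;
    sensitivity is TP over all planted flux proteins and FDR is the fraction
    of ir_up/ir_down calls that are not direction-matched planted proteins.
    """
    up_called = {c.protein_id for c in calls if c.flux_class == "ir_up"}
    down_called = {c.protein_id for c in calls if c.flux_class == "ir_down"}
    tp = len(up_called & truth.ir_up_ids) + len(down_called & truth.ir_down_ids)
    n_called = len(up_called) + len(down_called)
    n_true = len(truth.ir_up_ids) + len(truth.ir_down_ids)
    removal = None
    if removed_contaminant_ids is not None and truth.contaminant_ids:
        removal = len(removed_contaminant_ids & truth.contaminant_ids) / len(
            truth.contaminant_ids
        )
    return FluxRecovery(
        n_true_flux=n_true,
        n_called=n_called,
        n_true_positive=tp,
        sensitivity=tp / n_true if n_true else float("nan"),
        fdr=1 - tp / n_called if n_called else 0.0,
        contaminant_removal_rate=removal,
    )


def condition_map_for(config: JunctionSimConfig) -> dict[str, str]:
    """Sample -> condition map implied by a junction sim config."""
    conditions: dict[str, str] = {}
    for ev in config.events:
        for cond in ev.psi_by_condition:
            for i in range(config.n_replicates):
                conditions[f"{cond}_r{i + 1}"] = cond
    return conditions
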