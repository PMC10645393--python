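import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from apexflux import ExperimentDesign, ProteinGroupRow, Sample


@pytest.fixture
def design3() -> ExperimentDesign:
    """Three arms x three replicates, the study's canonical layout."""
    return ExperimentDesign(
        tuple(
            Sample(f"{arm}_r{i}", arm, i)
            for arm in ("control", "minus_ir", "plus_ir")
            for i in (1, 2, 3)
        )
    )


def make_row(
    pid: str,
    ibaq: dict[str, float],
    peptides: int | dict[str, int] = 3,
    decoy: bool = False,
    contaminant: bool = False,
    gene: str | None = None,
) -> ProteinGroupRow:
    """Handy constructor: `peptides` as an int applies to detected samples."""
    if isinstance(peptides, int):
        peptides = {sid: peptides for sid in ibaq}
    return ProteinGroupRow(
        protein_ids=(pid,),
        gene_name=gene if gene is not None else f"g{pid}",
        unique_peptides_by_sample=dict(peptides),
        ibaq_by_sample={s: v for s, v in ibaq.items() if v > 0},
        is_decoy=decoy,
        is_flagged_contaminant=contaminant,
    )


@pytest.fixture
def row_factory():
    return make_row
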