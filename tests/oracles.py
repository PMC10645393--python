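"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and scipy's
hypergeometric machinery) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def hypergeom_tail_by_enumeration(n_universe: int, size_a: int, size_b: int,
                                  k: int) -> float:
    """P(|A & B| >= k) by exhaustively enumerating every possible draw of B
    from the universe, with A fixed. Feasible for universes up to ~12."""
    universe = range(n_universe)
    a = set(range(size_a))
    hits = total = 0
    for b in combinations(universe, size_b):
        total += 1
        if len(a & set(b)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_closed_form(n_universe: int, size_a: int, size_b: int,
                               k: int) -> float:
    """Same tail via the combinatorial sum, independent of scipy."""
    total = comb(n_universe, size_b)
    hits = sum(
        comb(size_a, i) * comb(n_universe - size_a, size_b - i)
        for i in range(k, min(size_a, size_b) + 1)
    )
    return hits / total


def naive_filter_pipeline(rows, design, min_unique=2, min_replicates=2,
                          min_control_detections=1):
    """Naive loop reference of the full filter pipeline.

    Returns {arm: set of retained protein ids} computed with plain loops
    and no shared helpers.
    """
    control = [s.sample_id for s in design.samples if s.arm == "control"]
    arms = {}
    for s in design.samples:
        if s.arm != "control":
            arms.setdefault(s.arm, []).append(s.sample_id)

    retained = {arm: set() for arm in arms}
    for row in rows:
        if row.is_decoy or row.is_flagged_contaminant:
            continue
        n_ctrl = 0
        for sid in control:
            ibaq = row.ibaq_by_sample.get(sid, 0.0)
            pep = row.unique_peptides_by_sample.get(sid, 0)
            if ibaq > 0 and pep >= 1:
                n_ctrl += 1
        if n_ctrl >= min_control_detections:
            continue
        best_pep = 0
        for pep in row.unique_peptides_by_sample.values():
            if pep > best_pep:
                best_pep = pep
        if best_pep < min_unique:
            continue
        for arm, sids in arms.items():
            n_det = 0
            for sid in sids:
                if row.ibaq_by_sample.get(sid, 0.0) > 0:
                    n_det += 1
            if n_det >= min_replicates:
                retained[arm].add(row.protein_ids[0])
    return retained
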