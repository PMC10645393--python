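"""IR-flux classification, set-overlap statistics, enrichment, and QC.

Flux to the interactome after ionizing radiation is classified from the
ratio of mean riBAQ between the +IR and -IR arms at a 1.5-fold threshold
(IR-Up / IR-Down); proteins detected in exactly one arm are reported
separately rather than folded into the fold-change classes, since their
ratio is undefined. Overlap between interactor lists is summarized as
percent of the union (with min-set and query-set denominators available for
comparison against conventions that differ) and, against a finite universe,
by an exact hypergeometric upper-tail test. Category enrichment over
user-supplied GMT sets uses the same hypergeometric tail with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .interactome import InteractorRecord, RibaqMatrix

logger = logging.getLogger(__name__)

FLUX_CLASSES = ("ir_up", "ir_down", "unchanged", "plus_ir_only", "minus_ir_only")


@dataclass
class FluxCall:
    """Per-protein -IR vs +IR fold change and class label.

    ``fold_change`` is mean(+IR)/mean(-IR) and is defined only when both
    arm means are present; arm-exclusive proteins carry ``None``.
    """

    protein_id: str
    gene_name: str
    mean_ribaq_minus_ir: float | None
    mean_ribaq_plus_ir: float | None
    fold_change: float | None
    flux_class: str


@dataclass
class SetOverlapResult:
    """Sizes, percent overlap, and (optionally) hypergeometric p for two sets."""

    size_a: int
    size_b: int
    size_intersection: int
    size_union: int
    percent_overlap: float
    denominator: str = "union"
    hypergeom_p: float | None = None
    universe_size: int | None = None

    @property
    def percent_rounded(self) -> int:
        """Percent overlap rounded to the nearest integer."""
        return int(round(self.percent_overlap))


@dataclass
class EnrichmentRow:
    """One category's hypergeometric enrichment result."""

    category: str
    k_overlap: int
    set_size: int
    category_size: int
    universe_size: int
    p_value: float
    q_value: float


def classify_flux(
    records: Sequence[InteractorRecord],
    fc_threshold: float = 1.5,
    inclusive: bool = True,
) -> list[FluxCall]:
    """Classify each interactor's IR flux at the given fold-change threshold.

    With the default inclusive rule, ir_up iff FC >= fc_threshold and
    ir_down iff FC <= 1/fc_threshold; ``inclusive=False`` uses strict
    inequalities. Proteins quantified in only one arm are labeled
    plus_ir_only / minus_ir_only.
    """
    if fc_threshold <= 1:
        raise ConfigError(f"fc_threshold must be > 1, got {fc_threshold}")
    calls: list[FluxCall] = []
    for rec in records:
        minus = rec.mean_ribaq_by_arm.get("minus_ir")
        plus = rec.mean_ribaq_by_arm.get("plus_ir")
        if minus is not None and plus is not None and minus > 0:
            fc = plus / minus
            if (fc >= fc_threshold) if inclusive else (fc > fc_threshold):
                label = "ir_up"
            elif (fc <= 1 / fc_threshold) if inclusive else (fc < 1 / fc_threshold):
                label = "ir_down"
            else:
                label = "unchanged"
        elif plus is not None and minus is None:
            fc, label = None, "plus_ir_only"
        elif minus is not None and plus is None:
            fc, label = None, "minus_ir_only"
        else:  # pragma: no cover - records always carry >=1 arm
            continue
        calls.append(
            FluxCall(
                protein_id=rec.protein_id,
                gene_name=rec.gene_name,
                mean_ribaq_minus_ir=minus,
                mean_ribaq_plus_ir=plus,
                fold_change=fc,
                flux_class=label,
            )
        )
    return calls


def flux_to_frame(calls: Sequence[FluxCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "gene_name": c.gene_name,
                "mean_ribaq_minus_ir": c.mean_ribaq_minus_ir,
                "mean_ribaq_plus_ir": c.mean_ribaq_plus_ir,
                "fold_change": c.fold_change,
                "flux_class": c.flux_class,
            }
            for c in calls
        ],
        columns=[
            "protein_id", "gene_name", "mean_ribaq_minus_ir",
            "mean_ribaq_plus_ir", "fold_change", "flux_class",
        ],
    )


def percent_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    denominator: str = "union",
) -> SetOverlapResult:
    """Percent overlap of two sets: 100 * |A n B| / denominator.

    The default denominator is the union; ``"min"`` (smaller set) and
    ``"query"`` (set A) are available for comparing against overlap figures
    computed under those conventions.
    """
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ConfigError("overlap of two empty sets is undefined")
    inter = a & b
    union = a | b
    denoms = {"union": len(union), "min": min(len(a), len(b)) or len(union),
              "query": len(a) or len(union)}
    if denominator not in denoms:
        raise ConfigError(
            f"denominator must be one of {sorted(denoms)}, got {denominator!r}"
        )
    return SetOverlapResult(
        size_a=len(a),
        size_b=len(b),
        size_intersection=len(inter),
        size_union=len(union),
        percent_overlap=100.0 * len(inter) / denoms[denominator],
        denominator=denominator,
    )


def hypergeom_overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
) -> SetOverlapResult:
    """Exact upper-tail hypergeometric test for the overlap of two sets drawn
    from a finite universe: p = P(X >= |A n B|) with X ~
    Hypergeom(N=|universe|, K=|A|, n=|B|)."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        stray = sorted((a | b) - u)[:5]
        raise ConfigError(f"sets must be contained in the universe; e.g. {stray}")
    inter, union = a & b, a | b
    p = float(hypergeom.sf(len(inter) - 1, len(u), len(a), len(b)))
    return SetOverlapResult(
        size_a=len(a),
        size_b=len(b),
        size_intersection=len(inter),
        size_union=len(union),
        percent_overlap=100.0 * len(inter) / len(union) if union else 0.0,
        hypergeom_p=min(1.0, p),
        universe_size=len(u),
    )


def overlap_to_frame(res: SetOverlapResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "size_a": res.size_a,
                "size_b": res.size_b,
                "size_intersection": res.size_intersection,
                "size_union": res.size_union,
                "denominator": res.denominator,
                "percent_overlap": res.percent_overlap,
                "percent_rounded": res.percent_rounded,
                "hypergeom_p": res.hypergeom_p,
                "universe_size": res.universe_size,
            }
        ]
    )


def enrich_categories(
    query_set: Iterable[str],
    gmt_map: Mapping[str, set[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment of a query set over GMT categories.

    Categories are intersected with the universe before testing; categories
    with zero overlap are reported with p = 1. Benjamini-Hochberg q-values
    are computed across all tested categories; rows are sorted by p-value,
    then category name.
    """
    u = set(universe)
    if not u:
        raise ConfigError("enrichment universe is empty")
    q = set(query_set)
    if not q <= u:
        raise ConfigError("query set must be contained in the universe")
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    names = sorted(gmt_map)
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for name in names:
        cat = set(gmt_map[name]) & u
        k = len(q & cat)
        p = float(hypergeom.sf(k - 1, len(u), len(cat), len(q)))
        p = min(1.0, p)
        pvals.append(p)
        rows.append(
            EnrichmentRow(
                category=name,
                k_overlap=k,
                set_size=len(q),
                category_size=len(cat),
                universe_size=len(u),
                p_value=p,
                q_value=np.nan,
            )
        )
    if rows:
        _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for row, qv in zip(rows, qvals):
            row.q_value = float(qv)
    rows.sort(key=lambda r: (r.p_value, r.category))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "k_overlap": r.k_overlap,
                "set_size": r.set_size,
                "category_size": r.category_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in rows
        ],
        columns=[
            "category", "k_overlap", "set_size", "category_size",
            "universe_size", "p_value", "q_value",
        ],
    )


@dataclass
class QCResult:
    """Sample-level QC: PCA coordinates and hierarchical-clustering order."""

    pca_coords: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dendrogram_order: list[str]


def qc_cluster(ribaq: RibaqMatrix, n_components: int | None = None) -> QCResult:
    """PCA and average-linkage clustering of samples from the riBAQ matrix.

    Values are log10-transformed after replacing missing entries with a
    floor of half the smallest observed positive riBAQ (a deterministic,
    data-adaptive pseudo-count). PCA signs follow the convention that each
    component's largest-magnitude loading is positive.
    """
    mat = ribaq.values
    if mat.shape[1] < 2:
        raise ConfigError("QC requires >=2 samples")
    positive = mat.values[np.isfinite(mat.values) & (mat.values > 0)]
    if positive.size == 0:
        raise ConfigError("riBAQ matrix has no present values")
    floor = positive.min() / 2.0
    X = np.log10(mat.fillna(floor).clip(lower=floor).values.T)
    k = n_components or min(X.shape[0] - 1, X.shape[1], 5)
    k = max(k, 1)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    coord_df = pd.DataFrame(
        coords,
        index=list(mat.columns),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    Z = linkage(X, method="average", metric="euclidean")
    order = [mat.columns[i] for i in leaves_list(Z)]
    return QCResult(
        pca_coords=coord_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dendrogram_order=list(order),
    )
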