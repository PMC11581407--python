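"""Overlap enrichment: fold-enrichment scores, Fisher exact tests, BY correction.

The enrichment score for a marker list is its overlap fraction — the share of
its detected members that are increased in the focal dataset — divided by the
whole-dataset background fraction (3.48% of transcripts, 8.58% of proteins in
the motivating analysis).  Significance is a one-sided Fisher exact test on the
2x2 table (in-list / out-of-list) x (increased / not), built over the detected
universe.  Cell-type enrichment against a marker database uses the same test
per term with Benjamini-Yekutieli correction across terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .de_table import DEDataset
from .marker_lists import MarkerList

logger = logging.getLogger(__name__)

SIDEDNESS = ("greater", "two_sided")


@dataclass(frozen=True)
class EnrichmentResult:
    """One marker list x one universe."""

    list_name: str
    modality: str
    n_raw: int
    n_list_detected: int
    n_overlap: int
    overlap_fraction: float
    background_fraction: float
    fold_enrichment: float
    fisher_p: float
    odds_ratio: float


@dataclass(frozen=True)
class CellTypeEnrichmentResult:
    term: str
    n_markers_detected: int
    n_overlap: int
    fold_enrichment: float
    p_raw: float
    p_adjusted: float
    rank: int


# ---------------------------------------------------------------------------
# Fisher exact test (log-space hypergeometric)
# ---------------------------------------------------------------------------

def _log_pmf(k: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    """log hypergeometric pmf: P(X = k) drawing n from N with K marked."""
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sidedness: str = "greater"
) -> tuple[float, float]:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Computed in log space (gammaln + logsumexp) so tables with totals in the
    tens of thousands do not underflow.  ``greater`` returns the upper
    hypergeometric tail P(X >= a) conditioning on both margins; ``two_sided``
    sums all tables with the same margins whose probability does not exceed
    the observed one (the standard convention).  Returns ``(p, odds_ratio)``
    with the sample odds ratio a*d / b*c (infinite when b*c = 0 and a*d > 0).
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"negative count in table {counts}")
    if not all(float(x).is_integer() for x in counts):
        raise ValueError(f"non-integer count in table {counts}")
    a, b, c, d = (int(x) for x in counts)
    N = a + b + c + d
    if N < 1:
        raise ValueError("table total must be >= 1")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")

    K = a + b  # row-1 margin
    n = a + c  # col-1 margin
    lo, hi = max(0, n - (N - K)), min(K, n)

    if lo == hi:  # degenerate margin: a single attainable table
        p = 1.0
    else:
        support = np.arange(lo, hi + 1)
        logp = _log_pmf(support, K, n, N)
        if sidedness == "greater":
            sel = support >= a
        else:
            # two-sided: tables no more probable than observed (small tolerance
            # for log-space round-off, as in the classical implementations)
            sel = logp <= logp[a - lo] + 1e-7
        p = float(np.exp(logsumexp(logp[sel])))
        p = min(p, 1.0)

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return p, odds


# ---------------------------------------------------------------------------
# list-level enrichment
# ---------------------------------------------------------------------------

def overlap_enrichment(
    lst: MarkerList,
    universe: DEDataset,
    direction: str = "increased",
    background: float | None = None,
    sidedness: str = "greater",
) -> EnrichmentResult:
    """Score one finalized marker list against one universe.

    ``background`` defaults to the universe's own fraction of features with
    the given direction; pass a constant (e.g. 0.0348) to reproduce published
    folds exactly regardless of how direction calls were derived.
    """
    if lst.modality != universe.modality:
        raise ValueError(
            f"list {lst.name!r} finalized for {lst.modality}, universe is {universe.modality}"
        )
    n_det = lst.n_detected
    if n_det == 0:
        if lst.n_raw:
            logger.warning("%s: no members detected in universe", lst.name)
        bg = background if background is not None else _safe_background(universe, direction)
        return EnrichmentResult(
            list_name=lst.name, modality=universe.modality, n_raw=lst.n_raw,
            n_list_detected=0, n_overlap=0, overlap_fraction=0.0,
            background_fraction=bg, fold_enrichment=0.0, fisher_p=1.0,
            odds_ratio=0.0,
        )
    if not lst.detected_members <= universe.detected_keys():
        raise ValueError(f"list {lst.name!r} was not finalized against this universe")

    hits = universe.direction_keys(direction)
    n_overlap = len(lst.detected_members & hits)
    overlap_fraction = n_overlap / n_det

    bg = background if background is not None else universe.n_direction(direction) / universe.n_detected
    fold = overlap_fraction / bg if bg > 0 else math.inf if overlap_fraction > 0 else 0.0

    n_dir = universe.n_direction(direction)
    N = universe.n_detected
    a = n_overlap
    b = n_det - a
    c = n_dir - a
    d = N - n_det - c
    p, odds = fisher_exact_2x2(a, b, c, d, sidedness=sidedness)
    return EnrichmentResult(
        list_name=lst.name, modality=universe.modality, n_raw=lst.n_raw,
        n_list_detected=n_det, n_overlap=n_overlap,
        overlap_fraction=overlap_fraction, background_fraction=bg,
        fold_enrichment=fold, fisher_p=p, odds_ratio=odds,
    )


def _safe_background(universe: DEDataset, direction: str) -> float:
    return (
        universe.n_direction(direction) / universe.n_detected
        if universe.n_detected
        else 0.0
    )


def run_comparisons(
    lists,
    transcript_universe: DEDataset,
    protein_universe: DEDataset | None = None,
    idmap=None,
    direction: str = "increased",
    background: float | None = None,
    protein_background: float | None = None,
    sidedness: str = "greater",
):
    """Run the full battery: every list against the transcript universe and,
    when a protein universe and id map are given, against the protein universe.

    Thin wrapper over :class:`listenrich.model.MarkerOverlapModel`; returns its
    fitted results object.  No cross-list multiple-testing adjustment is
    applied — each list is reported with its own Fisher p.
    """
    from .model import MarkerOverlapModel

    model = MarkerOverlapModel(
        lists,
        transcript_universe,
        protein_universe=protein_universe,
        idmap=idmap,
        direction=direction,
        background=background,
        protein_background=protein_background,
        sidedness=sidedness,
    )
    return model.fit()


# ---------------------------------------------------------------------------
# multiple testing & cell-type enrichment
# ---------------------------------------------------------------------------

def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (original order, clipped to 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def celltype_enrich(
    gene_list,
    db: dict,
    universe,
    alpha: float = 0.05,
    top_n: int = 20,
    sidedness: str = "greater",
) -> list[CellTypeEnrichmentResult]:
    """Single-gene-list enrichment against a cell-type marker database.

    Per term: overlap of the query with the term's detection-filtered markers,
    fold enrichment relative to the term's share of the universe, Fisher p,
    then BY adjustment across all terms.  Terms with adjusted p < ``alpha``
    are ranked by fold enrichment descending (ties: smaller adjusted p, then
    lexical term order) and truncated to ``top_n``.
    """
    if not db:
        raise ValueError("empty cell-type marker database")
    universe = set(universe)
    query = set(gene_list)
    stray = query - universe
    if stray:
        logger.warning("%d query genes outside the universe were dropped", len(stray))
        query -= stray
    if not query:
        raise ValueError("empty gene list after detection filtering")

    N = len(universe)
    n_query = len(query)
    rows = []
    for term in sorted(db):
        markers = set(db[term]) & universe
        m = len(markers)
        a = len(query & markers)
        b = n_query - a
        c = m - a
        d = N - n_query - c
        p, _ = fisher_exact_2x2(a, b, c, d, sidedness=sidedness)
        fold = (a / n_query) / (m / N) if m else 0.0
        rows.append((term, m, a, fold, p))

    padj = by_adjust([r[4] for r in rows])
    kept = [
        (term, m, a, fold, p, q)
        for (term, m, a, fold, p), q in zip(rows, padj)
        if q < alpha
    ]
    kept.sort(key=lambda r: (-r[3], r[5], r[0]))
    return [
        CellTypeEnrichmentResult(
            term=term, n_markers_detected=m, n_overlap=a,
            fold_enrichment=fold, p_raw=p, p_adjusted=q, rank=i + 1,
        )
        for i, (term, m, a, fold, p, q) in enumerate(kept[:top_n])
    ]
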