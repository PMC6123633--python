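"""Multiple-testing control, hypergeometric enrichment and presence screening.

Benjamini-Hochberg adjustment is delegated to statsmodels; Storey's q-value
(pi0 estimated on a lambda grid with cubic-spline smoothing) is implemented
here.  Term enrichment uses the upper-tail hypergeometric probability
P(X >= k) with BH correction across terms; the presence/absence screen calls
a panel gene present in a taxon when any similarity hit reaches the E-value
threshold (E <= 1e-5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io_formats import HitRecord
from .tree_ops import PresenceAbsenceMatrix

__all__ = [
    "TestResult",
    "EnrichmentCounts",
    "bh_adjust",
    "storey_qvalue",
    "hypergeometric_test",
    "enrich_terms",
    "build_presence_absence",
]

ALPHA = 0.05


@dataclass
class TestResult:
    """Per-unit (family or term) test outcome with adjusted values."""

    unit_id: str
    p: float
    adjusted_p: float
    q: float
    significant: bool


@dataclass
class EnrichmentCounts:
    """2x2 counts for one term: k of K foreground, n of N background."""

    term: str
    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.K, self.n)
            and self.n <= self.N
            and self.K <= self.N
        )
        if not ok:
            raise InputError(f"impossible enrichment counts for {self.term!r}: {self}")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def storey_qvalue(
    p_values: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
) -> tuple[list[float], float]:
    """Storey q-values and the estimated null proportion pi0.

    pi0 is estimated as #{p > lambda} / (m (1 - lambda)) over the grid
    (default 0.05..0.95 step 0.05), smoothed by a natural cubic spline and
    evaluated at the largest lambda, clamped to (0, 1].  q_i = pi0 * BH_i with
    cumulative-minimum enforcement.  Degenerate grids fall back to pi0 = 1
    with a warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InputError("at least one p-value required")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    grid = np.asarray(
        lambda_grid if lambda_grid is not None else np.arange(0.05, 0.96, 0.05)
    )
    m = p.size

    pi0 = 1.0
    usable = (grid >= 0) & (grid < 1)
    grid = np.unique(grid[usable])
    if grid.size >= 4:
        est = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
        try:
            spline = CubicSpline(grid, est, bc_type="natural")
            pi0 = float(spline(grid.max()))
        except Exception:
            warnings.warn("pi0 spline failed; falling back to pi0 = 1")
            pi0 = 1.0
    elif grid.size >= 1:
        pi0 = float(((p > grid.max()).sum()) / (m * (1.0 - grid.max())))
    else:
        warnings.warn("degenerate lambda grid; falling back to pi0 = 1")
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    bh = np.asarray(bh_adjust(p))
    order = np.argsort(p, kind="stable")[::-1]  # largest p first
    q = np.minimum(pi0 * bh, 1.0)
    running = np.minimum.accumulate(q[order])
    out = np.empty_like(q)
    out[order] = running
    return list(out), pi0


def hypergeometric_test(counts: EnrichmentCounts) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeom(N, n, K)."""
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.n, counts.K))


def enrichment_counts(
    foreground: set[str],
    background: set[str],
    annotations: Mapping[str, Iterable[str]],
) -> dict[str, EnrichmentCounts]:
    """Per-term 2x2 counts for every term annotated to >=1 foreground gene."""
    if not foreground <= background:
        raise InputError("foreground must be a subset of the background")
    term_fg: dict[str, int] = {}
    term_bg: dict[str, int] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in foreground:
                term_fg[term] = term_fg.get(term, 0) + 1
    return {
        t: EnrichmentCounts(t, term_fg[t], len(foreground), term_bg[t], len(background))
        for t in sorted(term_fg)
    }


def enrich_terms(
    foreground: set[str],
    background: set[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = ALPHA,
) -> list[TestResult]:
    """Hypergeometric over-representation of terms in the foreground gene set.

    One upper-tail test per term annotated to >=1 foreground gene; BH
    adjustment across terms (terms are the multiple-testing units); ties in p
    broken stably by term id.  Returns results sorted by (p, term).
    """
    if not foreground <= background:
        raise InputError("foreground must be a subset of the background")
    if not foreground:
        return []
    by_term = enrichment_counts(foreground, background, annotations)
    terms = list(by_term)
    counts = [by_term[t] for t in terms]
    p_vals = [hypergeometric_test(c) for c in counts]
    adj = bh_adjust(p_vals)
    q_vals, _pi0 = storey_qvalue(p_vals) if len(p_vals) > 1 else ([min(p_vals[0], 1.0)], 1.0)
    results = [
        TestResult(t, p, a, q, a <= alpha)
        for t, p, a, q in zip(terms, p_vals, adj, q_vals)
    ]
    results.sort(key=lambda r: (r.p, r.unit_id))
    return results


def enrichment_table(results: Sequence[TestResult], counts: Mapping[str, EnrichmentCounts] | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "term": r.unit_id,
            "p": r.p,
            "bh_p": r.adjusted_p,
            "q": r.q,
            "significant": r.significant,
        }
        if counts and r.unit_id in counts:
            c = counts[r.unit_id]
            row.update({"k": c.k, "K": c.K, "n": c.n, "N": c.N})
        rows.append(row)
    return pd.DataFrame(rows)


def build_presence_absence(
    hits: Sequence[HitRecord],
    gene_panel: Sequence[str],
    taxa: Sequence[str],
    taxon_of_subject: Mapping[str, str] | None = None,
    evalue_max: float = 1e-5,
) -> PresenceAbsenceMatrix:
    """Presence/absence of panel genes per taxon from similarity hits.

    A cell is present iff at least one hit of the panel gene against that
    taxon's proteins reaches ``evalue_max`` (boundary inclusive).  Subjects
    map to taxa through ``taxon_of_subject``; if omitted, the subject id
    itself must be a taxon name.
    """
    df = pd.DataFrame(False, index=list(taxa), columns=list(gene_panel), dtype=bool)
    taxa_set = set(taxa)
    panel_set = set(gene_panel)
    for hit in hits:
        if hit.query_id not in panel_set or hit.evalue > evalue_max:
            continue
        taxon = (
            taxon_of_subject.get(hit.subject_id)
            if taxon_of_subject is not None
            else hit.subject_id
        )
        if taxon in taxa_set:
            df.loc[taxon, hit.query_id] = True
    return PresenceAbsenceMatrix(df)
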