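"""End-to-end orchestration of the positive-selection screen.

The screen funnels homologous families through composition and alignment
filters, the tree-congruence paralog filter (multi-copy families only),
codon back-translation, branch-site model fits (two-step: branch lengths from
M0, then null/alternative), the likelihood-ratio test, and FDR control over
all tested families.  Families are independent work units processed in input
order with seeds derived from the run seed, so a rerun of the same inputs and
configuration is byte-identical.

Two side analyses share the same machinery: pairwise NG86 dN/dS of duplicated
gene pairs from collinear blocks, and the gene-panel presence/absence screen
with Dollo gain/loss reconstruction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import family_filter as ff
from .codon_evolution import (
    FitOptions,
    backtranslate,
    fit_model,
    likelihood_ratio_test,
    ng86_pairwise,
)
from .errors import BacktranslationError, InputError, NumericError
from .io_formats import CollinearPair, HitRecord, SequenceRecord
from .stats_testing import bh_adjust, build_presence_absence, storey_qvalue
from .tree_ops import (
    CongruenceClass,
    GainLossSummary,
    Phylogeny,
    classify_congruence,
    dollo_gain_loss,
)

logger = logging.getLogger("symscreen")

__all__ = [
    "ScreenConfig",
    "FamilyOutcome",
    "ScreenReport",
    "run_selection_screen",
    "run_duplication_dnds",
    "run_toolkit_screen",
    "summarize_report",
    "flagged_protein_percentage",
]


@dataclass
class ScreenConfig:
    """Declarative thresholds and fit settings for the selection screen."""

    min_family_size: int = 4
    min_protein_len: int = 30
    min_alignment_cols: int = 60
    min_alignment_rows: int = 4
    max_gap_fraction: float = 0.5
    alpha: float = 0.05
    evalue_max: float = 1e-5
    fdr_method: str = "qvalue"  # qvalue | bh
    foreground: str = "stem"  # stem | all_focal
    freq_model: str = "F3x4"
    n_starts: int = 1
    branch_mode: str = "scale"  # M0 branch-length protocol for the screen
    fix_kappa: bool = True  # hold kappa at the M0 estimate in both bs models
    seed: int = 0


# stages of the funnel
STAGE_INPUT = "input"
STAGE_COMPOSITION = "excluded_composition"
STAGE_ALIGNMENT = "excluded_alignment"
STAGE_PARALOG = "excluded_paralog"
STAGE_FIT_FAILED = "fit_failed"
STAGE_TESTED = "tested"


@dataclass
class FamilyOutcome:
    """Per-family record of the screen: where it stopped and test results."""

    family_id: str
    stage: str
    reason: str = ""
    copy_class: str = ""
    congruence: str = ""
    loglik_null: float = float("nan")
    loglik_alt: float = float("nan")
    lrt_stat: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    selected: bool = False

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class ScreenReport:
    outcomes: list[FamilyOutcome]
    funnel: dict[str, int]
    pi0: float
    config: ScreenConfig

    @property
    def selected_families(self) -> list[str]:
        return [o.family_id for o in self.outcomes if o.selected]

    @property
    def tested_families(self) -> list[str]:
        return [o.family_id for o in self.outcomes if o.stage == STAGE_TESTED]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([o.__dict__ for o in self.outcomes])

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False, float_format="%.6g")

    def to_jsonl(self) -> str:
        return "\n".join(o.to_json() for o in self.outcomes) + "\n"


def _mark_foreground(
    tree: Phylogeny, focal_tips: Sequence[str], mode: str
) -> Phylogeny:
    """Copy of ``tree`` with foreground marks on the focal stem (+ clade)."""
    marked = tree.copy()
    for node in marked.postorder():
        node.foreground = False
    mrca = marked.mrca(focal_tips)
    if mrca.parent is None:
        raise InputError("focal clade spans the root; stem branch undefined")
    mrca.foreground = True
    if mode == "all_focal":
        stack = list(mrca.children)
        while stack:
            node = stack.pop()
            node.foreground = True
            stack.extend(node.children)
    elif mode != "stem":
        raise InputError(f"unknown foreground mode {mode!r}")
    return marked


def run_selection_screen(inputs, config: ScreenConfig | None = None) -> ScreenReport:
    """Run the full screen over ``inputs``.

    ``inputs`` provides ``families`` (HomologFamily), ``protein_alignments``
    (family id -> aligned SequenceRecords), ``cds`` (sequence id -> CDS),
    ``family_trees`` (family id -> sequence-labelled Phylogeny),
    ``reference_tree``, ``genus_map`` and ``focal_genus`` — the shape emitted
    by :func:`symscreen.synthetic_data.simulate_screen_dataset`.

    Every exclusion is recorded with its reason; family-level failures never
    abort the run.  FDR control (Storey q-values by default, BH optionally)
    runs over all tested families; selection is called at q <= alpha.
    """
    config = config or ScreenConfig()
    genus_map = inputs.genus_map
    focal_genus = inputs.focal_genus
    outcomes: list[FamilyOutcome] = []
    funnel = {
        STAGE_INPUT: len(inputs.families),
        STAGE_COMPOSITION: 0,
        STAGE_ALIGNMENT: 0,
        STAGE_PARALOG: 0,
        STAGE_FIT_FAILED: 0,
        STAGE_TESTED: 0,
    }

    tested: list[FamilyOutcome] = []
    for idx, family in enumerate(inputs.families):
        out = FamilyOutcome(family.family_id, STAGE_TESTED)
        outcomes.append(out)

        decision = ff.family_passes_composition(
            family, genus_map, focal_genus, min_size=config.min_family_size
        )
        if not decision.passed:
            out.stage, out.reason = STAGE_COMPOSITION, decision.reason
            funnel[STAGE_COMPOSITION] += 1
            continue

        alignment = inputs.protein_alignments[family.family_id]
        keep = ff.gappy_column_keep_indices(alignment, config.max_gap_fraction)
        trimmed = [
            SequenceRecord(
                r.id,
                "".join(r.residues[c] for c in keep),
                kind=r.kind,
                taxon=r.taxon,
            )
            for r in alignment
        ]
        decision = ff.alignment_passes_length(
            trimmed,
            family.family_id,
            min_cols=config.min_alignment_cols,
            min_rows=config.min_alignment_rows,
        )
        if not decision.passed:
            out.stage, out.reason = STAGE_ALIGNMENT, decision.reason
            funnel[STAGE_ALIGNMENT] += 1
            continue

        out.copy_class = ff.classify_copy_number(family)
        tree = inputs.family_trees[family.family_id]
        if out.copy_class == ff.MULTI_COPY:
            try:
                label = classify_congruence(
                    tree,
                    inputs.reference_tree,
                    genus_map,
                    focal_genus,
                    taxon_of=family.taxon_of(),
                )
            except InputError as exc:
                out.stage, out.reason = STAGE_PARALOG, str(exc)
                funnel[STAGE_PARALOG] += 1
                continue
            out.congruence = label
            if label != CongruenceClass.CONGRUENT_COORTHOLOG:
                out.stage, out.reason = STAGE_PARALOG, label
                funnel[STAGE_PARALOG] += 1
                continue

        try:
            codon_aln = backtranslate(alignment, inputs.cds)
            if keep and len(keep) < len(alignment[0].residues):
                rows = {
                    sid: "".join(
                        seq[3 * c : 3 * c + 3] for c in keep
                    )
                    for sid, seq in codon_aln.rows.items()
                }
                codon_aln = type(codon_aln)(rows, codon_aln.code)
            taxon_of = family.taxon_of()
            focal_tips = [
                sid for sid, taxon in family.members
                if genus_map[taxon] == focal_genus
            ]
            marked = _mark_foreground(tree, focal_tips, config.foreground)

            fam_seed = (config.seed * 1000003 + idx) % (2**31 - 1)
            fit_opts = FitOptions(
                n_starts=config.n_starts,
                seed=fam_seed,
                freq_model=config.freq_model,
                branch_mode=config.branch_mode,
                fix_kappa=config.fix_kappa,
            )
            m0 = fit_model(codon_aln, marked, "M0", fit_opts)
            null = fit_model(
                codon_aln, marked, "bs_null", fit_opts,
                branch_lengths=m0.branch_lengths, init=m0.params,
            )
            alt = fit_model(
                codon_aln, marked, "bs_alt", fit_opts,
                branch_lengths=m0.branch_lengths, init=null.params,
            )
            lrt = likelihood_ratio_test(null, alt)
        except (BacktranslationError, InputError, NumericError) as exc:
            out.stage, out.reason = STAGE_FIT_FAILED, str(exc)
            funnel[STAGE_FIT_FAILED] += 1
            logger.warning("family %s: %s", family.family_id, exc)
            continue
        if lrt.skipped:
            out.stage, out.reason = STAGE_FIT_FAILED, "unconverged"
            funnel[STAGE_FIT_FAILED] += 1
            continue

        out.loglik_null = null.loglik
        out.loglik_alt = alt.loglik
        out.lrt_stat = lrt.stat
        out.p = lrt.p
        funnel[STAGE_TESTED] += 1
        tested.append(out)

    pi0 = 1.0
    if tested:
        p_values = [o.p for o in tested]
        if config.fdr_method == "qvalue":
            q_values, pi0 = storey_qvalue(p_values)
        elif config.fdr_method == "bh":
            q_values = bh_adjust(p_values)
        else:
            raise InputError(f"unknown fdr_method {config.fdr_method!r}")
        for o, q in zip(tested, q_values):
            o.q = float(q)
            o.selected = bool(o.q <= config.alpha)
    return ScreenReport(outcomes, funnel, pi0, config)


# ---------------------------------------------------------------------------
# Duplicated-gene-pair dN/dS
# ---------------------------------------------------------------------------


@dataclass
class DuplicationSummary:
    """Distribution summary of pairwise dN/dS over collinear-block gene pairs."""

    n_pairs: int
    n_computed: int
    n_skipped_missing: int
    n_excluded: int  # undefined or saturated omega (identical pairs included)
    mean: float
    median: float
    fraction_gt1: float
    histogram: list[int] = field(default_factory=list)  # 12 bins over [0, 6]
    bin_edges: list[float] = field(default_factory=list)
    omegas: list[float] = field(default_factory=list)


def run_duplication_dnds(
    pairs: Sequence[CollinearPair], cds: Mapping[str, str]
) -> DuplicationSummary:
    """NG86 omega for each homologous gene pair inside collinear blocks.

    Pairs with a missing gene are skipped with a log entry; pairs whose omega
    is undefined (dS = 0, identical sequences) or saturated are excluded from
    the distribution summary but counted.  The histogram covers omega in
    [0, 6], the conventional display range.
    """
    omegas: list[float] = []
    skipped = excluded = 0
    for pair in pairs:
        if pair.gene_a not in cds or pair.gene_b not in cds:
            skipped += 1
            logger.warning("pair %s/%s: missing CDS", pair.gene_a, pair.gene_b)
            continue
        a, b = cds[pair.gene_a], cds[pair.gene_b]
        if len(a) != len(b):
            skipped += 1
            logger.warning("pair %s/%s: unequal CDS lengths", pair.gene_a, pair.gene_b)
            continue
        rates = ng86_pairwise(a, b)
        if rates.omega is None:
            excluded += 1
            continue
        omegas.append(rates.omega)
    edges = [0.5 * i for i in range(13)]
    hist, _ = np.histogram(omegas, bins=edges) if omegas else (np.zeros(12, int), None)
    n_comp = len(omegas)
    return DuplicationSummary(
        n_pairs=len(pairs),
        n_computed=n_comp,
        n_skipped_missing=skipped,
        n_excluded=excluded,
        mean=float(np.mean(omegas)) if omegas else float("nan"),
        median=float(np.median(omegas)) if omegas else float("nan"),
        fraction_gt1=float(np.mean([w > 1 for w in omegas])) if omegas else float("nan"),
        histogram=[int(h) for h in hist],
        bin_edges=edges,
        omegas=omegas,
    )


# ---------------------------------------------------------------------------
# Gene-panel (toolkit) screen + Dollo
# ---------------------------------------------------------------------------


@dataclass
class ToolkitReport:
    matrix_df: pd.DataFrame  # taxa x panel genes, bool
    recovered_per_taxon: dict[str, int]
    gain_loss: GainLossSummary


def run_toolkit_screen(
    hits: Sequence[HitRecord],
    panel: Sequence[str],
    taxa: Sequence[str],
    tree: Phylogeny,
    evalue_max: float = 1e-5,
) -> ToolkitReport:
    """Presence/absence of panel genes per taxon, then Dollo gain/loss.

    A gene is recovered in a taxon when any hit reaches ``evalue_max``.  The
    (rooted) tree is pruned to the screened taxa for the reconstruction.
    """
    missing = set(taxa) - set(tree.tip_labels)
    if missing:
        raise InputError(f"taxa absent from tree: {sorted(missing)}")
    matrix = build_presence_absence(hits, panel, taxa, evalue_max=evalue_max)
    counts = {t: int(matrix.df.loc[t].sum()) for t in taxa}
    sub = tree.prune_to(taxa) if set(tree.tip_labels) != set(taxa) else tree
    if not sub.is_rooted:
        raise InputError("Dollo reconstruction requires a rooted tree")
    # all-absent genes are skipped (and counted) by the reconstruction
    summary = dollo_gain_loss(sub, matrix)
    return ToolkitReport(matrix.df, counts, summary)


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------


def summarize_report(report: ScreenReport) -> tuple[str, dict[str, pd.DataFrame]]:
    """Stage-funnel text summary plus tidy tables (for TSV export)."""
    funnel_rows = [
        ("input families", report.funnel[STAGE_INPUT]),
        ("failed composition", report.funnel[STAGE_COMPOSITION]),
        ("failed alignment filters", report.funnel[STAGE_ALIGNMENT]),
        ("excluded as paralogous", report.funnel[STAGE_PARALOG]),
        ("fit failures", report.funnel[STAGE_FIT_FAILED]),
        ("tested (LRT + FDR)", report.funnel[STAGE_TESTED]),
        ("selected at q <= alpha", len(report.selected_families)),
    ]
    lines = ["selection screen funnel:"]
    for label, count in funnel_rows:
        lines.append(f"  {label:28s} {count:6d}")
    lines.append(f"  estimated pi0{'':15s} {report.pi0:8.3f}")
    tables = {
        "families": report.to_frame(),
        "funnel": pd.DataFrame(funnel_rows, columns=["stage", "count"]),
        "selected": report.to_frame().query("selected"),
    }
    return "\n".join(lines), tables


def flagged_protein_percentage(n_flagged: int, n_total: int, ndigits: int = 1) -> float:
    """Percentage of proteins in flagged families, rounded as printed."""
    if n_total <= 0 or n_flagged < 0 or n_flagged > n_total:
        raise InputError("need 0 <= n_flagged <= n_total with n_total > 0")
    return round(100.0 * n_flagged / n_total, ndigits)
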