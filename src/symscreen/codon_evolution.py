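"""Codon-model numerics: back-translation, NG86, branch-site likelihood, LRT.

The selection test follows the classical branch-site formulation: a codon
substitution process of GY94 type (single-nucleotide exchanges, transition
bias kappa, equilibrium codon frequencies pi, selection intensity omega on
nonsynonymous changes), with four site classes

    class 0   omega0 on all branches           weight p0
    class 1   omega = 1 on all branches        weight p1
    class 2a  omega0 background / omega2 fg    weight (1-p0-p1) p0/(p0+p1)
    class 2b  1 background / omega2 foreground weight (1-p0-p1) p1/(p0+p1)

The null model fixes omega2 = 1; the alternative frees omega2 >= 1 on the
designated foreground branches.  Twice the log-likelihood difference is
referred to a chi-square(1) distribution (optionally the 50:50 {0, chi2(1)}
boundary mixture).

Branch lengths are expected substitutions per codon under the background
class mixture: a single scale factor, computed from the class weights and the
background omegas, converts the raw generator to that unit so branch lengths
are comparable across classes and models.

Likelihoods are computed by Felsenstein pruning over site-pattern-compressed
alignments, with transition matrices from the symmetric eigendecomposition of
the pi-similarity-transformed generator (the model is time-reversible, so the
spectrum is real) and per-node rescaling to avoid underflow.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2
from Bio.Data import CodonTable

from .errors import BacktranslationError, InputError, NumericError
from .io_formats import SequenceRecord
from .tree_ops import Phylogeny

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "CodonAlignment",
    "PairwiseRates",
    "BranchSiteParams",
    "FitResult",
    "FitOptions",
    "LRTResult",
    "backtranslate",
    "ng86_pairwise",
    "build_rate_matrix",
    "transition_matrix",
    "f3x4_frequencies",
    "equal_frequencies",
    "branch_site_loglik",
    "fit_model",
    "likelihood_ratio_test",
]

NUCLEOTIDES = "ACGT"
_PURINES = frozenset("AG")


# ---------------------------------------------------------------------------
# Genetic code and codon-pair structure
# ---------------------------------------------------------------------------


class GeneticCode:
    """Codon -> amino-acid map with an ordered list of sense codons."""

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.stop_codons = frozenset(table.stop_codons)
        self.forward = dict(table.forward_table)
        self.sense_codons: tuple[str, ...] = tuple(
            c
            for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
            if c not in self.stop_codons
        )
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        self.n = len(self.sense_codons)

    def translate(self, codon: str) -> str:
        if codon in self.stop_codons:
            return "*"
        try:
            return self.forward[codon]
        except KeyError:
            return "X"

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


STANDARD_CODE = GeneticCode(1)


def _pair_structure(code: GeneticCode):
    """Masks over sense-codon pairs differing at exactly one position."""
    n = code.n
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            transition[i, j] = (ci[k] in _PURINES) == (cj[k] in _PURINES)
            nonsyn[i, j] = code.translate(ci) != code.translate(cj)
    return single, transition, nonsyn


_SINGLE, _TRANSITION, _NONSYN = _pair_structure(STANDARD_CODE)


# ---------------------------------------------------------------------------
# Codon alignments and back-translation
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """In-frame aligned CDS matrix keyed by sequence id.

    Gaps occur only as whole codons ('---'); no ungapped row contains an
    internal stop codon.
    """

    rows: dict[str, str]
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise InputError(f"unequal row lengths: {sorted(lengths)}")
        if lengths and lengths.pop() % 3 != 0:
            raise InputError("alignment length not divisible by 3")
        for seq_id, seq in self.rows.items():
            for pos in range(0, len(seq), 3):
                codon = seq[pos : pos + 3]
                if "-" in codon and codon != "---":
                    raise InputError(
                        f"{seq_id}: partial-codon gap at codon {pos // 3}"
                    )
                if self.code.is_stop(codon):
                    raise InputError(
                        f"{seq_id}: internal stop codon at codon {pos // 3}"
                    )

    @property
    def n_sites(self) -> int:
        if not self.rows:
            return 0
        return len(next(iter(self.rows.values()))) // 3

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def codon_strings(self, seq_id: str) -> list[str]:
        seq = self.rows[seq_id]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def index_matrix(self, order: Sequence[str]) -> np.ndarray:
        """(len(order), n_sites) matrix of sense-codon indices; -1 = gap/ambiguous."""
        out = np.full((len(order), self.n_sites), -1, dtype=np.int64)
        for r, seq_id in enumerate(order):
            for s, codon in enumerate(self.codon_strings(seq_id)):
                out[r, s] = self.code.codon_index.get(codon, -1)
        return out


def backtranslate(
    protein_alignment: Sequence[SequenceRecord],
    cds_by_id: Mapping[str, str],
    code: GeneticCode = STANDARD_CODE,
) -> CodonAlignment:
    """Thread each CDS through its aligned protein, codon by codon.

    The ungapped translation of the CDS must match the aligned protein's
    residues exactly ('X' in the protein matches any residue); a terminal stop
    codon on the CDS is stripped.  Any mismatch or internal stop is an error
    naming the sequence and position.
    """
    rows: dict[str, str] = {}
    for rec in protein_alignment:
        if rec.id not in cds_by_id:
            raise BacktranslationError(f"{rec.id}: no CDS provided")
        cds = cds_by_id[rec.id].upper()
        if len(cds) % 3 != 0:
            raise BacktranslationError(f"{rec.id}: CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and code.is_stop(codons[-1]):
            codons = codons[:-1]
        for pos, codon in enumerate(codons):
            if code.is_stop(codon):
                raise BacktranslationError(
                    f"{rec.id}: internal stop codon at residue {pos}"
                )
        protein = rec.residues.upper()
        ungapped = [c for c in protein if c not in "-."]
        if len(codons) != len(ungapped):
            raise BacktranslationError(
                f"{rec.id}: CDS encodes {len(codons)} residues, protein has "
                f"{len(ungapped)}"
            )
        for pos, (codon, aa) in enumerate(zip(codons, ungapped)):
            if code.is_stop(codon):
                raise BacktranslationError(
                    f"{rec.id}: internal stop codon at residue {pos}"
                )
            trans = code.translate(codon)
            if aa not in ("X", trans):
                raise BacktranslationError(
                    f"{rec.id}: residue {pos} is {aa!r} but CDS encodes {trans!r}"
                )
        it = iter(codons)
        rows[rec.id] = "".join(
            "---" if c in "-." else next(it) for c in protein
        )
    return CodonAlignment(rows, code)


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS
# ---------------------------------------------------------------------------


@dataclass
class PairwiseRates:
    """Nei-Gojobori (1986) pairwise rates with Jukes-Cantor correction."""

    dN: float
    dS: float
    omega: float | None
    S_sites: float
    N_sites: float
    saturated: bool
    n_codons: int


def _codon_site_counts(codon: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    At each position the 3 possible changes are classified; changes to stop
    codons are excluded and the position's one site is split by the fraction
    synonymous among the remaining changes, so counts always total 3.
    """
    s = 0.0
    aa = code.translate(codon)
    for k in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[k]:
                continue
            alt = codon[:k] + nt + codon[k + 1 :]
            if code.is_stop(alt):
                continue
            valid += 1
            if code.translate(alt) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _pathway_counts(
    ca: str, cb: str, code: GeneticCode
) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over minimal pathways.

    All orderings of the differing positions are weighted equally; pathways
    through stop codons are excluded.  If every pathway is blocked by a stop,
    all pathways are used (stop steps count as nonsynonymous).
    """
    diffs = [k for k in range(3) if ca[k] != cb[k]]

    def walk(allow_stops: bool) -> list[tuple[int, int]]:
        results = []
        for order in itertools.permutations(diffs):
            cur = ca
            syn = non = 0
            ok = True
            for k in order:
                nxt = cur[:k] + cb[k] + cur[k + 1 :]
                if code.is_stop(nxt) and not allow_stops:
                    ok = False
                    break
                if code.translate(cur) == code.translate(nxt):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            if ok:
                results.append((syn, non))
        return results

    paths = walk(allow_stops=False)
    if not paths:
        paths = walk(allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    if p <= 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def ng86_pairwise(
    cds_a: str, cds_b: str, code: GeneticCode = STANDARD_CODE
) -> PairwiseRates:
    """NG86 estimator of dN and dS between two equal-length in-frame CDS.

    Codon columns where either sequence is gapped, ambiguous, or a stop are
    skipped.  Site counts are averaged over the two sequences; multi-hit
    codons are averaged over all equally weighted minimal pathways.  Distances
    use the Jukes-Cantor correction; either class with proportion >= 3/4 is
    flagged saturated.  omega is defined only when dS > 0 and unsaturated.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise InputError("sequences must have equal length")
    if len(cds_a) % 3 != 0:
        raise InputError("sequence length not divisible by 3")

    S = N = Sd = Nd = 0.0
    n_comp = 0
    for pos in range(0, len(cds_a), 3):
        ca, cb = cds_a[pos : pos + 3], cds_b[pos : pos + 3]
        if ca not in code.codon_index or cb not in code.codon_index:
            continue
        n_comp += 1
        sa, na = _codon_site_counts(ca, code)
        sb, nb = _codon_site_counts(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        if ca != cb:
            sd, nd = _pathway_counts(ca, cb, code)
            Sd += sd
            Nd += nd
    if n_comp == 0:
        raise InputError("no comparable codon columns")

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    dS, sat_s = _jukes_cantor(ps)
    dN, sat_n = _jukes_cantor(pn)
    saturated = sat_s or sat_n
    omega = dN / dS if (not saturated and dS > 0.0) else None
    return PairwiseRates(dN, dS, omega, S, N, saturated, n_comp)


# ---------------------------------------------------------------------------
# Rate matrices, frequencies, transition probabilities
# ---------------------------------------------------------------------------


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """GY94-type 61x61 generator (unscaled).

    Off-diagonal rate i->j is 0 unless the codons differ at exactly one
    position and j is a sense codon; otherwise pi_j, times kappa for a
    transition and omega for a nonsynonymous change.  Diagonal = -row sum.
    """
    if code is not STANDARD_CODE:
        single, transition, nonsyn = _pair_structure(code)
    else:
        single, transition, nonsyn = _SINGLE, _TRANSITION, _NONSYN
    q = np.where(single, np.broadcast_to(pi, (code.n, code.n)), 0.0).astype(float)
    q[transition] *= kappa
    q[nonsyn] *= omega
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def substitution_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time: -sum_i pi_i q_ii."""
    return float(-(pi * np.diag(q)).sum())


class _Propagator:
    """Eigendecomposition of one generator for repeated matrix exponentials."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        sym = q * d[:, None] / d[None, :]
        sym = (sym + sym.T) / 2.0  # symmetrise roundoff
        lam, u = np.linalg.eigh(sym)
        self.lam = lam
        self.left = u / d[:, None]  # D^-1 U
        self.right = u.T * d[None, :]  # U^T D

    def matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t_b) for a vector of times; shape (len(t), 61, 61)."""
        t = np.asarray(t, dtype=float)
        n = self.lam.shape[0]
        e = np.exp(np.multiply.outer(t, self.lam))
        scaled = (self.left[None, :, :] * e[:, None, :]).reshape(-1, n)
        p = (scaled @ self.right).reshape(t.shape[0], n, n)
        np.maximum(p, 0.0, out=p)
        return p


def transition_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    t: float,
    scale: float | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> np.ndarray:
    """P(t) = exp(Q t / scale); scale defaults to the generator's own rate."""
    q = build_rate_matrix(kappa, omega, pi, code)
    if scale is None:
        scale = substitution_rate(q, pi)
    return _Propagator(q, pi).matrices(np.array([t / scale]))[0]


def f3x4_frequencies(
    aln: CodonAlignment, floor: float = 1e-6
) -> np.ndarray:
    """F3x4 codon frequencies: position-specific nucleotide frequencies."""
    counts = np.full((3, 4), floor)
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq_id in aln.ids:
        for codon in aln.codon_strings(seq_id):
            if codon == "---":
                continue
            for k, nt in enumerate(codon):
                if nt in nuc_index:
                    counts[k, nuc_index[nt]] += 1
    pos = counts / counts.sum(axis=1, keepdims=True)
    code = aln.code
    pi = np.array(
        [
            pos[0, nuc_index[c[0]]] * pos[1, nuc_index[c[1]]] * pos[2, nuc_index[c[2]]]
            for c in code.sense_codons
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def f1x4_frequencies(aln: CodonAlignment, floor: float = 1e-6) -> np.ndarray:
    """F1x4 codon frequencies: one overall nucleotide distribution."""
    counts = np.full(4, floor)
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq_id in aln.ids:
        for nt in aln.rows[seq_id]:
            if nt in nuc_index:
                counts[nuc_index[nt]] += 1
    nucf = counts / counts.sum()
    code = aln.code
    pi = np.array(
        [nucf[nuc_index[c[0]]] * nucf[nuc_index[c[1]]] * nucf[nuc_index[c[2]]] for c in code.sense_codons]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def equal_frequencies(code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    return np.full(code.n, 1.0 / code.n)


# ---------------------------------------------------------------------------
# Branch-site parameters
# ---------------------------------------------------------------------------


@dataclass
class BranchSiteParams:
    """Parameters of the branch-site mixture (M0 stores its omega in omega0)."""

    kappa: float
    omega0: float
    p0: float = 1.0
    p1: float = 0.0
    omega2: float = 1.0
    pi: np.ndarray = field(default_factory=lambda: equal_frequencies())

    @property
    def p2a(self) -> float:
        rest = 1.0 - self.p0 - self.p1
        denom = self.p0 + self.p1
        return rest * self.p0 / denom if denom > 0 else 0.0

    @property
    def p2b(self) -> float:
        rest = 1.0 - self.p0 - self.p1
        denom = self.p0 + self.p1
        return rest * self.p1 / denom if denom > 0 else 0.0

    def site_classes(self, model: str) -> tuple[np.ndarray, list[float], list[float]]:
        """(weights, background omegas, foreground omegas) per class."""
        if model == "M0":
            return np.array([1.0]), [self.omega0], [self.omega0]
        weights = np.array([self.p0, self.p1, self.p2a, self.p2b])
        bg = [self.omega0, 1.0, self.omega0, 1.0]
        fg = [self.omega0, 1.0, self.omega2, self.omega2]
        return weights, bg, fg


MODELS = ("M0", "bs_null", "bs_alt")


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


class TreeIndex:
    """Flattened postorder representation of a phylogeny for the likelihood.

    Branch i is the branch above postorder node i; the root's entry is unused.
    """

    def __init__(self, tree: Phylogeny):
        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root_index = len(self.nodes) - 1
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.is_tip = np.array([n.is_leaf for n in self.nodes])
        self.tip_label = {i: n.label for i, n in enumerate(self.nodes) if n.is_leaf}
        self.lengths = np.array([max(n.length, 0.0) for n in self.nodes])
        self.foreground = np.array([bool(n.foreground) for n in self.nodes])
        if self.foreground[-1]:
            raise InputError("the root has no branch to mark as foreground")
        # does any branch in the subtree below node i (inclusive of its own
        # branch) carry a foreground mark?
        self.subtree_has_fg = np.zeros(len(self.nodes), dtype=bool)
        for i, kids in enumerate(self.children):
            flag = self.foreground[i]
            for k in kids:
                flag = flag or self.subtree_has_fg[k]
            self.subtree_has_fg[i] = flag
        self.internal_postorder = [
            i for i in range(len(self.nodes)) if not self.is_tip[i]
        ]
        self.fg_internal_postorder = [
            i for i in self.internal_postorder if self.subtree_has_fg[i]
        ]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _tip_partials(
    patterns: np.ndarray, tidx: TreeIndex, aln_ids: Iterable[str], n_states: int
) -> list[np.ndarray | None]:
    """Per-node tip partial-likelihood matrices (None for internal nodes).

    A gap or ambiguous codon contributes an all-ones column.  Computed once
    per alignment/tree pairing and reused across every likelihood evaluation.
    """
    row_of: dict[str, int] = {}
    tip_labels = [tidx.tip_label[i] for i in sorted(tidx.tip_label)]
    missing = set(tip_labels) - set(aln_ids)
    if missing:
        raise InputError(f"alignment missing rows for tips: {sorted(missing)}")
    for r, label in enumerate(tip_labels):
        row_of[label] = r
    n_pat = patterns.shape[1]
    out: list[np.ndarray | None] = [None] * tidx.n_nodes
    for node, label in tidx.tip_label.items():
        states = patterns[row_of[label]]
        part = np.zeros((n_states, n_pat))
        gap = states < 0
        part[states[~gap], np.nonzero(~gap)[0]] = 1.0
        part[:, gap] = 1.0
        out[node] = part
    return out


def _mixture_loglik(
    tip_parts: Sequence[np.ndarray | None],
    counts: np.ndarray,
    tidx: TreeIndex,
    lengths: np.ndarray,
    params: BranchSiteParams,
    model: str,
    pass1_cache: dict | None = None,
) -> float:
    """Log-likelihood of the site-class mixture by stacked pruning.

    The background classes (0 and 1) are pruned together as a batched stack;
    the foreground classes (2a/2b) reuse every partial from subtrees that
    contain no foreground branch, so only the path from the foreground
    branches to the root is recomputed with the omega2 matrices.
    """
    weights, bg, fg = params.site_classes(model)
    pi = params.pi
    if model == "M0":
        obg = [bg[0]]
    else:
        obg = [params.omega0, 1.0]
    fg_classes = model != "M0" and bool(tidx.foreground.any())
    w2 = params.omega2

    qs: dict[float, np.ndarray] = {}
    rates: dict[float, float] = {}
    for w in sorted(set(obg) | ({w2} if fg_classes else set())):
        qs[w] = build_rate_matrix(params.kappa, w, pi)
        rates[w] = substitution_rate(qs[w], pi)
    _props: dict[float, _Propagator] = {}

    def props(w: float) -> _Propagator:
        if w not in _props:
            _props[w] = _Propagator(qs[w], pi)
        return _props[w]

    scale = float(sum(wt * rates[w] for wt, w in zip(weights, bg)))
    if not np.isfinite(scale) or scale <= 0:
        raise NumericError("degenerate substitution-rate scale")
    times = lengths / scale

    root = tidx.n_nodes - 1
    internal = tidx.internal_postorder
    log = math.log

    def full_prune(pm: np.ndarray) -> tuple[list, list]:
        """Post-order partials under one omega's matrices on every branch."""
        parts: list = list(tip_parts)
        scales = [0.0] * tidx.n_nodes
        for node in internal:
            children = tidx.children[node]
            c0 = children[0]
            acc = pm[c0] @ parts[c0]
            ls = scales[c0]
            for c in children[1:]:
                acc *= pm[c] @ parts[c]
                ls += scales[c]
            mx = float(acc.max())
            if not np.isfinite(mx) or mx <= 0.0:
                raise NumericError(f"vanishing partial likelihood at node {node}")
            acc /= mx
            parts[node] = acc
            scales[node] = ls + log(mx)
        return parts, scales

    # background pass: one pruning per background omega (classes 0 and 1;
    # all of M0).  Depends only on (kappa, obg, times), so within one fit it
    # is reused while omega2 alone moves (the omega2 profile stage).
    cache_key = (params.kappa, tuple(obg), times.tobytes())
    cached = pass1_cache.get(cache_key) if pass1_cache is not None else None
    if cached is not None:
        pmats, class_parts, class_scales = cached
    else:
        pmats = {w: props(w).matrices(times) for w in obg}
        class_parts, class_scales = [], []
        for w in obg:
            parts, scales = full_prune(pmats[w])
            class_parts.append(parts)
            class_scales.append(scales)
        if pass1_cache is not None:
            if len(pass1_cache) > 4:
                pass1_cache.clear()
            pass1_cache[cache_key] = (pmats, class_parts, class_scales)

    liks = [pi @ class_parts[k][root] for k in range(len(obg))]
    offsets = [class_scales[k][root] for k in range(len(obg))]

    # foreground pass: classes 2a/2b reuse every partial from subtrees with
    # no foreground branch; only nodes above a marked branch are recomputed
    if fg_classes:
        w2_mats = {
            int(b): props(w2).matrices(times[[b]])[0]
            for b in np.nonzero(tidx.foreground)[0]
        }
        for k, w in enumerate(obg):
            pm = pmats[w]
            base_parts, base_scales = class_parts[k], class_scales[k]
            over_p: dict[int, np.ndarray] = {}
            over_s: dict[int, float] = {}
            for node in tidx.fg_internal_postorder:
                acc = None
                ls = 0.0
                for c in tidx.children[node]:
                    cp = over_p.get(c)
                    if cp is None:
                        cp = base_parts[c]
                        ls += base_scales[c]
                    else:
                        ls += over_s[c]
                    m = w2_mats.get(c)
                    prod = (m if m is not None else pm[c]) @ cp
                    acc = prod if acc is None else acc * prod
                mx = float(acc.max())
                if not np.isfinite(mx) or mx <= 0.0:
                    raise NumericError(
                        f"vanishing partial likelihood at node {node}"
                    )
                acc /= mx
                over_p[node] = acc
                over_s[node] = ls + log(mx)
            if root in over_p:
                liks.append(pi @ over_p[root])
                offsets.append(over_s[root])
            else:  # foreground marks present but above no internal node
                liks.append(liks[k])
                offsets.append(offsets[k])
    elif model != "M0":
        liks.extend(liks)
        offsets.extend(offsets)

    if model == "M0":
        site = weights[0] * liks[0]
        offset = offsets[0]
    else:
        offset = max(offsets)
        site = sum(
            float(weights[k]) * liks[k] * math.exp(offsets[k] - offset)
            for k in range(4)
        )
    if np.any(site <= 0.0) or not np.all(np.isfinite(site)):
        bad = int(np.nonzero((site <= 0) | ~np.isfinite(site))[0][0])
        raise NumericError(f"non-finite site likelihood at pattern {bad}")
    return float((counts * (np.log(site) + offset)).sum())


def branch_site_loglik(
    aln: CodonAlignment,
    tree: Phylogeny,
    params: BranchSiteParams,
    model: str = "bs_alt",
) -> float:
    """Log-likelihood of a codon alignment under the branch-site mixture.

    ``model='M0'`` evaluates the single-ratio model (omega taken from
    ``params.omega0``); the branch-site models use foreground marks on
    ``tree``.  Branch lengths are read from the tree, in expected
    substitutions per codon under the background mixture.
    """
    if model not in MODELS:
        raise InputError(f"unknown model {model!r}")
    tidx = TreeIndex(tree)
    tip_order = [tidx.tip_label[i] for i in sorted(tidx.tip_label)]
    missing = set(tip_order) - set(aln.ids)
    if missing:
        raise InputError(f"alignment missing rows for tips: {sorted(missing)}")
    codes = aln.index_matrix(tip_order)
    patterns, counts = _compress_patterns(codes)
    tip_parts = _tip_partials(patterns, tidx, aln.ids, params.pi.shape[0])
    return _mixture_loglik(tip_parts, counts, tidx, tidx.lengths, params, model)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Optimiser settings for :func:`fit_model`."""

    n_starts: int = 3
    seed: int = 0
    freq_model: str = "F3x4"  # F3x4 | F1x4 | equal
    branch_mode: str = "free"  # free | scale (M0 only)
    fix_kappa: bool = False  # bs models: hold kappa at the init (M0) estimate
    tol: float = 1e-8
    max_iter: int = 500
    explore_iter: int = 15
    omega2_max: float = 999.0
    perturb: float = 0.4


@dataclass
class FitResult:
    model: str
    loglik: float
    params: BranchSiteParams
    converged: bool
    n_restarts_used: int
    branch_lengths: np.ndarray  # postorder branch lengths (root entry 0)

    def fitted_tree(self, tree: Phylogeny) -> Phylogeny:
        """Copy of ``tree`` carrying the fitted branch lengths."""
        new = tree.copy()
        for node, t in zip(new.postorder(), self.branch_lengths):
            node.length = float(t)
        return new


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1.0 - p))


_OMEGA2_EPS = 1e-4


def _frequencies(aln: CodonAlignment, options: FitOptions) -> np.ndarray:
    if options.freq_model == "F3x4":
        return f3x4_frequencies(aln)
    if options.freq_model == "F1x4":
        return f1x4_frequencies(aln)
    if options.freq_model == "equal":
        return equal_frequencies(aln.code)
    raise InputError(f"unknown frequency model {options.freq_model!r}")


def fit_model(
    aln: CodonAlignment,
    tree: Phylogeny,
    model: str,
    options: FitOptions | None = None,
    branch_lengths: np.ndarray | None = None,
    init: BranchSiteParams | None = None,
) -> FitResult:
    """Maximise the log-likelihood of one model.

    M0 frees kappa, omega and branch lengths (all branches by default;
    ``branch_mode='scale'`` keeps the input tree's relative lengths and frees
    a single multiplier).  The branch-site models free kappa, p0, p1, omega0
    (and omega2 in the alternative) with branch lengths fixed — pass the M0
    estimates via ``branch_lengths`` (two-step protocol) or the input tree's
    lengths are used as-is.  Deterministic multi-start: one informed start
    plus short exploratory random restarts; the best start is refined to full
    tolerance.
    """
    options = options or FitOptions()
    if model not in MODELS:
        raise InputError(f"unknown model {model!r}")
    tidx = TreeIndex(tree)
    if model != "M0" and not tidx.foreground.any():
        raise InputError("branch-site models require a foreground branch mark")
    tip_order = [tidx.tip_label[i] for i in sorted(tidx.tip_label)]
    missing = set(tip_order) - set(aln.ids)
    if missing:
        raise InputError(f"alignment missing rows for tips: {sorted(missing)}")
    codes = aln.index_matrix(tip_order)
    patterns, counts = _compress_patterns(codes)
    pi = init.pi if init is not None else _frequencies(aln, options)
    tip_parts = _tip_partials(patterns, tidx, aln.ids, pi.shape[0])

    base_lengths = (
        np.asarray(branch_lengths, dtype=float)
        if branch_lengths is not None
        else tidx.lengths.copy()
    )
    base_lengths = np.maximum(base_lengths, 1e-6)
    base_lengths[-1] = 0.0  # root has no branch
    n_branch = tidx.n_nodes - 1

    pass1_cache: dict = {}

    def loglik(params: BranchSiteParams, lengths: np.ndarray) -> float:
        return _mixture_loglik(
            tip_parts, counts, tidx, lengths, params, model, pass1_cache
        )

    # -- parameter packing ---------------------------------------------------
    if model == "M0":
        if options.branch_mode == "free":
            n_t = n_branch
        elif options.branch_mode == "scale":
            n_t = 1
        else:
            raise InputError(f"unknown branch_mode {options.branch_mode!r}")

        def unpack(theta: np.ndarray) -> tuple[BranchSiteParams, np.ndarray]:
            kappa = math.exp(theta[0])
            omega = math.exp(theta[1])
            params = BranchSiteParams(kappa=kappa, omega0=omega, pi=pi)
            if options.branch_mode == "free":
                lengths = np.append(np.exp(theta[2:]), 0.0)
            else:
                lengths = base_lengths * math.exp(theta[2])
            return params, lengths

        k0 = init.kappa if init else 2.0
        w0 = init.omega0 if init else 0.4
        theta0 = np.concatenate(
            [
                [math.log(k0), math.log(w0)],
                np.log(base_lengths[:-1]) if options.branch_mode == "free" else [0.0],
            ]
        )
        bounds = [(-4.6, 6.9), (-11.5, 6.9)] + [(-13.8, 3.9)] * n_t
    else:
        if options.fix_kappa and init is None:
            raise InputError("fix_kappa requires an init carrying the kappa estimate")
        fixed_kappa = init.kappa if (options.fix_kappa and init) else None
        off = 0 if fixed_kappa is not None else 1  # theta offset of p0's logit

        def unpack(theta: np.ndarray) -> tuple[BranchSiteParams, np.ndarray]:
            kappa = fixed_kappa if fixed_kappa is not None else math.exp(theta[0])
            u, v = _sigmoid(theta[off]), _sigmoid(theta[off + 1])
            p0 = u
            p1 = (1.0 - u) * v
            omega0 = _sigmoid(theta[off + 2])
            if model == "bs_alt":
                omega2 = 1.0 - _OMEGA2_EPS + math.exp(theta[off + 3])
            else:
                omega2 = 1.0
            params = BranchSiteParams(
                kappa=kappa, omega0=omega0, p0=p0, p1=p1, omega2=omega2, pi=pi
            )
            return params, base_lengths

        if init is not None:
            k0, w0 = init.kappa, min(init.omega0, 0.95)
            p0_init = min(max(init.p0, 0.05), 0.9)
            p1_init = min(max(init.p1, 0.02), 1.0 - p0_init - 0.02)
        else:
            k0, w0, p0_init, p1_init = 2.0, 0.3, 0.6, 0.2
        theta0 = [] if fixed_kappa is not None else [math.log(k0)]
        theta0 += [
            _logit(p0_init),
            _logit(p1_init / (1.0 - p0_init)),
            _logit(w0),
        ]
        bounds = ([] if fixed_kappa is not None else [(-4.6, 6.9)]) + [
            (-12.0, 12.0),
            (-12.0, 12.0),
            (-12.0, 12.0),
        ]
        if model == "bs_alt":
            # omega2 sits on a boundary at 1; the profile stage below keeps
            # the optimiser from being trapped there
            theta0.append(math.log(2.0 - 1.0 + _OMEGA2_EPS))
            bounds.append((-20.0, math.log(options.omega2_max - 1.0)))
        theta0 = np.array(theta0)

    def objective(theta: np.ndarray) -> float:
        params, lengths = unpack(theta)
        try:
            return -loglik(params, lengths)
        except NumericError:
            return 1e12

    # -- multistart ----------------------------------------------------------
    rng = np.random.default_rng(options.seed)
    starts = [theta0]
    if model == "bs_alt":
        # omega2 sits on a boundary at 1, where the optimiser is easily
        # trapped.  Profile the likelihood over omega2 alone (cheap: the
        # background pruning pass is cached) and start from the best value.
        profile = theta0.copy()
        best_w2_obj, best_w2_x = objective(profile), profile[-1]
        for w2 in (4.0, 8.0, 16.0, 64.0):
            profile[-1] = math.log(w2 - 1.0 + _OMEGA2_EPS)
            obj = objective(profile)
            if obj < best_w2_obj:
                best_w2_obj, best_w2_x = obj, profile[-1]
        profiled = theta0.copy()
        profiled[-1] = best_w2_x
        starts = [profiled]
    for _ in range(max(options.n_starts - len(starts), 0)):
        starts.append(theta0 + rng.normal(0.0, options.perturb, theta0.shape[0]))

    if len(starts) == 1:
        start = starts[0]
    else:
        explored = []
        for th in starts:
            res = minimize(
                objective,
                th,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.explore_iter, "ftol": 1e-6},
            )
            explored.append(res)
        start = min(explored, key=lambda r: r.fun).x
    final = minimize(
        objective,
        start,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": options.max_iter,
            "ftol": options.tol,
            "gtol": 1e-7,
        },
    )
    params, lengths = unpack(final.x)
    return FitResult(
        model=model,
        loglik=-float(final.fun),
        params=params,
        converged=bool(final.success),
        n_restarts_used=len(starts),
        branch_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass
class LRTResult:
    stat: float
    p: float
    skipped: bool = False


def likelihood_ratio_test(
    fit_null: FitResult, fit_alt: FitResult, mixture: bool = False
) -> LRTResult:
    """LRT of positive selection: 2(l_alt - l_null) against chi-square(1).

    Negative raw differences (optimiser noise under the null) are clamped to
    zero.  ``mixture=True`` uses the 50:50 {0, chi2(1)} boundary mixture.
    Unconverged fits yield a skipped result.
    """
    if not (fit_null.converged and fit_alt.converged):
        return LRTResult(math.nan, math.nan, skipped=True)
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    if mixture:
        p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 1.0
    else:
        p = float(chi2.sf(stat, 1))
    return LRTResult(stat, p)
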