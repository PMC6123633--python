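"""Synthetic inputs with planted ground truth for the whole screen.

The generator emulates the study conditions of the real analysis: a 15-taxon
species tree whose focal clade of four *Symbiodinium* lineages sits on a
marked stem branch, with *Perkinsus marinus* as the basal outgroup and
*Polarella glacialis* among the background dinoflagellates; codon alignments
evolved under the branch-site null (omega2 = 1) or alternative (omega2 > 1 on
the stem); families contaminated with planted paralogs that violate
genus-level congruence; and presence/absence matrices with single-origin
gains and Poisson losses.

Codon evolution samples each branch transition from the exact matrix
exponential of the same GY94 generator the likelihood uses; the generator
checks that are independent of the pruning code (stationarity, counting) live
in the test-suite.  All functions are pure in (config, seed): the same seed
reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codon_evolution import (
    BranchSiteParams,
    CodonAlignment,
    GeneticCode,
    STANDARD_CODE,
    _Propagator,
    build_rate_matrix,
    substitution_rate,
)
from .errors import InputError
from .io_formats import CollinearPair, HitRecord, SequenceRecord
from .family_filter import HomologFamily
from .tree_ops import Node, Phylogeny, PresenceAbsenceMatrix

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "ScreenDataset",
    "default_pi",
    "simulate_tree",
    "simulate_codon_alignment",
    "simulate_screen_dataset",
    "simulate_dollo_matrix",
    "simulate_gene_pairs",
    "simulate_toolkit_hits",
]

FOCAL_GENUS = "Symbiodinium"
OUTGROUP = "Perkinsus_marinus"
POLARELLA = "Polarella_glacialis"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the real setting: 15 taxa with a 4-lineage focal clade,
    coding G+C around 0.56, 300-codon alignments, a 20% pool of sites
    (1 - p0 - p1) eligible for foreground selection at omega2 = 8, 30% of
    families truly selected and 20% contaminated with paralogs.
    """

    seed: int = 0
    n_taxa: int = 15
    focal_clade_size: int = 4
    birth_rate: float = 1.0
    mean_branch_length: float = 0.2
    n_codons: int = 300
    kappa: float = 2.0
    p0: float = 0.45
    p1: float = 0.35
    omega0: float = 0.2
    omega2: float = 8.0
    fraction_selected: float = 0.3
    paralog_rate: float = 0.2
    duplication_rate: float = 0.3
    loss_rate: float = 1.0
    gc_content: float = 0.56
    n_families: int = 200

    def __post_init__(self) -> None:
        if self.n_taxa < 4 or not (2 <= self.focal_clade_size < self.n_taxa):
            raise InputError("need n_taxa >= 4 and 2 <= focal_clade_size < n_taxa")

    def params(self, model: str) -> BranchSiteParams:
        omega2 = self.omega2 if model == "bs_alt" else 1.0
        return BranchSiteParams(
            kappa=self.kappa,
            omega0=self.omega0,
            p0=self.p0,
            p1=self.p1,
            omega2=omega2,
            pi=default_pi(self.gc_content),
        )

    def taxa(self) -> list[str]:
        focal = [f"{FOCAL_GENUS}_{chr(ord('A') + i)}" for i in range(self.focal_clade_size)]
        n_bg = self.n_taxa - self.focal_clade_size - 2
        background = [f"Dinophyte_{i + 1:02d}" for i in range(n_bg)]
        return [OUTGROUP, POLARELLA, *background, *focal]

    def genus_map(self) -> dict[str, str]:
        out = {}
        for taxon in self.taxa():
            genus = FOCAL_GENUS if taxon.startswith(FOCAL_GENUS + "_") else taxon
            out[taxon] = genus
        return out

    def focal_taxa(self) -> list[str]:
        return [t for t in self.taxa() if t.startswith(FOCAL_GENUS + "_")]


@dataclass
class TruthRecord:
    """Planted truth for one simulated family."""

    family_id: str
    is_selected: bool
    is_paralogous: bool
    congruence_class: str  # expected classify_congruence label (multi-copy only)
    copy_class: str
    true_params: BranchSiteParams
    site_classes: np.ndarray | None = None


def default_pi(gc: float = 0.56, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Codon frequencies from a seed nucleotide composition with the given G+C."""
    nuc = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    pi = np.array([nuc[c[0]] * nuc[c[1]] * nuc[c[2]] for c in code.sense_codons])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _yule_topology(labels: Sequence[str], rng: np.random.Generator) -> Node:
    """Random Yule (uniform-split) topology; exponential branch lengths."""
    tips = [Node(label=lab, length=float(rng.exponential(1.0))) for lab in labels]
    lineages = list(tips)
    rng.shuffle(lineages)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = Node(length=float(rng.exponential(1.0)))
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j] = parent
        lineages.pop(i)
    return lineages[0]


def _rescale_lengths(root: Node, target_mean: float) -> None:
    nodes = []
    stack = [root]
    while stack:
        n = stack.pop()
        nodes.append(n)
        stack.extend(n.children)
    branches = [n for n in nodes if n.parent is not None]
    mean = sum(n.length for n in branches) / len(branches)
    f = target_mean / mean
    for n in branches:
        n.length *= f
    root.length = 0.0


def simulate_tree(config: SimulationConfig, seed: int | None = None) -> Phylogeny:
    """Rooted species tree with an exclusively monophyletic focal clade.

    The outgroup attaches at the root; the focal clade replaces one ingroup
    tip of a Yule topology and its stem branch carries the foreground mark.
    Branch lengths are rescaled to the configured mean (expected
    substitutions per codon).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    taxa = config.taxa()
    focal = config.focal_taxa()
    ingroup_labels = [t for t in taxa if t != OUTGROUP and t not in focal]

    placeholder = "__FOCAL__"
    ingroup = _yule_topology([*ingroup_labels, placeholder], rng)
    focal_sub = _yule_topology(focal, rng)

    # swap the placeholder tip for the focal subtree, keeping its stem length
    stack = [ingroup]
    while stack:
        node = stack.pop()
        for i, child in enumerate(node.children):
            if child.is_leaf and child.label == placeholder:
                focal_sub.length = child.length
                focal_sub.parent = node
                node.children[i] = focal_sub
                stack.clear()
                break
            stack.append(child)

    root = Node()
    out_tip = Node(label=OUTGROUP, length=float(rng.exponential(1.0)))
    root.add_child(out_tip)
    root.add_child(ingroup)
    _rescale_lengths(root, config.mean_branch_length)
    focal_sub.foreground = True
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------


def simulate_codon_alignment(
    tree: Phylogeny,
    params: BranchSiteParams,
    n_codons: int,
    model: str = "bs_null",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment down the tree under the site-class mixture.

    Each site draws a class from the mixture weights (single class for M0),
    the root codon from pi, and each branch transition from the exact
    exponential of the class- and branch-appropriate generator.  Returns the
    alignment and the per-site class indices (the planted truth).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    weights, bg, fg = params.site_classes(model)
    if model != "M0" and not any(n.foreground for n in tree.postorder()):
        raise InputError("branch-site simulation requires a foreground mark")
    pi = params.pi
    code = STANDARD_CODE

    omegas = sorted({*bg, *fg})
    props = {}
    rates = {}
    for w in omegas:
        q = build_rate_matrix(params.kappa, w, pi)
        rates[w] = substitution_rate(q, pi)
        props[w] = _Propagator(q, pi)
    scale = float(sum(wt * rates[w] for wt, w in zip(weights, bg)))

    classes = rng.choice(len(weights), size=n_codons, p=weights / weights.sum())
    root_states = rng.choice(len(pi), size=n_codons, p=pi)

    states: dict[int, np.ndarray] = {}
    order = list(tree.postorder())
    root = order[-1]
    states[id(root)] = root_states
    for node in tree.preorder():
        if node is root:
            continue
        parent_states = states[id(node.parent)]
        child_states = parent_states.copy()
        t = max(node.length, 0.0) / scale
        for ci in range(len(weights)):
            sites = np.nonzero(classes == ci)[0]
            if sites.size == 0:
                continue
            w = fg[ci] if node.foreground else bg[ci]
            p = props[w].matrices(np.array([t]))[0]
            p = p / p.sum(axis=1, keepdims=True)
            probs = p[parent_states[sites]]
            u = rng.random(sites.size)
            child_states[sites] = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        states[id(node)] = child_states

    rows = {
        tip.label: "".join(code.sense_codons[s] for s in states[id(tip)])
        for tip in tree.tips()
    }
    return CodonAlignment(rows, code), classes


def _evolve_row(
    source_states: np.ndarray,
    params: BranchSiteParams,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one sequence for time t under the background omega0 process."""
    q = build_rate_matrix(params.kappa, params.omega0, params.pi)
    scale = substitution_rate(q, params.pi)
    p = _Propagator(q, params.pi).matrices(np.array([t / scale]))[0]
    p = p / p.sum(axis=1, keepdims=True)
    probs = p[source_states]
    u = rng.random(source_states.size)
    return (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)


# ---------------------------------------------------------------------------
# Screen dataset
# ---------------------------------------------------------------------------


@dataclass
class ScreenDataset:
    """Everything the selection screen consumes, plus planted truth."""

    config: SimulationConfig
    reference_tree: Phylogeny
    genus_map: dict[str, str]
    focal_genus: str
    families: list[HomologFamily]
    protein_alignments: dict[str, list[SequenceRecord]]
    cds: dict[str, str]
    family_trees: dict[str, Phylogeny]
    truth: dict[str, TruthRecord]


def _find_tip(tree: Phylogeny, label: str) -> Node:
    for tip in tree.tips():
        if tip.label == label:
            return tip
    raise InputError(f"tip {label!r} not found")


def _graft_sister(tree: Phylogeny, target_label: str, new_label: str, length: float) -> None:
    """Insert a new tip as sister of ``target_label`` (in place)."""
    target = _find_tip(tree, target_label)
    parent = target.parent
    assert parent is not None
    joint = Node(length=max(target.length - length, length))
    new_tip = Node(label=new_label, length=length)
    idx = parent.children.index(target)
    parent.children[idx] = joint
    joint.parent = parent
    target.length = length
    joint.add_child(target)
    joint.add_child(new_tip)


def _translate_rows(aln: CodonAlignment) -> dict[str, str]:
    code = aln.code
    out = {}
    for seq_id in aln.ids:
        out[seq_id] = "".join(
            "-" if c == "---" else code.translate(c) for c in aln.codon_strings(seq_id)
        )
    return out


def simulate_screen_dataset(config: SimulationConfig) -> ScreenDataset:
    """Families of codon/protein alignments with planted selection and paralogy.

    A deterministic fraction of families (``fraction_selected``) evolves under
    the branch-site alternative (omega2 on the focal stem); the rest under the
    null.  A ``paralog_rate`` fraction of the null families is contaminated by
    duplicating a sequence and grafting the copy where it breaks genus-level
    congruence (or focal-clade monophyly); a ``duplication_rate`` fraction
    receives a benign within-taxon duplicate (a co-ortholog, still congruent).
    Sequence ids are ``<taxon>@<family>`` (duplicates ``<taxon>.2@<family>``).
    """
    master = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    reference = simulate_tree(config, seed=config.seed)
    genus_map = config.genus_map()
    focal = config.focal_taxa()
    n = config.n_families

    # deterministic planted-truth assignment: exact counts, shuffled positions
    n_sel = int(round(config.fraction_selected * n))
    order = assign_rng.permutation(n)
    selected = set(order[:n_sel].tolist())
    non_selected = [i for i in order.tolist() if i not in selected]
    n_par = min(int(round(config.paralog_rate * n)), len(non_selected))
    paralogous = set(non_selected[:n_par])

    fam_seeds = master.spawn(n)
    families: list[HomologFamily] = []
    proteins: dict[str, list[SequenceRecord]] = {}
    cds: dict[str, str] = {}
    trees: dict[str, Phylogeny] = {}
    truth: dict[str, TruthRecord] = {}
    from .family_filter import MULTI_COPY, SINGLE_COPY  # avoid module cycle

    for i in range(n):
        fam = f"OG{i:04d}"
        rng = np.random.default_rng(fam_seeds[i])
        model = "bs_alt" if i in selected else "bs_null"
        params = config.params(model)
        aln, classes = simulate_codon_alignment(
            reference, params, config.n_codons, model=model, rng=rng
        )
        seq_of = {taxon: f"{taxon}@{fam}" for taxon in reference.tip_labels}
        rows = {seq_of[t]: aln.rows[t] for t in reference.tip_labels}
        tree = reference.copy().relabel_tips(seq_of)
        for node in tree.postorder():
            node.foreground = False
        members = [(seq_of[t], t) for t in reference.tip_labels]
        congruence = ""
        copy_class = SINGLE_COPY

        def add_duplicate(source_taxon: str, sister_taxon: str) -> None:
            src_id = seq_of[source_taxon]
            dup_id = f"{source_taxon}.2@{fam}"
            src_states = np.array(
                [STANDARD_CODE.codon_index[c] for c in aln.codon_strings(source_taxon)]
            )
            dup_states = _evolve_row(src_states, params, 0.05, rng)
            rows[dup_id] = "".join(STANDARD_CODE.sense_codons[s] for s in dup_states)
            _graft_sister(tree, seq_of[sister_taxon], dup_id, 0.025)
            members.append((dup_id, source_taxon))

        non_focal = [t for t in reference.tip_labels if t not in focal]
        if i in paralogous:
            copy_class = MULTI_COPY
            src = non_focal[int(rng.integers(len(non_focal)))]
            if rng.random() < 0.5:
                # graft the copy next to an unrelated non-focal taxon:
                # the source genus is no longer monophyletic
                others = [t for t in non_focal if t != src]
                sister = others[int(rng.integers(len(others)))]
                congruence = "paralogous"
            else:
                # graft the copy inside the focal clade
                sister = focal[int(rng.integers(len(focal)))]
                congruence = "focal_not_monophyletic"
            add_duplicate(src, sister)
        elif rng.random() < config.duplication_rate:
            copy_class = MULTI_COPY
            taxa = reference.tip_labels
            src = taxa[int(rng.integers(len(taxa)))]
            add_duplicate(src, src)  # benign: copy is sister of its source
            congruence = "congruent_coortholog"

        family = HomologFamily(fam, members, copy_class=copy_class)
        families.append(family)
        code = STANDARD_CODE
        fam_aln = CodonAlignment(rows, code)
        proteins[fam] = [
            SequenceRecord(
                seq_id,
                "".join(code.translate(c) for c in fam_aln.codon_strings(seq_id)),
                kind="aligned_protein",
                taxon=dict(members)[seq_id],
            )
            for seq_id, _ in members
        ]
        for seq_id, _ in members:
            cds[seq_id] = rows[seq_id]
        trees[fam] = tree
        truth[fam] = TruthRecord(
            family_id=fam,
            is_selected=i in selected,
            is_paralogous=i in paralogous,
            congruence_class=congruence,
            copy_class=copy_class,
            true_params=params,
            site_classes=classes,
        )

    return ScreenDataset(
        config=config,
        reference_tree=reference,
        genus_map=genus_map,
        focal_genus=FOCAL_GENUS,
        families=families,
        protein_alignments=proteins,
        cds=cds,
        family_trees=trees,
        truth=truth,
    )


def simulate_dollo_matrix(
    tree: Phylogeny, n_families: int, loss_rate: float, seed: int = 0
) -> tuple[PresenceAbsenceMatrix, list[dict]]:
    """Presence/absence under single-origin gain and Poisson branch losses.

    Each family gains on a uniformly chosen branch (any node, root included);
    each branch strictly below the origin loses the family with probability
    P(Poisson(loss_rate * length) >= 1); a tip is present iff the family was
    gained above it and no loss lies on the connecting path.
    """
    if not tree.is_rooted:
        raise InputError("Dollo simulation requires a rooted tree")
    rng = np.random.default_rng(seed)
    nodes = list(tree.postorder())
    below = tree.clades()
    histories = []
    presence: dict[str, set[str]] = {}
    for i in range(n_families):
        fam = f"fam{i:04d}"
        origin = nodes[int(rng.integers(len(nodes)))]
        present: set[str] = set()
        lost_branches: list[frozenset[str]] = []

        def walk(node: Node, alive: bool) -> None:
            lost_here = False
            if node is not origin:  # the origin's own branch cannot lose it
                lost_here = alive and rng.poisson(loss_rate * max(node.length, 0.0)) >= 1
            now_alive = alive and not lost_here
            if lost_here:
                lost_branches.append(below[id(node)])
            if node.is_leaf:
                if now_alive:
                    present.add(node.label)
            for child in node.children:
                walk(child, now_alive)

        walk(origin, True)
        presence[fam] = present
        histories.append(
            {
                "family_id": fam,
                "origin_clade": below[id(origin)],
                "lost_clades": lost_branches,
                "present": frozenset(present),
            }
        )
    matrix = PresenceAbsenceMatrix.from_dict(presence, tree.tip_labels)
    return matrix, histories


# ---------------------------------------------------------------------------
# Pairwise-dN/dS and toolkit-screen inputs
# ---------------------------------------------------------------------------


def simulate_gene_pairs(
    n_pairs: int,
    omega: float,
    kappa: float = 2.0,
    t: float = 0.5,
    n_codons: int = 300,
    gc: float = 0.56,
    seed: int = 0,
) -> tuple[list[CollinearPair], dict[str, str]]:
    """Duplicated gene pairs diverged under an M0 process at the given omega.

    Each pair descends from a stationary ancestor, with each copy evolving
    for time t/2 (total divergence t expected substitutions per codon).
    Returns collinear-pair records (one 5-pair block per 5 pairs) and a CDS
    map.
    """
    rng = np.random.default_rng(seed)
    pi = default_pi(gc)
    params = BranchSiteParams(kappa=kappa, omega0=omega, pi=pi)
    code = STANDARD_CODE
    pairs: list[CollinearPair] = []
    cds: dict[str, str] = {}
    for i in range(n_pairs):
        anc = rng.choice(len(pi), size=n_codons, p=pi)
        a = _evolve_row(anc, params, t / 2.0, rng)
        b = _evolve_row(anc, params, t / 2.0, rng)
        ga, gb = f"gene{i:04d}a", f"gene{i:04d}b"
        cds[ga] = "".join(code.sense_codons[s] for s in a)
        cds[gb] = "".join(code.sense_codons[s] for s in b)
        pairs.append(CollinearPair(f"block{i // 5:03d}", ga, gb, "genomeA", "genomeA"))
    return pairs, cds


def simulate_toolkit_hits(
    panel: Sequence[str],
    taxa: Sequence[str],
    absence: dict[str, set[str]] | None = None,
    seed: int = 0,
    evalue_present: float = 1e-30,
    evalue_absent: float = 1e-3,
) -> tuple[list[HitRecord], dict[str, set[str]]]:
    """Similarity hits for a gene-panel screen with planted absences.

    ``absence`` maps panel gene -> taxa lacking it; when omitted, each
    (gene, taxon) cell is absent with probability 0.05.  Present cells get a
    strong hit (E = 1e-30); absent cells get either no hit or a weak one
    above the screening threshold.
    """
    rng = np.random.default_rng(seed)
    if absence is None:
        absence = {
            g: {t for t in taxa if rng.random() < 0.05} for g in panel
        }
    hits: list[HitRecord] = []
    for gene in panel:
        for taxon in taxa:
            if taxon in absence.get(gene, set()):
                if rng.random() < 0.5:  # weak, above-threshold hit
                    hits.append(
                        HitRecord(gene, taxon, 30.0, 80, evalue_absent, 40.0,
                                  ("1", "80", "1", "80", "1", "80")))
            else:
                hits.append(
                    HitRecord(gene, taxon, 75.0, 200, evalue_present, 300.0,
                              ("1", "200", "1", "200", "1", "200")))
    return hits, absence
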