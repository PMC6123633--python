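"""Tree containers and algorithms.

Everything the screen needs from a phylogeny lives here: a light rooted/unrooted
tree structure (:class:`Phylogeny`), exclusive-monophyly testing, genus-level
collapse, Robinson-Foulds congruence (the paralog filter) and Dollo-parsimony
gain/loss reconstruction over gene-family presence/absence matrices.

Bipartitions are always taken in the unrooted sense and canonicalised relative
to an anchor tip, so rooted and unrooted encodings of the same topology compare
equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import InputError

__all__ = [
    "Node",
    "Phylogeny",
    "PresenceAbsenceMatrix",
    "GainLossSummary",
    "NonMonophyleticGenusError",
    "CongruenceClass",
    "is_exclusive_monophyletic",
    "collapse_to_genus",
    "rf_distance",
    "classify_congruence",
    "dollo_gain_loss",
]


class NonMonophyleticGenusError(InputError):
    """A genus with >=2 tips does not form an exclusive clade."""

    def __init__(self, genus: str):
        super().__init__(f"genus {genus!r} is not exclusively monophyletic")
        self.genus = genus


@dataclass
class Node:
    """Tree node; ``length`` and ``foreground`` describe the branch above it."""

    label: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    foreground: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """Rooted or unrooted phylogeny with branch lengths and foreground marks.

    A basal polytomy (root with >2 children) encodes an unrooted tree; a
    bifurcating root encodes a rooted one.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = [t.label for t in self.tips()]
        if len(labels) != len(set(labels)):
            raise InputError("duplicate tip labels in tree")
        if any(lbl is None or lbl == "" for lbl in labels):
            raise InputError("every tip must carry a non-empty label")

    # -- traversal -----------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]  # type: ignore[misc]

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, foreground=node.foreground)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root))

    # -- queries -------------------------------------------------------------

    def mrca(self, tip_labels: Iterable[str]) -> Node:
        wanted = set(tip_labels)
        missing = wanted - set(self.tip_labels)
        if missing:
            raise InputError(f"tips not in tree: {sorted(missing)}")
        below: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label} & wanted  # type: ignore[arg-type]
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if below[id(node)] == wanted:
                return node
        return self.root

    def clades(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> set of tip labels below that node."""
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])  # type: ignore[list-item]
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc |= below[id(child)]
                below[id(node)] = frozenset(acc)
        return below

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, canonicalised by an anchor tip.

        Each internal branch is represented by the side that excludes the
        lexicographically smallest tip label.
        """
        all_tips = frozenset(self.tip_labels)
        anchor = min(all_tips)
        out: set[frozenset[str]] = set()
        below = self.clades()
        for node in self.postorder():
            if node is self.root:
                continue
            side = below[id(node)]
            if anchor in side:
                side = all_tips - side
            if 2 <= len(side) <= len(all_tips) - 2:
                out.add(side)
        return out

    # -- editing -------------------------------------------------------------

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Restriction of the tree to ``keep`` tips, unifurcations suppressed."""
        keep_set = set(keep)
        missing = keep_set - set(self.tip_labels)
        if missing:
            raise InputError(f"tips not in tree: {sorted(missing)}")
        if len(keep_set) < 2:
            raise InputError("cannot prune to fewer than 2 tips")

        def build(node: Node) -> Node | None:
            if node.is_leaf:
                if node.label in keep_set:
                    return Node(node.label, node.length, foreground=node.foreground)
                return None
            kept = [c for c in (build(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                only = kept[0]
                only.length += node.length
                only.foreground = only.foreground or node.foreground
                return only
            new = Node(node.label, node.length, foreground=node.foreground)
            for c in kept:
                new.add_child(c)
            return new

        new_root = build(self.root)
        assert new_root is not None
        if len(new_root.children) == 1:  # root became unifurcate
            new_root = new_root.children[0]
            new_root.parent = None
            new_root.length = 0.0
        return Phylogeny(new_root)

    def relabel_tips(self, mapping: Mapping[str, str]) -> "Phylogeny":
        new = self.copy()
        for tip in new.tips():
            tip.label = mapping.get(tip.label, tip.label)  # type: ignore[arg-type]
        return Phylogeny(new.root)  # re-validates uniqueness

    # -- serialisation -------------------------------------------------------

    def to_newick(self, lengths: bool = True, foreground_marks: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner}){node.label or ''}"
            if foreground_marks and node.foreground:
                body += "#1"
            if lengths and node.parent is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({len(self.tip_labels)} tips, rooted={self.is_rooted})"


# ---------------------------------------------------------------------------
# Monophyly and genus collapse
# ---------------------------------------------------------------------------


def is_exclusive_monophyletic(tree: Phylogeny, focal_tips: Iterable[str]) -> bool:
    """True iff ``focal_tips`` form one side of some branch (unrooted sense).

    The full tip set is exclusively monophyletic by convention.
    """
    focal = frozenset(focal_tips)
    all_tips = frozenset(tree.tip_labels)
    if not focal <= all_tips:
        raise InputError(f"focal tips not in tree: {sorted(focal - all_tips)}")
    if focal == all_tips or len(focal) == 1:
        return True
    if not focal:
        raise InputError("focal tip set is empty")
    for side in tree.clades().values():
        if side == focal or all_tips - side == focal:
            return True
    return False


def collapse_to_genus(
    tree: Phylogeny, genus_of: Mapping[str, str]
) -> Phylogeny:
    """Collapse each genus' tips to a single tip labelled by genus.

    Every genus with >=2 tips must be exclusively monophyletic in the unrooted
    sense; otherwise :class:`NonMonophyleticGenusError` is raised.  Because a
    monophyletic genus occupies one side of a branch, pruning to one
    representative tip per genus preserves the genus-level topology exactly.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in genus_of]
    if missing:
        raise InputError(f"tips without genus assignment: {missing}")
    by_genus: dict[str, list[str]] = {}
    for t in tips:
        by_genus.setdefault(genus_of[t], []).append(t)
    for genus, members in sorted(by_genus.items()):
        if len(members) >= 2 and not is_exclusive_monophyletic(tree, members):
            raise NonMonophyleticGenusError(genus)
    representatives = {min(members): genus for genus, members in by_genus.items()}
    pruned = tree.prune_to(representatives)
    return pruned.relabel_tips(representatives)


# ---------------------------------------------------------------------------
# Robinson-Foulds congruence (the paralog filter)
# ---------------------------------------------------------------------------


def rf_distance(t1: Phylogeny, t2: Phylogeny) -> int:
    """Robinson-Foulds distance: |symmetric difference of bipartition sets|."""
    if set(t1.tip_labels) != set(t2.tip_labels):
        raise InputError("trees must share an identical tip set")
    return len(t1.bipartitions() ^ t2.bipartitions())


class CongruenceClass:
    """Outcome labels of the multi-copy paralog filter."""

    CONGRUENT_COORTHOLOG = "congruent_coortholog"
    PARALOGOUS = "paralogous"
    FOCAL_NOT_MONOPHYLETIC = "focal_not_monophyletic"


def classify_congruence(
    family_tree: Phylogeny,
    reference_tree: Phylogeny,
    genus_map: Mapping[str, str],
    focal_genus: str,
    taxon_of: Mapping[str, str] | None = None,
) -> str:
    """Judge a multi-copy family paralog-free or not by tree congruence.

    A family passes (``congruent_coortholog``) when (a) all focal-genus
    sequences form an exclusive monophyletic clade and (b) the family tree,
    collapsed to genus level, is topologically identical (RF = 0, unrooted) to
    the reference species tree collapsed to genus level and pruned to the
    genera present in the family.  ``taxon_of`` maps family tip (sequence) ids
    to taxa; identity by default.
    """
    tips = family_tree.tip_labels
    if len(tips) < 4:
        raise InputError("congruence classification requires >=4 tips")
    taxon_of = taxon_of or {t: t for t in tips}
    missing = [t for t in tips if t not in taxon_of]
    if missing:
        raise InputError(f"family tips without taxon assignment: {missing}")
    tip_genus = {}
    for t in tips:
        taxon = taxon_of[t]
        if taxon not in genus_map:
            raise InputError(f"taxon {taxon!r} missing from genus map")
        tip_genus[t] = genus_map[taxon]

    focal_tips = [t for t in tips if tip_genus[t] == focal_genus]
    if not focal_tips:
        raise InputError("family contains no focal-genus sequence")
    if not is_exclusive_monophyletic(family_tree, focal_tips):
        return CongruenceClass.FOCAL_NOT_MONOPHYLETIC

    try:
        fam_genus_tree = collapse_to_genus(family_tree, tip_genus)
    except NonMonophyleticGenusError:
        return CongruenceClass.PARALOGOUS

    family_genera = set(fam_genus_tree.tip_labels)
    ref_genus_tree = collapse_to_genus(reference_tree, genus_map)
    shared = family_genera & set(ref_genus_tree.tip_labels)
    if family_genera - shared:
        raise InputError(
            f"family genera absent from reference tree: {sorted(family_genera - shared)}"
        )
    if len(shared) < len(family_genera):
        fam_genus_tree = fam_genus_tree.prune_to(shared)
    ref_pruned = ref_genus_tree.prune_to(family_genera)
    if rf_distance(fam_genus_tree, ref_pruned) == 0:
        return CongruenceClass.CONGRUENT_COORTHOLOG
    return CongruenceClass.PARALOGOUS


# ---------------------------------------------------------------------------
# Dollo parsimony gain/loss
# ---------------------------------------------------------------------------


@dataclass
class PresenceAbsenceMatrix:
    """Boolean taxa x families matrix backed by a pandas DataFrame."""

    df: pd.DataFrame  # index = taxa, columns = families, dtype bool

    @classmethod
    def from_dict(
        cls, presence: Mapping[str, Iterable[str]], taxa: Sequence[str]
    ) -> "PresenceAbsenceMatrix":
        """Build from family -> iterable of taxa where it is present."""
        families = list(presence)
        df = pd.DataFrame(False, index=list(taxa), columns=families, dtype=bool)
        for fam, present in presence.items():
            for taxon in present:
                df.loc[taxon, fam] = True
        return cls(df)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def families(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class GainLossSummary:
    """Per-branch gain/loss totals and per-family origin branches.

    Branches are identified by the label of the node below them (tip label for
    terminal branches, assigned ``N<i>`` labels for unlabelled internal nodes,
    ``root`` for the root).
    """

    gains: dict[str, int]
    losses: dict[str, int]
    origin: dict[str, str]
    branch_clades: dict[str, frozenset[str]]
    skipped_absent: int = 0

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())


def _branch_ids(tree: Phylogeny) -> dict[int, str]:
    """Stable branch ids: tip label, internal label, or postorder N<i>."""
    ids: dict[int, str] = {}
    counter = 0
    for node in tree.postorder():
        if node is tree.root:
            ids[id(node)] = "root"
        elif node.is_leaf:
            ids[id(node)] = node.label  # type: ignore[assignment]
        elif node.label:
            ids[id(node)] = node.label
        else:
            ids[id(node)] = f"N{counter}"
            counter += 1
    return ids


def dollo_gain_loss(
    tree: Phylogeny, matrix: PresenceAbsenceMatrix
) -> GainLossSummary:
    """Dollo-parsimony reconstruction of family gains and losses.

    Each family present in >=1 taxon is gained exactly once, on the branch
    above the MRCA of its present tips (the root when the MRCA is the root).
    Losses are minimal: one per maximal all-absent clade inside the origin
    subtree.  All-absent families are skipped and counted.
    """
    if not tree.is_rooted:
        raise InputError("Dollo reconstruction requires a rooted tree")
    tip_set = set(tree.tip_labels)
    if set(matrix.taxa) != tip_set:
        raise InputError("matrix taxa must equal the tree tip set")

    ids = _branch_ids(tree)
    below = tree.clades()
    gains = {bid: 0 for bid in ids.values()}
    losses = {bid: 0 for bid in ids.values()}
    origin: dict[str, str] = {}
    branch_clades = {ids[k]: v for k, v in below.items()}
    skipped = 0

    nodes = list(tree.postorder())
    for fam in matrix.families:
        col = matrix.df[fam]
        present = frozenset(col.index[col])
        if not present:
            skipped += 1
            continue
        mrca = tree.mrca(present)
        bid = ids[id(mrca)]
        gains[bid] += 1
        origin[fam] = bid
        # one loss per maximal all-absent clade below the origin
        stack = list(mrca.children)
        while stack:
            node = stack.pop()
            if not (below[id(node)] & present):
                losses[ids[id(node)]] += 1
            else:
                stack.extend(node.children)
    return GainLossSummary(gains, losses, origin, branch_clades, skipped)


def gain_loss_table(summary: GainLossSummary) -> pd.DataFrame:
    """Per-branch gains/losses as a tidy DataFrame (for TSV export)."""
    rows = []
    for bid in summary.gains:
        rows.append(
            {
                "branch": bid,
                "gains": summary.gains[bid],
                "losses": summary.losses[bid],
                "n_descendant_tips": len(summary.branch_clades[bid]),
            }
        )
    return pd.DataFrame(rows)
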