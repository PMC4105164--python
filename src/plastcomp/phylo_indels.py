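"""Binary indel characters on trees: extraction, Fitch parsimony mapping and
synapomorphy / autapomorphy / homoplasy classification.

Each distinct alignment gap block (same column span and row membership within
one region alignment) becomes one presence/absence character.  Characters are
mapped onto a user-supplied rooted tree by Fitch parsimony; missing states
act as wildcards.  Polarity is read off the outgroup-rooted reconstruction:
gaining the gap relative to the ancestral state is a deletion ('-'), losing
it an insertion ('+'), ambiguous ancestors give '±'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import dendropy
import pandas as pd

from .alignment import Alignment
from .divergence import _gap_blocks

log = logging.getLogger(__name__)

PRESENT, ABSENT, MISSING = 1, 0, None


@dataclass
class IndelCharacter:
    id: str
    region: str
    length: int
    states: dict[str, int | None]     # taxon -> 1 (gap present) / 0 / None
    informative: bool = False


@dataclass
class BinaryCharacterMatrix:
    taxa: list[str]
    characters: list[IndelCharacter] = field(default_factory=list)

    def informative(self) -> list[IndelCharacter]:
        return [c for c in self.characters if c.informative]


@dataclass
class CharacterAssignment:
    character: IndelCharacter
    min_changes: int
    branches: list[str]               # head-node labels of change branches
    klass: str                        # synapomorphy | autapomorphy | homoplasy
    polarity: str                     # '+', '-', or '±' (per first change)


@dataclass
class CharacterMapping:
    tree: dendropy.Tree
    assignments: list[CharacterAssignment] = field(default_factory=list)


def build_indel_matrix(
    alignments: list[tuple[str, Alignment]],
    min_taxa_present: int = 2,
) -> BinaryCharacterMatrix:
    """Turn gap blocks of region alignments into binary characters.

    A character is flagged informative when the gap is present in at least
    ``min_taxa_present`` taxa and absent in at least two.
    """
    taxa: list[str] | None = None
    chars: list[IndelCharacter] = []
    for region, aln in alignments:
        if taxa is None:
            taxa = list(aln.labels)
        elif set(taxa) != set(aln.labels):
            raise ValueError(
                f"alignment for {region!r} has taxa {sorted(aln.labels)}, "
                f"expected {sorted(taxa)}"
            )
        for ev in _gap_blocks(aln, exclude_terminal=True):
            states = {
                t: (PRESENT if i in ev.bearer else ABSENT)
                for i, t in enumerate(aln.labels)
            }
            present = sum(1 for v in states.values() if v == PRESENT)
            absent = sum(1 for v in states.values() if v == ABSENT)
            if present == 0 or absent == 0:
                continue
            chars.append(
                IndelCharacter(
                    id=f"{region}:{ev.column_start}+{ev.length}",
                    region=region,
                    length=ev.length,
                    states=states,
                    informative=(
                        present >= min_taxa_present and absent >= 2
                    ),
                )
            )
    return BinaryCharacterMatrix(taxa=taxa or [], characters=chars)


def _prepare_tree(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    t = tree.clone(depth=1)
    og = t.find_node_with_taxon_label(outgroup)
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    t.to_outgroup_position(og, update_bipartitions=False)
    poly = [n for n in t.preorder_node_iter()
            if len(n.child_nodes()) > 2]
    if poly:
        log.warning("resolving %d polytomies arbitrarily", len(poly))
        t.resolve_polytomies()
    return t


def fitch_min_changes(
    tree: dendropy.Tree, states: dict[str, int | None]
) -> int:
    """Fitch parsimony minimum change count for a binary character.

    Missing states contribute the full state set {0, 1} and never force a
    change.  The count is the number of union operations in the bottom-up
    pass, the standard Fitch result (invariant to the rooting).
    """
    changes = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label, MISSING)
            sets[id(node)] = (
                frozenset((0, 1)) if s is MISSING else frozenset((s,))
            )
        else:
            acc: frozenset | None = None
            for ch in node.child_nodes():
                cs = sets[id(ch)]
                if acc is None:
                    acc = cs
                else:
                    inter = acc & cs
                    if inter:
                        acc = inter
                    else:
                        acc = acc | cs
                        changes += 1
            sets[id(node)] = acc if acc is not None else frozenset((0, 1))
    return changes


def _acctran_states(
    tree: dendropy.Tree, states: dict[str, int | None],
    root_pref: int | None = None,
) -> dict[int, int]:
    """One most-parsimonious ancestral reconstruction.

    Node states minimise the subtree cost (Sankoff with unit costs); ties are
    broken toward the state differing from the parent, placing changes as
    close to the root as possible (accelerated transformation).
    """
    INF = 10 ** 6
    cost: dict[int, tuple[int, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label, MISSING)
            cost[id(node)] = (
                (0, 0) if s is MISSING else
                ((0, INF) if s == ABSENT else (INF, 0))
            )
        else:
            c0 = c1 = 0
            for ch in node.child_nodes():
                k0, k1 = cost[id(ch)]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            cost[id(node)] = (c0, c1)
    chosen: dict[int, int] = {}
    root = tree.seed_node
    r0, r1 = cost[id(root)]
    best = 0 if r0 <= r1 else 1
    if root_pref is not None and cost[id(root)][root_pref] == min(r0, r1):
        best = root_pref          # polarise by the outgroup when cost-free
    chosen[id(root)] = best
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = chosen[id(node.parent_node)]
        k0, k1 = cost[id(node)]
        t0 = k0 + (1 if p != 0 else 0)
        t1 = k1 + (1 if p != 1 else 0)
        if t0 < t1:
            chosen[id(node)] = 0
        elif t1 < t0:
            chosen[id(node)] = 1
        else:
            chosen[id(node)] = 1 - p    # tie: change near the root (acctran)
    return chosen


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    tips = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "(" + ",".join(tips) + ")"


def fitch_assign(
    tree: dendropy.Tree,
    matrix: BinaryCharacterMatrix,
    outgroup: str,
) -> CharacterMapping:
    """Map every character onto the outgroup-rooted tree."""
    t = _prepare_tree(tree, outgroup)
    mapping = CharacterMapping(tree=t)
    for ch in matrix.characters:
        mc = fitch_min_changes(t, ch.states)
        og_state = ch.states.get(outgroup, MISSING)
        chosen = _acctran_states(
            t, ch.states, None if og_state is MISSING else og_state
        )
        branches = []
        change_on_leaf = []
        polarity = "±"
        for node in t.preorder_node_iter():
            if node is t.seed_node:
                continue
            p = chosen[id(node.parent_node)]
            s = chosen[id(node)]
            if p != s:
                branches.append(_node_label(node))
                change_on_leaf.append(node.is_leaf())
                if polarity == "±":
                    polarity = "-" if s == PRESENT else "+"
        if mc == 0:
            klass = "invariant"
        elif mc == 1:
            klass = "autapomorphy" if (change_on_leaf and change_on_leaf[0]) \
                else "synapomorphy"
        else:
            klass = "homoplasy"
        mapping.assignments.append(
            CharacterAssignment(ch, mc, branches, klass, polarity)
        )
    return mapping


def _derived_clade_size(tree: dendropy.Tree, chosen: dict[int, int]) -> int:
    root_state = chosen[id(tree.seed_node)]
    return sum(
        1 for lf in tree.leaf_node_iter()
        if chosen[id(lf)] != root_state
    )


def classify_characters(mapping: CharacterMapping) -> pd.DataFrame:
    """Per-character table (id, region, length, class, branches, polarity)."""
    return pd.DataFrame(
        [
            {
                "id": a.character.id,
                "region": a.character.region,
                "length": a.character.length,
                "informative": a.character.informative,
                "min_changes": a.min_changes,
                "class": a.klass,
                "branches": "; ".join(a.branches),
                "polarity": a.polarity,
            }
            for a in mapping.assignments
        ]
    )


def brute_force_min_changes(
    tree: dendropy.Tree, states: dict[str, int | None]
) -> int:
    """Exhaustive minimum over all ancestral assignments (small trees only)."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = 10 ** 9
    for combo in product((0, 1), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        for lf in leaves:
            s = states.get(lf.taxon.label, MISSING)
            assign[id(lf)] = s
        changes = 0
        ok = True
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            p = assign[id(node.parent_node)]
            s = assign[id(node)]
            if s is MISSING:
                continue
            if p != s:
                changes += 1
        best = min(best, changes)
    return best
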