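"""Protein domain arrangement evolution.

Every protein is represented as a domain arrangement: the N->C ordered tuple
of its domain identifiers with consecutive repeats collapsed (A-B-B-B-C
becomes A-B-C), because copy numbers of tandem repeats vary strongly even
between close relatives.  Per node the proteome is summarized as a *set* of
arrangements (copy number ignored) plus the set of domains present.

Ancestral content is reconstructed by a combined parsimony: each arrangement
follows Dollo parsimony (a specific arrangement arises only once, so it is
present on the minimal connected subtree spanning the tips that carry it),
while each single domain's presence follows unordered binary parsimony so
that a domain can survive at a node even when none of that node's
arrangements contains it.

Changes between a parent and child node are then classified into six event
types — fusion, fission, terminal loss, terminal emergence, single-domain
loss, single-domain emergence — keeping only changes explained by *exactly
one* single-step derivation; zero derivations is "unsolved", several is
"ambiguous", and both are excluded from event counts and proportions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .ancestral_counts import reconstruct_family
from .errors import ValidationError
from .treeio import DomainAnnotationTable, Phylogeny

__all__ = [
    "Arrangement",
    "ArrangementSet",
    "RearrangementEvent",
    "EVENT_TYPES",
    "collapse_repeats",
    "select_longest_isoform",
    "arrangement_set_from_annotations",
    "reconstruct_arrangements",
    "classify_event",
    "classify_domain_loss",
    "tally_events",
    "EventTally",
]

Arrangement = Tuple[str, ...]

EVENT_TYPES = (
    "fusion",
    "fission",
    "terminal_loss",
    "terminal_emergence",
    "single_domain_loss",
    "single_domain_emergence",
)


def collapse_repeats(raw: Sequence[str]) -> Arrangement:
    """Collapse runs of adjacent equal domains: A-B-B-B-C -> A-B-C.

    Non-adjacent duplicates are kept (A-B-A stays A-B-A).  Idempotent.
    """
    if not raw:
        raise ValidationError("empty domain list")
    out = [raw[0]]
    for d in raw[1:]:
        if d != out[-1]:
            out.append(d)
    return tuple(out)


def select_longest_isoform(table: DomainAnnotationTable) -> DomainAnnotationTable:
    """Keep one record per gene: the longest isoform.

    Length ties break toward the lexicographically smallest protein id, so
    the choice is reproducible.
    """
    best: Dict[str, str] = {}
    for pid, rec in table.records.items():
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = pid
            continue
        cur_rec = table.records[cur]
        if (rec.aa_length, _neg_str(pid)) > (cur_rec.aa_length, _neg_str(cur)):
            best[rec.gene_id] = pid
    kept = {pid: table.records[pid] for pid in best.values()}
    return DomainAnnotationTable(species=table.species, records=kept)


class _neg_str(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


@dataclass(frozen=True)
class ArrangementSet:
    """The arrangements (and domains) present at one node."""

    node: str
    arrangements: FrozenSet[Arrangement]
    domains: FrozenSet[str]

    @staticmethod
    def build(node: str, arrangements: Iterable[Arrangement],
              extra_domains: Iterable[str] = ()) -> "ArrangementSet":
        arrs = frozenset(tuple(a) for a in arrangements)
        doms = frozenset(d for a in arrs for d in a) | frozenset(extra_domains)
        return ArrangementSet(node=node, arrangements=arrs, domains=doms)


def arrangement_set_from_annotations(
    table: DomainAnnotationTable, node: Optional[str] = None
) -> ArrangementSet:
    """Longest-isoform filter, repeat collapse, then set-ify a proteome."""
    filtered = select_longest_isoform(table)
    arrs = {collapse_repeats(rec.domains) for rec in filtered.records.values()}
    return ArrangementSet.build(node or table.species, arrs)


# ---------------------------------------------------------------------------
# Combined parsimony reconstruction
# ---------------------------------------------------------------------------


def reconstruct_arrangements(
    tree: Phylogeny, tips: Mapping[str, ArrangementSet]
) -> Dict[str, ArrangementSet]:
    """Ancestral arrangement content at every node.

    Arrangement presence is Dollo (single origin at the MRCA of the carrying
    tips, present on the whole spanning subtree); single-domain presence is
    unordered binary parsimony with ties resolved toward absence.  A node's
    domain set is the union over its arrangements plus any domain inferred
    present on its own.
    """
    tip_names = set(tree.tips)
    unknown = set(tips) - tip_names
    if unknown:
        raise ValidationError(f"unknown species: {sorted(unknown)}")
    missing = tip_names - set(tips)
    if missing:
        raise ValidationError(f"missing species: {sorted(missing)}")

    post = tree.postorder()
    all_arrangements = sorted({a for s in tips.values() for a in s.arrangements})
    node_arrs: Dict[str, set] = {v: set() for v in tree.preorder()}
    for arr in all_arrangements:
        carrying = {t for t in tip_names if arr in tips[t].arrangements}
        # below[v]: number of carrying tips in v's subtree
        below: Dict[str, int] = {}
        for v in post:
            kids = tree.children[v]
            if not kids:
                below[v] = 1 if v in carrying else 0
            else:
                below[v] = sum(below[c] for c in kids)
        total = below[tree.root]
        # MRCA: lowest node whose subtree holds all carrying tips
        mrca = tree.root
        while True:
            nxt = [c for c in tree.children[mrca] if below[c] == total]
            if nxt and below[nxt[0]] == total and len(nxt) == 1 and tree.children[mrca]:
                mrca = nxt[0]
            else:
                break
        # presence: within MRCA's subtree, wherever a carrying tip lies below
        stack = [mrca]
        while stack:
            v = stack.pop()
            if below[v] > 0:
                node_arrs[v].add(arr)
                stack.extend(tree.children[v])

    all_domains = sorted({d for s in tips.values() for d in s.domains})
    domain_present: Dict[str, set] = {v: set() for v in tree.preorder()}
    for dom in all_domains:
        presence = {t: 1 if dom in tips[t].domains else 0 for t in tip_names}
        states, _ = reconstruct_family(tree, presence)
        for v, s in states.items():
            if s:
                domain_present[v].add(dom)

    out: Dict[str, ArrangementSet] = {}
    for v in tree.preorder():
        out[v] = ArrangementSet.build(v, node_arrs[v], domain_present[v])
    return out


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RearrangementEvent:
    parent_node: str
    child_node: str
    arrangement: Optional[Arrangement]  # the new (or for domain loss: None)
    type: str  # one of EVENT_TYPES, or "unsolved" / "ambiguous"
    operands: Tuple = ()
    candidates: Tuple[str, ...] = ()  # candidate types when ambiguous


def _derivations(
    child_new: Arrangement,
    parent: ArrangementSet,
    child: Optional[ArrangementSet],
) -> List[Tuple[str, Tuple]]:
    """All single-step derivations of ``child_new`` from the parent content."""
    der: List[Tuple[str, Tuple]] = []
    parr = parent.arrangements

    # fusion: order-respecting concatenation of two distinct parent arrangements
    for x in parr:
        for y in parr:
            if x is y or x == y:
                continue
            if collapse_repeats(x + y) == child_new:
                der.append(("fusion", (x, y)))

    # fission: child_new is one piece of a split parent arrangement and the
    # sibling piece is observable at the child
    child_arrs = child.arrangements if child is not None else frozenset()
    fission_siblings = set()
    for p in parr:
        for i in range(1, len(p)):
            left, right = p[:i], p[i:]
            if child_new == left and right in child_arrs:
                der.append(("fission", (p, i)))
                fission_siblings.add((p, right))
            elif child_new == right and left in child_arrs:
                der.append(("fission", (p, i)))
                fission_siblings.add((p, left))

    # terminal loss: one terminal domain dropped from a parent arrangement;
    # suppressed when the dropped domain survives as its own arrangement at
    # the child (then the change is the fission counted above)
    for p in parr:
        if len(p) < 2:
            continue
        if p[1:] == child_new and (p[:1] not in child_arrs):
            der.append(("terminal_loss", (p, p[0], "head")))
        if p[:-1] == child_new and (p[-1:] not in child_arrs):
            der.append(("terminal_loss", (p, p[-1], "tail")))

    # terminal emergence: a domain novel to the parent proteome added at
    # either end of a parent arrangement
    for p in parr:
        if len(child_new) != len(p) + 1:
            continue
        if child_new[1:] == p and child_new[0] not in parent.domains:
            der.append(("terminal_emergence", (p, child_new[0], "head")))
        if child_new[:-1] == p and child_new[-1] not in parent.domains:
            der.append(("terminal_emergence", (p, child_new[-1], "tail")))

    # single domain emergence: a novel domain appearing as its own arrangement
    if len(child_new) == 1 and child_new[0] not in parent.domains:
        der.append(("single_domain_emergence", (child_new[0],)))

    return der


def classify_event(
    child_new: Arrangement,
    parent: ArrangementSet,
    child: Optional[ArrangementSet] = None,
) -> RearrangementEvent:
    """Classify one new child arrangement against the parent content.

    Exactly one single-step derivation gives that event type; zero gives
    "unsolved"; more than one (even of the same type) gives "ambiguous".
    The child's own arrangement set is needed to separate fission (sibling
    piece observable at the child) from terminal loss; without it, fission
    cannot be asserted.
    """
    if child_new in parent.arrangements:
        raise ValidationError("arrangement already present in parent")
    child_node = child.node if child is not None else ""
    der = _derivations(child_new, parent, child)
    if len(der) == 1:
        typ, operands = der[0]
        return RearrangementEvent(parent.node, child_node, child_new, typ, operands)
    if not der:
        return RearrangementEvent(parent.node, child_node, child_new, "unsolved")
    return RearrangementEvent(
        parent.node, child_node, child_new, "ambiguous",
        candidates=tuple(sorted({t for t, _ in der})),
    )


def classify_domain_loss(
    domain: str, parent: ArrangementSet, child: ArrangementSet
) -> RearrangementEvent:
    """A domain present in the parent proteome and gone from the child."""
    return RearrangementEvent(
        parent.node, child.node, None, "single_domain_loss", (domain,)
    )


@dataclass
class EventTally:
    events: List[RearrangementEvent]
    per_branch: pd.DataFrame  # parent, child, one column per type + ambiguous/unsolved
    counts: Dict[str, int]  # totals per solvable type
    n_ambiguous: int
    n_unsolved: int
    proportions: Dict[str, float]  # percent of solvable events, sums to 100

    def solvable_per_branch(self) -> Dict[str, int]:
        df = self.per_branch
        return dict(zip(df["child"], df[list(EVENT_TYPES)].sum(axis=1)))


def tally_events(
    tree: Phylogeny, reconstruction: Mapping[str, ArrangementSet]
) -> EventTally:
    """Classify and count every arrangement/domain change on every branch.

    New arrangements at the child are classified by ``classify_event`` (a
    fission split is counted once even though it yields two new pieces);
    domains disappearing from the proteome are single-domain losses.
    Ambiguous and unsolved changes are tallied separately and excluded from
    the per-type proportions.
    """
    events: List[RearrangementEvent] = []
    rows = []
    for parent_node, child_node in tree.branches():
        pset = reconstruction[parent_node]
        cset = reconstruction[child_node]
        branch_events: List[RearrangementEvent] = []
        seen_fissions = set()
        for arr in sorted(cset.arrangements - pset.arrangements):
            ev = classify_event(arr, pset, cset)
            if ev.type == "fission":
                key = ev.operands  # (source arrangement, split index)
                if key in seen_fissions:
                    continue  # sibling piece of an already-counted split
                seen_fissions.add(key)
            branch_events.append(ev)
        for dom in sorted(pset.domains - cset.domains):
            branch_events.append(classify_domain_loss(dom, pset, cset))
        events.extend(branch_events)
        row = {"parent": parent_node, "child": child_node}
        c = Counter(ev.type for ev in branch_events)
        for t in EVENT_TYPES + ("ambiguous", "unsolved"):
            row[t] = c.get(t, 0)
        rows.append(row)

    per_branch = pd.DataFrame(
        rows, columns=["parent", "child", *EVENT_TYPES, "ambiguous", "unsolved"]
    )
    counts = {t: int(per_branch[t].sum()) for t in EVENT_TYPES}
    n_solvable = sum(counts.values())
    proportions = {
        t: (100.0 * counts[t] / n_solvable) if n_solvable else 0.0 for t in EVENT_TYPES
    }
    return EventTally(
        events=events,
        per_branch=per_branch,
        counts=counts,
        n_ambiguous=int(per_branch["ambiguous"].sum()),
        n_unsolved=int(per_branch["unsolved"].sum()),
        proportions=proportions,
    )
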