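"""Phylogeny, count-matrix, and domain-annotation I/O.

The analyses downstream need three kinds of input: a rooted dated phylogeny
(ultrametric, branch lengths in millions of years, My), a families x species
matrix of non-negative gene counts, and per-species tables mapping each
protein to its ordered list of Pfam-style domain identifiers.  This module
reads and validates all three and offers node-age / branch-duration services
on the tree.

Counts are stored dense: a species absent from a family is an explicit zero,
because the extinction inference downstream needs explicit absences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Phylogeny",
    "CountMatrix",
    "DomainRecord",
    "DomainAnnotationTable",
    "UltrametricReport",
    "read_tree",
    "parse_tree",
    "write_tree",
    "tree_to_newick",
    "validate_ultrametric",
    "read_count_matrix",
    "write_count_matrix",
    "read_domain_annotations",
    "write_domain_annotations",
    "prune_tips",
]


@dataclass
class Phylogeny:
    """A rooted tree with named nodes and per-branch lengths.

    Tips carry species names; internal nodes carry stable labels (kept
    verbatim from the newick if present, else assigned their preorder index).
    ``duration_my`` maps every non-root node to the length (in My) of the
    branch above it; ``subs_length`` optionally holds branch lengths in
    substitutions per site for the same branches.
    """

    root: str
    parent: Dict[str, str]
    children: Dict[str, Tuple[str, ...]]
    duration_my: Dict[str, float] = field(default_factory=dict)
    subs_length: Dict[str, float] = field(default_factory=dict)

    # -- topology services -------------------------------------------------

    def preorder(self) -> List[str]:
        out: List[str] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return out

    def postorder(self) -> List[str]:
        return list(reversed(self.preorder()))

    @property
    def nodes(self) -> List[str]:
        return self.preorder()

    @property
    def tips(self) -> List[str]:
        return [v for v in self.preorder() if not self.children[v]]

    @property
    def internal_nodes(self) -> List[str]:
        return [v for v in self.preorder() if self.children[v]]

    def is_tip(self, node: str) -> bool:
        return not self.children[node]

    def ancestors(self, node: str) -> List[str]:
        """Strict ancestors, nearest first."""
        out = []
        while node != self.root:
            node = self.parent[node]
            out.append(node)
        return out

    # -- age / length services --------------------------------------------

    def age_my(self) -> Dict[str, float]:
        """Node age = maximum summed duration down to any descendant tip."""
        if not self.duration_my and len(self.parent) > 0:
            raise ValidationError("duration_my is not populated")
        age: Dict[str, float] = {}
        for v in self.postorder():
            kids = self.children[v]
            if not kids:
                age[v] = 0.0
            else:
                age[v] = max(age[c] + self.duration_my[c] for c in kids)
        return age

    def height(self) -> float:
        return self.age_my()[self.root]

    def branches(self) -> List[Tuple[str, str]]:
        """(parent, child) pairs in preorder of the child."""
        return [(self.parent[v], v) for v in self.preorder() if v != self.root]


# ---------------------------------------------------------------------------
# Newick reading / writing
# ---------------------------------------------------------------------------


def _check_dialect(text: str) -> None:
    # Quoted labels and bracket comments are rejected rather than silently
    # stripped: their intent in third-party files is ambiguous.
    if "'" in text or '"' in text:
        raise FormatError("quoted labels are not supported; rename nodes instead")
    if "[" in text or "]" in text:
        raise FormatError("newick comments are not supported")
    if not text.strip().endswith(";"):
        raise FormatError("newick string must end with ';'")


def parse_tree(text: str, length_unit: str = "my") -> Phylogeny:
    """Parse a single-tree newick string.

    length_unit selects which length map is populated: "my" (branch
    durations in millions of years) or "subs" (substitutions/site).
    """
    if length_unit not in ("my", "subs"):
        raise ValueError("length_unit must be 'my' or 'subs'")
    _check_dialect(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparseable newick: {exc}") from None

    parent: Dict[str, str] = {}
    children: Dict[str, Tuple[str, ...]] = {}
    lengths: Dict[str, float] = {}
    labels: Dict[int, str] = {}

    preorder_nodes = list(dtree.preorder_node_iter())
    for idx, nd in enumerate(preorder_nodes):
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise FormatError("tip without a name")
            label = nd.taxon.label
        else:
            label = nd.label if nd.label else str(idx)
        labels[id(nd)] = label

    seen = set()
    for nd in preorder_nodes:
        label = labels[id(nd)]
        if label in seen:
            raise ValidationError(f"duplicate node label {label!r}")
        seen.add(label)

    root = labels[id(dtree.seed_node)]
    for nd in preorder_nodes:
        label = labels[id(nd)]
        children[label] = tuple(labels[id(c)] for c in nd.child_nodes())
        if nd is dtree.seed_node:
            continue
        parent[label] = labels[id(nd.parent_node)]
        if nd.edge.length is None:
            raise FormatError(f"branch above {label!r} has no length")
        length = float(nd.edge.length)
        if length < 0:
            raise ValidationError(f"negative branch length on {label!r}")
        lengths[label] = length

    tree = Phylogeny(root=root, parent=parent, children=children)
    if length_unit == "my":
        tree.duration_my = lengths
    else:
        tree.subs_length = lengths
    return tree


def read_tree(path, length_unit: str = "my") -> Phylogeny:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_tree(fh.read(), length_unit=length_unit)


def _fmt_len(x: float) -> str:
    return format(float(x), ".17g")


def tree_to_newick(tree: Phylogeny, length_unit: str = "my") -> str:
    lengths = tree.duration_my if length_unit == "my" else tree.subs_length

    def rec(v: str) -> str:
        kids = tree.children[v]
        if kids:
            inner = ",".join(rec(c) for c in kids)
            label = f"({inner}){v}"
        else:
            label = v
        if v == tree.root:
            return label
        return f"{label}:{_fmt_len(lengths[v])}"

    return rec(tree.root) + ";"


def write_tree(tree: Phylogeny, path, length_unit: str = "my") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree_to_newick(tree, length_unit=length_unit) + "\n")


# ---------------------------------------------------------------------------
# Ultrametricity
# ---------------------------------------------------------------------------


@dataclass
class UltrametricReport:
    max_deviation: float
    height: float
    tol: float
    passed: bool


def validate_ultrametric(tree: Phylogeny, tol: float = 1e-6) -> UltrametricReport:
    """Report-only check that all root-to-tip path sums agree.

    Passes iff the spread of tip depths is at most ``tol`` times the tree
    height (max tip depth).
    """
    depth = {tree.root: 0.0}
    for v in tree.preorder():
        for c in tree.children[v]:
            depth[c] = depth[v] + tree.duration_my[c]
    tip_depths = [depth[t] for t in tree.tips]
    height = max(tip_depths) if tip_depths else 0.0
    deviation = (max(tip_depths) - min(tip_depths)) if tip_depths else 0.0
    passed = deviation <= tol * height if height > 0 else True
    return UltrametricReport(max_deviation=deviation, height=height, tol=tol, passed=passed)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Families x species non-negative integer gene counts, stored dense."""

    counts: pd.DataFrame  # index: family ids, columns: species ids, int64

    @property
    def families(self) -> List[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> List[str]:
        return list(self.counts.columns)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")


FAMILY_COLUMN = "family_id"


def read_count_matrix(path, taxa: Optional[Sequence[str]] = None) -> CountMatrix:
    """Read a TSV with a ``family_id`` column plus one column per species.

    If ``taxa`` is given, the header must contain exactly those species
    (order-insensitive); the returned columns follow the requested order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if FAMILY_COLUMN not in df.columns:
        raise FormatError(f"count matrix must have a {FAMILY_COLUMN!r} column")
    if df[FAMILY_COLUMN].duplicated().any():
        dup = df[FAMILY_COLUMN][df[FAMILY_COLUMN].duplicated()].iloc[0]
        raise ValidationError(f"duplicate family id {dup!r}")
    df = df.set_index(FAMILY_COLUMN)
    present = list(df.columns)
    if taxa is not None:
        missing = sorted(set(taxa) - set(present))
        if missing:
            raise ValidationError(f"species missing from header: {missing}")
        extra = sorted(set(present) - set(taxa))
        if extra:
            raise ValidationError(f"unexpected species columns: {extra}")
        df = df[list(taxa)]
    for col in df.columns:
        bad = ~df[col].str.fullmatch(r"\d+")
        if bad.any():
            cell = df[col][bad].iloc[0]
            raise FormatError(f"non-integer count {cell!r} in column {col!r}")
    out = df.astype("int64")
    return CountMatrix(counts=out)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    df = matrix.counts.copy()
    df.index.name = FAMILY_COLUMN
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------


@dataclass
class DomainRecord:
    protein_id: str
    gene_id: str
    aa_length: int
    domains: Tuple[str, ...]  # N->C order as annotated, repeats NOT collapsed


@dataclass
class DomainAnnotationTable:
    species: str
    records: Dict[str, DomainRecord]


_DOMAIN_HEADER = ["protein_id", "gene_id", "aa_length", "domains"]


def read_domain_annotations(path, species: str) -> DomainAnnotationTable:
    """Read a per-species Pfam-scan-like TSV of domain arrangements.

    Columns: protein_id, gene_id, aa_length, domains (comma-separated domain
    ids in N->C order).  Rows with an empty domain list are skipped with a
    warning; duplicate protein ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _DOMAIN_HEADER:
        raise FormatError(f"expected header {_DOMAIN_HEADER}, got {list(df.columns)}")
    records: Dict[str, DomainRecord] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid in records:
            raise ValidationError(f"duplicate protein id {pid!r}")
        domains = tuple(d for d in row.domains.split(",") if d)
        if not domains:
            warnings.warn(f"{species}: protein {pid!r} has no domains; skipped")
            continue
        try:
            length = int(row.aa_length)
        except ValueError:
            raise FormatError(f"non-integer aa_length {row.aa_length!r}") from None
        records[pid] = DomainRecord(pid, row.gene_id, length, domains)
    return DomainAnnotationTable(species=species, records=records)


def write_domain_annotations(table: DomainAnnotationTable, path) -> None:
    rows = [
        (r.protein_id, r.gene_id, r.aa_length, ",".join(r.domains))
        for r in sorted(table.records.values(), key=lambda r: r.protein_id)
    ]
    df = pd.DataFrame(rows, columns=_DOMAIN_HEADER)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Tip pruning (for the jackknife)
# ---------------------------------------------------------------------------


def prune_tips(tree: Phylogeny, remove: Iterable[str]) -> Phylogeny:
    """Drop the given tips, suppressing degree-2 nodes.

    Durations (and substitution lengths, if present) across a suppressed node
    are re-summed so path lengths between surviving nodes are preserved.  A
    suppressed node's label disappears from the result.
    """
    remove = set(remove)
    tips = set(tree.tips)
    unknown = remove - tips
    if unknown:
        raise ValidationError(f"not tips: {sorted(unknown)}")
    if not (tips - remove):
        raise ValidationError("cannot remove all tips")

    has_subs = bool(tree.subs_length)
    keep_children: Dict[str, Tuple[str, ...]] = {}
    dur: Dict[str, float] = {}
    subs: Dict[str, float] = {}

    # Returns the surviving representative of v's subtree (or None), together
    # with the extra length accumulated through suppressed nodes.
    def rec(v: str) -> Optional[Tuple[str, float, float]]:
        kids = tree.children[v]
        if not kids:
            if v in remove:
                return None
            keep_children[v] = ()
            return (v, tree.duration_my.get(v, 0.0), tree.subs_length.get(v, 0.0))
        surviving = [r for r in (rec(c) for c in kids) if r is not None]
        if not surviving:
            return None
        own_d = tree.duration_my.get(v, 0.0)
        own_s = tree.subs_length.get(v, 0.0)
        if len(surviving) == 1:
            (c, d, s) = surviving[0]
            return (c, d + own_d, s + own_s)
        keep_children[v] = tuple(c for c, _, _ in surviving)
        for c, d, s in surviving:
            dur[c] = d
            if has_subs:
                subs[c] = s
        return (v, own_d, own_s)

    res = rec(tree.root)
    assert res is not None
    new_root = res[0]
    if new_root not in keep_children:
        keep_children[new_root] = ()
    parent = {c: p for p, kids in keep_children.items() for c in kids}
    # A pendant length accumulated above the new root is discarded.
    dur = {k: v for k, v in dur.items() if k in parent}
    subs = {k: v for k, v in subs.items() if k in parent}
    return Phylogeny(
        root=new_root, parent=parent, children=keep_children,
        duration_my=dur, subs_length=subs,
    )
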