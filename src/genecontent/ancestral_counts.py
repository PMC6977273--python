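"""Wagner (linear-cost) parsimony on integer gene counts.

Given a rooted phylogeny and observed per-species family sizes, reconstruct
the family size at every internal node so that the total absolute change
summed over branches is minimal, then tally per-branch expansions,
contractions, family extinctions and family emergences.  A taxon-jackknife
assesses how robust reconstructed ancestral totals are to species sampling.

The reconstruction is a Sankoff-style dynamic program over the integer
states 0..max(tip counts) with cost |parent - child| per branch; the
min-over-states convolution is computed in linear time by two sweeps.  Ties
are broken deterministically toward the smallest state, root first and then
top-down, which biases ambiguous histories toward later gains rather than
earlier gains plus losses.  Multifurcations are handled natively (child cost
vectors are summed, never resolved into binary nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .treeio import CountMatrix, Phylogeny, prune_tips

__all__ = [
    "AncestralCountTable",
    "BranchChangeTally",
    "reconstruct_family",
    "reconstruct_all",
    "tally_changes",
    "origin_nodes",
    "jackknife",
]

_INF = np.float64(np.inf)


def _min_linear_convolve(cost: np.ndarray, gain_cost: float, loss_cost: float) -> np.ndarray:
    """m[s] = min over child states t of branch cost + cost[t], in O(len).

    Branch cost from parent state s to child state t is
    gain_cost * max(t - s, 0) + loss_cost * max(s - t, 0).
    """
    m = cost.copy()
    for s in range(1, m.size):  # child below parent: one loss per step
        if m[s - 1] + loss_cost < m[s]:
            m[s] = m[s - 1] + loss_cost
    for s in range(m.size - 2, -1, -1):  # child above parent: gains
        if m[s + 1] + gain_cost < m[s]:
            m[s] = m[s + 1] + gain_cost
    return m


def _branch_cost(s: int, t: np.ndarray, gain_cost: float, loss_cost: float) -> np.ndarray:
    delta = t - s
    return gain_cost * np.clip(delta, 0, None) + loss_cost * np.clip(-delta, 0, None)


def reconstruct_family(
    tree: Phylogeny,
    tip_counts: Mapping[str, int],
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> Tuple[Dict[str, int], float]:
    """Minimal-total-change ancestral states for one family.

    With the default unit costs this is Wagner parsimony (minimal summed
    |child - parent|); ``gain_cost``/``loss_cost`` weigh per-copy gains and
    losses asymmetrically.  Returns (per-node integer counts, global minimal
    cost; an int under unit costs).  Among cost-minimizing assignments, every
    node receives the smallest optimal state given its parent's
    already-chosen state (root: smallest global argmin), which makes the
    output deterministic.
    """
    tips = tree.tips
    missing = [t for t in tips if t not in tip_counts]
    if missing:
        raise ValidationError(f"missing tip counts: {missing}")
    if not tips:
        raise ValidationError("empty tree")
    for t in tips:
        if tip_counts[t] < 0:
            raise ValidationError("negative tip count")

    smax = max(int(tip_counts[t]) for t in tips)
    n_states = smax + 1
    post = tree.postorder()
    cost: Dict[str, np.ndarray] = {}
    for v in post:
        kids = tree.children[v]
        if not kids:
            c = np.full(n_states, _INF)
            c[int(tip_counts[v])] = 0.0
        else:
            c = np.zeros(n_states)
            for k in kids:
                c += _min_linear_convolve(cost[k], gain_cost, loss_cost)
        cost[v] = c

    states: Dict[str, int] = {}
    root_cost = cost[tree.root]
    states[tree.root] = int(np.argmin(root_cost))  # argmin -> smallest on tie
    total = float(root_cost[states[tree.root]])
    offsets = np.arange(n_states)
    for v in tree.preorder():
        s = states[v]
        for k in tree.children[v]:
            states[k] = int(np.argmin(_branch_cost(s, offsets, gain_cost, loss_cost) + cost[k]))
    return states, int(total) if total == int(total) else total


@dataclass
class AncestralCountTable:
    """Reconstructed counts for every family at every node (tips included)."""

    counts: pd.DataFrame  # index: family ids, columns: node ids (int64)
    cost: pd.Series  # per family, total parsimony cost

    @property
    def families(self) -> List[str]:
        return list(self.counts.index)

    @property
    def nodes(self) -> List[str]:
        return list(self.counts.columns)


def reconstruct_all(
    tree: Phylogeny,
    matrix: CountMatrix,
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> AncestralCountTable:
    """Reconstruct every family in the matrix; see reconstruct_family."""
    if set(matrix.taxa) != set(tree.tips):
        raise ValidationError("matrix taxa do not match tree tips")
    node_order = tree.preorder()
    rows = np.empty((len(matrix.families), len(node_order)), dtype=np.int64)
    costs = []
    values = matrix.counts
    for i, fam in enumerate(matrix.families):
        tip_counts = values.loc[fam].to_dict()
        states, c = reconstruct_family(tree, tip_counts, gain_cost, loss_cost)
        rows[i, :] = [states[v] for v in node_order]
        costs.append(c)
    counts = pd.DataFrame(rows, index=matrix.families, columns=node_order)
    return AncestralCountTable(counts=counts, cost=pd.Series(costs, index=matrix.families))


@dataclass
class BranchChangeTally:
    """Per-branch change counts plus the global aggregates."""

    branches: pd.DataFrame  # parent, child, n_expansions, n_contractions,
    #                         n_extinctions, n_emergences
    total_expansions: int
    total_contractions: int
    total_changes: int  # expansions + contractions summed over branches
    families_extinct: int  # families with >=1 extinction branch
    families_emerged: int  # families absent at the root with >=1 origin node


def origin_nodes(table: AncestralCountTable, tree: Phylogeny) -> Dict[str, Tuple[str, ...]]:
    """Candidate parsimony origin node(s) per family.

    A node is a candidate origin when the family is present there and absent
    at every strict ancestor.  Families present at the root have no origin
    (they are ancestral); a family may have several candidate origins when
    the reconstruction places disjoint presence islands in the tree.
    """
    pre = tree.preorder()
    present = table.counts[pre].to_numpy() > 0  # families x nodes, preorder
    col = {v: i for i, v in enumerate(pre)}
    above = np.zeros_like(present)
    for v in pre:
        if v == tree.root:
            continue
        p = tree.parent[v]
        above[:, col[v]] = above[:, col[p]] | present[:, col[p]]
    candidate = present & ~above
    candidate[:, col[tree.root]] = False  # root presence means ancestral
    out: Dict[str, Tuple[str, ...]] = {}
    for i, fam in enumerate(table.families):
        if present[i, col[tree.root]]:
            out[fam] = ()
        else:
            out[fam] = tuple(v for v in pre if candidate[i, col[v]])
    return out


def tally_changes(table: AncestralCountTable, tree: Phylogeny) -> BranchChangeTally:
    """Count expansions, contractions, extinctions, emergences per branch."""
    origins = origin_nodes(table, tree)
    origin_count: Dict[str, int] = {v: 0 for v in tree.preorder()}
    for fam, nodes in origins.items():
        for v in nodes:
            origin_count[v] += 1

    rows = []
    fam_extinct = np.zeros(len(table.families), dtype=bool)
    for parent, child in tree.branches():
        delta = table.counts[child].to_numpy() - table.counts[parent].to_numpy()
        extinct = (table.counts[parent].to_numpy() > 0) & (table.counts[child].to_numpy() == 0)
        fam_extinct |= extinct
        rows.append(
            {
                "parent": parent,
                "child": child,
                "n_expansions": int((delta > 0).sum()),
                "n_contractions": int((delta < 0).sum()),
                "n_extinctions": int(extinct.sum()),
                "n_emergences": origin_count[child],
            }
        )
    branches = pd.DataFrame(
        rows,
        columns=["parent", "child", "n_expansions", "n_contractions",
                 "n_extinctions", "n_emergences"],
    )
    total_exp = int(branches["n_expansions"].sum())
    total_con = int(branches["n_contractions"].sum())
    families_emerged = sum(1 for nodes in origins.values() if nodes)
    return BranchChangeTally(
        branches=branches,
        total_expansions=total_exp,
        total_contractions=total_con,
        total_changes=total_exp + total_con,
        families_extinct=int(fam_extinct.sum()),
        families_emerged=families_emerged,
    )


def jackknife(
    tree: Phylogeny,
    matrix: CountMatrix,
    n_reps: int = 100,
    n_remove: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Taxon-jackknife of reconstructed per-node total gene counts.

    Each replicate removes ``n_remove`` random species, prunes the tree
    (re-summing durations across suppressed degree-2 nodes) and re-runs the
    reconstruction.  For every internal node of the full tree the report
    gives the number of replicates in which the node survived pruning and the
    mean / sample SD / min / max of its total reconstructed gene count (sum
    over families) across those replicates.
    """
    taxa = list(matrix.taxa)
    if n_remove >= len(taxa):
        raise ValidationError("n_remove must be smaller than the number of taxa")
    rng = np.random.default_rng(seed)
    totals: Dict[str, List[int]] = {v: [] for v in tree.internal_nodes}
    for _ in range(n_reps):
        removed = list(rng.choice(taxa, size=n_remove, replace=False)) if n_remove else []
        sub = prune_tips(tree, removed) if removed else tree
        kept = [t for t in taxa if t not in removed]
        submatrix = CountMatrix(matrix.counts[kept])
        table = reconstruct_all(sub, submatrix)
        node_totals = table.counts.sum(axis=0)
        for v in sub.internal_nodes:
            if v in totals:
                totals[v].append(int(node_totals[v]))
    rows = []
    for v in tree.internal_nodes:
        vals = np.array(totals[v], dtype=float)
        rows.append(
            {
                "node": v,
                "n_replicates": len(vals),
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "min": float(vals.min()) if len(vals) else float("nan"),
                "max": float(vals.max()) if len(vals) else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("node")
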