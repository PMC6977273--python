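"""Per-branch rates of genomic change per million years.

Three numerators over the same denominators (branch durations in My):
amino-acid substitutions per site (from a substitutions-per-site tree that is
topologically identical to the dated tree), the number of gene families
changing on a branch, and the number of solvable domain-rearrangement
events.  The root has no branch and never appears; zero-duration branches
are kept in the table but flagged undefined and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ancestral_counts import BranchChangeTally
from .errors import ValidationError
from .treeio import Phylogeny

__all__ = [
    "RateTable",
    "substitution_rates",
    "gain_loss_rates",
    "domain_event_rates",
]


@dataclass
class RateTable:
    """Per-branch rates: numerator / duration_my, child-labeled branches."""

    branches: pd.DataFrame  # parent, child, numerator, duration_my, rate, defined

    def summary(
        self,
        exclude: Sequence[str] = (),
        time_weighted: bool = False,
    ) -> Dict[str, float]:
        """Mean and sample SD (ddof=1) over defined branches.

        ``exclude`` lists child node ids whose branches are left out of the
        summary (e.g. known outlier lineages).  ``time_weighted=True``
        replaces the unweighted branch mean with total numerator / total
        duration.
        """
        df = self.branches
        keep = df["defined"] & ~df["child"].isin(set(exclude))
        sub = df[keep]
        rates = sub["rate"].to_numpy(dtype=float)
        if time_weighted:
            mean = float(sub["numerator"].sum() / sub["duration_my"].sum())
        else:
            mean = float(rates.mean()) if rates.size else float("nan")
        sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
        return {
            "mean": mean,
            "sd": sd,
            "n": int(rates.size),
            "n_excluded": int(len(df) - keep.sum()),
        }


def _make_table(tree: Phylogeny, numerators: Mapping[str, float]) -> RateTable:
    rows = []
    for parent, child in tree.branches():
        num = float(numerators[child])
        dur = float(tree.duration_my[child])
        defined = dur > 0
        rows.append(
            {
                "parent": parent,
                "child": child,
                "numerator": num,
                "duration_my": dur,
                "rate": num / dur if defined else float("nan"),
                "defined": defined,
            }
        )
    return RateTable(branches=pd.DataFrame(rows))


def substitution_rates(subs_tree: Phylogeny, time_tree: Phylogeny) -> RateTable:
    """Substitutions/site/My per branch: subs length / branch duration.

    The two trees must have identical labeled topologies; branches are
    joined by child label, so node ordering within the files is irrelevant.
    """
    if set(subs_tree.parent.items()) != set(time_tree.parent.items()) or (
        subs_tree.root != time_tree.root
    ):
        raise ValidationError("substitution and time trees differ in topology or labels")
    if not subs_tree.subs_length:
        raise ValidationError("subs_tree has no substitutions/site lengths")
    return _make_table(time_tree, subs_tree.subs_length)


def gain_loss_rates(tally: BranchChangeTally, tree: Phylogeny) -> RateTable:
    """Gene families changing on each branch, per My.

    A family counts once per branch when its reconstructed count changes
    there in either direction (expansions + contractions are disjoint family
    sets on a branch).
    """
    df = tally.branches
    changing = dict(zip(df["child"], df["n_expansions"] + df["n_contractions"]))
    missing = [c for _, c in tree.branches() if c not in changing]
    if missing:
        raise ValidationError(f"tally missing branches: {missing}")
    return _make_table(tree, changing)


def domain_event_rates(event_counts: Mapping[str, int], tree: Phylogeny) -> RateTable:
    """Domain rearrangement events per My, from child-keyed event counts."""
    counts = {c: float(event_counts.get(c, 0)) for _, c in tree.branches()}
    return _make_table(tree, counts)
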