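"""Statistics on reconstructed gene-family counts.

Three analyses sit on top of the parsimony reconstruction:

* the rapid-change test — under a stochastic birth-death view of family
  evolution the expected relationship between a node and its direct
  descendant is no change, i.e. the points (parent count, child count) fall
  on the one-to-one line; a branch is flagged as a significant (rapid)
  change for a family when its ancestor-descendant difference exceeds k
  (default 2) times the family's RMS deviation about that line;
* emergent-family extraction — families whose parsimony origin is exactly a
  queried internal node (zero counts in all tips outside that clade);
* the unobserved-loss correction — ancestral totals shrink with node age
  because losses deep in the tree cannot be observed; regressing total gene
  count at internal nodes on node age and reading off the intercept at age 0
  gives the expected count with no unobserved loss, and every node is
  shifted so its residual about the regression is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral_counts import AncestralCountTable, origin_nodes
from .errors import DegenerateRegressionError, ValidationError
from .treeio import Phylogeny

__all__ = [
    "RapidChangeResult",
    "ExtinctionCorrectionFit",
    "rapid_change_test",
    "emergent_families",
    "extinction_correction",
]


@dataclass
class RapidChangeResult:
    residuals: pd.DataFrame  # families x branches (child-labeled), child - parent
    sd: pd.Series  # per family
    flagged: pd.DataFrame  # family, parent, child, residual, sd
    n_rapid_branches: int  # branch-level flags summed over families
    n_rapid_families: int  # families with >=1 flagged branch


def rapid_change_test(
    table: AncestralCountTable,
    tree: Phylogeny,
    k: float = 2.0,
    center: bool = False,
) -> RapidChangeResult:
    """Flag branches whose per-family change departs from the 1:1 line.

    The per-family spread is the RMS of the ancestor-to-descendant
    differences about zero (the one-to-one line is the null, so deviations
    are not re-centered; ``center=True`` switches to the mean-centered SD for
    sensitivity analysis).  A branch is flagged iff |difference| > k * sd,
    strictly, so constant families (sd = 0) never flag.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    branches = tree.branches()
    if len(branches) < 2:
        raise ValidationError("need at least 2 branches")
    children = [c for _, c in branches]
    parents = {c: p for p, c in branches}
    child_counts = table.counts[children].to_numpy()
    parent_counts = table.counts[[parents[c] for c in children]].to_numpy()
    res = (child_counts - parent_counts).astype(float)
    if center:
        dev = res - res.mean(axis=1, keepdims=True)
    else:
        dev = res
    sd = np.sqrt((dev**2).mean(axis=1))
    flag = np.abs(res) > (k * sd)[:, None]

    residuals = pd.DataFrame(res, index=table.families, columns=children)
    sd_series = pd.Series(sd, index=table.families)
    fam_idx, br_idx = np.nonzero(flag)
    flagged = pd.DataFrame(
        {
            "family": [table.families[i] for i in fam_idx],
            "parent": [parents[children[j]] for j in br_idx],
            "child": [children[j] for j in br_idx],
            "residual": res[fam_idx, br_idx],
            "sd": sd[fam_idx],
        }
    )
    return RapidChangeResult(
        residuals=residuals,
        sd=sd_series,
        flagged=flagged,
        n_rapid_branches=int(flag.sum()),
        n_rapid_families=int(flag.any(axis=1).sum()),
    )


def emergent_families(
    table: AncestralCountTable, tree: Phylogeny, node: str
) -> List[str]:
    """Families whose parsimony origin is exactly the queried internal node.

    Equivalently: the family is absent from every tip outside the node's
    clade and its single candidate origin is the node itself.
    """
    if node not in tree.parent and node != tree.root:
        raise ValidationError(f"unknown node {node!r}")
    if tree.is_tip(node):
        raise ValidationError(f"{node!r} is a tip, not an internal node")
    origins = origin_nodes(table, tree)
    return [fam for fam in table.families if origins[fam] == (node,)]


@dataclass
class ExtinctionCorrectionFit:
    slope: float
    intercept: float  # predicted total gene count at age 0 (present day)
    r_squared: float
    p_value: float
    ages: pd.Series  # per internal node
    totals: pd.Series  # observed total gene count per internal node
    corrected: pd.Series  # intercept + residual(node) = total - slope * age


def extinction_correction(
    table: AncestralCountTable,
    tree: Phylogeny,
    include_root: bool = True,
) -> ExtinctionCorrectionFit:
    """Correct ancestral totals for unobservable gene losses.

    OLS of total gene count at each internal node on the node's age (My);
    the intercept is the expected present-day count, and each node's
    corrected count shifts the observed one so that residuals about the fit
    are preserved: corrected(node) = intercept + residual(node).
    """
    nodes = [v for v in tree.internal_nodes if include_root or v != tree.root]
    if len(nodes) < 3:
        raise DegenerateRegressionError("need at least 3 internal nodes")
    age = tree.age_my()
    ages = np.array([age[v] for v in nodes])
    if np.unique(ages).size < 2:
        raise DegenerateRegressionError("all internal node ages are identical")
    totals = table.counts[nodes].sum(axis=0).to_numpy(dtype=float)
    fit = stats.linregress(ages, totals)
    corrected = totals - fit.slope * ages
    return ExtinctionCorrectionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        ages=pd.Series(ages, index=nodes),
        totals=pd.Series(totals, index=nodes),
        corrected=pd.Series(corrected, index=nodes),
    )
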