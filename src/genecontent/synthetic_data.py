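"""Synthetic dated trees, gene-count histories, and domain-arrangement
histories with ground truth.

The generator produces the three inputs the pipeline consumes — a dated
ultrametric phylogeny, a families x species count matrix, and per-node
domain-arrangement sets — together with the full event history, so that
every downstream stage can be tested against a known truth without any
external data.

Gene family counts evolve by a per-family Poisson gain process and per-copy
exponential survival (binomial thinning) for losses, with optional family
origination seeded at branch midpoints; domain arrangements evolve by the
six rearrangement event types at per-My Poisson rates, and every applied
event is post-checked to be single-step identifiable from the branch's
parent/child snapshots (the branch is re-drawn otherwise, up to a retry
cap).

All randomness flows through ``numpy.random.Generator`` streams seeded from
the config, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .domain_evo import (
    Arrangement,
    ArrangementSet,
    EVENT_TYPES,
    classify_event,
    collapse_repeats,
)
from .errors import SimulationError, ValidationError
from .treeio import CountMatrix, Phylogeny

__all__ = [
    "SimulationConfig",
    "CountGroundTruth",
    "ArrangementGroundTruth",
    "simulate_tree",
    "simulate_counts",
    "replay_counts",
    "simulate_arrangements",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults emulate a desk-scale version of a deep arthropod-like dataset:
    a ~500 My ultrametric tree, several hundred families with a mean of ~3
    copies at the root, and per-family change rates of order 1e-3 per My so
    a typical family changes about once along a root-to-tip path.  Domain
    event rates are proportioned roughly as observed in real proteomes
    (fusions dominate, then losses, then fissions; novel-domain emergences
    are rare), scaled to the small root repertoire simulated here.
    """

    n_tips: int = 16
    tree_height_my: float = 500.0
    seed: int = 0

    # gene family model
    n_families: int = 500
    root_count_mean: float = 3.0  # geometric (support 1,2,...) mean
    gain_rate: float = 6e-4  # gains per family per My (Poisson)
    loss_rate: float = 6e-4  # loss hazard per gene copy per My (thinning)
    origination_rate: float = 0.0  # new families per My per branch
    extinction_allowed: bool = True  # False keeps every existing family at >=1

    # domain arrangement model
    alphabet_size: int = 500
    n_root_arrangements: int = 40
    fusion_rate: float = 8e-3  # events per My per branch
    fission_rate: float = 2.5e-3
    terminal_loss_rate: float = 2.5e-3
    terminal_emergence_rate: float = 2e-4
    single_domain_loss_rate: float = 4e-3
    single_domain_emergence_rate: float = 2e-4
    max_retries: int = 200

    def event_rates(self) -> Dict[str, float]:
        return {
            "fusion": self.fusion_rate,
            "fission": self.fission_rate,
            "terminal_loss": self.terminal_loss_rate,
            "terminal_emergence": self.terminal_emergence_rate,
            "single_domain_loss": self.single_domain_loss_rate,
            "single_domain_emergence": self.single_domain_emergence_rate,
        }


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, height_my: float, seed: int = 0) -> Phylogeny:
    """Random coalescent-style rooted ultrametric tree scaled to height_my.

    Lineages merge pairwise at random with strictly increasing node heights
    (exponential waiting times), then all heights are rescaled so the root
    sits at exactly ``height_my``.  Tips are named t1..tN; internal nodes
    get preorder-stable labels n0, n1, ... (n0 is the root).
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    active: List[str] = [f"t{i+1}" for i in range(n_tips)]
    children: Dict[str, Tuple[str, ...]] = {name: () for name in active}
    heights: Dict[str, float] = {name: 0.0 for name in active}
    height = 0.0
    k = 0
    while len(active) > 1:
        height += float(rng.exponential(1.0)) + 1e-6
        i, j = sorted(int(x) for x in rng.choice(len(active), size=2, replace=False))
        k += 1
        name = f"merge{k}"
        children[name] = (active[i], active[j])
        heights[name] = height
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append(name)
    root = active[0]
    scale = height_my / heights[root]

    parent: Dict[str, str] = {}
    duration: Dict[str, float] = {}
    for v, kids in children.items():
        for c in kids:
            parent[c] = v
            duration[c] = (heights[v] - heights[c]) * scale
    tree = Phylogeny(root=root, parent=parent, children=children, duration_my=duration)

    rename: Dict[str, str] = {}
    counter = 0
    for v in tree.preorder():
        if tree.children[v]:
            rename[v] = f"n{counter}"
            counter += 1
        else:
            rename[v] = v
    return Phylogeny(
        root=rename[root],
        parent={rename[c]: rename[p] for c, p in parent.items()},
        children={rename[v]: tuple(rename[c] for c in kids) for v, kids in children.items()},
        duration_my={rename[c]: d for c, d in duration.items()},
    )


# ---------------------------------------------------------------------------
# Gene family counts
# ---------------------------------------------------------------------------


@dataclass
class CountGroundTruth:
    """True per-node counts and the event log of a count simulation."""

    true_counts: pd.DataFrame  # families x nodes (preorder)
    events: pd.DataFrame  # child (branch), family, type, delta
    origin_node: Dict[str, str]  # family -> node where it first existed


def simulate_counts(
    tree: Phylogeny, config: SimulationConfig
) -> Tuple[CountMatrix, CountGroundTruth]:
    """Evolve per-family integer counts along the dated tree.

    Per branch of duration t: gains ~ Poisson(gain_rate * t) per family;
    each existing copy independently survives with probability
    exp(-loss_rate * t) (losses floor the count at 0, or at 1 when
    extinction is disallowed).  Originations seed new single-copy families
    at branch midpoints, which then evolve over the remaining half branch
    and the whole subtree below.
    """
    rng = np.random.default_rng(config.seed)
    pre = tree.preorder()
    families = [f"fam{i+1}" for i in range(config.n_families)]
    p_geom = 1.0 / max(config.root_count_mean, 1.0)  # geometric on 1,2,... mean m
    counts: Dict[str, Dict[str, int]] = {
        f: {tree.root: int(rng.geometric(p_geom))} for f in families
    }
    origin_node = {f: tree.root for f in families}
    log_rows: List[Tuple[str, str, str, int]] = []

    def evolve(count: int, t: float, child: str, fam: str) -> int:
        gains = int(rng.poisson(config.gain_rate * t))
        survive_p = math.exp(-config.loss_rate * t)
        losses = int(rng.binomial(count, 1.0 - survive_p)) if count else 0
        floor = 0 if config.extinction_allowed else min(1, count + gains)
        if count + gains - losses < floor:
            losses = count + gains - floor
        if gains:
            log_rows.append((child, fam, "gain", gains))
        if losses:
            log_rows.append((child, fam, "loss", -losses))
        return count + gains - losses

    n_orig = 0
    for v in pre:
        if v == tree.root:
            continue
        p = tree.parent[v]
        t = tree.duration_my[v]
        for fam in list(counts):
            start = counts[fam].get(p)
            if start is not None:
                counts[fam][v] = evolve(start, t, v, fam)
        k_new = int(rng.poisson(config.origination_rate * t))
        for _ in range(k_new):
            n_orig += 1
            fam = f"orig{n_orig}"
            families.append(fam)
            origin_node[fam] = v
            log_rows.append((v, fam, "origination", 1))
            counts[fam] = {v: evolve(1, t / 2.0, v, fam)}

    data = {fam: [counts[fam].get(u, 0) for u in pre] for fam in families}
    true_counts = pd.DataFrame.from_dict(data, orient="index", columns=pre)
    tip_matrix = CountMatrix(true_counts[tree.tips].copy())
    events = pd.DataFrame(log_rows, columns=["child", "family", "type", "delta"])
    truth = CountGroundTruth(true_counts=true_counts, events=events, origin_node=origin_node)
    return tip_matrix, truth


def replay_counts(tree: Phylogeny, truth: CountGroundTruth) -> pd.DataFrame:
    """Re-derive per-node counts from root states plus the event log.

    Used as an oracle: the replayed table must equal the simulator's
    ``true_counts`` exactly, which certifies the log is complete.
    """
    pre = tree.preorder()
    deltas: Dict[Tuple[str, str], int] = {}
    origin_init: Dict[Tuple[str, str], int] = {}
    for row in truth.events.itertuples(index=False):
        if row.type == "origination":
            origin_init[(row.child, row.family)] = row.delta
        else:
            deltas[(row.child, row.family)] = deltas.get((row.child, row.family), 0) + row.delta
    out = {}
    for fam in truth.true_counts.index:
        origin = truth.origin_node[fam]
        vals: Dict[str, int] = {}
        for v in pre:
            if v == tree.root:
                vals[v] = int(truth.true_counts.loc[fam, tree.root])
                continue
            base = origin_init.get((v, fam), vals[tree.parent[v]] if origin != v else 0)
            vals[v] = base + deltas.get((v, fam), 0)
        out[fam] = [vals[u] for u in pre]
    return pd.DataFrame.from_dict(out, orient="index", columns=pre)


# ---------------------------------------------------------------------------
# Domain arrangements
# ---------------------------------------------------------------------------


@dataclass
class ArrangementGroundTruth:
    node_sets: Dict[str, ArrangementSet]  # every node, true content
    events: pd.DataFrame  # child (branch), type, arrangement, detail


def _random_arrangement(rng, alphabet: List[str], max_len: int = 4) -> Arrangement:
    n = int(rng.integers(1, max_len + 1))
    return collapse_repeats([alphabet[int(i)] for i in rng.integers(0, len(alphabet), n)])


def _event_key(typ: str, arrangement: str, detail: str) -> Tuple[str, str]:
    """Canonical identity of an event for log-vs-classifier comparison."""
    if typ == "fission":
        return ("fission", detail)  # detail = "<source>@<split>"
    if typ == "single_domain_loss":
        return ("single_domain_loss", detail)  # detail = the domain
    return (typ, arrangement)


def simulate_arrangements(
    tree: Phylogeny, config: SimulationConfig
) -> Tuple[Dict[str, ArrangementSet], ArrangementGroundTruth]:
    """Evolve domain arrangement sets along the tree by the six event types.

    Each branch draws Poisson event counts per type and applies them in a
    random order; the resulting child snapshot is accepted only when every
    logged event is recovered, with its logged type, by the single-step
    classifier run on the (parent, child) snapshots — otherwise the whole
    branch is re-drawn, up to ``config.max_retries`` attempts.

    Returns (tip sets, ground truth with all node sets and the event log).
    """
    rng = np.random.default_rng(config.seed + 1)
    alphabet = [f"D{i:04d}" for i in range(config.alphabet_size)]

    root_arrs: set = set()
    while len(root_arrs) < config.n_root_arrangements:
        root_arrs.add(_random_arrangement(rng, alphabet[: config.alphabet_size // 2]))
    used = {d for a in root_arrs for d in a}
    novel_pool = [d for d in alphabet if d not in used]

    node_sets: Dict[str, frozenset] = {tree.root: frozenset(root_arrs)}
    log_rows: List[Tuple[str, str, str, str]] = []
    rates = config.event_rates()

    def novel_domain(pool: List[str]) -> str:
        if not pool:
            raise SimulationError("domain alphabet exhausted; increase alphabet_size")
        return pool.pop(int(rng.integers(0, len(pool))))

    def apply_event(typ: str, arrs: set, pool: List[str]) -> Optional[Tuple[Arrangement, str]]:
        """Mutate ``arrs`` in place; return (result arrangement, detail)."""
        current = sorted(arrs)
        if typ == "fusion":
            if len(current) < 2:
                return None
            for _ in range(20):
                i, j = (int(x) for x in rng.integers(0, len(current), 2))
                if i == j:
                    continue
                new = collapse_repeats(current[i] + current[j])
                if new not in arrs:
                    arrs.add(new)
                    return new, f"{'-'.join(current[i])}+{'-'.join(current[j])}"
            return None
        if typ == "fission":
            long = [a for a in current if len(a) >= 2]
            if not long:
                return None
            for _ in range(20):
                p = long[int(rng.integers(0, len(long)))]
                i = int(rng.integers(1, len(p)))
                left, right = p[:i], p[i:]
                if left in arrs or right in arrs:
                    continue
                arrs.discard(p)
                arrs.add(left)
                arrs.add(right)
                return left, f"{'-'.join(p)}@{i}"
            return None
        if typ == "terminal_loss":
            long = [a for a in current if len(a) >= 2]
            if not long:
                return None
            for _ in range(20):
                p = long[int(rng.integers(0, len(long)))]
                end = "head" if rng.integers(0, 2) else "tail"
                new = p[1:] if end == "head" else p[:-1]
                dropped = p[0] if end == "head" else p[-1]
                others = {d for a in arrs if a != p for d in a}
                # the dropped domain must survive elsewhere (else this would
                # also be a proteome-level domain loss) but not as its own
                # arrangement (else the change would read as a fission)
                if new in arrs or dropped not in others or (dropped,) in arrs:
                    continue
                arrs.discard(p)
                arrs.add(new)
                return new, f"{'-'.join(p)}|{end}"
            return None
        if typ == "terminal_emergence":
            p = current[int(rng.integers(0, len(current)))]
            d = novel_domain(pool)
            new = ((d,) + p) if rng.integers(0, 2) else (p + (d,))
            arrs.add(new)
            return new, d
        if typ == "single_domain_loss":
            standalone = [
                a for a in current
                if len(a) == 1 and not any(a[0] in b for b in arrs if b != a)
            ]
            if not standalone:
                return None
            victim = standalone[int(rng.integers(0, len(standalone)))]
            arrs.discard(victim)
            return victim, victim[0]
        if typ == "single_domain_emergence":
            d = novel_domain(pool)
            arrs.add((d,))
            return (d,), d
        raise ValueError(typ)

    for v in tree.preorder():
        if v == tree.root:
            continue
        p = tree.parent[v]
        t = tree.duration_my[v]
        parent_set = ArrangementSet.build(p, node_sets[p])
        attempt = 0
        while True:
            attempt += 1
            if attempt > config.max_retries:
                raise SimulationError(
                    f"branch to {v!r}: could not draw identifiable events "
                    f"after {config.max_retries} attempts"
                )
            pool = list(novel_pool)
            arrs = set(node_sets[p])
            planned: List[str] = []
            for typ in EVENT_TYPES:
                planned.extend([typ] * int(rng.poisson(rates[typ] * t)))
            order = rng.permutation(len(planned)) if planned else []
            branch_log: List[Tuple[str, str, str, str]] = []
            for idx in order:
                typ = planned[int(idx)]
                res = apply_event(typ, arrs, pool)
                if res is None:
                    continue  # not constructible in this state; dropped
                key, detail = res
                branch_log.append((v, typ, "-".join(key), detail))
            child_set = ArrangementSet.build(v, arrs)
            if _verify_branch(parent_set, child_set, branch_log):
                node_sets[v] = frozenset(arrs)
                novel_pool = pool
                log_rows.extend(branch_log)
                break

    out_sets = {v: ArrangementSet.build(v, node_sets[v]) for v in tree.preorder()}
    tips = {t: out_sets[t] for t in tree.tips}
    events = pd.DataFrame(log_rows, columns=["child", "type", "arrangement", "detail"])
    return tips, ArrangementGroundTruth(node_sets=out_sets, events=events)


def _verify_branch(
    parent: ArrangementSet,
    child: ArrangementSet,
    branch_log: List[Tuple[str, str, str, str]],
) -> bool:
    """True iff the classifier recovers exactly the logged events."""
    logged: Dict[Tuple[str, str], int] = {}
    for _, typ, arrangement, detail in branch_log:
        key = _event_key(typ, arrangement, detail)
        logged[key] = logged.get(key, 0) + 1

    recovered: Dict[Tuple[str, str], int] = {}
    fission_seen: set = set()
    for arr in sorted(child.arrangements - parent.arrangements):
        ev = classify_event(arr, parent, child)
        if ev.type in ("ambiguous", "unsolved"):
            return False
        if ev.type == "fission":
            source, split = ev.operands
            key = ("fission", f"{'-'.join(source)}@{split}")
            if key in fission_seen:
                continue  # sibling piece of an already-recovered split
            fission_seen.add(key)
        else:
            key = (ev.type, "-".join(arr))
        recovered[key] = recovered.get(key, 0) + 1
    for dom in parent.domains - child.domains:
        key = ("single_domain_loss", dom)
        recovered[key] = recovered.get(key, 0) + 1
    return recovered == logged
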