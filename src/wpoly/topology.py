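"""Per-window trees and topology weighting for group-level discordance.

Windows of a fixed SNP count get a neighbor-joining tree on pairwise
Hamming distances between sequences.  Each tree is decomposed, exactly
or by Monte-Carlo subsampling, into the proportion of one-tip-per-group
subtrees matching each possible unrooted group topology ("topology
weights"; five groups admit 15 topologies, n groups (2n-5)!!).  Windows
are then classified by majority weight into the species topology, the
plumage (morph-concordant) topology, or the residual incomplete-lineage-
sorting pool, with bootstrap CIs on the category proportions.

Topologies are encoded canonically as the frozenset of their non-trivial
leaf-set splits, which makes matching independent of newick rotation.
"""

from __future__ import annotations

import io as _io
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import MISSING, SiteTable

__all__ = [
    "enumerate_topologies",
    "topology_from_newick",
    "topology_to_newick",
    "window_tree",
    "topology_weights",
    "classify_window",
    "bootstrap_category_proportions",
    "TopologyWeighting",
]

CATEGORIES = ("Species", "Plumage", "ILS", "unresolved")


# ---------------------------------------------------------------------------
# topology enumeration and canonical encoding
# ---------------------------------------------------------------------------

def _splits_from_edges(edges: list[tuple], labels: Sequence[str]) -> frozenset:
    """Non-trivial splits of an unrooted tree given as an edge list."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    label_set = frozenset(labels)
    splits = set()
    for u, v in edges:
        # leaves reachable from v without crossing u
        seen, stack = {u, v}, [v]
        side = set()
        while stack:
            x = stack.pop()
            if x in label_set:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if v in label_set:
            side.add(v)
        a = frozenset(side)
        b = label_set - a
        if len(a) >= 2 and len(b) >= 2:
            splits.add(frozenset({a, b}))
    return frozenset(splits)


def enumerate_topologies(group_labels: Sequence[str]) -> list[frozenset]:
    """All unrooted binary topologies on the labels, canonically encoded.

    Returns a list of split-set keys; its length is (2n-5)!! (3 labels ->
    1, 4 -> 3, 5 -> 15, 6 -> 105).
    """
    labels = list(group_labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 group labels")
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    trees = [[("i0", labels[0]), ("i0", labels[1]), ("i0", labels[2])]]
    for k, lab in enumerate(labels[3:], start=1):
        new_trees = []
        for t in trees:
            for idx in range(len(t)):
                u, v = t[idx]
                inode = f"i{k}_{idx}"
                nt = t[:idx] + t[idx + 1:] + [(u, inode), (inode, v), (inode, lab)]
                new_trees.append(nt)
        trees = new_trees
    keys, seen = [], set()
    for t in trees:
        key = _splits_from_edges(t, labels)
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys


def _tree_splits(tree: TreeNode, label_set: frozenset) -> frozenset:
    """Non-trivial splits of a (possibly rooted) skbio tree on its tips."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        a = frozenset(t.name for t in node.tips())
        b = label_set - a
        if len(a) >= 2 and len(b) >= 2:
            splits.add(frozenset({a, b}))
    return frozenset(splits)


def topology_from_newick(newick: str) -> frozenset:
    """Canonical split-set key of a group-level topology given as newick."""
    tree = TreeNode.read(_io.StringIO(newick), convert_underscores=False)
    labels = frozenset(t.name for t in tree.tips())
    return _tree_splits(tree, labels)


def topology_to_newick(key: frozenset, labels: Sequence[str]) -> str:
    """Readable newick for a canonical topology key (labels as tips)."""
    # rebuild by matching against enumerated trees (n is small here)
    labels = list(labels)
    trees = [[("i0", labels[0]), ("i0", labels[1]), ("i0", labels[2])]]
    for k, lab in enumerate(labels[3:], start=1):
        trees = [
            t[:idx] + t[idx + 1:] + [(u, f"i{k}_{idx}"), (f"i{k}_{idx}", v), (f"i{k}_{idx}", lab)]
            for t in trees
            for idx, (u, v) in enumerate(t)
        ]
    for t in trees:
        if _splits_from_edges(t, labels) == key:
            adj: dict = {}
            for u, v in t:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)

            def sub(node, parent):
                kids = [c for c in adj[node] if c != parent]
                if not kids:
                    return str(node)
                return "(" + ",".join(sub(c, node) for c in kids) + ")"

            return sub("i0", None) + ";"
    raise ValueError("key does not correspond to a topology on these labels")


# ---------------------------------------------------------------------------
# per-window trees
# ---------------------------------------------------------------------------

def window_tree(genotypes: np.ndarray, names: Sequence[str]) -> TreeNode | None:
    """Neighbor-joining tree on Hamming distances for one SNP block.

    ``genotypes`` is (n_sites, n_sequences) with entries 0/1/missing;
    distance is the proportion of differing alleles over sites called in
    both sequences.  Returns None when any pair shares no called site.
    """
    g = np.asarray(genotypes)
    n = g.shape[1]
    if n < 4:
        raise ValueError("need at least 4 sequences for an unrooted topology")
    called = g != MISSING
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                return None
            dm[i, j] = dm[j, i] = float((g[both, i] != g[both, j]).mean())
    return nj(DistanceMatrix(dm, ids=list(names)))


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

def topology_weights(
    tree: TreeNode,
    group_map: Mapping[str, str],
    topologies: list[frozenset] | None = None,
    group_order: Sequence[str] | None = None,
    exhaustive_limit: int = 20_000,
    n_samples: int = 2_000,
    seed: int = 0,
) -> np.ndarray:
    """Weight of each group topology among one-tip-per-group subtrees.

    Iterates over combinations of one tip per group (all of them when
    their number is at most ``exhaustive_limit``, otherwise a Monte-Carlo
    sample of ``n_samples``), reduces the tree to the chosen tips and
    tallies the induced unrooted topology.  Weights are non-negative and
    sum to one.
    """
    tips_by_group: dict[str, list[str]] = {}
    tip_names = [t.name for t in tree.tips()]
    for t in tip_names:
        if t not in group_map:
            raise ValueError(f"tip {t!r} has no group assignment")
        tips_by_group.setdefault(group_map[t], []).append(t)
    groups = list(group_order) if group_order else sorted(tips_by_group)
    for g in groups:
        if not tips_by_group.get(g):
            raise ValueError(f"group {g!r} has no tips in the tree")
    if topologies is None:
        topologies = enumerate_topologies(groups)
    index = {key: i for i, key in enumerate(topologies)}

    # tip sets below each internal edge, with tips mapped to groups later
    edge_sides = []
    all_tips = frozenset(tip_names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(all_tips) - 2:
            edge_sides.append(side)
    edge_sides = list(dict.fromkeys(edge_sides))

    def induced_key(chosen: dict[str, str]) -> frozenset:
        # chosen: tip -> group label; one per group
        chosen_set = set(chosen)
        k = len(chosen_set)
        splits = set()
        for side in edge_sides:
            a = chosen_set & side
            if 2 <= len(a) <= k - 2:
                ga = frozenset(chosen[t] for t in a)
                gb = frozenset(chosen[t] for t in chosen_set - a)
                splits.add(frozenset({ga, gb}))
        return frozenset(splits)

    counts = np.zeros(len(topologies))
    sizes = [len(tips_by_group[g]) for g in groups]
    total = int(np.prod(sizes))
    if total <= exhaustive_limit:
        for combo in itertools.product(*(tips_by_group[g] for g in groups)):
            chosen = dict(zip(combo, groups))
            counts[index[induced_key(chosen)]] += 1
        denom = total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            combo = [tips_by_group[g][rng.integers(len(tips_by_group[g]))] for g in groups]
            chosen = dict(zip(combo, groups))
            counts[index[induced_key(chosen)]] += 1
        denom = n_samples
    return counts / denom


def classify_window(
    weights: np.ndarray,
    topologies: list[frozenset],
    species_topology: frozenset,
    plumage_topology: frozenset,
    threshold: float = 0.5,
    ils_mode: str = "summed",
) -> str:
    """Majority-consensus category of one window.

    ``Species`` when the species-topology weight reaches the threshold
    (inclusive), else ``Plumage``, else ``ILS`` when the remaining
    topologies jointly (default) or any single one (``ils_mode='single'``)
    reach it; otherwise ``unresolved``.
    """
    index = {key: i for i, key in enumerate(topologies)}
    try:
        i_sp = index[species_topology]
        i_pl = index[plumage_topology]
    except KeyError:
        raise ValueError("reference topology not in the enumerated set") from None
    if weights[i_sp] >= threshold:
        return "Species"
    if weights[i_pl] >= threshold:
        return "Plumage"
    rest = np.delete(weights, [i_sp, i_pl])
    ils = rest.sum() if ils_mode == "summed" else (rest.max() if len(rest) else 0.0)
    if ils >= threshold:
        return "ILS"
    return "unresolved"


def bootstrap_category_proportions(
    categories: Sequence[str], B: int = 1000, seed: int = 0,
    include_unresolved: bool = True,
) -> pd.DataFrame:
    """Percentile-bootstrap mean and 95% CI of each category proportion."""
    cats = [c for c in categories if include_unresolved or c != "unresolved"]
    if not cats:
        raise ValueError("no classified windows")
    arr = np.asarray(cats, dtype=object)
    rng = np.random.default_rng(seed)
    levels = [c for c in CATEGORIES if c in set(arr)] or sorted(set(arr))
    boot = np.zeros((B, len(levels)))
    n = len(arr)
    for b in range(B):
        take = arr[rng.integers(0, n, size=n)]
        for j, lv in enumerate(levels):
            boot[b, j] = np.mean(take == lv)
    rows = []
    for j, lv in enumerate(levels):
        rows.append(
            dict(category=lv, proportion=float(np.mean(arr == lv)),
                 boot_mean=boot[:, j].mean(),
                 ci_low=np.percentile(boot[:, j], 2.5),
                 ci_high=np.percentile(boot[:, j], 97.5))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator object
# ---------------------------------------------------------------------------

class TopologyWeighting:
    """Windowed topology-weighting analysis over a site table.

    Sequences (haplotypes) are grouped by sample metadata columns into
    group labels (default ``species_morph``); windows of ``window_snps``
    SNPs that pass the per-individual completeness rule get an NJ tree
    and a weight vector over all group topologies.
    """

    def __init__(
        self,
        sites: SiteTable,
        meta: pd.DataFrame,
        groups: Mapping[str, Sequence[str]],
        species_topology: str | frozenset,
        plumage_topology: str | frozenset,
        window_snps: int = 100,
        min_scored: int = 10,
        threshold: float = 0.5,
        ils_mode: str = "summed",
        exhaustive_limit: int = 20_000,
        n_samples: int = 2_000,
        seed: int = 0,
    ):
        self.sites = sites
        self.meta = meta
        self.groups = {g: list(v) for g, v in groups.items()}
        self.window_snps = window_snps
        self.min_scored = min_scored
        self.threshold = threshold
        self.ils_mode = ils_mode
        self.exhaustive_limit = exhaustive_limit
        self.n_samples = n_samples
        self.seed = seed
        self.topologies = enumerate_topologies(sorted(self.groups))
        self.species_key = (
            topology_from_newick(species_topology)
            if isinstance(species_topology, str) else species_topology
        )
        self.plumage_key = (
            topology_from_newick(plumage_topology)
            if isinstance(plumage_topology, str) else plumage_topology
        )

    def fit(self) -> "TopologyWeightingResults":
        ids = [s for g in sorted(self.groups) for s in self.groups[g]]
        geno, names = self.sites.haplotypes(ids)
        group_map = {}
        for g, samples in self.groups.items():
            for nm in names:
                if nm.rsplit("/", 1)[0] in samples:
                    group_map[nm] = g
        n_sites = geno.shape[0]
        rows, weight_rows, skipped = [], [], 0
        for start in range(0, n_sites - self.window_snps + 1, self.window_snps):
            block = geno[start : start + self.window_snps]
            scored = (block != MISSING).sum(axis=0)
            if scored.min() < self.min_scored:
                skipped += 1
                continue
            tree = window_tree(block, names)
            if tree is None:
                skipped += 1
                continue
            w = topology_weights(
                tree, group_map, self.topologies, sorted(self.groups),
                self.exhaustive_limit, self.n_samples, self.seed,
            )
            cat = classify_window(
                w, self.topologies, self.species_key, self.plumage_key,
                self.threshold, self.ils_mode,
            )
            rows.append(
                dict(
                    chrom=self.sites.chrom[start],
                    start_pos=int(self.sites.pos[start]),
                    end_pos=int(self.sites.pos[start + self.window_snps - 1]),
                    n_snps=self.window_snps,
                    category=cat,
                )
            )
            weight_rows.append(w)
        table = pd.DataFrame(rows)
        weights = (
            np.vstack(weight_rows) if weight_rows
            else np.empty((0, len(self.topologies)))
        )
        return TopologyWeightingResults(self, table, weights, skipped)


@dataclass
class TopologyWeightingResults:
    model: TopologyWeighting
    table: pd.DataFrame
    weights: np.ndarray
    n_skipped: int

    def category_proportions(self, B: int = 1000, seed: int = 0,
                             include_unresolved: bool = True) -> pd.DataFrame:
        return bootstrap_category_proportions(
            list(self.table["category"]), B=B, seed=seed,
            include_unresolved=include_unresolved,
        )

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            f"Topology weighting: {n} windows of {self.model.window_snps} SNPs "
            f"({self.n_skipped} skipped), {len(self.model.topologies)} topologies",
        ]
        if n:
            for cat, k in self.table["category"].value_counts().items():
                lines.append(f"  {cat:>10s}: {k} ({k / n:.1%})")
        return "\n".join(lines)
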