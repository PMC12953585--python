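"""Window gene trees and exact topology weighting over population groups.

Local genealogies are summarized in consecutive 100-SNP windows by
neighbor-joining trees on haplotype p-distances; each window tree is then
decomposed, twisst-style, into weights over all possible unrooted
topologies of the population groups: iterate every combination of one
tip per group, prune the tree to those tips, and count which group-level
topology the induced tree matches. Weights are exact (the full Cartesian
product, no subsampling) and sum to 1 per window.

Windows carry the bp-overlap-weighted local recombination rate so that
weights can be stratified into low (<0.2), medium (0.2-2) and high
(>2 cM/Mb) recombination classes — the axis the analyses use to separate
introgressed from historical phylogenetic signal.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .cohort import Cohort, CohortError, PopulationMap, RecombinationMap

logger = logging.getLogger(__name__)

MAX_COMBINATIONS = 10**6
_ZERO_EPS = 1e-12


@dataclass
class SnpWindow:
    chrom: str
    first: int  # global site index, inclusive
    last: int  # global site index, inclusive
    start: int  # bp, half-open span
    end: int
    n_snps: int
    mean_recomb_rate: float


@dataclass
class StratificationConfig:
    """Recombination-rate boundaries (cM/Mb); both boundaries go to medium."""

    low: float = 0.2
    high: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise CohortError("need 0 < low < high")

    def stratum_of(self, rate: float) -> str:
        if rate < self.low:
            return "low"
        if rate <= self.high:
            return "medium"
        return "high"


def make_snp_windows(
    cohort: Cohort, recomb_map: RecombinationMap, window_snps: int = 100
) -> list[SnpWindow]:
    """Consecutive disjoint ``window_snps``-SNP windows per chromosome.

    The terminal remainder of each chromosome (fewer than ``window_snps``
    SNPs) is dropped, as in twisst-style pipelines.
    """
    if window_snps < 2:
        raise CohortError("window_snps must be >= 2")
    windows: list[SnpWindow] = []
    n_dropped = 0
    for ci, chrom in enumerate(cohort.chrom_ids):
        idx = np.flatnonzero(cohort.chrom_index == ci)
        n_full = len(idx) // window_snps
        n_dropped += len(idx) - n_full * window_snps
        for w in range(n_full):
            block = idx[w * window_snps : (w + 1) * window_snps]
            start = int(cohort.positions[block[0]])
            end = int(cohort.positions[block[-1]]) + 1
            windows.append(
                SnpWindow(
                    chrom=chrom,
                    first=int(block[0]),
                    last=int(block[-1]),
                    start=start,
                    end=end,
                    n_snps=window_snps,
                    mean_recomb_rate=recomb_map.mean_rate_in(chrom, start, end),
                )
            )
    if n_dropped:
        logger.info("make_snp_windows dropped %d terminal SNPs", n_dropped)
    return windows


# ---------------------------------------------------------------------------
# window trees
# ---------------------------------------------------------------------------


def haplotype_matrix(
    cohort: Cohort, window: SnpWindow, samples: list[str]
) -> tuple[np.ndarray, list[str]]:
    """(2*n_samples, n_snps) haplotype alleles (-1 missing) and tip names."""
    sel = slice(window.first, window.last + 1)
    names: list[str] = []
    rows: list[np.ndarray] = []
    for s in samples:
        j = cohort.sample_index(s)
        for h in range(2):
            rows.append(cohort.gt[sel, j, h])
            names.append(f"{s}_{'A' if h == 0 else 'B'}")
    return np.array(rows, dtype=np.int8), names


def _collapse_zero_branches(tree: TreeNode) -> TreeNode:
    """Suppress internal edges of length <= 0, producing multifurcations."""
    for node in list(tree.postorder()):
        if node.is_tip() or node.is_root():
            if node.length is not None and node.length < 0:
                node.length = 0.0
            continue
        if node.length is not None and node.length <= _ZERO_EPS:
            parent = node.parent
            for child in list(node.children):
                node.remove(child)
                parent.append(child)
            parent.remove(node)
    return tree


def infer_window_tree(
    cohort: Cohort, window: SnpWindow, samples: list[str]
) -> TreeNode:
    """Neighbor-joining tree on haplotype p-distances within one window.

    Distances are the proportion of differing alleles among
    pairwise-complete sites. Tips are the two phased haplotypes of each
    sample, named ``SAMPLE_A``/``SAMPLE_B`` and sorted lexicographically
    before joining, so the result is deterministic. Zero-length internal
    branches are collapsed, so windows without signal yield
    multifurcating (ultimately star) trees.
    """
    H, names = haplotype_matrix(cohort, window, samples)
    called = H >= 0
    if (~called).all(axis=1).any():
        bad = [n for n, row in zip(names, called) if not row.any()]
        raise CohortError(f"haplotypes with all-missing window sites: {bad}")
    order = np.argsort(names)
    H, names = H[order], [names[i] for i in order]
    called = H >= 0
    both = called[:, None, :] & called[None, :, :]
    diff = (H[:, None, :] != H[None, :, :]) & both
    n_both = both.sum(axis=2)
    if (n_both == 0).any():
        raise CohortError("a haplotype pair shares no called window sites")
    dm = diff.sum(axis=2) / n_both
    np.fill_diagonal(dm, 0.0)
    tree = nj(DistanceMatrix(dm, names))
    return _collapse_zero_branches(tree)


# ---------------------------------------------------------------------------
# topology catalog
# ---------------------------------------------------------------------------


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


class _UnrootedTree:
    """Minimal adjacency-list unrooted tree used only for enumeration."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.label: dict[int, str] = {}
        self._next = 0

    def _new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.label[nid] = label
        return nid

    @classmethod
    def star3(cls, labels: tuple[str, str, str]) -> "_UnrootedTree":
        t = cls()
        center = t._new_node()
        for lab in labels:
            tip = t._new_node(lab)
            t.adj[center].add(tip)
            t.adj[tip].add(center)
        return t

    def copy(self) -> "_UnrootedTree":
        t = _UnrootedTree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.label = dict(self.label)
        t._next = self._next
        return t

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def insert_leaf(self, edge: tuple[int, int], label: str) -> None:
        u, v = edge
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        mid = self._new_node()
        tip = self._new_node(label)
        for a, b in ((u, mid), (v, mid), (tip, mid)):
            self.adj[a].add(b)
            self.adj[b].add(a)

    def _tips_below(self, node: int, parent: int) -> frozenset[str]:
        if node in self.label:
            return frozenset([self.label[node]])
        out: set[str] = set()
        for nb in self.adj[node]:
            if nb != parent:
                out |= self._tips_below(nb, node)
        return frozenset(out)

    def splits(self) -> frozenset[frozenset[str]]:
        """Canonical nontrivial splits (side not containing the min label)."""
        labels = frozenset(self.label.values())
        anchor = min(labels)
        k = len(labels)
        out: set[frozenset[str]] = set()
        for u, v in self.edges():
            side = self._tips_below(u, v)
            if anchor in side:
                side = labels - side
            if 2 <= len(side) <= k - 2:
                out.add(side)
        return frozenset(out)

    def newick(self) -> str:
        anchor = min(self.label.values())
        anchor_id = next(i for i, lab in self.label.items() if lab == anchor)
        root = next(iter(self.adj[anchor_id]))

        def render(node: int, parent: int) -> str:
            if node in self.label:
                return self.label[node]
            parts = sorted(render(nb, node) for nb in self.adj[node] if nb != parent)
            return "(" + ",".join(parts) + ")"

        parts = sorted(render(nb, root) for nb in self.adj[root] if nb != anchor_id)
        return "(" + ",".join(parts + [anchor]) + ");"


@dataclass
class TopologyEntry:
    index: int
    splits: frozenset[frozenset[str]]
    newick: str


@dataclass
class TopologyCatalog:
    """All distinct unrooted leaf-labeled binary topologies on the groups."""

    groups: tuple[str, ...]
    entries: list[TopologyEntry]
    _by_splits: dict[frozenset, int] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def index_of(self, splits: frozenset[frozenset[str]]) -> int:
        return self._by_splits[splits]

    def compatible_with(self, splits: frozenset[frozenset[str]]) -> list[int]:
        """Entries refining a (possibly multifurcating) split set."""
        return [e.index for e in self.entries if splits <= e.splits]


def enumerate_topologies(groups: list[str] | tuple[str, ...]) -> TopologyCatalog:
    """Enumerate the (2k-5)!! unrooted binary topologies on k groups.

    k = 5 gives the 15 topologies of four population groups plus an
    outgroup; k = 6 gives 105.
    """
    groups = tuple(groups)
    k = len(groups)
    if not (3 <= k <= 7):
        raise CohortError("group count must be between 3 and 7")
    if len(set(groups)) != k:
        raise CohortError("duplicate group names")
    trees = [_UnrootedTree.star3(tuple(groups[:3]))]
    for lab in groups[3:]:
        nxt = []
        for t in trees:
            for e in t.edges():
                t2 = t.copy()
                t2.insert_leaf(e, lab)
                nxt.append(t2)
        trees = nxt
    assert len(trees) == _double_factorial(2 * k - 5)
    entries: list[TopologyEntry] = []
    by_splits: dict[frozenset, int] = {}
    for t in trees:
        s = t.splits()
        if s in by_splits:  # pragma: no cover - enumeration yields no duplicates
            raise AssertionError("duplicate topology generated")
        idx = len(entries)
        by_splits[s] = idx
        entries.append(TopologyEntry(idx, s, t.newick()))
    return TopologyCatalog(groups, entries, by_splits)


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------


def _edge_sides(tree: TreeNode) -> list[frozenset[str]]:
    """Tip-name sets below each edge of the (rooted representation of a) tree."""
    sides = []
    for node in tree.postorder(include_self=False):
        sides.append(frozenset(t.name for t in node.tips()) or frozenset([node.name]))
    return sides


def weight_topologies(
    tree: TreeNode,
    tip_groups: dict[str, str],
    catalog: TopologyCatalog,
    max_combinations: int = MAX_COMBINATIONS,
) -> np.ndarray:
    """Exact twisst weights of ``tree`` over the catalog's topologies.

    Iterates the full Cartesian product of one tip per group, reads off
    the induced group-level topology from the tree's splits, and counts
    matches; an unresolved (multifurcating) induced topology distributes
    its count equally over all compatible binary topologies. Returns the
    normalized weight vector (sums to 1).
    """
    k = len(catalog.groups)
    anchor = min(catalog.groups)
    all_groups = frozenset(catalog.groups)
    tips_by_group: dict[str, list[str]] = {g: [] for g in catalog.groups}
    tip_names = {t.name for t in tree.tips()}
    for tip, group in tip_groups.items():
        if tip in tip_names and group in tips_by_group:
            tips_by_group[group].append(tip)
    for g, tips in tips_by_group.items():
        if not tips:
            raise CohortError(f"group {g!r} has no tips in the tree")
    n_combos = int(np.prod([len(t) for t in tips_by_group.values()], dtype=object))
    if n_combos > max_combinations:
        raise CohortError(f"{n_combos} combinations exceed the cap {max_combinations}")

    sides = _edge_sides(tree)
    group_of = dict(tip_groups)
    weights = np.zeros(len(catalog))
    for combo in itertools.product(*(tips_by_group[g] for g in catalog.groups)):
        selected = frozenset(combo)
        splits: set[frozenset[str]] = set()
        for side in sides:
            inter = selected & side
            if 2 <= len(inter) <= k - 2:
                gs = frozenset(group_of[t] for t in inter)
                if anchor in gs:
                    gs = all_groups - gs
                if 2 <= len(gs) <= k - 2:
                    splits.add(gs)
        fsplits = frozenset(splits)
        if len(fsplits) == k - 3:
            weights[catalog.index_of(fsplits)] += 1.0
        else:
            comp = catalog.compatible_with(fsplits)
            weights[comp] += 1.0 / len(comp)
    return weights / n_combos


def window_weights(
    cohort: Cohort,
    popmap: PopulationMap,
    windows: list[SnpWindow],
    catalog: TopologyCatalog,
    samples: list[str] | None = None,
) -> np.ndarray:
    """Stack of per-window weight vectors (n_windows x n_topologies).

    ``samples`` restricts which individuals contribute haplotypes; by
    default every sample whose population is one of the catalog groups
    contributes both haplotypes.
    """
    if samples is None:
        samples = [
            s for s in cohort.sample_ids if popmap.population_of(s) in catalog.groups
        ]
    tip_groups = {}
    for s in samples:
        for suffix in ("_A", "_B"):
            tip_groups[s + suffix] = popmap.population_of(s)
    out = np.empty((len(windows), len(catalog)))
    for i, w in enumerate(windows):
        tree = infer_window_tree(cohort, w, samples)
        out[i] = weight_topologies(tree, tip_groups, catalog)
    return out


@dataclass
class StratumSummary:
    stratum: str
    n_windows: int
    mean_weights: np.ndarray | None  # None when the stratum is empty


def stratify_weights(
    weights: np.ndarray,
    windows: list[SnpWindow],
    config: StratificationConfig | None = None,
) -> dict[str, StratumSummary]:
    """Unweighted mean weight vector per recombination stratum.

    Windows partition into low [0, 0.2), medium [0.2, 2] and high (2, inf)
    cM/Mb; empty strata are reported with count 0 and no mean.
    """
    config = config or StratificationConfig()
    rates = np.array([w.mean_recomb_rate for w in windows])
    out: dict[str, StratumSummary] = {}
    for stratum in ("low", "medium", "high"):
        mask = np.array([config.stratum_of(r) == stratum for r in rates], dtype=bool)
        if mask.any():
            out[stratum] = StratumSummary(stratum, int(mask.sum()), weights[mask].mean(axis=0))
        else:
            warnings.warn(f"empty recombination stratum {stratum!r}", stacklevel=2)
            out[stratum] = StratumSummary(stratum, 0, None)
    return out


def weights_frame(
    weights: np.ndarray, windows: list[SnpWindow], catalog: TopologyCatalog
) -> pd.DataFrame:
    cols = {f"topo{e.index}": weights[:, e.index] for e in catalog.entries}
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "recomb_rate": [w.mean_recomb_rate for w in windows],
            **cols,
        }
    )
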