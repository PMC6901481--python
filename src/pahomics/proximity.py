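"""Network proximity between two protein sets and its permutation null.

Proximity is the average shortest-path hop length over all cross-pairs
between the two sets ("Shortest" variant),

    d_AB = (1 / (|A| * |B|)) * sum_{a in A, b in B} d(a, b),

with |A|, |B| the counts of members mapped into the analysis graph.
Significance comes from a degree-preserving permutation null: both sets are
re-drawn at each iteration from degree bins matching the observed sets'
degree distributions, giving a null mean, SD, z-score and an empirical
one-sided p-value (smaller distance = closer). A Fisher's-exact overlap test
is provided as the contrasting, topology-blind comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .interactome import (DegreeBins, Interactome, distance_matrix,
                          largest_connected_component, make_degree_bins)

logger = logging.getLogger(__name__)


class ProximityError(ValueError):
    pass


@dataclass
class NodeSet:
    """A labelled set of protein identifiers to map onto the interactome."""

    label: str
    members: frozenset[str]

    def __init__(self, label: str, members: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "members", frozenset(str(m) for m in members))

    def mapped(self, net: Interactome) -> list[str]:
        """Members present in the graph, sorted; logs any dropped members."""
        inside = sorted(m for m in self.members if net.has_node(m))
        dropped = len(self.members) - len(inside)
        if dropped:
            logger.info("node set %r: %d member(s) not in graph dropped",
                        self.label, dropped)
        return inside

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ProximityResult:
    """Observed proximity with its degree-preserving permutation null."""

    d_obs: float
    null_mean: float
    null_sd: float
    z: float | None
    p_emp: float
    n_perm: int
    n_pairs_used: int
    dropped_pairs: int
    n_a: int
    n_b: int
    label_a: str = ""
    label_b: str = ""
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "d_obs": self.d_obs, "null_mean": self.null_mean,
            "null_sd": self.null_sd, "z": self.z, "p_emp": self.p_emp,
            "n_perm": self.n_perm, "n_pairs_used": self.n_pairs_used,
            "dropped_pairs": self.dropped_pairs, "n_a": self.n_a,
            "n_b": self.n_b, "label_a": self.label_a, "label_b": self.label_b,
            "seed": self.seed,
        }


def _pairwise_mean(dist_block: np.ndarray, allow_disconnected: bool
                   ) -> tuple[float, int, int]:
    """Mean over a distance block; optionally drop unreachable pairs."""
    finite = np.isfinite(dist_block)
    n_total = dist_block.size
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ProximityError("no reachable cross-pairs between the two sets")
    if n_finite < n_total and not allow_disconnected:
        raise ProximityError(
            f"{n_total - n_finite} unreachable pair(s); restrict to the "
            "largest connected component or pass allow_disconnected=True")
    return float(dist_block[finite].mean()), n_finite, n_total - n_finite


class ProximityAnalysis:
    """Precomputes all-pairs distances and degree bins on one graph so that
    repeated proximity and permutation-test calls are cheap."""

    def __init__(self, net: Interactome, *, use_lcc: bool = True,
                 min_bin_size: int | None = None,
                 allow_disconnected: bool = False):
        if use_lcc:
            lcc = largest_connected_component(net)
            if lcc.n_nodes < net.n_nodes:
                logger.info("restricted to largest connected component: "
                            "%d of %d nodes", lcc.n_nodes, net.n_nodes)
            net = lcc
        self.net = net
        self.allow_disconnected = allow_disconnected
        self._dist, self._index = distance_matrix(net)
        self._order = net.sorted_nodes()
        self.bins: DegreeBins = make_degree_bins(net, min_bin_size)
        self._bin_indices = [
            np.array([self._index[n] for n in members], dtype=np.intp)
            for (_rng, members) in self.bins.bins
        ]
        degs = net.degrees()
        self._node_bin = {n: self.bins.bin_of(d) for n, d in degs.items()}

    def _map_indices(self, node_set: NodeSet) -> np.ndarray:
        mapped = node_set.mapped(self.net)
        if not mapped:
            raise ProximityError(
                f"node set {node_set.label!r} has no members in the graph")
        return np.array([self._index[n] for n in mapped], dtype=np.intp)

    def proximity(self, a: NodeSet, b: NodeSet) -> float:
        ia, ib = self._map_indices(a), self._map_indices(b)
        d, _, _ = _pairwise_mean(self._dist[np.ix_(ia, ib)],
                                 self.allow_disconnected)
        return d

    def _bin_counts(self, idx: np.ndarray) -> np.ndarray:
        counts = np.zeros(len(self.bins), dtype=np.intp)
        for i in idx:
            counts[self._node_bin[self._order[i]]] += 1
        return counts

    def sample_matched(self, counts: np.ndarray, rng: np.random.Generator
                       ) -> np.ndarray:
        """Draw one degree-matched random index set (without replacement
        within each bin)."""
        parts = []
        for b, c in enumerate(counts):
            if c == 0:
                continue
            pool = self._bin_indices[b]
            if c > len(pool):
                lo, hi = self.bins.bins[b][0]
                raise ProximityError(
                    f"degree bin [{lo}, {hi}] holds {len(pool)} node(s) but "
                    f"{c} are required; rebuild with a larger min_bin_size")
            parts.append(rng.choice(pool, size=int(c), replace=False))
        return np.concatenate(parts)

    def permutation_test(self, a: NodeSet, b: NodeSet, n_perm: int = 10_000,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         fix_a: bool = False,
                         two_sided: bool = False) -> ProximityResult:
        if n_perm < 100:
            raise ProximityError("n_perm must be at least 100")
        if rng is None:
            rng = np.random.default_rng(seed)
        ia, ib = self._map_indices(a), self._map_indices(b)
        d_obs, n_used, dropped = _pairwise_mean(self._dist[np.ix_(ia, ib)],
                                                self.allow_disconnected)
        cb = self._bin_counts(ib)
        null = np.empty(n_perm)
        if fix_a:
            # literature variant: only B re-drawn, independently of A
            for i in range(n_perm):
                rb = self.sample_matched(cb, rng)
                null[i], _, _ = _pairwise_mean(self._dist[np.ix_(ia, rb)],
                                               self.allow_disconnected)
        else:
            # both sets re-drawn jointly, preserving each set's size and
            # degree distribution AND the observed overlap between them, so
            # d(v, v) = 0 pairs occur in the null exactly as often as in
            # the observed configuration
            shared = np.intersect1d(ia, ib)
            a_only = np.setdiff1d(ia, shared)
            b_only = np.setdiff1d(ib, shared)
            cs = self._bin_counts(shared)
            ca_only = self._bin_counts(a_only)
            cb_only = self._bin_counts(b_only)
            totals = cs + ca_only + cb_only
            for i in range(n_perm):
                ra_parts, rb_parts = [], []
                for bi, total in enumerate(totals):
                    if total == 0:
                        continue
                    pool = self._bin_indices[bi]
                    if total > len(pool):
                        lo, hi = self.bins.bins[bi][0]
                        raise ProximityError(
                            f"degree bin [{lo}, {hi}] holds {len(pool)} "
                            f"node(s) but {total} are required; rebuild "
                            "with a larger min_bin_size")
                    draw = rng.choice(pool, size=int(total), replace=False)
                    n_s, n_a = int(cs[bi]), int(ca_only[bi])
                    ra_parts.append(draw[:n_s + n_a])
                    rb_parts.append(np.concatenate([draw[:n_s],
                                                    draw[n_s + n_a:]]))
                ra = np.concatenate(ra_parts)
                rb = np.concatenate(rb_parts)
                null[i], _, _ = _pairwise_mean(self._dist[np.ix_(ra, rb)],
                                               self.allow_disconnected)
        null_mean, null_sd, z, p_emp = summarize_null(d_obs, null,
                                                      two_sided=two_sided)
        return ProximityResult(
            d_obs=d_obs, null_mean=null_mean, null_sd=null_sd, z=z,
            p_emp=p_emp, n_perm=n_perm, n_pairs_used=n_used,
            dropped_pairs=dropped, n_a=len(ia), n_b=len(ib),
            label_a=a.label, label_b=b.label, seed=seed)


def summarize_null(d_obs: float, null: np.ndarray, *, two_sided: bool = False
                   ) -> tuple[float, float, float | None, float]:
    """Null mean/SD, z-score and add-one empirical p from a null sample.

    The one-sided p counts null distances <= observed (closer-than-random);
    the +1 correction keeps p >= 1/(n_perm+1), so 10,000 permutations floor
    at ~0.0001. A degenerate null (SD = 0) leaves z undefined.
    """
    n_perm = len(null)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (d_obs - null_mean) / null_sd if null_sd > 0 else None
    p_lower = (int((null <= d_obs).sum()) + 1) / (n_perm + 1)
    if two_sided:
        p_upper = (int((null >= d_obs).sum()) + 1) / (n_perm + 1)
        p_emp = min(1.0, 2.0 * min(p_lower, p_upper))
    else:
        p_emp = min(1.0, p_lower)
    return null_mean, null_sd, z, p_emp


def network_proximity(net: Interactome, a: NodeSet, b: NodeSet, *,
                      use_lcc: bool = False,
                      allow_disconnected: bool = False) -> float:
    """Average shortest-path hop distance over all mapped cross-pairs.

    A node appearing in both sets contributes d(v, v) = 0 pairs. By default
    the graph is used as given and unreachable pairs raise; pass
    ``use_lcc=True`` to restrict to the largest component first, or
    ``allow_disconnected=True`` to drop unreachable pairs from the average.
    """
    analysis = ProximityAnalysis(net, use_lcc=use_lcc, min_bin_size=1,
                                 allow_disconnected=allow_disconnected)
    return analysis.proximity(a, b)


def degree_preserving_sample(net: Interactome, template: NodeSet,
                             bins: DegreeBins, rng: np.random.Generator
                             ) -> NodeSet:
    """Random node set matching the template's size and degree distribution:
    one uniform draw without replacement from each member's degree bin."""
    mapped = template.mapped(net)
    if not mapped:
        raise ProximityError(
            f"template {template.label!r} has no members in the graph")
    degs = net.degrees()
    needed: dict[int, int] = {}
    for n in mapped:
        b = bins.bin_of(degs[n])
        needed[b] = needed.get(b, 0) + 1
    sampled: list[str] = []
    for b in sorted(needed):
        pool = bins.members(b)
        c = needed[b]
        if c > len(pool):
            lo, hi = bins.bins[b][0]
            raise ProximityError(
                f"degree bin [{lo}, {hi}] holds {len(pool)} node(s) but {c} "
                f"are required; rebuild with a larger min_bin_size")
        picked = rng.choice(len(pool), size=c, replace=False)
        sampled.extend(pool[i] for i in picked)
    return NodeSet(label=f"{template.label}_null", members=sampled)


def permutation_test(net: Interactome, a: NodeSet, b: NodeSet,
                     n_perm: int = 10_000, seed: int | None = None, *,
                     min_bin_size: int | None = None, use_lcc: bool = True,
                     fix_a: bool = False, two_sided: bool = False,
                     allow_disconnected: bool = False) -> ProximityResult:
    """One-shot degree-preserving permutation test (both sets re-sampled
    each iteration unless ``fix_a``)."""
    analysis = ProximityAnalysis(net, use_lcc=use_lcc,
                                 min_bin_size=min_bin_size,
                                 allow_disconnected=allow_disconnected)
    return analysis.permutation_test(a, b, n_perm=n_perm, seed=seed,
                                     fix_a=fix_a, two_sided=two_sided)


def overlap_fisher(a: NodeSet, b: NodeSet, universe) -> tuple[int, float]:
    """Two-sided Fisher's exact test of set overlap within a universe.

    ``universe`` may be an integer count or an explicit set of identifiers
    (sets are then intersected with it first). Returns (overlap, p).
    """
    if isinstance(universe, int):
        n_universe = universe
        mem_a, mem_b = set(a.members), set(b.members)
    else:
        uni = set(universe)
        n_universe = len(uni)
        mem_a, mem_b = set(a.members) & uni, set(b.members) & uni
    if len(mem_a) > n_universe or len(mem_b) > n_universe:
        raise ProximityError("set larger than the universe")
    k = len(mem_a & mem_b)
    table = [[k, len(mem_a) - k],
             [len(mem_b) - k, n_universe - len(mem_a) - len(mem_b) + k]]
    if min(min(row) for row in table) < 0:
        raise ProximityError("overlap table is infeasible for this universe")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return k, float(p)
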