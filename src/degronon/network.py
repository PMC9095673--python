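"""Interactome-level co-degradation analysis.

Physically interacting proteins tend to have correlated half-lives; groups
of interacting, functionally coherent proteins whose half-lives are mutually
similar form co-degrading modules ("degronons").  Operationally a degronon
is a shortest network path in which every member has Biological Process
semantic similarity >= 0.6 to the first member; paths of length >= 6 hops
are reported.

Half-life ratios are always min/max of the two values (in (0, 1]) and are
never computed across different half-life datasets.  Pairs fall into three
categories: similar (0.8-1.0], different [0.5-0.8) and very different
(0-0.5); a ratio exactly on a printed boundary goes to the upper category.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .stats import spearman

logger = logging.getLogger(__name__)

SIMILAR_BOUNDARY = 0.8
DIFFERENT_BOUNDARY = 0.5

DEFAULT_SEMSIM_CUTOFF = 0.6
DEFAULT_MIN_LENGTH = 6
DEFAULT_N_RANDOM = 10

RATIO_BINS = np.linspace(0.0, 1.0, 11)  # ten equal ratio bins over (0, 1]


class RatioCategory(str, Enum):
    SIMILAR = "similar"
    DIFFERENT = "different"
    VERY_DIFFERENT = "very_different"


class HalfLifeUnits(str, Enum):
    RELATIVE = "relative"
    MINUTES = "minutes"


@dataclass
class HalfLifeTable:
    values: dict[str, float]
    units: HalfLifeUnits = HalfLifeUnits.RELATIVE
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        bad = [p for p, t in self.values.items() if t <= 0]
        if bad:
            raise ValueError(f"non-positive half-lives for: {sorted(bad)[:5]}")


@dataclass
class PairRecord:
    pair: tuple[str, str]
    half_life_ratio: float
    category: RatioCategory
    semsim: Optional[float] = None
    coexpression: Optional[float] = None
    abundance_ratio: Optional[float] = None


@dataclass
class Degronon:
    members: list[str]
    length: int
    semsim_vs_first: list[float]
    ratio_vs_first: list[float]


def validate_network(net: nx.Graph) -> nx.Graph:
    """Reject self-loops; networkx Graph already deduplicates edges."""
    loops = list(nx.selfloop_edges(net))
    if loops:
        raise ValueError(f"network contains self-loops: {loops[:5]}")
    return net


def half_life_ratio_and_category(t1: float, t2: float) -> tuple[float, RatioCategory]:
    """Ratio = min/max; category boundaries at 0.5 and 0.8 (upper wins)."""
    if t1 <= 0 or t2 <= 0:
        raise ValueError(f"half-lives must be positive, got ({t1}, {t2})")
    ratio = min(t1, t2) / max(t1, t2)
    if ratio >= SIMILAR_BOUNDARY:
        cat = RatioCategory.SIMILAR
    elif ratio >= DIFFERENT_BOUNDARY:
        cat = RatioCategory.DIFFERENT
    else:
        cat = RatioCategory.VERY_DIFFERENT
    return ratio, cat


@dataclass
class RandomizationDiagnostics:
    n_swaps: int
    removed_original_edges: int
    residual_original_overlap: int
    n_edges_in: int
    n_edges_out: int


def randomize_network(
    net: nx.Graph,
    seed: int,
    swap_factor: int = 10,
    max_tries_factor: int = 100,
    prune: bool = True,
) -> tuple[nx.Graph, RandomizationDiagnostics]:
    """Degree-preserving null network.

    Three steps: (1) a degree-preserving double-edge-swap shuffle that never
    introduces self-loops or parallel edges; (2) a node-label permutation
    without replacement; (3) removal of any edge also present in the original
    network.  After step 3 the overlap with the original edge set is zero by
    construction; the diagnostics record how many edges that pruning cost.
    ``prune=False`` stops after step 2 (degree multiset then equals the
    input's exactly).
    """
    validate_network(net)
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    m = net.number_of_edges()
    rnd = nx.Graph()
    rnd.add_nodes_from(nodes)
    rnd.add_edges_from(net.edges())

    # step 1: double edge swaps (u-v, x-y) -> (u-x, v-y)
    target_swaps = swap_factor * m
    max_tries = max_tries_factor * m
    edges = [tuple(sorted(e)) for e in rnd.edges()]
    swaps = tries = 0
    while swaps < target_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if rnd.has_edge(u, x) or rnd.has_edge(v, y):
            continue
        rnd.remove_edge(u, v)
        rnd.remove_edge(x, y)
        rnd.add_edge(u, x)
        rnd.add_edge(v, y)
        edges[i] = tuple(sorted((u, x)))
        edges[j] = tuple(sorted((v, y)))
        swaps += 1
    if swaps < target_swaps:
        logger.warning(
            "edge shuffle stopped at %d/%d swaps after %d tries", swaps, target_swaps, tries
        )

    # step 2: node-label permutation (without replacement)
    perm = rng.permutation(len(nodes))
    relabel = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    rnd = nx.relabel_nodes(rnd, relabel)

    # step 3: prune edges still present in the original network
    shared = [e for e in rnd.edges() if net.has_edge(*e)]
    if prune:
        rnd.remove_edges_from(shared)
    residual = sum(1 for e in rnd.edges() if net.has_edge(*e))
    diag = RandomizationDiagnostics(
        n_swaps=swaps,
        removed_original_edges=len(shared) if prune else 0,
        residual_original_overlap=residual,
        n_edges_in=m,
        n_edges_out=rnd.number_of_edges(),
    )
    return rnd, diag


def build_pair_records(
    net: nx.Graph,
    halflives: HalfLifeTable,
    semsim: Optional[Mapping[frozenset, float]] = None,
    coexpression: Optional[Mapping[frozenset, float]] = None,
    abundances: Optional[Mapping[str, float]] = None,
) -> list[PairRecord]:
    """One record per network edge with both half-lives available.

    Optional per-pair annotations (semantic similarity, co-expression) and
    per-protein abundances fill the corresponding fields when present; a
    missing annotation leaves the field ``None`` (the pair still enters
    ratio-based analyses, but is excluded from that property's grouping).
    """
    records: list[PairRecord] = []
    for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
        t1 = halflives.values.get(u)
        t2 = halflives.values.get(v)
        if t1 is None or t2 is None:
            continue
        ratio, cat = half_life_ratio_and_category(t1, t2)
        key = frozenset((u, v))
        ab_ratio = None
        if abundances is not None and u in abundances and v in abundances:
            a1, a2 = abundances[u], abundances[v]
            if a1 > 0 and a2 > 0:
                ab_ratio = min(a1, a2) / max(a1, a2)
        records.append(
            PairRecord(
                pair=(u, v),
                half_life_ratio=ratio,
                category=cat,
                semsim=semsim.get(key) if semsim else None,
                coexpression=coexpression.get(key) if coexpression else None,
                abundance_ratio=ab_ratio,
            )
        )
    return records


def category_fractions(records: Sequence[PairRecord]) -> dict[RatioCategory, float]:
    n = len(records)
    out = {c: 0 for c in RatioCategory}
    for r in records:
        out[r.category] += 1
    return {c: (k / n if n else float("nan")) for c, k in out.items()}


@dataclass
class RatioEnvelope:
    bin_edges: np.ndarray
    observed: np.ndarray          # per-bin fraction of real edges
    random_mean: np.ndarray       # per-bin mean fraction across random nets
    random_sd: np.ndarray
    observed_similar_fraction: float
    random_similar_mean: float
    random_similar_sd: float


def ratio_distribution_vs_random(
    net: nx.Graph,
    halflives: HalfLifeTable,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
) -> RatioEnvelope:
    """Half-life-ratio histogram of real edges vs a randomized-network envelope.

    The envelope is the per-bin mean +/- 1 sd of the edge-ratio histograms of
    ``n_random`` independent degree-preserving randomizations.
    """
    def edge_ratios(g: nx.Graph) -> np.ndarray:
        vals = []
        for u, v in g.edges():
            t1 = halflives.values.get(u)
            t2 = halflives.values.get(v)
            if t1 is not None and t2 is not None:
                vals.append(min(t1, t2) / max(t1, t2))
        return np.asarray(vals)

    def hist(vals: np.ndarray) -> np.ndarray:
        if vals.size == 0:
            return np.zeros(len(RATIO_BINS) - 1)
        h, _ = np.histogram(vals, bins=RATIO_BINS)
        return h / vals.size

    obs = edge_ratios(net)
    rand_hists = []
    rand_sim = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_random):
        rnd, _ = randomize_network(net, seed=int(child.generate_state(1)[0] % 2**31))
        vals = edge_ratios(rnd)
        rand_hists.append(hist(vals))
        rand_sim.append(float(np.mean(vals >= SIMILAR_BOUNDARY)) if vals.size else np.nan)
    rand_hists = np.vstack(rand_hists)
    return RatioEnvelope(
        bin_edges=RATIO_BINS,
        observed=hist(obs),
        random_mean=rand_hists.mean(axis=0),
        random_sd=rand_hists.std(axis=0, ddof=1),
        observed_similar_fraction=float(np.mean(obs >= SIMILAR_BOUNDARY)) if obs.size else np.nan,
        random_similar_mean=float(np.nanmean(rand_sim)),
        random_similar_sd=float(np.nanstd(rand_sim, ddof=1)),
    )


def _bfs_shortest_paths(net: nx.Graph, source: str) -> dict[str, list[str]]:
    """Single-source shortest paths with deterministic lexicographic tie-break.

    Neighbors are expanded in sorted order and the first parent found is
    kept, so every node receives the path choosing the lexicographically
    smallest next node at each expansion.
    """
    paths: dict[str, list[str]] = {source: [source]}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in sorted(net.neighbors(u)):
            if v not in paths:
                paths[v] = paths[u] + [v]
                queue.append(v)
    return paths


def shortest_path_ratio_profile(
    net: nx.Graph,
    halflives: HalfLifeTable,
    max_len: int = 6,
) -> dict[str, np.ndarray]:
    """Half-life ratios of unordered node pairs bucketed by network distance.

    Buckets are distances ``1 .. max_len-1`` plus ``">=max_len"``; pairs in
    different components or missing a half-life are excluded.
    """
    buckets: dict[str, list[float]] = {str(d): [] for d in range(1, max_len)}
    buckets[f">={max_len}"] = []
    nodes = sorted(net.nodes())
    dist = dict(nx.all_pairs_shortest_path_length(net))
    for i, u in enumerate(nodes):
        tu = halflives.values.get(u)
        if tu is None:
            continue
        du = dist.get(u, {})
        for v in nodes[i + 1 :]:
            d = du.get(v)
            if d is None:
                continue
            tv = halflives.values.get(v)
            if tv is None:
                continue
            key = str(d) if d < max_len else f">={max_len}"
            buckets[key].append(min(tu, tv) / max(tu, tv))
    return {k: np.asarray(v) for k, v in buckets.items()}


def detect_degronons(
    net: nx.Graph,
    halflives: HalfLifeTable,
    semsim: Mapping[frozenset, float],
    cutoff: float = DEFAULT_SEMSIM_CUTOFF,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[Degronon], dict[str, list[float]], dict[str, list[float]]]:
    """Detect co-degrading, functionally coherent shortest paths.

    Iterates one shortest path per ordered node pair (deterministic
    lexicographic tie-break).  A path is a high-SemSim path when every member
    has pairwise semantic similarity >= ``cutoff`` with the first member; a
    member pair with no similarity value excludes the path from the
    high-SemSim subset (missing data, not a failure).

    Returns ``(degronons, all_path_ratios, high_semsim_ratios)``: the
    deduplicated high-SemSim paths of hop length >= ``min_length``, and the
    first-member-vs-member half-life-ratio distributions per path-length bin
    (``1..5`` and ``>=6``) for all paths and for the high-SemSim subset.
    """
    def bin_key(d: int) -> str:
        return str(d) if d < min_length else f">={min_length}"

    all_ratios: dict[str, list[float]] = {bin_key(d): [] for d in range(1, min_length + 1)}
    high_ratios: dict[str, list[float]] = {bin_key(d): [] for d in range(1, min_length + 1)}
    degronons: list[Degronon] = []
    seen_paths: set[tuple[str, ...]] = set()

    for source in sorted(net.nodes()):
        t0 = halflives.values.get(source)
        paths = _bfs_shortest_paths(net, source)
        for target in sorted(paths):
            path = paths[target]
            if len(path) < 2:
                continue
            # ratios of first member vs every subsequent member
            member_ratios: list[float] = []
            member_sims: list[Optional[float]] = []
            for d, member in enumerate(path[1:], start=1):
                tm = halflives.values.get(member)
                if t0 is not None and tm is not None:
                    r = min(t0, tm) / max(t0, tm)
                    all_ratios[bin_key(d)].append(r)
                    member_ratios.append(r)
                else:
                    member_ratios.append(float("nan"))
                member_sims.append(semsim.get(frozenset((source, member))))
            if any(s is None for s in member_sims):
                continue
            if all(s >= cutoff for s in member_sims):
                for d, member in enumerate(path[1:], start=1):
                    if not np.isnan(member_ratios[d - 1]):
                        high_ratios[bin_key(d)].append(member_ratios[d - 1])
                hops = len(path) - 1
                if hops >= min_length:
                    key = tuple(path)
                    if key not in seen_paths:
                        seen_paths.add(key)
                        degronons.append(
                            Degronon(
                                members=list(path),
                                length=hops,
                                semsim_vs_first=[float(s) for s in member_sims],
                                ratio_vs_first=member_ratios,
                            )
                        )
    return degronons, all_ratios, high_ratios


def dedupe_member_sets(degronons: Sequence[Degronon]) -> list[Degronon]:
    """Keep one representative per unordered member set (drops reverse paths)."""
    seen: set[frozenset] = set()
    out = []
    for d in degronons:
        key = frozenset(d.members)
        if key not in seen:
            seen.add(key)
            out.append(d)
    return out


def degree_halflife_correlation(
    net: nx.Graph,
    halflives: HalfLifeTable,
    abundances: Optional[Mapping[str, float]] = None,
) -> dict[str, tuple[float, float, int]]:
    """Correlation of half-life with node degree and mean partner abundance.

    Returns Spearman ``(r, p, n)`` for ``'degree'`` and, when abundances are
    supplied, ``'mean_partner_abundance'``.
    """
    nodes = [n for n in sorted(net.nodes()) if n in halflives.values]
    hl = [halflives.values[n] for n in nodes]
    deg = [net.degree(n) for n in nodes]
    out = {"degree": spearman(deg, hl)}
    if abundances is not None:
        mpa, hl2 = [], []
        for n in nodes:
            vals = [abundances[p] for p in net.neighbors(n) if p in abundances]
            if vals:
                mpa.append(float(np.mean(vals)))
                hl2.append(halflives.values[n])
        out["mean_partner_abundance"] = spearman(mpa, hl2)
    return out
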