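"""Evolutionary strata: Z/W similarity, segmentation, and origin testing.

The differentiated region of a ZW pair is a mosaic of strata — blocks whose
Z-W recombination stopped at different times and which therefore show
homogeneous but distinct levels of Z/W sequence identity. This module turns
filtered Z<->W alignment blocks into 100-kb windowed identity, segments the
window series into strata with an exact changepoint search, and tests
whether a stratum arose once in a common ancestor (W gametologs cluster
together across species) or independently (each species' Z+W pair clusters)
using p-distances and a neighbor-joining topology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from . import simdata


@dataclass(frozen=True)
class AlignmentBlock:
    """One Z<->W local alignment in Z coordinates (0-based half-open)."""

    z_scaffold: str
    z_start: int
    z_end: int
    w_scaffold: str
    aligned_length: int
    matches: int
    aligned_fraction: float = 1.0  # of the W query segment

    def __post_init__(self) -> None:
        if self.z_end <= self.z_start:
            raise ValueError("z_start must be < z_end")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if not 0 <= self.matches <= self.aligned_length:
            raise ValueError("matches must be within [0, aligned_length]")

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length


@dataclass(frozen=True)
class SimilarityWindow:
    z_start: int
    z_end: int
    mean_identity: float  # nan when aligned_bp == 0
    aligned_bp: float


@dataclass(frozen=True)
class StratumAnnotation:
    label: str
    z_start: int
    z_end: int
    mean_identity: float
    n_windows: int


def filter_blocks(
    blocks: Iterable[AlignmentBlock],
    min_aligned_fraction: float = 0.60,
    min_aligned_bp: int = 65,
    max_identity: float = 0.96,
) -> list[AlignmentBlock]:
    """Remove likely-false alignments: short, poorly aligned, or repeat-like.

    Keeps blocks with aligned_fraction >= 60%, aligned_length >= 65 bp and
    identity <= 96% (near-perfect hits are typically repeat alignments, not
    diverged gametologous sequence). Boundary values are retained because
    the removal rules are strict inequalities.
    """
    return [
        b
        for b in blocks
        if b.aligned_fraction >= min_aligned_fraction
        and b.aligned_length >= min_aligned_bp
        and b.identity <= max_identity
    ]


def windowed_similarity(
    blocks: Sequence[AlignmentBlock],
    window: int = 100_000,
    z_length: int | None = None,
) -> list[SimilarityWindow]:
    """Length-weighted Z/W identity in non-overlapping windows on the Z.

    A block spanning a window edge contributes its matches and aligned
    length pro-rata to each window by bp overlap of its Z span. Windows
    without any aligned bp carry identity nan and are excluded from
    downstream means.
    """
    if z_length is None:
        z_length = max((b.z_end for b in blocks), default=0)
    n_win = max(1, math.ceil(z_length / window)) if z_length else 0
    matches = np.zeros(n_win)
    aligned = np.zeros(n_win)
    for b in blocks:
        span = b.z_end - b.z_start
        first = b.z_start // window
        last = (b.z_end - 1) // window
        for wi in range(first, last + 1):
            lo = max(b.z_start, wi * window)
            hi = min(b.z_end, (wi + 1) * window)
            frac = (hi - lo) / span
            matches[wi] += b.matches * frac
            aligned[wi] += b.aligned_length * frac
    out = []
    for wi in range(n_win):
        ident = matches[wi] / aligned[wi] if aligned[wi] > 0 else float("nan")
        out.append(SimilarityWindow(wi * window, (wi + 1) * window, ident, aligned[wi]))
    return out


def direct_colinear_similarity(
    z_sequence: str, w_sequence: str, window: int = 100_000
) -> list[SimilarityWindow]:
    """Alignment-free windowed identity for a colinear Z/W pair.

    The W must be in the Z coordinate frame with deletions as '-'. Per
    window, identity = matching positions / compared (non-deleted)
    positions; fully deleted windows get identity nan.
    """
    if len(z_sequence) != len(w_sequence):
        raise ValueError("sequences must share a coordinate frame")
    z = simdata.str_to_codes(z_sequence)
    w = simdata.str_to_codes(w_sequence)
    compared = w != simdata.GAP_CODE
    match = compared & (z == w)
    n = z.size
    out = []
    for start in range(0, n, window):
        end = min(start + window, n)
        ncomp = int(compared[start:end].sum())
        nmatch = int(match[start:end].sum())
        ident = nmatch / ncomp if ncomp else float("nan")
        out.append(SimilarityWindow(start, min(start + window, n), ident, ncomp))
    return out


def _optimal_partition(values: np.ndarray, n_changepoints: int, min_size: int):
    """Exact minimal-SSE partition into n_changepoints+1 segments (DP).

    Returns (boundaries, rss) where boundaries are interior split indices
    (a split at i separates values[:i] from values[i:]).
    """
    n = values.size
    c1 = np.concatenate([[0.0], np.cumsum(values)])
    c2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def seg_cost(i: int, j: int) -> float:  # [i, j)
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / (j - i)

    k = n_changepoints
    INF = float("inf")
    # cost[m][j]: best cost of splitting values[:j] into m segments
    cost = np.full((k + 2, n + 1), INF)
    back = np.zeros((k + 2, n + 1), dtype=int)
    for j in range(min_size, n + 1):
        cost[1][j] = seg_cost(0, j)
    for m in range(2, k + 2):
        for j in range(m * min_size, n + 1):
            best, arg = INF, -1
            for i in range((m - 1) * min_size, j - min_size + 1):
                c = cost[m - 1][i] + seg_cost(i, j)
                if c < best:  # strict: earliest split wins ties
                    best, arg = c, i
            cost[m][j], back[m][j] = best, arg
    if not np.isfinite(cost[k + 1][n]):
        return None, None
    bounds = []
    j, m = n, k + 1
    while m > 1:
        i = back[m][j]
        bounds.append(int(i))
        j, m = i, m - 1
    return sorted(bounds), float(cost[k + 1][n])


def segment_strata(
    windows: Sequence[SimilarityWindow],
    max_segments: int = 4,
    min_windows_per_segment: int = 5,
    par_threshold: float = 0.985,
    boundaries: Sequence[int] | None = None,
) -> list[StratumAnnotation]:
    """Segment windowed identity into strata (piecewise-constant fit + BIC).

    Exact changepoint search: for each candidate number of segments up to
    ``max_segments`` the minimal within-segment squared error partition is
    found by dynamic programming, and the segment count is chosen by BIC
    (two parameters — level and location — per extra changepoint). Segments
    whose mean identity reaches ``par_threshold`` are labeled PAR; the rest
    are labeled S0, S1, ... in increasing order of mean identity (the most
    diverged stratum is the oldest). Windows without defined identity are
    ignored for the fit but bridged inside the reported intervals.

    ``boundaries`` (bp on the Z) overrides the automatic search.
    """
    defined = [w for w in windows if not math.isnan(w.mean_identity)]
    if not defined:
        raise ValueError("no windows with defined identity")
    values = np.array([w.mean_identity for w in defined])
    n = values.size

    if boundaries is not None:
        bset = sorted(boundaries)
        idx_bounds = [
            next((i for i, w in enumerate(defined) if w.z_start >= b), n) for b in bset
        ]
    elif n < 2 * min_windows_per_segment:
        warnings.warn("too few windows to segment; returning a single stratum")
        idx_bounds = []
    else:
        rss_floor = 1e-12 * n
        best_bic, idx_bounds = None, []
        for k in range(0, max_segments):
            bounds, rss = _optimal_partition(values, k, min_windows_per_segment)
            if bounds is None:
                continue
            bic = n * math.log(max(rss, rss_floor) / n) + 2 * k * math.log(n)
            if best_bic is None or bic < best_bic:
                best_bic, idx_bounds = bic, bounds
    cuts = [0] + list(idx_bounds) + [n]
    segments = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if a == b:
            continue
        seg = defined[a:b]
        segments.append(
            (seg[0].z_start, seg[-1].z_end, float(np.mean(values[a:b])), b - a)
        )
    # label: PAR above threshold, then S0 (lowest identity) upward
    non_par = sorted(
        [i for i, s in enumerate(segments) if s[2] < par_threshold],
        key=lambda i: segments[i][2],
    )
    labels = {}
    for rank, i in enumerate(non_par):
        labels[i] = f"S{rank}"
    out = []
    for i, (zs, ze, ident, nw) in enumerate(segments):
        label = labels.get(i, "PAR")
        out.append(StratumAnnotation(label, zs, ze, ident, nw))
    return out


def p_distance_matrix(
    sequences: dict, gap_chars: str = "-"
) -> tuple[np.ndarray, list]:
    """Pairwise p-distances with pairwise gap-column deletion.

    ``sequences`` maps a label to an aligned sequence (all equal length).
    d(i,j) = mismatches / compared sites over columns where neither
    sequence carries a gap. Returns (matrix, labels in order).
    """
    labels = list(sequences)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    arrs = [np.frombuffer(sequences[l].encode("ascii"), dtype=np.uint8) for l in labels]
    length = arrs[0].size
    if any(a.size != length for a in arrs):
        raise ValueError("sequences must be aligned to equal length")
    gaps = np.zeros((len(arrs), length), dtype=bool)
    for i, a in enumerate(arrs):
        for g in gap_chars.encode("ascii"):
            gaps[i] |= a == g
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
            mism = int((arrs[i][ok] != arrs[j][ok]).sum())
            d[i, j] = d[j, i] = mism / ncomp
    return d, labels


def neighbor_joining(matrix: np.ndarray, labels: Sequence) -> nx.Graph:
    """Neighbor-joining tree from a distance matrix.

    Deterministic: at each agglomeration the Q-minimal pair with the lowest
    (i, j) index order is joined. Returns an unrooted tree as a graph with
    'length' edge attributes; leaves are the given labels, internal nodes
    are integers.
    """
    d = np.asarray(matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with n >= 3")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("matrix must be symmetric, non-negative, zero diagonal")
    tree = nx.Graph()
    nodes = list(labels)
    d = d.copy()
    next_internal = 0
    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best[0], best[1]] - 1e-12:
                    best = (i, j)
        i, j = best
        vi = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        new = ("internal", next_internal)
        next_internal += 1
        tree.add_edge(nodes[i], new, length=max(vi, 0.0))
        tree.add_edge(nodes[j], new, length=max(vj, 0.0))
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
    # terminal 3-star: closed-form branch lengths
    center = ("internal", next_internal)
    a, b, c = range(3)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, ln in zip((a, b, c), (la, lb, lc)):
        tree.add_edge(nodes[k], center, length=max(ln, 0.0))
    return tree


def tree_to_newick(tree: nx.Graph, root=None) -> str:
    """Serialize an unrooted NJ tree to newick, rooted arbitrarily."""
    if root is None:
        root = next(n for n in tree.nodes if isinstance(n, tuple) and n[0] == "internal")

    def fmt(node, parent):
        children = [n for n in tree.neighbors(node) if n != parent]
        name = "" if isinstance(node, tuple) else str(node)
        if not children:
            return name
        inner = ",".join(
            fmt(c, node) + f":{tree.edges[node, c]['length']:.6f}" for c in children
        )
        return f"({inner}){name}"

    return fmt(root, None) + ";"


def _bipartitions(tree: nx.Graph) -> list[frozenset]:
    """Leaf sets split off by each internal edge (smaller side returned too)."""
    leaves = {n for n in tree.nodes if tree.degree(n) == 1}
    parts = []
    for u, v in tree.edges:
        t = tree.copy()
        t.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(t, u) if n in leaves}
        parts.append(frozenset(side))
        parts.append(frozenset(leaves - side))
    return parts


def classify_origin(
    sequences_or_matrix,
    labels: Sequence[tuple[str, str]] | None = None,
    outgroup: str = "outgroup",
) -> str:
    """Shared vs independent stratum origin from gametolog clustering.

    Accepts either {(species, 'Z'|'W'): aligned sequence} or a precomputed
    distance matrix plus ``labels``. Builds the NJ topology and checks its
    bipartitions: 'shared' if all W copies split off together (they trace
    to one recombination-stop event predating speciation), 'independent'
    if every species' Z+W pair splits off together, else 'unresolved'. An
    outgroup, when present, participates in the tree but belongs to
    neither tested group.
    """
    if labels is None:
        d, labels = p_distance_matrix(sequences_or_matrix)
    else:
        d = np.asarray(sequences_or_matrix, dtype=float)
        labels = list(labels)
    species = {sp for sp, _ in labels if sp != outgroup}
    with_both = [
        sp
        for sp in species
        if (sp, "Z") in labels and (sp, "W") in labels
    ]
    if len(with_both) < 2:
        raise ValueError("need >=2 species with both Z and W copies")
    tree = neighbor_joining(d, labels)
    parts = set(_bipartitions(tree))
    w_set = frozenset(l for l in labels if l[1] == "W" and l[0] != outgroup)
    if len(w_set) >= 2 and w_set in parts:
        return "shared"
    pairs_ok = all(
        frozenset({(sp, "Z"), (sp, "W")}) in parts for sp in with_both
    )
    if pairs_ok:
        return "independent"
    return "unresolved"
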