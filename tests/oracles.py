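"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (double loops over characters, textbook
agglomeration on Python lists, exhaustive scans) and shares no code with the
package's vectorised implementations.
"""

from __future__ import annotations

import collections
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


# ---------------------------------------------------------------------------
# distances


def naive_pair_distance(s1: str, s2: str, model: str) -> float:
    """Per-site double loop p / K2P distance with pairwise deletion."""
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in BASES or b not in BASES:
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ZeroDivisionError("no comparable sites")
    if model == "p":
        return (ts + tv) / n
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def naive_distance_matrix(seqs: Sequence[str], model: str = "p") -> np.ndarray:
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = naive_pair_distance(seqs[i], seqs[j], model)
    return D


# ---------------------------------------------------------------------------
# random additive (tree-metric) instances


def random_additive_tree(
    n: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, set[frozenset[str]], dict]:
    """Random binary unrooted tree with positive lengths and its path metric.

    Returns (labels, distance matrix, non-trivial bipartitions in canonical
    form, edge lengths keyed by leaf name for pendants and by canonical block
    for internal edges).
    """
    labels = [f"T{i:02d}" for i in range(n)]
    adj: dict[str, dict[str, float]] = {}

    def add(u: str, v: str, l: float) -> None:
        adj.setdefault(u, {})[v] = l
        adj.setdefault(v, {})[u] = l

    counter = [0]

    def internal() -> str:
        counter[0] += 1
        return f"__I{counter[0]}"

    hub = internal()
    for leaf in labels[:3]:
        add(hub, leaf, float(rng.uniform(0.1, 1.0)))
    for leaf in labels[3:]:
        edges = sorted(
            (u, v) for u in adj for v in adj[u] if u < v
        )
        u, v = edges[int(rng.integers(len(edges)))]
        L = adj[u][v]
        t = float(rng.uniform(0.3, 0.7))
        w = internal()
        del adj[u][v]
        del adj[v][u]
        add(u, w, L * t)
        add(w, v, L * (1 - t))
        add(w, leaf, float(rng.uniform(0.1, 1.0)))

    leafset = set(labels)

    def dists_from(a: str) -> dict[str, float]:
        dist = {a: 0.0}
        dq = collections.deque([a])
        while dq:
            x = dq.popleft()
            for y, l in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + l
                    dq.append(y)
        return dist

    D = np.array([[dists_from(a)[b] for b in labels] for a in labels])

    def side(u: str, v: str) -> frozenset[str]:
        """Leaves reachable from u without crossing edge (u, v)."""
        seen = {u, v}
        stack = [u]
        out = set()
        while stack:
            x = stack.pop()
            if x in leafset:
                out.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    anchor = min(labels)

    def canonical(block: frozenset[str]) -> frozenset[str]:
        return frozenset(leafset) - block if anchor in block else block

    biparts: set[frozenset[str]] = set()
    lengths: dict = {}
    for u in adj:
        for v, l in adj[u].items():
            if u > v:
                continue
            if u in leafset or v in leafset:
                leaf = u if u in leafset else v
                lengths[leaf] = l
            else:
                block = canonical(side(u, v))
                biparts.add(block)
                lengths[block] = l
    return labels, D, biparts, lengths


# ---------------------------------------------------------------------------
# naive neighbour joining (for the bootstrap recount)


def naive_nj_bipartitions(
    labels: Sequence[str], D: np.ndarray
) -> set[frozenset[str]]:
    """Textbook NJ on Python lists; lowest-(row, col) tie-break.

    Returns the non-trivial bipartitions of the resulting unrooted tree in
    canonical form (block not containing the smallest leaf).
    """
    clusters = [frozenset([l]) for l in labels]
    d = [list(map(float, row)) for row in D]
    blocks: list[frozenset[str]] = []
    while len(clusters) > 3:
        m = len(clusters)
        r = [sum(row) for row in d]
        best = None
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i][j] - r[i] - r[j]
                if best is None or q < best:
                    best, bi, bj = q, i, j
        merged = clusters[bi] | clusters[bj]
        blocks.append(merged)
        new_row = [
            0.5 * (d[bi][k] + d[bj][k] - d[bi][bj])
            for k in range(m)
            if k not in (bi, bj)
        ]
        keep = [k for k in range(m) if k not in (bi, bj)]
        d = [[d[a][b] for b in keep] for a in keep]
        for row, val in zip(d, new_row):
            row.append(val)
        d.append(new_row + [0.0])
        clusters = [clusters[k] for k in keep] + [merged]

    leafset = frozenset(labels)
    anchor = min(labels)
    out = set()
    for block in blocks:
        if 2 <= len(block) <= len(labels) - 2:
            out.add(leafset - block if anchor in block else block)
    return out


# ---------------------------------------------------------------------------
# character-attribute purity scan


def exhaustive_simple_cas(
    seqs_by_species: Mapping[str, Sequence[str]],
    clade: Iterable[str],
    context: Iterable[str],
) -> set[tuple[int, str]]:
    """Every (1-based position, state) pure for *clade* within *context*."""
    clade = set(clade)
    others = [sp for sp in context if sp not in clade]
    L = len(next(iter(seqs_by_species.values()))[0])
    out = set()
    for pos in range(L):
        for state in BASES:
            if not all(
                seq[pos] == state for sp in clade for seq in seqs_by_species[sp]
            ):
                continue
            if any(seq[pos] == state for sp in others for seq in seqs_by_species[sp]):
                continue
            out.add((pos + 1, state))
    return out


def jointly_pure(
    seqs_by_species: Mapping[str, Sequence[str]],
    clade: Iterable[str],
    context: Iterable[str],
    cas: Sequence[tuple[int, str]],
) -> bool:
    """True if the conjunction of (pos, state) pairs is pure for the clade."""
    clade = set(clade)
    others = [sp for sp in context if sp not in clade]
    for sp in clade:
        for seq in seqs_by_species[sp]:
            if not all(seq[p - 1] == s for p, s in cas):
                return False
    for sp in others:
        for seq in seqs_by_species[sp]:
            if all(seq[p - 1] == s for p, s in cas):
                return False
    return True
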