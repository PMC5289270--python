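"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a route disjoint from the library:
quaternion (Horn) superposition, BFS path enumeration for edge
betweenness, exhaustive monotone-mapping enumeration for the alignment
DP, hypergeometric table enumeration for the Fisher test, and quadratic
distance scans for interface counts.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def horn_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = a0.T @ b0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e = float((a0**2).sum() + (b0**2).sum() - 2.0 * lam)
    return math.sqrt(max(e, 0.0) / len(a))


def bfs_edge_betweenness(edges: list[tuple]) -> dict[tuple, float]:
    """Edge betweenness by explicit shortest-path enumeration (small graphs).

    Every unordered connected node pair contributes one unit of credit,
    split equally over its shortest paths; each path credits its edges.
    """
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    nodes = sorted(adj, key=str)
    bet = {tuple(sorted(e, key=str)): 0.0 for e in edges}

    def all_shortest_paths(s, t):
        dist = {s: 0}
        q = deque([s])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    q.append(y)
        if t not in dist:
            return []
        paths = []

        def walk(path):
            x = path[-1]
            if x == t:
                paths.append(list(path))
                return
            for y in adj[x]:
                if dist.get(y) == dist[x] + 1 and dist[y] <= dist[t]:
                    path.append(y)
                    walk(path)
                    path.pop()

        walk([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for p in paths:
                for u, v in zip(p, p[1:]):
                    bet[tuple(sorted((u, v), key=str))] += w
    return bet


def enumerate_monotone_mappings(n: int, m: int):
    """Yield every non-empty sequential mapping between ranges n and m."""
    for k in range(1, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.combinations(range(m), k):
                yield list(zip(rows, cols))


def mapping_objective(S: np.ndarray, mapping, gap_open: float = 0.6) -> float:
    """Reference DP objective: sum of pair scores minus gap openings.

    A run of skipped residues between consecutive mapped pairs costs
    ``gap_open`` per chain with skipped residues; overhangs are free.
    """
    total = sum(S[i, j] for i, j in mapping)
    for (i1, j1), (i2, j2) in zip(mapping[:-1], mapping[1:]):
        if i2 - i1 > 1:
            total -= gap_open
        if j2 - j1 > 1:
            total -= gap_open
    return total


def fisher_two_sided_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p by full enumeration at fixed margins."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def brute_force_interface(chain_a, chain_b, cutoff: float):
    """Residue contact pairs by a plain double loop over all atoms."""
    pairs = set()
    for i, ra in enumerate(chain_a.residues):
        for j, rb in enumerate(chain_b.residues):
            done = False
            for at_a in ra.atoms:
                for at_b in rb.atoms:
                    if np.linalg.norm(at_a.coord - at_b.coord) < cutoff:
                        pairs.add((i, j))
                        done = True
                        break
                if done:
                    break
    return pairs


def brute_force_ca_contacts(chain_a, chain_b, cutoff: float) -> int:
    """Count inter-chain CA pairs below cutoff, double loop."""
    n = 0
    for ra in chain_a.residues:
        ca_a = ra.atom("CA")
        if ca_a is None:
            continue
        for rb in chain_b.residues:
            ca_b = rb.atom("CA")
            if ca_b is None:
                continue
            if np.linalg.norm(ca_a.coord - ca_b.coord) < cutoff:
                n += 1
    return n
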