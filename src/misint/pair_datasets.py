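"""Positive/negative pair dataset construction and pair annotation.

Implements the five negative-selection strategies used to assemble
non-interacting datasets: uniform random sampling of non-edges, balanced
(degree-preserving) sampling, non-colocalized filtering, false-negative-
rate reduction by network distance, and direct-method filtering for the
positive side.  Pair abundance is the minimum of the two proteins'
abundance classes (a scarce partner limits complex formation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinPair",
    "sample_negative_random",
    "sample_negative_balanced",
    "filter_fnr",
    "filter_noncolocalized",
    "filter_direct",
    "pair_abundance",
    "DIRECT_METHODS",
]

#: detection methods accepted as evidence of a direct physical interaction
DIRECT_METHODS = frozenset(
    {
        "Two-hybrid",
        "PCA",
        "Biochemical Activity",
        "Co-crystal Structure",
        "Reconstituted Complex",
        "Far Western",
        "FRET",
    }
)

_ABUNDANCE_ORDER = {"low": 0, "medium": 1, "high": 2}


@dataclass(frozen=True)
class ProteinPair:
    """An unordered protein pair with a label and a source strategy tag."""

    id_a: str
    id_b: str
    label: str = "unknown"  # interacting | non-interacting | unknown
    source: str = ""

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-pair not allowed: {self.id_a}")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))


class InfeasibleSamplingError(RuntimeError):
    """No negative set satisfying the constraints exists / was found."""


def _as_key(pair) -> tuple[str, str]:
    if isinstance(pair, ProteinPair):
        return pair.key
    a, b = pair
    return tuple(sorted((a, b)))


def sample_negative_random(
    native: nx.Graph, n: int, seed: int, source: str = "random"
) -> list[ProteinPair]:
    """Uniform sample (without replacement) of non-adjacent node pairs."""
    nodes = sorted(native.nodes)
    n_nodes = len(nodes)
    n_possible = n_nodes * (n_nodes - 1) // 2 - native.number_of_edges()
    if n > n_possible:
        raise ValueError(f"requested {n} negatives but only {n_possible} non-edges exist")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    out: list[ProteinPair] = []
    while len(out) < n:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        key = tuple(sorted((nodes[i], nodes[j])))
        if key in chosen or native.has_edge(*key):
            continue
        chosen.add(key)
        out.append(ProteinPair(key[0], key[1], "non-interacting", source))
    return out


def sample_negative_balanced(
    native: nx.Graph, seed: int, max_restarts: int = 1000, source: str = "balanced"
) -> list[ProteinPair]:
    """Degree-preserving negative set by stub matching.

    Every node appears in exactly as many negative pairs as its native
    degree; self-loops, duplicate pairs and native edges are rejected,
    restarting on dead ends.  Raises when no feasible set is found within
    ``max_restarts`` restarts.
    """
    rng = np.random.default_rng(seed)
    degrees = dict(native.degree())
    stubs_template = [n for n, d in degrees.items() for _ in range(d)]
    for _ in range(max_restarts):
        stubs = list(stubs_template)
        rng.shuffle(stubs)
        chosen: set[tuple[str, str]] = set()
        ok = True
        while stubs:
            a = stubs.pop()
            # find a partner stub compatible with a
            idx = None
            for k in range(len(stubs) - 1, -1, -1):
                b = stubs[k]
                if b == a:
                    continue
                key = tuple(sorted((a, b)))
                if key in chosen or native.has_edge(*key):
                    continue
                idx = k
                break
            if idx is None:
                ok = False
                break
            chosen.add(tuple(sorted((a, stubs.pop(idx)))))
        if ok:
            return [
                ProteinPair(a, b, "non-interacting", source) for a, b in sorted(chosen)
            ]
    raise InfeasibleSamplingError(
        f"no degree-preserving negative set found in {max_restarts} restarts"
    )


def filter_fnr(
    pairs: list[ProteinPair], native: nx.Graph, min_path: int = 10
) -> list[ProteinPair]:
    """Keep pairs whose network distance exceeds ``min_path`` (strict).

    Pairs in different components (infinite distance) are kept; pairs with
    an endpoint absent from the network are dropped with a warning.
    """
    out = []
    for p in pairs:
        if p.id_a not in native or p.id_b not in native:
            logger.warning("dropping pair with endpoint outside network: %s", p.key)
            continue
        try:
            dist = nx.shortest_path_length(native, p.id_a, p.id_b)
        except nx.NetworkXNoPath:
            out.append(p)
            continue
        if dist > min_path:
            out.append(p)
    return out


def filter_noncolocalized(
    pairs: list[ProteinPair], localization: dict[str, list[str] | str]
) -> list[ProteinPair]:
    """Keep pairs with exactly one, differing, localization each.

    Proteins with several localizations (or none annotated) disqualify
    their pairs.
    """

    def locs(pid: str) -> list[str]:
        v = localization.get(pid)
        if v is None:
            return []
        if isinstance(v, str):
            return v.split(";") if v else []
        return list(v)

    out = []
    for p in pairs:
        la, lb = locs(p.id_a), locs(p.id_b)
        if len(la) == 1 and len(lb) == 1 and la[0] != lb[0]:
            out.append(p)
    return out


def filter_direct(
    pairs: list[ProteinPair],
    method_annotations: dict[tuple[str, str], set[str]],
    allowed: frozenset[str] = DIRECT_METHODS,
) -> list[ProteinPair]:
    """Keep pairs whose detection-method set intersects ``allowed``."""
    out = []
    for p in pairs:
        methods = method_annotations.get(p.key, set())
        if methods & allowed:
            out.append(p)
    return out


def pair_abundance(pair, abundance_class: dict[str, str]) -> str:
    """Pair abundance class: the lower of the two proteins' classes.

    Returns "unknown" when either protein is unclassed.
    """
    a, b = _as_key(pair)
    ca, cb = abundance_class.get(a), abundance_class.get(b)
    if ca not in _ABUNDANCE_ORDER or cb not in _ABUNDANCE_ORDER:
        return "unknown"
    return min(ca, cb, key=_ABUNDANCE_ORDER.get)
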