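"""Synthetic structures, dimer libraries, benchmarks, networks, annotations.

Everything downstream of this module (precedent search, interface
descriptors, network analysis, extrapolation arithmetic) is exercised on
data produced here, so the generators reproduce the statistical structure
the analyses assume:

* dimer templates with more than 10 inter-chain residue contacts at 5 A
  (the library inclusion rule) and interfaces large enough to pass the
  20-residue validity check;
* monomer "homology models" as noise-perturbed, arbitrarily re-posed
  copies of template chains (positives and structure-compatible
  negatives) or unrelated fresh folds (plain negatives);
* interaction networks with heavy-tailed degree distributions
  (preferential attachment);
* protein annotation tables (localization, abundance quartile classes,
  term sets).

All generators are deterministic given their seed; one integer seeds the
whole benchmark.  Side chains are represented by CB only, so all 5 A
atom-contact rules operate on backbone + CB.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .precedent import DimerRecord
from .structures_io import Atom, Chain, Residue, Structure, write_pdb

__all__ = [
    "GeneratorConfig",
    "BenchmarkPair",
    "Benchmark",
    "make_chain",
    "make_dimer",
    "perturb_structure",
    "make_benchmark",
    "make_network",
    "make_two_community_network",
    "make_annotations",
    "write_benchmark",
]

_AA20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


class GenerationError(RuntimeError):
    """A generator could not satisfy its constraints within its trial budget."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    noise_sigma is the per-coordinate Gaussian noise (A) applied to planted
    monomer models; contact_target is the minimum inter-chain residue
    contact count (5 A) a generated dimer must reach; compat_fraction is
    the share of negatives that are structure-compatible (perturbed copies
    of one library dimer's chains, labelled non-interacting).
    """

    seed: int = 0
    noise_sigma: float = 0.3
    n_dimers: int = 8
    chain_length_range: tuple[int, int] = (30, 60)
    contact_target: int = 25
    compat_fraction: float = 0.2
    min_interface_residues: int = 24

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.chain_length_range[0] < 20:
            raise ValueError("chain lengths must be >= 20")
        if self.contact_target <= 10:
            raise ValueError("contact_target must exceed the >10 library rule")

    @classmethod
    def from_toml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "chain_length_range" in data:
            data["chain_length_range"] = tuple(data["chain_length_range"])
        return cls(**data)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _helix_ca(n: int) -> np.ndarray:
    """Ideal alpha-helical CA trace: 1.5 A rise, 100 deg/residue, r 2.3 A."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _strand_ca(n: int) -> np.ndarray:
    """Extended-strand CA trace: 3.3 A rise with a slight zigzag."""
    i = np.arange(n)
    return np.column_stack([3.3 * i, 0.9 * (-1.0) ** i, np.zeros(n)])


def _backbone_atoms(ca: np.ndarray, resname: str, i: int, n: int) -> list[Atom]:
    """Place N, C, O, CB around a CA trace from a local frame.

    Approximate geometry only: bond lengths are canonical, angles are not.
    """
    prev_ca = ca[max(i - 1, 0)]
    next_ca = ca[min(i + 1, n - 1)]
    t = next_ca - prev_ca
    tn = np.linalg.norm(t)
    t = t / tn if tn > 1e-9 else np.array([1.0, 0.0, 0.0])
    step = next_ca - ca[i] if i < n - 1 else ca[i] - prev_ca
    p = np.cross(t, step)
    pn = np.linalg.norm(p)
    if pn < 1e-9:
        p = np.cross(t, np.array([0.0, 0.0, 1.0]))
        pn = np.linalg.norm(p)
        if pn < 1e-9:
            p = np.cross(t, np.array([0.0, 1.0, 0.0]))
            pn = np.linalg.norm(p)
    p = p / pn
    q = np.cross(t, p)
    x = ca[i]
    c_coord = x + 1.52 * _unit(0.85 * t - 0.53 * p)
    atoms = [
        Atom("N", "N", x - 1.46 * _unit(0.85 * t + 0.53 * p)),
        Atom("CA", "C", x.copy()),
        Atom("C", "C", c_coord),
        Atom("O", "O", c_coord + 1.23 * p),
    ]
    if resname != "GLY":
        atoms.append(Atom("CB", "C", x + 1.53 * q))
    return atoms


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_chain(n_res: int, motif_seed: int, chain_id: str = "A") -> Chain:
    """A backbone+CB chain built from ideal helix/strand segments.

    Segments (6-12 residues) are joined by random turns; the trace is
    rejected and re-drawn whenever two non-consecutive CA atoms come
    closer than 3.6 A.  Residue names are uniform over the 20 standard
    codes under the seed.
    """
    if n_res < 5:
        raise ValueError("need at least 5 residues")
    rng = np.random.default_rng(motif_seed)
    names = [str(_AA20[k]) for k in rng.integers(0, 20, size=n_res)]

    ca = None
    for _restart in range(50):
        try:
            ca = _build_trace(n_res, rng)
            break
        except GenerationError:
            continue
    if ca is None:
        raise GenerationError("could not build a clash-free CA trace")

    residues = []
    for i in range(n_res):
        residues.append(
            Residue(index=i + 1, name=names[i], atoms=_backbone_atoms(ca, names[i], i, n_res))
        )
    return Chain(id=chain_id, residues=residues)


def _build_trace(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """One attempt at a clash-free segmented CA trace."""
    ca = np.empty((0, 3))
    remaining = n_res
    while remaining > 0:
        seg_len = int(min(remaining, rng.integers(6, 13)))
        local = _helix_ca(seg_len) if rng.random() < 0.5 else _strand_ca(seg_len)
        local = local - local[0]
        if len(ca) == 0:
            ca = local @ _random_rotation(rng).T
            remaining -= seg_len
            continue
        placed = None
        centroid = ca.mean(axis=0)
        for _ in range(300):
            rot = _random_rotation(rng)
            seg = local @ rot.T
            u = _unit(_unit(ca[-1] - centroid) + 0.8 * _unit(rng.normal(size=3)))
            start = ca[-1] + 3.8 * u
            seg = seg + start
            merged = np.vstack([ca, seg])
            d2 = ((merged[:, None, :] - merged[None, :, :]) ** 2).sum(axis=2)
            k = len(merged)
            mask = ~np.eye(k, dtype=bool)
            off = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) == 1
            mask &= ~off
            if d2[mask].min() >= 3.6**2:
                placed = merged
                break
        if placed is None:
            raise GenerationError("could not place a turn without a CA clash")
        ca = placed
        remaining -= seg_len
    return ca


def _shift_chain(chain: Chain, offset: np.ndarray, rotation: np.ndarray | None = None) -> Chain:
    import copy as _copy

    out = _copy.deepcopy(chain)
    for res in out.residues:
        for atom in res.atoms:
            if rotation is not None:
                atom.coord = rotation @ atom.coord
            atom.coord = atom.coord + offset
    return out


def _center(chain: Chain) -> Chain:
    c = chain.all_coords().mean(axis=0)
    return _shift_chain(chain, -c)


def make_dimer(
    len_a: int,
    len_b: int,
    config: GeneratorConfig,
    seed: int | None = None,
    dimer_id: str = "T0001",
    max_trials: int = 500,
) -> DimerRecord:
    """Rigid-body dock two generated chains into a template dimer.

    Chain B approaches chain A along a random contact axis until the
    inter-chain residue contact count at 5 A reaches ``contact_target``
    (and the pooled interface has at least ``min_interface_residues``
    residues) with no CA pair closer than 3.0 A.  Fails after
    ``max_trials`` orientations.
    """
    if len_a < 20 or len_b < 20:
        raise ValueError("chain lengths must be >= 20")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    homodimer = bool(rng.random() < 0.25)
    seed_a = int(rng.integers(0, 2**31 - 1))
    seed_b = seed_a if homodimer else int(rng.integers(0, 2**31 - 1))
    if homodimer:
        len_b = len_a
    chain_a = _center(make_chain(len_a, seed_a, chain_id="A"))
    chain_b0 = _center(make_chain(len_b, seed_b, chain_id="B"))

    xa = chain_a.all_coords()
    res_idx_a = chain_a.atom_residue_index()
    is_ca_a = np.array([at.name == "CA" for r in chain_a.residues for at in r.atoms])
    xb_base = chain_b0.all_coords()
    res_idx_b = chain_b0.atom_residue_index()
    is_ca_b = np.array([at.name == "CA" for r in chain_b0.residues for at in r.atoms])
    ra = float(np.linalg.norm(xa, axis=1).max())

    n_res_b = len(chain_b0.residues)
    for _ in range(max_trials):
        rot = _random_rotation(rng)
        u = _unit(rng.normal(size=3))
        xb0 = xb_base @ rot.T
        # atom-pair distance along the slide t is a quadratic:
        # d^2(t) = |w|^2 - 2 t (w.u) + t^2 with w = xa_i - xb0_j
        w = xa[:, None, :] - xb0[None, :, :]
        P = (w**2).sum(axis=2)
        Q = w @ u
        # deepest approach before a CA-CA clash (< 3.0 A)
        Pc = P[np.ix_(is_ca_a, is_ca_b)]
        Qc = Q[np.ix_(is_ca_a, is_ca_b)]
        disc = Qc**2 - Pc + 3.0**2
        mask = disc > 0
        t_clash = float((Qc[mask] + np.sqrt(disc[mask])).max()) if mask.any() else 0.0
        # atom pairs that can come within 5 A for some t
        disc5 = Q**2 - P + 5.0**2
        cand = disc5 > 0
        if not cand.any():
            continue
        t_hi = Q[cand] + np.sqrt(disc5[cand])
        t_first = float(t_hi.max())
        if t_first <= t_clash + 0.05:
            continue
        ia, ib = np.nonzero(cand)
        Pcand, Qcand = P[cand], Q[cand]
        rkey = res_idx_a[ia] * n_res_b + res_idx_b[ib]
        found = None
        for t in np.arange(t_first, t_clash + 0.05, -0.4):
            close = Pcand - 2.0 * t * Qcand + t * t < 5.0**2
            if not close.any():
                continue
            keys = np.unique(rkey[close])
            if len(keys) >= config.contact_target:
                res_a = np.unique(keys // n_res_b)
                res_b = np.unique(keys % n_res_b)
                if len(res_a) + len(res_b) >= config.min_interface_residues:
                    found = _shift_chain(chain_b0, t * u, rotation=rot)
                    break
        if found is not None:
            dimer = DimerRecord(
                id=dimer_id,
                chain_x=chain_a,
                chain_y=found,
                is_homodimer=homodimer,
                is_obligate=bool(rng.random() < 0.5),
                from_higher_order=bool(rng.random() < 0.3),
            )
            dimer.validate()
            return dimer
    raise GenerationError(
        f"docking failed to reach {config.contact_target} contacts in {max_trials} trials"
    )


def perturb_structure(s: Structure | Chain, sigma: float, seed: int) -> Structure | Chain:
    """Gaussian coordinate noise plus a random rigid re-posing.

    Topology (chains, residues, atom names) is unchanged; with sigma 0 the
    output is an exact rigid transform of the input.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    import copy as _copy

    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, size=3)
    out = _copy.deepcopy(s)
    chains = out.chains if isinstance(out, Structure) else [out]
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                noisy = atom.coord + rng.normal(0.0, sigma, size=3) if sigma > 0 else atom.coord
                atom.coord = rot @ noisy + trans
    return out


@dataclass
class BenchmarkPair:
    """A candidate pair: protein ids, available monomer models, truth."""

    id_a: str
    id_b: str
    models_a: list[Structure]
    models_b: list[Structure]
    label: str  # "interacting" | "non-interacting"
    kind: str  # "positive" | "negative-compatible" | "negative-unrelated"
    template: str | None  # planted template id, None when unrelated

    @property
    def pair_id(self) -> str:
        return f"{self.id_a}--{self.id_b}"


@dataclass
class Benchmark:
    """A planted-precedent benchmark: library, pairs and truth table."""

    library: list[DimerRecord]
    pairs: list[BenchmarkPair]
    config: GeneratorConfig

    def truth(self) -> pd.DataFrame:
        rows = [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "label": p.label,
                "kind": p.kind,
                "template": p.template if p.template is not None else "",
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows)


def _monomer(chain: Chain, sigma: float, seed: int, name: str) -> Structure:
    pert = perturb_structure(chain, sigma, seed)
    pert.id = "m"
    return Structure(id=name, chains=[Chain(id="A", residues=pert.residues)])


def make_benchmark(
    n_templates: int,
    n_pos_pairs: int,
    n_neg_pairs: int,
    config: GeneratorConfig,
) -> Benchmark:
    """Generate a dimer library with planted positives and negatives.

    Positive pairs are noise-perturbed copies of both chains of a library
    dimer, assigned round-robin over the templates.  Negatives are either
    unrelated fresh chains (no precedent) or, for a ``compat_fraction``
    share, perturbed copies of one dimer's chains (structure-compatible
    but labelled non-interacting), assigned at even strides over the
    library so every part of it is represented.
    """
    if min(n_templates, n_pos_pairs, n_neg_pairs) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.chain_length_range
    library: list[DimerRecord] = []
    for t in range(n_templates):
        len_a = int(rng.integers(lo, hi + 1))
        len_b = int(rng.integers(lo, hi + 1))
        dimer = make_dimer(
            len_a,
            len_b,
            config,
            seed=int(rng.integers(0, 2**31 - 1)),
            dimer_id=f"T{t:03d}",
        )
        library.append(dimer)

    pairs: list[BenchmarkPair] = []
    counter = 0

    def next_ids():
        nonlocal counter
        counter += 1
        return f"P{2 * counter - 1:04d}", f"P{2 * counter:04d}"

    for j in range(n_pos_pairs):
        tpl = library[j % n_templates]
        id_a, id_b = next_ids()
        ma = _monomer(tpl.chain_x, config.noise_sigma, int(rng.integers(0, 2**31 - 1)), id_a)
        mb = _monomer(tpl.chain_y, config.noise_sigma, int(rng.integers(0, 2**31 - 1)), id_b)
        pairs.append(
            BenchmarkPair(id_a, id_b, [ma], [mb], "interacting", "positive", tpl.id)
        )

    n_comp = int(round(config.compat_fraction * n_neg_pairs))
    for j in range(n_neg_pairs):
        id_a, id_b = next_ids()
        if j < n_comp:
            tpl = library[(j * n_templates) // max(n_comp, 1) % n_templates]
            ma = _monomer(tpl.chain_x, config.noise_sigma, int(rng.integers(0, 2**31 - 1)), id_a)
            mb = _monomer(tpl.chain_y, config.noise_sigma, int(rng.integers(0, 2**31 - 1)), id_b)
            pairs.append(
                BenchmarkPair(
                    id_a, id_b, [ma], [mb], "non-interacting", "negative-compatible", tpl.id
                )
            )
        else:
            la = int(rng.integers(lo, hi + 1))
            lb = int(rng.integers(lo, hi + 1))
            sa = make_chain(la, int(rng.integers(0, 2**31 - 1)), chain_id="A")
            sb = make_chain(lb, int(rng.integers(0, 2**31 - 1)), chain_id="A")
            pairs.append(
                BenchmarkPair(
                    id_a,
                    id_b,
                    [Structure(id=id_a, chains=[sa])],
                    [Structure(id=id_b, chains=[sb])],
                    "non-interacting",
                    "negative-unrelated",
                    None,
                )
            )
    return Benchmark(library=library, pairs=pairs, config=config)


def make_network(n_nodes: int, mean_degree: float, seed: int) -> nx.Graph:
    """Preferential-attachment (heavy-tailed) protein network.

    Nodes are labelled P0000..; the graph is simple and undirected with
    roughly mean_degree * n_nodes / 2 edges (up to attachment rounding).
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    m = max(1, int(round(mean_degree / 2.0)))
    g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    return nx.relabel_nodes(g, {i: f"P{i:04d}" for i in g.nodes})


def make_two_community_network(
    n_per_community: int, mean_degree: float, n_bridges: int, seed: int
) -> tuple[nx.Graph, dict[str, str]]:
    """Two preferential-attachment communities joined by a few bridges.

    Returns the graph and a node -> community ("left"/"right") map.
    """
    rng = np.random.default_rng(seed)
    m = max(1, int(round(mean_degree / 2.0)))
    g1 = nx.barabasi_albert_graph(n_per_community, m, seed=int(rng.integers(0, 2**31 - 1)))
    g2 = nx.barabasi_albert_graph(n_per_community, m, seed=int(rng.integers(0, 2**31 - 1)))
    g1 = nx.relabel_nodes(g1, {i: f"L{i:04d}" for i in g1.nodes})
    g2 = nx.relabel_nodes(g2, {i: f"R{i:04d}" for i in g2.nodes})
    g = nx.union(g1, g2)
    community = {n: "left" for n in g1.nodes} | {n: "right" for n in g2.nodes}
    added = 0
    while added < n_bridges:
        a = f"L{int(rng.integers(0, n_per_community)):04d}"
        b = f"R{int(rng.integers(0, n_per_community)):04d}"
        if not g.has_edge(a, b):
            g.add_edge(a, b)
            added += 1
    return g, community


_LOCALIZATIONS = ["nucleus", "cytoplasm", "mitochondrion", "ER", "membrane"]


def make_annotations(
    protein_ids: list[str], seed: int, n_terms: int = 30
) -> pd.DataFrame:
    """Per-protein annotation table: localization, abundance class, terms.

    Abundance values are log-normal draws classed by quartiles (bottom 25%
    low, top 25% high); ~15% of proteins carry two localizations; term
    sets are drawn with popularity weights so some terms are common.
    """
    rng = np.random.default_rng(seed)
    n = len(protein_ids)
    abundance = rng.lognormal(mean=3.0, sigma=1.2, size=n)
    q25, q75 = np.quantile(abundance, [0.25, 0.75])
    classes = np.where(abundance <= q25, "low", np.where(abundance >= q75, "high", "medium"))
    term_ids = [f"GO:{7000 + t:07d}" for t in range(n_terms)]
    popularity = rng.dirichlet(np.full(n_terms, 0.5))
    rows = []
    for i, pid in enumerate(protein_ids):
        locs = list(rng.choice(_LOCALIZATIONS, size=2, replace=False)) if rng.random() < 0.15 else [
            str(rng.choice(_LOCALIZATIONS))
        ]
        k = int(rng.integers(2, 7))
        terms = list(np.array(term_ids)[rng.choice(n_terms, size=k, replace=False, p=None)])
        # bias toward popular terms by mixing one weighted draw in
        terms[0] = str(np.array(term_ids)[rng.choice(n_terms, p=popularity)])
        rows.append(
            {
                "id": pid,
                "localization": ";".join(sorted(set(locs))),
                "abundance": float(abundance[i]),
                "abundance_class": str(classes[i]),
                "terms": ";".join(sorted(set(terms))),
            }
        )
    return pd.DataFrame(rows)


def write_benchmark(benchmark: Benchmark, outdir: str | Path) -> None:
    """Write library/*.pdb, models/*.pdb, pairs.tsv and truth.tsv."""
    outdir = Path(outdir)
    (outdir / "library").mkdir(parents=True, exist_ok=True)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    for dimer in benchmark.library:
        write_pdb(dimer.as_structure(), outdir / "library" / f"{dimer.id}.pdb")
    for pair in benchmark.pairs:
        for models in (pair.models_a, pair.models_b):
            for k, m in enumerate(models):
                write_pdb(m, outdir / "models" / f"{m.id}_{k}.pdb")
    truth = benchmark.truth()
    truth[["id_a", "id_b", "label"]].to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
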