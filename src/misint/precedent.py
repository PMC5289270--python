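"""Structural-precedent search and interaction-model construction.

A *structural precedent* of a candidate protein pair (A, B) is a template
dimer (X, Y) such that each monomer is structurally similar to one template
chain.  Similarity of the pair to the template is summarized by TMmin, the
minimum of the two per-chain TM-scores, maximized over the two possible
chain assignments.  Superposing the monomers onto their precedent yields an
*interaction model*, which must pass an interface validity check (enough
interface residues, few CA clashes) to be accepted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .interface_features import interface_residues, residue_contact_pairs
from .structal import AlignmentResult, align_structures
from .structures_io import Chain, Structure

__all__ = [
    "DimerRecord",
    "PrecedentHit",
    "InteractionModel",
    "NoModelsError",
    "tmmin_for_template",
    "build_interaction_model",
    "validate_interface",
    "find_precedents",
    "AlignmentCache",
]


class NoModelsError(ValueError):
    """No 3D models available for one of the proteins (distinct from
    'models available but no precedent found')."""


@dataclass
class DimerRecord:
    """A two-chain template complex from the dimer library.

    Library members must have more than ``min_contacts`` inter-chain residue
    contacts at 5 A (the library inclusion rule).
    """

    id: str
    chain_x: Chain
    chain_y: Chain
    is_homodimer: bool = False
    is_obligate: bool = False
    from_higher_order: bool = False

    MIN_CONTACTS = 10

    def validate(self, cutoff: float = 5.0) -> None:
        n = len(residue_contact_pairs(self.chain_x, self.chain_y, cutoff))
        if n <= self.MIN_CONTACTS:
            raise ValueError(
                f"dimer {self.id}: {n} residue contacts at {cutoff} A "
                f"(library requires > {self.MIN_CONTACTS})"
            )

    def as_structure(self) -> Structure:
        return Structure(id=self.id, chains=[self.chain_x, self.chain_y])


@dataclass
class PrecedentHit:
    """One evaluated (pair, template) combination.

    ``assignment`` is ``"AX"`` when monomer A maps to template chain X (and
    B to Y), ``"AY"`` for the swapped assignment.
    """

    pair_id: str
    template_id: str
    assignment: str
    tm_a: float
    tm_b: float
    tmmin: float
    valid_interface: bool | None = None
    interface_size: int | None = None
    clash_count: int | None = None
    alignment_a: AlignmentResult | None = field(default=None, repr=False)
    alignment_b: AlignmentResult | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.tmmin, min(self.tm_a, self.tm_b)):
            raise ValueError("tmmin must equal min(tm_a, tm_b)")
        if not (0.0 <= self.tmmin <= 1.0):
            raise ValueError("tmmin out of [0, 1]")


@dataclass
class InteractionModel:
    """Two superposed monomers in the template frame, plus provenance."""

    structure: Structure
    provenance: PrecedentHit

    def __post_init__(self) -> None:
        if len(self.structure.chains) != 2:
            raise ValueError("interaction model must have exactly two chains")
        for chain in self.structure.chains:
            if not np.all(np.isfinite(chain.all_coords())):
                raise ValueError("non-finite coordinates in interaction model")


class AlignmentCache:
    """Memoizes chain-vs-template-chain alignments across a screen."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str, str], AlignmentResult] = {}

    def align(self, model: Structure, template: DimerRecord, which: str) -> AlignmentResult:
        key = (model.id, template.id, which)
        if key not in self._store:
            tchain = template.chain_x if which == "X" else template.chain_y
            self._store[key] = align_structures(model.chains[0], tchain)
        return self._store[key]


def tmmin_for_template(
    model_a: Structure | Chain,
    model_b: Structure | Chain,
    dimer: DimerRecord,
    pair_id: str = "",
    cache: AlignmentCache | None = None,
) -> PrecedentHit:
    """Score a candidate pair against one template dimer.

    Both chain assignments (A->X, B->Y) and (A->Y, B->X) are evaluated; the
    assignment with the larger min(tm_a, tm_b) wins (ties go to A->X).
    """

    def as_structure(m, name):
        if isinstance(m, Chain):
            return Structure(id=name, chains=[m])
        return m

    sa = as_structure(model_a, "model_a")
    sb = as_structure(model_b, "model_b")
    if cache is None:
        cache = AlignmentCache()
    ax = cache.align(sa, dimer, "X")
    by = cache.align(sb, dimer, "Y")
    ay = cache.align(sa, dimer, "Y")
    bx = cache.align(sb, dimer, "X")
    tm1 = min(ax.tm_score, by.tm_score)
    tm2 = min(ay.tm_score, bx.tm_score)
    if tm1 >= tm2:
        return PrecedentHit(
            pair_id=pair_id, template_id=dimer.id, assignment="AX",
            tm_a=ax.tm_score, tm_b=by.tm_score, tmmin=tm1,
            alignment_a=ax, alignment_b=by,
        )
    return PrecedentHit(
        pair_id=pair_id, template_id=dimer.id, assignment="AY",
        tm_a=ay.tm_score, tm_b=bx.tm_score, tmmin=tm2,
        alignment_a=ay, alignment_b=bx,
    )


def _transform_structure(s: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    out = copy.deepcopy(s)
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = rotation @ atom.coord + translation
    return out


def build_interaction_model(
    model_a: Structure | Chain,
    model_b: Structure | Chain,
    dimer: DimerRecord,
    hit: PrecedentHit,
) -> InteractionModel:
    """Place both monomers in the template frame using the hit's transforms.

    The template's own coordinates are not part of the output; only the two
    transformed monomers are.
    """
    if hit.alignment_a is None or hit.alignment_b is None:
        raise ValueError("hit carries no alignments; recompute with tmmin_for_template")

    def as_chain(m) -> Chain:
        if isinstance(m, Chain):
            return m
        if len(m.chains) != 1:
            raise ValueError("monomer model must have exactly one chain")
        return m.chains[0]

    ca = copy.deepcopy(as_chain(model_a))
    cb = copy.deepcopy(as_chain(model_b))
    for chain, aln in ((ca, hit.alignment_a), (cb, hit.alignment_b)):
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = aln.rotation @ atom.coord + aln.translation
    ca.id, cb.id = "A", "B"
    structure = Structure(id=f"{hit.pair_id}|{hit.template_id}", chains=[ca, cb])
    return InteractionModel(structure=structure, provenance=hit)


def validate_interface(
    model: InteractionModel | Structure,
    contact_cutoff: float = 5.0,
    min_interface: int = 20,
    clash_cutoff: float = 3.0,
    max_clashes: int = 2,
) -> tuple[bool, int, int]:
    """Interface validity: enough interface residues, few CA clashes.

    The interface size pools the residues of both chains (any atom within
    ``contact_cutoff`` of the partner chain); clashes are inter-chain CA
    pairs closer than ``clash_cutoff``.  Valid means interface_size >=
    ``min_interface`` and clash_count <= ``max_clashes``.
    """
    structure = getattr(model, "structure", model)
    res_a, res_b = interface_residues(structure, contact_cutoff)
    interface_size = len(res_a) + len(res_b)
    ca_a = structure.chains[0].ca_coords()
    ca_b = structure.chains[1].ca_coords()
    if len(ca_a) and len(ca_b):
        d2 = ((ca_a[:, None, :] - ca_b[None, :, :]) ** 2).sum(axis=2)
        clash_count = int((d2 < clash_cutoff**2).sum())
    else:
        clash_count = 0
    valid = interface_size >= min_interface and clash_count <= max_clashes
    return valid, interface_size, clash_count


def find_precedents(
    models_a: list[Structure],
    models_b: list[Structure],
    library: list[DimerRecord],
    threshold: float = 0.6,
    pair_id: str = "",
    cache: AlignmentCache | None = None,
) -> PrecedentHit | None:
    """Best valid structural precedent for a pair, or None.

    Every combination of candidate models and library dimers is scored by
    TMmin; hits at or above ``threshold`` are ranked by decreasing TMmin
    (ties by template id, then assignment order), and the first whose
    interaction model passes :func:`validate_interface` is returned.
    """
    if not library:
        raise ValueError("empty template library")
    if not models_a or not models_b:
        raise NoModelsError(f"pair {pair_id}: no 3D models for one protein")
    if cache is None:
        cache = AlignmentCache()
    hits: list[tuple[PrecedentHit, Structure, Structure]] = []
    for ma in models_a:
        for mb in models_b:
            for dimer in library:
                hit = tmmin_for_template(ma, mb, dimer, pair_id=pair_id, cache=cache)
                if hit.tmmin >= threshold:
                    hits.append((hit, ma, mb))
    hits.sort(key=lambda t: (-t[0].tmmin, t[0].template_id, t[0].assignment))
    by_id = {d.id: d for d in library}
    for hit, ma, mb in hits:
        model = build_interaction_model(ma, mb, by_id[hit.template_id], hit)
        valid, size, clashes = validate_interface(model)
        hit.valid_interface, hit.interface_size, hit.clash_count = valid, size, clashes
        if valid:
            return hit
    return None
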