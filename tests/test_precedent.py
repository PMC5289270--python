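import copy

import numpy as np
import pytest

from misint.precedent import (
    AlignmentCache,
    DimerRecord,
    InteractionModel,
    NoModelsError,
    PrecedentHit,
    build_interaction_model,
    find_precedents,
    tmmin_for_template,
    validate_interface,
)
from misint.structal import AlignmentResult
from misint.structures_io import Atom, Chain, Residue, Structure
from misint.synthetic_data import make_benchmark, perturb_structure, GeneratorConfig

from _oracles import brute_force_interface


class _StubCache:
    """Serves canned TM-scores for assignment-logic tests."""

    def __init__(self, scores):
        self.scores = scores  # (model id, template chain) -> tm

    def align(self, model, template, which):
        tm = self.scores[(model.id, which)]
        return AlignmentResult(
            mapping=np.array([[0, 0], [1, 1], [2, 2]]),
            rotation=np.eye(3),
            translation=np.zeros(3),
            rmsd=0.0,
            tm_score=tm,
            d0=1.0,
            norm_length=3,
        )


def _tiny_chain(cid="A"):
    res = [
        Residue(i + 1, "ALA", [Atom("CA", "C", [3.8 * i, 0.0, 0.0]), Atom("CB", "C", [3.8 * i, 1.5, 0.0])])
        for i in range(5)
    ]
    return Chain(cid, res)


def _fake_dimer():
    # geometry is irrelevant for the stub-cache tests; skip validation
    return DimerRecord(id="T", chain_x=_tiny_chain("A"), chain_y=_tiny_chain("B"))


class TestTMmin:
    def test_best_assignment_wins(self):
        """Of the two chain assignments, the larger min TM is returned."""
        a = Structure("A", [_tiny_chain()])
        b = Structure("B", [_tiny_chain()])
        scores = {("A", "X"): 0.7, ("B", "Y"): 0.65, ("A", "Y"): 0.3, ("B", "X"): 0.2}
        hit = tmmin_for_template(a, b, _fake_dimer(), cache=_StubCache(scores))
        assert hit.assignment == "AX"
        assert hit.tmmin == pytest.approx(0.65)

    def test_swapped_assignment_wins(self):
        a = Structure("A", [_tiny_chain()])
        b = Structure("B", [_tiny_chain()])
        scores = {("A", "X"): 0.2, ("B", "Y"): 0.3, ("A", "Y"): 0.8, ("B", "X"): 0.75}
        hit = tmmin_for_template(a, b, _fake_dimer(), cache=_StubCache(scores))
        assert hit.assignment == "AY"
        assert hit.tmmin == pytest.approx(0.75)

    def test_template_own_chains_score_one(self, small_dimer):
        a = Structure("ma", [copy.deepcopy(small_dimer.chain_x)])
        b = Structure("mb", [copy.deepcopy(small_dimer.chain_y)])
        a.chains[0].id = "A"
        b.chains[0].id = "A"
        hit = tmmin_for_template(a, b, small_dimer)
        assert hit.tmmin == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_under_pair_swap(self, small_dimer):
        cfg_seed = 77
        a = Structure("ma", [perturb_structure(small_dimer.chain_x, 0.3, cfg_seed)])
        b = Structure("mb", [perturb_structure(small_dimer.chain_y, 0.3, cfg_seed + 1)])
        h1 = tmmin_for_template(a, b, small_dimer)
        h2 = tmmin_for_template(b, a, small_dimer)
        assert h1.tmmin == pytest.approx(h2.tmmin, abs=1e-9)

    def test_hit_invariants(self):
        with pytest.raises(ValueError):
            PrecedentHit("p", "t", "AX", tm_a=0.7, tm_b=0.8, tmmin=0.8)


class TestBuildModel:
    def test_exact_copies_land_on_template(self, small_dimer):
        """Monomers that are re-posed template chains rebuild the template."""
        a = Structure("ma", [perturb_structure(small_dimer.chain_x, 0.0, 5)])
        b = Structure("mb", [perturb_structure(small_dimer.chain_y, 0.0, 6)])
        hit = tmmin_for_template(a, b, small_dimer)
        model = build_interaction_model(a, b, small_dimer, hit)
        np.testing.assert_allclose(
            model.structure.chains[0].all_coords(),
            small_dimer.chain_x.all_coords(),
            atol=1e-3,
        )
        np.testing.assert_allclose(
            model.structure.chains[1].all_coords(),
            small_dimer.chain_y.all_coords(),
            atol=1e-3,
        )

    def test_invariant_to_input_pose(self, small_dimer):
        """Superposition removes any pre-rotation of an input monomer."""
        a1 = Structure("ma", [perturb_structure(small_dimer.chain_x, 0.0, 5)])
        a2 = Structure("ma", [perturb_structure(small_dimer.chain_x, 0.0, 99)])
        b = Structure("mb", [perturb_structure(small_dimer.chain_y, 0.0, 6)])
        m1 = build_interaction_model(a1, b, small_dimer, tmmin_for_template(a1, b, small_dimer))
        m2 = build_interaction_model(a2, b, small_dimer, tmmin_for_template(a2, b, small_dimer))
        np.testing.assert_allclose(
            m1.structure.chains[0].all_coords(),
            m2.structure.chains[0].all_coords(),
            atol=1e-3,
        )

    def test_missing_alignment_rejected(self, small_dimer):
        hit = PrecedentHit("p", small_dimer.id, "AX", 0.9, 0.9, 0.9)
        a = Structure("ma", [copy.deepcopy(small_dimer.chain_x)])
        b = Structure("mb", [copy.deepcopy(small_dimer.chain_y)])
        with pytest.raises(ValueError):
            build_interaction_model(a, b, small_dimer, hit)


def _grid_chain(cid, n, y, spacing=3.8, z=0.0):
    res = []
    for i in range(n):
        res.append(Residue(i + 1, "LEU", [Atom("CA", "C", [spacing * i, y, z])]))
    return Chain(cid, res)


class TestValidateInterface:
    def test_distant_chains_invalid(self):
        s = Structure("m", [_grid_chain("A", 12, 0.0), _grid_chain("B", 12, 50.0)])
        valid, size, clashes = validate_interface(s)
        assert (valid, size, clashes) == (False, 0, 0)

    def test_twenty_residue_interface_is_valid(self):
        """Exactly 20 pooled interface residues, zero clashes -> valid."""
        s = Structure("m", [_grid_chain("A", 10, 0.0), _grid_chain("B", 10, 4.5)])
        valid, size, clashes = validate_interface(s)
        oracle = brute_force_interface(s.chains[0], s.chains[1], 5.0)
        assert size == len({i for i, _ in oracle}) + len({j for _, j in oracle}) == 20
        assert clashes == 0
        assert valid

    def test_three_clashes_invalid(self):
        a = _grid_chain("A", 25, 0.0, spacing=5.0)
        b_res = []
        for i in range(25):
            y = 2.0 if i < 3 else 4.5
            b_res.append(Residue(i + 1, "LEU", [Atom("CA", "C", [5.0 * i, y, 0.0])]))
        s = Structure("m", [a, Chain("B", b_res)])
        valid, size, clashes = validate_interface(s)
        assert clashes == 3
        assert not valid

    def test_agrees_with_brute_force(self, screen):
        """Interface sizes in the screen match a quadratic rescan."""
        models = screen.attrs["models"][:10]
        for model in models:
            _, size, _ = validate_interface(model)
            pairs = brute_force_interface(
                model.structure.chains[0], model.structure.chains[1], 5.0
            )
            assert size == len({i for i, _ in pairs}) + len({j for _, j in pairs})


@pytest.fixture(scope="module")
def tiny_bench():
    return make_benchmark(3, 3, 2, GeneratorConfig(seed=31, n_dimers=3))


class TestFindPrecedents:
    def test_planted_pair_recovers_its_template(self, tiny_bench):
        pair = tiny_bench.pairs[0]
        hit = find_precedents(pair.models_a, pair.models_b, tiny_bench.library, 0.6)
        assert hit is not None
        assert hit.template_id == pair.template
        assert hit.valid_interface

    def test_impossible_threshold_returns_none(self, tiny_bench):
        pair = tiny_bench.pairs[0]
        assert find_precedents(pair.models_a, pair.models_b, tiny_bench.library, 1.01) is None

    def test_threshold_monotonicity(self, tiny_bench):
        """A hit at threshold t is also found at any lower threshold."""
        pair = tiny_bench.pairs[0]
        cache = AlignmentCache()
        hit_hi = find_precedents(pair.models_a, pair.models_b, tiny_bench.library, 0.6, cache=cache)
        hit_lo = find_precedents(pair.models_a, pair.models_b, tiny_bench.library, 0.4, cache=cache)
        assert hit_hi is not None and hit_lo is not None
        assert hit_lo.template_id == hit_hi.template_id

    def test_no_models_is_distinct_outcome(self, tiny_bench):
        with pytest.raises(NoModelsError):
            find_precedents([], tiny_bench.pairs[0].models_b, tiny_bench.library, 0.6)

    def test_empty_library_rejected(self, tiny_bench):
        pair = tiny_bench.pairs[0]
        with pytest.raises(ValueError):
            find_precedents(pair.models_a, pair.models_b, [], 0.6)

    def test_deterministic(self, tiny_bench):
        pair = tiny_bench.pairs[1]
        h1 = find_precedents(pair.models_a, pair.models_b, tiny_bench.library, 0.5)
        h2 = find_precedents(pair.models_a, pair.models_b, tiny_bench.library, 0.5)
        assert h1.template_id == h2.template_id
        assert h1.tmmin == h2.tmmin
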