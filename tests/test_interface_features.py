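import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from misint.interface_features import (
    ContactSignature,
    ZeroInterfaceError,
    accessible_surface,
    contact_signature,
    gap_volume,
    interface_hydrophobicity,
    interface_residues,
    signature_distance,
)
from misint.structures_io import Atom, Chain, Residue, Structure

from _oracles import brute_force_interface


def _res(i, name, atoms):
    return Residue(i, name, [Atom(n, e, c) for n, e, c in atoms])


def _pair_structure(chain_a, chain_b):
    return Structure("m", [chain_a, chain_b])


class TestInterfaceResidues:
    def test_disjoint_chains_empty(self):
        a = Chain("A", [_res(1, "ALA", [("CA", "C", [0, 0, 0])])])
        b = Chain("B", [_res(1, "ALA", [("CA", "C", [50, 0, 0])])])
        ra, rb = interface_residues(_pair_structure(a, b))
        assert ra == set() and rb == set()

    def test_single_cb_pair_at_boundary(self):
        """One CB-CB pair at 4.9 A makes exactly one residue per chain."""
        a = Chain("A", [
            _res(1, "LEU", [("CA", "C", [0, 0, 0]), ("CB", "C", [0, 1.5, 0])]),
            _res(2, "ALA", [("CA", "C", [30, 0, 0])]),
        ])
        b = Chain("B", [
            _res(1, "VAL", [("CA", "C", [0, 8.0, 0]), ("CB", "C", [0, 6.4, 0])]),
            _res(2, "ALA", [("CA", "C", [30, 30, 0])]),
        ])
        ra, rb = interface_residues(_pair_structure(a, b))
        assert ra == {0} and rb == {0}
        oracle = brute_force_interface(a, b, 5.0)
        assert oracle == {(0, 0)}

    def test_matches_quadratic_scan_on_random_models(self, screen):
        for model in screen.attrs["models"][:8]:
            a, b = model.structure.chains
            ra, rb = interface_residues(model.structure)
            oracle = brute_force_interface(a, b, 5.0)
            assert ra == {i for i, _ in oracle}
            assert rb == {j for _, j in oracle}


class TestAccessibleSurface:
    def test_single_sphere_analytic(self):
        s = Structure("x", [Chain("A", [_res(1, "ALA", [("CA", "C", [0, 0, 0])])])])
        asa = accessible_surface(s)
        analytic = 4 * np.pi * (1.87 + 1.4) ** 2
        assert float(asa.iloc[0]) == pytest.approx(analytic, rel=0.02)

    def test_distant_atoms_additive(self):
        s2 = Structure("x", [Chain("A", [
            _res(1, "ALA", [("CA", "C", [0, 0, 0])]),
            _res(2, "ALA", [("CA", "C", [100, 0, 0])]),
        ])])
        asa = accessible_surface(s2)
        single = 4 * np.pi * (1.87 + 1.4) ** 2
        assert float(asa.sum()) == pytest.approx(2 * single, rel=0.02)

    def test_occlusion_decreases_asa(self):
        lone = Structure("x", [Chain("A", [_res(1, "ALA", [("CA", "C", [0, 0, 0])])])])
        touching = Structure("x", [Chain("A", [
            _res(1, "ALA", [("CA", "C", [0, 0, 0])]),
            _res(2, "ALA", [("CA", "C", [3.0, 0, 0])]),
        ])])
        a1 = float(accessible_surface(lone).sum())
        a2 = float(accessible_surface(touching).iloc[0])
        assert a2 < a1

    def test_point_count_convergence(self, small_dimer):
        s = Structure("x", [small_dimer.chain_x])
        coarse = float(accessible_surface(s, n_points=480).sum())
        fine = float(accessible_surface(s, n_points=960).sum())
        assert abs(fine - coarse) / fine < 0.01

    def test_cross_check_against_biotite(self, small_dimer):
        """Independent Shrake-Rupley route (biotite, same radii) agrees."""
        import biotite.structure as struc

        chain = small_dimer.chain_x
        atoms = [(r, a) for r in chain.residues for a in r.atoms]
        arr = struc.AtomArray(len(atoms))
        arr.coord = np.array([a.coord for _, a in atoms], dtype=np.float32)
        arr.chain_id = np.array(["A"] * len(atoms))
        arr.res_id = np.array([r.index for r, _ in atoms])
        arr.res_name = np.array([r.name for r, _ in atoms])
        arr.atom_name = np.array([a.name for _, a in atoms])
        arr.element = np.array([a.element.upper() for _, a in atoms])
        from misint.interface_features import ATOM_RADII

        radii = np.array([ATOM_RADII[a.element.upper()] for _, a in atoms])
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=960)
        from misint.structures_io import Structure as S

        mine = accessible_surface(S("x", [chain]), n_points=960)
        assert float(mine.sum()) == pytest.approx(float(ref.sum()), rel=0.02)

    def test_unknown_element_rejected(self):
        s = Structure("x", [Chain("A", [_res(1, "ALA", [("XX", "Xx", [0, 0, 0])])])])
        with pytest.raises(ValueError, match="radius"):
            accessible_surface(s)


def _slab(cid, names, y, with_cb=True):
    res = []
    for i, name in enumerate(names):
        atoms = [("CA", "C", [4.5 * i, y, 0.0])]
        if with_cb and name != "GLY":
            cb_y = y + 1.5 if y < 3 else y - 1.5
            atoms.append(("CB", "C", [4.5 * i, cb_y, 0.0]))
        res.append(_res(i + 1, name, atoms))
    return Chain(cid, res)


class TestHydrophobicity:
    def _compute(self, names_a, names_b):
        a = _slab("A", names_a, 0.0)
        b = _slab("B", names_b, 6.0)
        s = _pair_structure(a, b)
        cpx = accessible_surface(s)
        iso = accessible_surface(Structure("a", [a])).combine_first(
            accessible_surface(Structure("b", [b]))
        )
        # keep original ordering irrelevant; interface_hydrophobicity aligns by index
        return interface_hydrophobicity(s, iso, cpx)

    def test_pure_hydrophobic_interface(self):
        frac, area = self._compute(["LEU"] * 6, ["LEU"] * 6)
        assert frac == pytest.approx(1.0)
        assert area > 0

    def test_pure_charged_interface(self):
        frac, _ = self._compute(["ASP"] * 6, ["GLU"] * 6)
        assert frac == pytest.approx(0.0)

    def test_mixed_interface_matches_hand_sum(self):
        """Hand-summed buried-area ledger reproduces the fraction."""
        names_a, names_b = ["LEU", "ASP", "VAL"], ["SER", "PHE", "LYS"]
        a = _slab("A", names_a, 0.0)
        b = _slab("B", names_b, 6.0)
        s = _pair_structure(a, b)
        cpx = accessible_surface(s)
        iso_a = accessible_surface(Structure("a", [a]))
        iso_b = accessible_surface(Structure("b", [b]))
        iso = iso_a.combine_first(iso_b)
        frac, area = interface_hydrophobicity(s, iso, cpx)
        hydro_names = {"LEU", "VAL", "PHE"}
        num = den = 0.0
        for chain, names in (("A", names_a), ("B", names_b)):
            for i, name in enumerate(names):
                d = max(0.0, float(iso[(chain, i + 1)]) - float(cpx[(chain, i + 1)]))
                den += d
                if name in hydro_names:
                    num += d
        assert frac == pytest.approx(num / den, abs=1e-9)
        assert area == pytest.approx(den / 2, abs=1e-9)

    def test_no_interface_flagged(self):
        a = _slab("A", ["LEU"] * 3, 0.0)
        b = _slab("B", ["LEU"] * 3, 60.0)
        s = _pair_structure(a, b)
        cpx = accessible_surface(s)
        iso = accessible_surface(Structure("a", [a])).combine_first(
            accessible_surface(Structure("b", [b]))
        )
        with pytest.raises(ZeroInterfaceError):
            interface_hydrophobicity(s, iso, cpx)


class TestGapVolume:
    def test_distant_chains_zero(self):
        a = _slab("A", ["LEU"] * 5, 0.0)
        b = _slab("B", ["LEU"] * 5, 40.0)
        assert gap_volume(_pair_structure(a, b)) == 0.0

    def test_monotone_in_separation(self):
        """Wider parallel CB sheets enclose strictly more gap volume.

        The expanded spheres (1.87 + 1.4 A) of two facing sheets touch up
        to ~6.5 A separation, so the inter-sheet slit only opens beyond
        that; within the open regime the volume must grow with the
        separation (shell widened so the slit, not the rim, dominates).
        """

        def sheet(cid, z):
            res = []
            k = 0
            for i in range(8):
                for j in range(8):
                    k += 1
                    res.append(_res(k, "LEU", [("CB", "C", [3.5 * i, 3.5 * j, z])]))
            return Chain(cid, res)

        vols = []
        for sep in (7.0, 8.0, 9.0):
            vols.append(
                gap_volume(
                    _pair_structure(sheet("A", 0.0), sheet("B", sep)),
                    grid_spacing=0.5,
                    shell=8.0,
                )
            )
        assert vols[0] < vols[1] < vols[2]

    def test_grid_convergence(self, small_dimer):
        s = small_dimer.as_structure()
        v1 = gap_volume(s, grid_spacing=1.0)
        v05 = gap_volume(s, grid_spacing=0.5)
        assert abs(v1 - v05) / v05 < 0.15


class TestContactSignature:
    def test_single_leu_asp_contact(self):
        a = Chain("A", [_res(1, "LEU", [("CA", "C", [0, 0, 0])])])
        b = Chain("B", [_res(1, "ASP", [("CA", "C", [5, 0, 0])])])
        sig = contact_signature(_pair_structure(a, b))
        # class 0 = {V,I,M,C,L}, class 5 = {D,E}
        assert sig.counts[0, 5] == 1 and sig.counts[5, 0] == 1
        assert sig.total() == 1

    def test_no_contacts_zero_matrix(self):
        a = Chain("A", [_res(1, "LEU", [("CA", "C", [0, 0, 0])])])
        b = Chain("B", [_res(1, "ASP", [("CA", "C", [20, 0, 0])])])
        sig = contact_signature(_pair_structure(a, b))
        assert sig.counts.sum() == 0
        with pytest.raises(ZeroInterfaceError):
            signature_distance(sig, sig)

    def test_total_matches_brute_force(self, small_dimer):
        from _oracles import brute_force_ca_contacts

        sig = contact_signature(small_dimer.as_structure(), cutoff=12.0)
        n = brute_force_ca_contacts(small_dimer.chain_x, small_dimer.chain_y, 12.0)
        assert sig.total() == n


class TestPositiveNegativeOverlap:
    def test_descriptor_distributions_overlap(self, screen):
        """Positive and negative models are not separable by descriptors.

        The interface ASA, hydrophobicity and gap-index distributions of
        interacting vs non-interacting models overlap substantially
        (overlap coefficient > 0.5 by kernel density on the benchmark).
        """
        from scipy.stats import gaussian_kde

        from misint.interface_features import interface_descriptors
        from misint.pipeline import best_hits

        best = best_hits(screen, threshold=0.6)
        winners = {(r["pair_id"], r["template"]) for _, r in best.iterrows()}
        labels = screen[["pair_id", "label"]].drop_duplicates().set_index("pair_id")["label"]
        rows = []
        for model in screen.attrs["models"]:
            hit = model.provenance
            if (hit.pair_id, hit.template_id) not in winners:
                continue
            d = interface_descriptors(model)
            rows.append((labels[hit.pair_id], d.interface_asa, d.hydrophobicity, d.gap_index))
        import pandas as pd

        df = pd.DataFrame(rows, columns=["label", "interface_asa", "hydrophobicity", "gap_index"])
        pos = df[df["label"] == "interacting"]
        neg = df[df["label"] == "non-interacting"]
        assert len(pos) >= 3 and len(neg) >= 3
        for col in ("interface_asa", "hydrophobicity", "gap_index"):
            lo = min(pos[col].min(), neg[col].min())
            hi = max(pos[col].max(), neg[col].max())
            grid = np.linspace(lo - 0.2 * (hi - lo) - 1e-9, hi + 0.2 * (hi - lo) + 1e-9, 256)
            f1 = gaussian_kde(pos[col])(grid)
            f2 = gaussian_kde(neg[col])(grid)
            ovl = np.trapezoid(np.minimum(f1, f2), grid)
            assert ovl > 0.5, f"{col}: overlap {ovl:.2f}"


class TestSignatureDistance:
    def test_identical_signatures(self, small_dimer):
        sig = contact_signature(small_dimer.as_structure())
        assert signature_distance(sig, sig) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support(self):
        m1 = np.zeros((7, 7), int)
        m2 = np.zeros((7, 7), int)
        m1[0, 0] = 4
        m2[5, 5] = 3
        assert signature_distance(ContactSignature(m1), ContactSignature(m2)) == pytest.approx(1.0)

    def test_scale_invariance(self):
        m = np.arange(49).reshape(7, 7)
        m = m + m.T
        s1, s2 = ContactSignature(m), ContactSignature(2 * m)
        assert signature_distance(s1, s2) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 2**31 - 1))
    def test_bounds_and_symmetry(self, seed1, seed2):
        rng1, rng2 = np.random.default_rng(seed1), np.random.default_rng(seed2)
        m1 = rng1.integers(0, 5, size=(7, 7))
        m2 = rng2.integers(0, 5, size=(7, 7))
        m1, m2 = m1 + m1.T, m2 + m2.T
        if m1.sum() == 0 or m2.sum() == 0:
            return
        s1, s2 = ContactSignature(m1), ContactSignature(m2)
        d12 = signature_distance(s1, s2)
        assert 0.0 <= d12 <= 1.0
        assert d12 == pytest.approx(signature_distance(s2, s1), abs=1e-12)
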