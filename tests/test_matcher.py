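import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (descriptors_to_site, oracle_best_match,
                     random_descriptors, scipy_rmsd)
from nucsite import fixtures
from nucsite.matcher import (MatchParams, blosum62, find_matches,
                             kabsch_superpose, scan_library, validate_match)
from nucsite.structio import ResidueDescriptor
from nucsite.templates import Library


class TestKabsch:
    def test_identical_points(self, rng):
        pts = rng.uniform(0, 10, (4, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)
        assert rmsd == pytest.approx(0, abs=1e-9)

    def test_recovers_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.uniform(0, 10, (6, 3))
        R_true = Rotation.random(rng=rng).as_matrix()
        t_true = rng.uniform(-5, 5, 3)
        moved = pts @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0, abs=1e-9)
        assert np.allclose(R, R_true, atol=1e-8)
        assert np.allclose(t, t_true, atol=1e-8)

    def test_matches_independent_minimizer(self, rng):
        for _ in range(20):
            P = rng.uniform(0, 10, (4, 3))
            Q = rng.uniform(0, 10, (4, 3))
            _, _, rmsd = kabsch_superpose(P, Q)
            assert rmsd == pytest.approx(scipy_rmsd(P, Q), abs=1e-6)

    def test_rotation_always_proper(self, rng):
        for _ in range(20):
            P = rng.uniform(0, 5, (3, 3))
            Q = rng.uniform(0, 5, (3, 3))
            R, _, _ = kabsch_superpose(P, Q)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))


class TestBlosum62:
    @pytest.mark.parametrize("a,b,score", [
        ("W", "W", 11), ("A", "A", 4), ("C", "C", 9),
        ("W", "G", -2), ("K", "E", 1),
    ])
    def test_published_values(self, a, b, score):
        assert blosum62(a, b) == score

    def test_symmetry_all_pairs(self):
        aas = "ARNDCQEGHILKMFPSTWYV"
        for a in aas:
            for b in aas:
                assert blosum62(a, b) == blosum62(b, a)

    def test_x_scores_row_minimum(self):
        assert blosum62("X", "W") == min(
            blosum62(a, "W") for a in "ARNDCQEGHILKMFPSTWYV")

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError):
            blosum62("B", "A")


class TestFindMatches:
    def test_verbatim_copy_matches_exactly(self, rng):
        site = fixtures.make_synthetic_site(4, seed=3)
        query = [ResidueDescriptor(("Q", i + 1, ""), r.aa, r.ca.copy(),
                                   r.sc_center.copy())
                 for i, r in enumerate(site.residues)]
        ms = find_matches(query, site)
        assert ms and ms[0].size == 4
        assert ms[0].rmsd == pytest.approx(0, abs=1e-9)

    def test_planted_noisy_motif_recovered(self):
        site = fixtures.make_synthetic_site(4, seed=11)
        decoy = fixtures.make_decoy_chain(30, seed=12)
        query_st, _ = fixtures.plant_motif(decoy, site, sigma=0.1, seed=13)
        from nucsite.structio import residue_descriptors
        query = residue_descriptors(query_st, "A")
        ms = find_matches(query, site)
        assert ms and ms[0].size == 4 and ms[0].rmsd <= 0.6

    def test_all_outputs_satisfy_contracts(self, rng):
        params = MatchParams()
        for _ in range(20):
            tmpl = random_descriptors(rng, int(rng.integers(3, 6)), box=8,
                                      prefix="T")
            query = random_descriptors(rng, int(rng.integers(6, 12)))
            site = descriptors_to_site(tmpl)
            for m in find_matches(query, site, params):
                validate_match(m, query, tmpl, params)

    def test_oracle_equivalence_small_instances(self, rng):
        params = MatchParams()
        for trial in range(30):
            tmpl = random_descriptors(rng, int(rng.integers(3, 6)), box=7,
                                      prefix="T")
            query = random_descriptors(rng, int(rng.integers(5, 10)))
            if trial % 2 == 0:
                # plant a noisy copy so matches exist
                for i, tr in enumerate(tmpl[:len(query)]):
                    query[i] = ResidueDescriptor(
                        ("Q", i + 1, ""), tr.aa,
                        tr.ca + rng.normal(0, 0.05, 3),
                        tr.sc_center + rng.normal(0, 0.05, 3))
            site = descriptors_to_site(tmpl)
            ms = find_matches(query, site, params)
            impl = (ms[0].size, ms[0].rmsd) if ms else (0, np.inf)
            orc = oracle_best_match(query, tmpl, params)
            assert impl[0] == orc[0]
            if impl[0]:
                assert impl[1] == pytest.approx(orc[1], abs=1e-6)

    def test_rmsd_monotonicity_in_threshold(self, rng):
        for _ in range(10):
            tmpl = random_descriptors(rng, 4, box=7, prefix="T")
            query = random_descriptors(rng, 9)
            site = descriptors_to_site(tmpl)
            sizes = []
            for rmsd_max in (0.6, 1.2, 2.4):
                ms = find_matches(query, site, MatchParams(rmsd_max=rmsd_max))
                sizes.append(ms[0].size if ms else 0)
            assert sizes == sorted(sizes)

    def test_rigid_invariance_of_query(self, rng):
        from scipy.spatial.transform import Rotation
        site = fixtures.make_synthetic_site(4, seed=21)
        decoy = fixtures.make_decoy_chain(15, seed=22)
        query_st, _ = fixtures.plant_motif(decoy, site, sigma=0.1, seed=23)
        from nucsite.structio import residue_descriptors
        query = residue_descriptors(query_st, "A")
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = [ResidueDescriptor(d.residue_ref, d.aa,
                                   R @ d.ca + t, R @ d.sc_center + t)
                 for d in query]
        m0 = find_matches(query, site)
        m1 = find_matches(moved, site)
        assert [m.pairs for m in m0] == [m.pairs for m in m1]
        for a, b in zip(m0, m1):
            assert a.rmsd == pytest.approx(b.rmsd, abs=1e-9)

    def test_empty_query_no_match(self):
        site = fixtures.make_synthetic_site(4, seed=5)
        assert find_matches([], site) == []

    def test_match_cap_respected(self):
        site = fixtures.make_synthetic_site(4, seed=7)
        query = []
        # 3 displaced copies of the motif produce many maximal pairings
        for copy_i in range(3):
            off = np.array([25.0 * copy_i, 0.0, 0.0])
            for i, r in enumerate(site.residues):
                query.append(ResidueDescriptor(
                    ("Q", 10 * copy_i + i, ""), r.aa, r.ca + off,
                    r.sc_center + off))
        params = MatchParams(max_matches_per_template=2)
        assert len(find_matches(query, site, params)) <= 2


class TestScanLibrary:
    def test_source_chain_matches_own_site(self, amp_complex, amp_library):
        from nucsite.structio import residue_descriptors
        descs = residue_descriptors(amp_complex, "A")
        hits = scan_library(descs, amp_library)
        for module_type in ("nucleobase", "carbohydrate", "phosphate"):
            assert len(hits[module_type]) >= 1

    def test_empty_library(self, amp_complex):
        from nucsite.structio import residue_descriptors
        descs = residue_descriptors(amp_complex, "A")
        hits = scan_library(descs, Library([]))
        assert all(v == [] for v in hits.values())

    def test_duplicated_template_duplicates_matches(self, amp_complex,
                                                    amp_library):
        import copy
        from nucsite.structio import residue_descriptors
        descs = residue_descriptors(amp_complex, "A")
        single = scan_library(descs, amp_library)
        twin_sites = amp_library.sites + [copy.deepcopy(s)
                                          for s in amp_library.sites]
        doubled = scan_library(descs, Library(twin_sites))
        for t in single:
            assert len(doubled[t]) == 2 * len(single[t])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_kabsch_rigid_pair_property(seed):
    """RMSD of a set against a rigidly moved copy of itself is zero and
    the recovered rotation is proper."""
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation
    pts = rng.uniform(-10, 10, (5, 3))
    R_true = Rotation.random(rng=rng).as_matrix()
    moved = pts @ R_true.T + rng.uniform(-3, 3, 3)
    R, _, rmsd = kabsch_superpose(pts, moved)
    assert rmsd < 1e-8
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)
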