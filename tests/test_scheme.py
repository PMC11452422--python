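"""Scheme generation, ordering, and the three subsampling strategies."""

import itertools

import numpy as np
import pytest

import dkisub as dk
from dkisub.scheme import (InfeasibleSubsetError, SingularConfigurationError,
                           SubsetSpec)

from conftest import unit_rows

SHELL_COUNTS = {32: {0.95: 30, 0.9: 29, 0.8: 26, 0.7: 22, 0.6: 19, 0.5: 16},
                60: {0.95: 57, 0.9: 54, 0.8: 48, 0.7: 42, 0.6: 36, 0.5: 30}}


class TestSubsetSizes:
    @pytest.mark.parametrize("n_dirs,fraction,expected", [
        (n, f, c) for n, row in SHELL_COUNTS.items() for f, c in row.items()
    ])
    def test_published_shell_counts(self, n_dirs, fraction, expected):
        assert dk.subset_sizes(n_dirs, fraction) == expected

    def test_identity_fraction(self):
        assert dk.subset_sizes(32, 1.0) == 32

    def test_fraction_domain(self):
        with pytest.raises(ValueError):
            dk.subset_sizes(32, 0.0)
        with pytest.raises(ValueError):
            dk.subset_sizes(32, 1.2)

    def test_too_small_subset(self):
        with pytest.raises(InfeasibleSubsetError):
            dk.subset_sizes(8, 0.5)


class TestElectrostaticEnergy:
    def test_orthogonal_pair(self):
        # both the difference and the sum of orthogonal unit vectors have
        # norm sqrt(2), so the pair contributes 2/sqrt(2) = sqrt(2)
        assert dk.electrostatic_energy([(1, 0, 0), (0, 1, 0)]) == pytest.approx(
            np.sqrt(2), rel=1e-12)

    def test_orthogonal_triple(self):
        assert dk.electrostatic_energy(
            [(1, 0, 0), (0, 1, 0), (0, 0, 1)]) == pytest.approx(3 * np.sqrt(2),
                                                                rel=1e-12)

    def test_coincident_pair_is_singular(self):
        with pytest.raises(SingularConfigurationError):
            dk.electrostatic_energy([(1, 0, 0), (1, 0, 0)])

    def test_antipodal_pair_is_singular(self):
        with pytest.raises(SingularConfigurationError):
            dk.electrostatic_energy([(1, 0, 0), (-1, 0, 0)])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_and_sign_flip_invariance(self, seed):
        from dkisub.sphere import random_rotation

        u = unit_rows(12, seed)
        e0 = dk.electrostatic_energy(u)
        r = random_rotation(np.random.default_rng(seed + 10))
        assert dk.electrostatic_energy(u @ r.T) == pytest.approx(e0, rel=1e-9)
        flipped = u.copy()
        flipped[::2] *= -1.0
        assert dk.electrostatic_energy(flipped) == pytest.approx(e0, rel=1e-9)


class TestCoveringRadius:
    def test_analytic_values(self):
        assert dk.covering_radius([(1, 0, 0), (0, 1, 0), (0, 0, 1)]) == pytest.approx(90.0)
        c, s = np.cos(np.radians(60)), np.sin(np.radians(60))
        assert dk.covering_radius([(1, 0, 0), (c, s, 0)]) == pytest.approx(60.0)
        assert dk.covering_radius([(1, 0, 0), (-1, 0, 0)]) == pytest.approx(0.0)

    def test_needs_two_directions(self):
        with pytest.raises(ValueError):
            dk.covering_radius([(1, 0, 0)])

    @pytest.mark.parametrize("seed", [3, 4])
    def test_non_increasing_as_directions_added(self, seed):
        u = unit_rows(10, seed)
        radii = [dk.covering_radius(u[:k]) for k in range(2, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(radii, radii[1:]))


class TestGenerate:
    def test_reference_scheme_scale(self, reference_scheme):
        s = reference_scheme
        assert s.n_volumes == 100
        assert (~s.dw_mask).sum() == 8
        assert len(s.shell_indices(1)) == 32
        assert len(s.shell_indices(2)) == 60
        norms = np.linalg.norm(s.directions[s.dw_mask], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_optimized_shell_beats_random_baseline(self):
        scheme = dk.generate_multishell_scheme(
            {1: 60}, {1: 2000.0}, n_b0=1, seed=3, n_restarts=3)
        opt = dk.electrostatic_energy(scheme.directions[scheme.shell_id == 1])
        best_random = min(
            dk.electrostatic_energy(unit_rows(60, s)) for s in range(100))
        assert opt < best_random

    def test_six_directions_near_octahedral(self):
        scheme = dk.generate_multishell_scheme(
            {1: 6}, {1: 1000.0}, n_b0=1, seed=2, n_restarts=5)
        dirs = scheme.directions[scheme.shell_id == 1]
        # the optimal 6-line arrangement (icosahedral axes) has 63.43° spacing
        assert dk.covering_radius(dirs) >= 60.0
        best_random = min(
            dk.electrostatic_energy(unit_rows(6, s)) for s in range(100))
        assert dk.electrostatic_energy(dirs) <= best_random

    def test_deterministic_given_seed(self):
        a = dk.generate_multishell_scheme({1: 8}, {1: 1000.0}, 2, seed=7,
                                          n_restarts=2)
        b = dk.generate_multishell_scheme({1: 8}, {1: 1000.0}, 2, seed=7,
                                          n_restarts=2)
        np.testing.assert_array_equal(a.directions, b.directions)


class TestIncrementalOrdering:
    def test_output_is_permutation(self, reference_scheme):
        # ordering only rearranges volumes; rebase() was applied so compare
        # the multiset of (direction, b) pairs against a fresh generation
        s = reference_scheme
        assert sorted(s.bvalues.tolist()) == [0.0] * 8 + [1000.0] * 32 + [2000.0] * 60

    def test_prefix_proportions_within_one(self, reference_scheme):
        s = reference_scheme
        dw_positions = np.flatnonzero(s.dw_mask)
        c1 = c2 = 0
        for length, pos in enumerate(dw_positions, start=1):
            if s.shell_id[pos] == 1:
                c1 += 1
            else:
                c2 += 1
            assert abs(c1 - length * 32 / 92) <= 1 + 1e-9
            assert abs(c2 - length * 60 / 92) <= 1 + 1e-9

    def test_first_volume_is_b0_and_b0s_interleaved(self, reference_scheme):
        b0_pos = np.flatnonzero(~reference_scheme.dw_mask)
        assert b0_pos[0] == 0
        gaps = np.diff(b0_pos)
        assert gaps.max() - gaps.min() <= 1

    @pytest.mark.parametrize("k", [20, 46, 70])
    def test_prefix_energy_beats_random_prefixes(self, reference_scheme, k):
        s = reference_scheme
        dw_positions = np.flatnonzero(s.dw_mask)
        prefix = s.directions[dw_positions[:k]]
        e_prefix = dk.electrostatic_energy(prefix)
        rng = np.random.default_rng(11)
        energies = []
        for _ in range(100):
            pick = rng.permutation(len(dw_positions))[:k]
            energies.append(
                dk.electrostatic_energy(s.directions[dw_positions[pick]]))
        assert e_prefix <= np.median(energies)


class TestSubsampleEEM:
    def test_prefix_nesting(self, reference_scheme):
        prev = None
        for fraction in (0.95, 0.9, 0.8, 0.7, 0.6, 0.5):
            spec = SubsetSpec.from_scheme(reference_scheme, fraction)
            sub = dk.subsample_eem(reference_scheme, spec)
            members = set(sub.source_index.tolist())
            if prev is not None:
                assert members <= prev
            prev = members

    def test_counts_match_spec(self, reference_scheme):
        spec = SubsetSpec.from_scheme(reference_scheme, 0.5)
        sub = dk.subsample_eem(reference_scheme, spec)
        assert len(sub.shell_indices(1)) == 16
        assert len(sub.shell_indices(2)) == 30
        assert (~sub.dw_mask).sum() == 8


class TestSubsampleSC:
    def test_sequential_chain_is_nested(self, small_scheme):
        prev = None
        prev_members = None
        for fraction in (0.95, 0.8, 0.6, 0.5):
            spec = SubsetSpec.from_scheme(small_scheme, fraction)
            sub = dk.subsample_sc(small_scheme, spec, previous=prev)
            members = set(sub.source_index.tolist())
            if prev_members is not None:
                assert members <= prev_members
            prev, prev_members = sub, members

    def test_covering_radius_monotone_under_removal(self, reference_scheme):
        spec = SubsetSpec.from_scheme(reference_scheme, 0.5)
        sub = dk.subsample_sc(reference_scheme, spec)
        for shell in (1, 2):
            cr_full = dk.covering_radius(
                reference_scheme.directions[reference_scheme.shell_id == shell])
            cr_sub = dk.covering_radius(sub.directions[sub.shell_id == shell])
            assert cr_sub >= cr_full - 1e-9

    def test_greedy_exchange_beats_random_search(self):
        # choose 8 of 16 on one shell; exhaustive search is the oracle
        dirs = unit_rows(16, 21)
        scheme = dk.GradientScheme(
            directions=dirs, bvalues=np.full(16, 1000.0),
            shell_id=np.ones(16, dtype=int))
        spec = SubsetSpec(fraction_retained=0.5, per_shell_counts={1: 8})
        sub = dk.subsample_sc(scheme, spec)
        achieved = dk.covering_radius(sub.directions)
        best_random = max(
            dk.covering_radius(dirs[np.random.default_rng(s).permutation(16)[:8]])
            for s in range(1000))
        exhaustive = max(
            dk.covering_radius(dirs[list(combo)])
            for combo in itertools.combinations(range(16), 8))
        assert achieved >= best_random - 1e-12
        assert achieved <= exhaustive + 1e-12

    def test_infeasible_spec_raises(self, small_scheme):
        spec = SubsetSpec(fraction_retained=0.5, per_shell_counts={1: 99, 2: 99})
        with pytest.raises(InfeasibleSubsetError):
            dk.subsample_sc(small_scheme, spec)


class TestSubsampleRandom:
    def test_full_fraction_is_permutation(self, reference_scheme):
        spec = SubsetSpec.from_scheme(reference_scheme, 1.0)
        sub = dk.subsample_random(reference_scheme, spec, seed=3)
        assert sub.n_volumes == reference_scheme.n_volumes
        assert sorted(sub.source_index.tolist()) == list(range(100))

    def test_deterministic_given_seed(self, reference_scheme):
        spec = SubsetSpec.from_scheme(reference_scheme, 0.5)
        a = dk.subsample_random(reference_scheme, spec, seed=7)
        b = dk.subsample_random(reference_scheme, spec, seed=7)
        np.testing.assert_array_equal(a.source_index, b.source_index)

    def test_truncates_to_matching_total(self, reference_scheme):
        spec = SubsetSpec.from_scheme(reference_scheme, 0.5)
        sub = dk.subsample_random(reference_scheme, spec, seed=7)
        assert sub.n_volumes == 8 + 16 + 30

    def test_sc_beats_random_on_covering_radius(self, reference_scheme):
        spec = SubsetSpec.from_scheme(reference_scheme, 0.5)
        sc = dk.subsample_sc(reference_scheme, spec)
        cr_sc = dk.covering_radius(sc.directions[sc.dw_mask])
        crs = []
        for seed in range(200):
            sub = dk.subsample_random(reference_scheme, spec, seed=seed)
            crs.append(dk.covering_radius(sub.directions[sub.dw_mask]))
        assert np.median(crs) < cr_sc
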