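"""Clustering, COM-centered profiles, PMF, and contact statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from condgram.constants import KB
from condgram.analysis import (
    RadialProfile,
    cluster_metrics,
    condensate_com,
    contact_numbers,
    find_clusters,
    pmf_from_rdf,
    rdf_about_com,
    shell_coverage,
    weighted_mean_pmf,
)
from condgram.synthetic import default_fixture_spec, generate_fixture


# --- independent oracles ----------------------------------------------------

def union_find_clusters(positions, box, cutoff):
    """Brute-force union-find over all pairs (the clustering oracle)."""
    n = len(positions)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            d = d - box * np.round(d / box)
            if float(d @ d) <= cutoff * cutoff:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    return roots


def partitions_equal(labels_a, roots_b):
    seen = {}
    for la, rb in zip(labels_a, roots_b):
        if la in seen:
            if seen[la] != rb:
                return False
        else:
            seen[la] = rb
    return len(set(seen.values())) == len(seen)


class TestClustering:
    def test_all_separated_gives_singletons(self):
        pos = np.array([[1.0, 1, 1], [5, 5, 5], [9, 1, 9]])
        labels = find_clusters(pos, 12.0, 1.0)
        assert len(np.unique(labels)) == 3

    def test_linear_chain_is_one_cluster(self):
        pos = np.column_stack([np.arange(10) * 0.5, np.zeros(10), np.zeros(10)])
        labels = find_clusters(pos + 1.0, 20.0, 0.6)
        assert len(np.unique(labels)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.random((100, 3)) * 10.0
        labels = find_clusters(pos, 10.0, 0.9)
        assert partitions_equal(labels, union_find_clusters(pos, 10.0, 0.9))

    def test_invariant_to_reordering_and_translation(self):
        rng = np.random.default_rng(3)
        pos = rng.random((80, 3)) * 8.0
        base = find_clusters(pos, 8.0, 0.8)
        perm = rng.permutation(80)
        permuted = find_clusters(pos[perm], 8.0, 0.8)
        assert partitions_equal(base[perm], list(permuted))
        shifted = find_clusters(np.mod(pos + 6.3, 8.0), 8.0, 0.8)
        assert partitions_equal(base, list(shifted))

    def test_cluster_count_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(4)
        pos = rng.random((120, 3)) * 9.0
        counts = [
            len(np.unique(find_clusters(pos, 9.0, c)))
            for c in (0.3, 0.6, 0.9, 1.3, 1.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_chain_level_merges_shared_chains(self):
        # two beads of one chain bridging two spatial blobs
        pos = np.array([[1.0, 1, 1], [1.2, 1, 1], [5.0, 5, 5], [5.2, 5, 5]])
        chain_id = np.array([0, 1, 1, 2])
        labels = find_clusters(pos, 12.0, 0.5, chain_id=chain_id, level="chain")
        assert labels[0] == labels[1] == labels[2]


class TestClusterMetrics:
    def test_two_bead_rg(self):
        pos = [np.array([[1.0, 1, 1], [2.0, 1, 1]])]
        m = cluster_metrics(pos, 20.0, cutoff=2.0, level="bead")
        assert m.largest_rg[0] == pytest.approx(0.5)
        assert m.n_clusters[0] == 1

    def test_thin_shell_rg_equals_radius(self):
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(4000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = [20.0 + 8.0 * dirs]
        m = cluster_metrics(pos, 40.0, cutoff=2.0, level="bead")
        assert m.largest_rg[0] == pytest.approx(8.0, rel=0.01)


class TestCondensateCOM:
    def test_single_bead(self):
        pos = np.array([[3.0, 4.0, 5.0]])
        np.testing.assert_allclose(condensate_com(pos, 20.0), pos[0], atol=1e-9)

    def test_centered_shell(self):
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(3000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = 20.0 + 6.0 * dirs
        np.testing.assert_allclose(condensate_com(pos, 40.0), 20.0, atol=0.3)

    def test_straddling_boundary_matches_unwrapped_oracle(self):
        rng = np.random.default_rng(2)
        blob = rng.normal(scale=1.5, size=(500, 3))
        true_center = np.array([0.4, 39.6, 0.1])  # at the box corner
        pos = np.mod(true_center + blob, 40.0)
        com = condensate_com(pos, 40.0)
        d = com - true_center
        d -= 40.0 * np.round(d / 40.0)
        assert np.linalg.norm(d) < 0.2

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            condensate_com(np.empty((0, 3)), 10.0)


class TestRadialProfiles:
    def test_uniform_gas_profile_is_flat(self):
        fx = generate_fixture(default_fixture_spec("uniform_gas", seed=0))
        box = fx.config.box_edge
        bins = np.arange(0.0, box / 2.0, 0.75)
        profile = rdf_about_com(
            fx.config.positions, {"all": fx.groups["all"]}, bins, box=box,
            com_override=np.full(3, box / 2.0),
        )
        counts = profile.counts["all"]
        shell_vol = 4.0 / 3.0 * np.pi * np.diff(bins**3)
        expected = len(fx.groups["all"]) * shell_vol / box**3
        usable = expected >= 10
        chi2 = float(np.sum((counts[usable] - expected[usable]) ** 2 / expected[usable]))
        p = stats.chi2.sf(chi2, usable.sum())
        assert p > 0.01

    def test_vesicle_fixture_peaks_at_specified_radii(self):
        fx = generate_fixture(default_fixture_spec("vesicle", seed=0))
        box = fx.config.box_edge
        bins = np.arange(0.0, box / 2.0, 0.75)
        profile = rdf_about_com(
            fx.config.positions, fx.groups, bins, box=box,
            com_override=np.full(3, box / 2.0),
        )
        r = profile.bin_centers
        g_l, g_hr = profile.g["DomainL"], profile.g["H+RNA"]
        assert abs(r[np.argmax(g_hr)] - 14.0) <= 0.75 + 1e-9
        inner = r < 11.0
        assert abs(r[inner][np.argmax(g_l[inner])] - 8.0) <= 0.75 + 1e-9
        outer = r > 17.0
        # outer shell has more beads but larger shells; compare densities
        shell_counts = profile.counts["DomainL"]
        assert abs(r[outer][np.argmax(shell_counts[outer])] - 20.0) <= 1.5
        central = r < 5.0
        assert profile.counts["all"][central].sum() < 0.01 * len(fx.groups["all"])

    def test_single_radius_single_bin_spike(self):
        rng = np.random.default_rng(5)
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = 15.0 + 7.5 * dirs
        bins = np.arange(0.0, 15.0, 1.0)
        profile = rdf_about_com(pos, {"g": np.arange(500)}, bins, box=30.0,
                                com_override=np.full(3, 15.0))
        assert np.flatnonzero(profile.counts["g"]).tolist() == [7]

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning, match="empty group"):
            rdf_about_com(
                np.ones((5, 3)), {"none": np.array([], dtype=int)},
                np.arange(0.0, 5.0, 1.0), box=10.0,
                com_override=np.ones(3),
            )


class TestPMF:
    def _profile(self, g):
        g = np.asarray(g, dtype=float)
        r = np.arange(len(g)) * 0.5 + 0.25
        return RadialProfile(bin_centers=r, g={"all": g})

    def test_flat_profile_zero_pmf(self):
        p = pmf_from_rdf(self._profile(np.ones(8)), 300.0)
        np.testing.assert_allclose(p.pmf, 0.0, atol=1e-14)
        assert weighted_mean_pmf(p, self._profile(np.ones(8))) == pytest.approx(0.0)

    def test_single_bin_value(self):
        kt = KB * 300.0
        p = pmf_from_rdf(self._profile([math.e]), 300.0)
        assert p.pmf[0] == pytest.approx(-kt, rel=1e-9)
        assert kt == pytest.approx(2.494, abs=0.001)

    def test_sign_convention(self):
        p = pmf_from_rdf(self._profile([2.0, 0.5]), 300.0)
        assert p.pmf[0] < 0 < p.pmf[1]

    def test_masked_bins_carry_no_weight(self):
        prof = self._profile([1.0, 0.0, 2.0])
        p = pmf_from_rdf(prof, 300.0)
        assert np.isnan(p.pmf[1]) and p.valid.tolist() == [True, False, True]
        assert np.isfinite(weighted_mean_pmf(p, prof))

    def test_two_bin_hand_computed_mean(self):
        kt = KB * 300.0
        g = [math.e, 1.0 / math.e]
        prof = self._profile(g)
        p = pmf_from_rdf(prof, 300.0)
        expected = -kt * (math.e - 1.0 / math.e) / (math.e + 1.0 / math.e)
        assert weighted_mean_pmf(p, prof) == pytest.approx(expected, abs=1e-12)
        assert p.weighted_mean == pytest.approx(expected, abs=1e-12)

    def test_round_trip_recovers_g(self):
        rng = np.random.default_rng(0)
        g = rng.random(20) * 3.0 + 0.01
        p = pmf_from_rdf(self._profile(g), 300.0)
        np.testing.assert_allclose(np.exp(-p.pmf / (KB * 300.0)), g, rtol=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(derandomize=True, max_examples=20)
    def test_weighted_mean_invariant_to_rescaling(self, scale):
        g = np.array([0.2, 1.5, 3.0, 0.7])
        p = pmf_from_rdf(self._profile(g), 300.0)
        base = weighted_mean_pmf(p, self._profile(g))
        rescaled = weighted_mean_pmf(p, self._profile(g * scale))
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            pmf_from_rdf(self._profile([0.0, 0.0]), 300.0)


class TestContacts:
    def test_single_rna_neighbor(self, table, params300):
        from condgram.model_core import concatenate_chains, parameterize, build_rna

        topo = concatenate_chains(
            [parameterize("R", table=table), build_rna(1, table)]
        )
        pos = np.array([[5.0, 5, 5], [6.0, 5, 5]])
        c = contact_numbers(pos, topo, 1.1, box=20.0)
        assert c.mean_rna_neighbors == 1.0
        assert c.mean_protein_neighbors == 0.0
        assert c.by_domain["H"]["rna"] == 1.0

    def test_isolated_bead_zero(self, table):
        from condgram.model_core import concatenate_chains, parameterize

        topo = concatenate_chains([parameterize("R", table=table)])
        c = contact_numbers(np.array([[5.0, 5, 5]]), topo, 1.1, box=20.0)
        assert c.mean_rna_neighbors == 0.0 and c.mean_protein_neighbors == 0.0

    def test_matches_double_loop_oracle(self, table):
        from condgram.model_core import SequenceSpec, SystemComposition, build_system
        from condgram.simulator import pack_random

        comp = SystemComposition(SequenceSpec("R", 4, "N3G2", 1), 4, 4, 10.0)
        topo = build_system(comp)
        config = pack_random(topo, 10.0, 0.5, seed=1)
        c = contact_numbers(config.positions, topo, 1.1, box=10.0)
        # oracle: plain double loop
        pos = config.positions
        n = topo.n_beads
        is_protein = topo.species == "protein"
        bonded = {(int(i), int(j)) for i, j in zip(topo.bond_i, topo.bond_j)}
        prot = np.zeros(n)
        rna = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i == j or (min(i, j), max(i, j)) in bonded:
                    continue
                d = pos[i] - pos[j]
                d = d - 10.0 * np.round(d / 10.0)
                if float(d @ d) <= 1.1**2:
                    if is_protein[j]:
                        prot[i] += 1
                    else:
                        rna[i] += 1
        assert c.mean_protein_neighbors == pytest.approx(prot[is_protein].mean())
        assert c.mean_rna_neighbors == pytest.approx(rna[is_protein].mean())

    def test_bonded_exclusion_flag(self, table):
        from condgram.model_core import concatenate_chains, parameterize

        topo = concatenate_chains([parameterize("RR", table=table)])
        pos = np.array([[5.0, 5, 5], [5.38, 5, 5]])
        with_excl = contact_numbers(pos, topo, 1.1, box=20.0, exclude_bonded=True)
        without = contact_numbers(pos, topo, 1.1, box=20.0, exclude_bonded=False)
        assert with_excl.mean_protein_neighbors == 0.0
        assert without.mean_protein_neighbors == 1.0


class TestShellCoverage:
    def test_closed_shell_near_one(self):
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(3000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = 20.0 + 10.0 * dirs
        cov = shell_coverage(pos, 40.0, np.full(3, 20.0), 9.0, 11.0)
        assert cov > 0.97

    def test_hemisphere_near_half(self):
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(6000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = dirs[dirs[:, 2] < 0][:2000]
        pos = 20.0 + 10.0 * dirs
        cov = shell_coverage(pos, 40.0, np.full(3, 20.0), 9.0, 11.0)
        assert 0.4 < cov < 0.6
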