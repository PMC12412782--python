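import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elongrate.genomic_io import GeneModel
from elongrate.lss import (
    RateRunConfig,
    base_ratios,
    bin_edges,
    bin_ratios,
    call_transitions,
    count_candidates,
    expansion_region,
    infer_rate,
    pointer_significance,
    refine_to_base,
    split_significance,
    ss_scan,
)
from conftest import make_track


# ---------------------------------------------------------------------------
# Brute-force oracle for the split scan
# ---------------------------------------------------------------------------

def brute_force_scan(values):
    """Exhaustive contiguous 2-partition search; SSE objective, ties -> smallest p."""
    v = np.asarray(values, dtype=float)
    L = len(v)
    ss = np.empty(L)
    for p in range(1, L + 1):
        left, right = v[:p], v[p:]
        sse_l = float(((left - left.mean()) ** 2).sum()) if left.size > 1 else 0.0
        sse_r = float(((right - right.mean()) ** 2).sum()) if right.size > 1 else 0.0
        ss[p - 1] = sse_l + sse_r
    return ss, int(np.argmin(ss)) + 1


class TestSsScan:
    def test_perfect_step(self):
        scan = ss_scan([0, 0, 0, 1, 1, 1])
        assert scan.argmin == 3
        assert scan.ss[2] == 0.0

    def test_constant_vector_tie_rule(self):
        scan = ss_scan([2.0] * 8)
        assert np.all(scan.ss == 0.0)
        assert scan.argmin == 1

    def test_matches_brute_force_fixed_vector(self):
        rng = np.random.default_rng(7)
        v = rng.random(10)
        scan = ss_scan(v)
        ss_bf, argmin_bf = brute_force_scan(v)
        np.testing.assert_allclose(scan.ss, ss_bf, atol=1e-10)
        assert scan.argmin == argmin_bf

    def test_too_short(self):
        with pytest.raises(ValueError):
            ss_scan([1.0])

    def test_n_candidates(self):
        assert ss_scan(np.arange(17.0)).n_candidates == 17

    @given(
        st.lists(st.floats(0, 100, allow_nan=False, width=32), min_size=2, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_kmeans_equivalence_property(self, values):
        """argmin equals the best contiguous 2-partition by exhaustive search."""
        scan = ss_scan(values)
        ss_bf, argmin_bf = brute_force_scan(values)
        np.testing.assert_allclose(scan.ss, ss_bf, atol=1e-6)
        assert scan.ss[scan.argmin - 1] <= ss_bf.min() + 1e-6

    @given(
        st.lists(st.floats(0, 10, allow_nan=False, width=32), min_size=2, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_zero_iff_constant_segments(self, values):
        scan = ss_scan(values)
        assert np.all(scan.ss >= 0)
        v = np.asarray(values)
        for p in range(1, len(v) + 1):
            segments_constant = (np.unique(v[:p]).size <= 1) and (
                np.unique(v[p:]).size <= 1
            )
            if segments_constant:
                assert scan.ss[p - 1] == 0.0
            elif scan.ss[p - 1] == 0.0:
                # zero implies both segments constant (up to float noise)
                assert np.ptp(v[:p]) < 1e-5 and (p == len(v) or np.ptp(v[p:]) < 1e-5)


class TestCountCandidates:
    def test_paper_case(self):
        assert count_candidates(40_000, 40, two_stage=True) == 2040

    def test_single_stage(self):
        assert count_candidates(40_000, 40, two_stage=False) == 40_000

    def test_n_equals_m(self):
        assert count_candidates(40, 40, two_stage=True) == 42

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_candidates(10, 20)


# ---------------------------------------------------------------------------
# Ratio profiles
# ---------------------------------------------------------------------------

class TestBinRatios:
    def _gene(self, n):
        return GeneModel("g", "chr1", 0, n, "+")

    def test_identity(self):
        gene = self._gene(400)
        counts = np.ones(400, dtype=int)
        t = make_track("g", counts, library_size=1000)
        r = make_track("g", counts.copy(), library_size=1000)
        profile = bin_ratios(t, r, gene, m=8)
        np.testing.assert_allclose(profile.values, 1.0)

    def test_pseudocount_floor(self):
        gene = self._gene(400)
        t = make_track("g", np.zeros(400, dtype=int), library_size=1000)
        r = make_track("g", np.ones(400, dtype=int), library_size=1000)
        profile = bin_ratios(t, r, gene, m=8, pseudocount=1.0)
        assert np.all(profile.values > 0)
        assert np.all(profile.values < 0.1)

    def test_hand_arithmetic(self):
        # n=8, m=4, T bins (0,0,4,4), R bins (2,2,2,2), equal libraries, pc=1
        gene = self._gene(8)
        t = make_track("g", [0, 0, 0, 0, 2, 2, 2, 2], library_size=100)
        r = make_track("g", [1, 1, 1, 1, 1, 1, 1, 1], library_size=100)
        profile = bin_ratios(t, r, gene, m=4)
        np.testing.assert_allclose(profile.values, [1 / 3, 1 / 3, 5 / 3, 5 / 3])

    def test_edges_tile_gene(self):
        edges = bin_edges(4003, 40)
        assert edges[0] == (1, 100)
        assert edges[-1] == (3901, 4003)
        # gapless and non-overlapping
        for (s1, e1), (s2, _) in zip(edges, edges[1:]):
            assert s2 == e1 + 1
        assert sum(e - s + 1 for s, e in edges) == 4003

    def test_m_larger_than_n_errors(self):
        gene = self._gene(8)
        t = make_track("g", np.ones(8, dtype=int))
        with pytest.raises(ValueError):
            bin_ratios(t, t, gene, m=16)

    def test_base_ratios_region(self):
        gene = self._gene(10)
        t = make_track("g", np.arange(10), library_size=100)
        r = make_track("g", np.ones(10, dtype=int), library_size=100)
        profile = base_ratios(t, r, gene, (3, 5))
        np.testing.assert_allclose(profile.values, [(2 + 1) / 2, (3 + 1) / 2, (4 + 1) / 2])
        assert profile.bin_edges == [(3, 3), (4, 4), (5, 5)]


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

class TestSplitSignificance:
    def test_exact_small_case(self):
        # one-sided permutation p = 1 / C(6,3) = 0.05
        assert split_significance([0, 0, 0, 1, 1, 1], 3) == pytest.approx(0.05)

    def test_no_separation(self):
        assert split_significance([1.0, 1.0, 1.0, 1.0], 2) >= 0.5

    def test_strong_separation(self):
        p = split_significance([0.0] * 20 + [1.0] * 20, 20)
        assert p < 1e-6

    def test_exact_matches_enumeration(self):
        """Tie-free exact path vs direct enumeration of rank assignments."""
        import itertools

        v = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        p_obs = split_significance(v, 3)
        left, right = v[:3], v[3:]
        u_obs = (left[:, None] > right[None, :]).sum()
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(combo)] = True
            u = (v[mask][:, None] > v[~mask][None, :]).sum()
            hits += u <= u_obs
            total += 1
        assert p_obs == pytest.approx(hits / total)

    def test_empty_segment_errors(self):
        with pytest.raises(ValueError):
            split_significance([1.0, 2.0], 2)

    def test_monotone_significance(self):
        """Strengthening a clean step never increases the one-sided p."""
        rng = np.random.default_rng(3)
        base = np.concatenate([rng.uniform(0, 0.2, 15), rng.uniform(0.8, 1.0, 15)])
        p_prev = split_significance(base, 15)
        for c in (1.5, 2.0, 5.0, 10.0):
            stronger = base.copy()
            stronger[15:] *= c
            p_new = split_significance(stronger, 15)
            assert p_new <= p_prev + 1e-12
            p_prev = p_new

    def test_pointer_significance_bonferroni(self):
        v = [0, 0, 0, 1, 1, 1]
        assert pointer_significance(v, 3) == pytest.approx(0.05 * 5)


# ---------------------------------------------------------------------------
# Two-stage refinement
# ---------------------------------------------------------------------------

def step_tracks(n, break_base, low=0, high=5, ref_level=5, lib=10**6):
    """Treatment depleted up to break_base (1-based, inclusive), intact after."""
    t = np.full(n, high, dtype=int)
    t[:break_base] = low
    r = np.full(n, ref_level, dtype=int)
    gene = GeneModel("g", "chr1", 0, n, "+")
    return gene, make_track("g", t, lib), make_track("g", r, lib)


class TestRefineToBase:
    def test_step_recovery(self):
        gene, t, r = step_tracks(4000, break_base=2150)
        # bin level: m=40, width 100; last depleted bin is 21 (bases 2001-2100)
        profile = bin_ratios(t, r, gene, 40)
        tbin = ss_scan(profile.values).argmin
        assert tbin == 21
        tbase, p_base, _ = refine_to_base(t, r, gene, tbin, 40)
        assert tbase == 2150
        assert p_base < 1e-6

    def test_constant_region_nonsignificant(self):
        gene, t, r = step_tracks(4000, break_base=0)  # treatment == intact everywhere
        tbase, p_base, profile = refine_to_base(t, r, gene, 5, 40)
        assert np.isnan(p_base) or p_base > 0.05

    def test_last_bin_region(self):
        assert expansion_region(4000, 40, 40) == (3901, 4000)
        assert expansion_region(4000, 40, 39) == (3801, 4000)
        assert expansion_region(4000, 40, 1) == (1, 200)


class TestInferRate:
    def test_paper_arithmetic(self):
        assert infer_rate(30_000, 15) == pytest.approx(2000.0)
        assert infer_rate(36_300, 25) == pytest.approx(1452.0)
        assert infer_rate(0, 15) == 0.0

    def test_invalid_minutes(self):
        with pytest.raises(ValueError):
            infer_rate(1000, 0)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class TestCallTransitions:
    def test_perfect_step_composition(self):
        """Step at bin 18 with a clean base step inside: both stages recover it."""
        n, m = 40_000, 40
        break_base = 17 * 1000 + 900  # late inside bin 18, so bin 18 reads depleted
        gene, t, r = step_tracks(n, break_base)
        config = RateRunConfig(window_num=m, treatment_minutes=15, min_length=0, min_fpkm=0)
        df = call_transitions([gene], {"g": t}, {"g": r}, config)
        row = df.iloc[0]
        assert row["transition_bin"] == 18
        assert row["transition_base"] == break_base
        assert bool(row["significant"])
        assert row["rate_bp_per_min"] == pytest.approx(break_base / 15)

    def test_treatment_equals_reference_negative_control(self):
        rng = np.random.default_rng(11)
        genes, ttracks, rtracks = [], {}, {}
        for i in range(20):
            n = 4000
            gid = f"g{i}"
            counts = rng.poisson(5.0, n)
            genes.append(GeneModel(gid, "chr1", i * 5000, i * 5000 + n, "+"))
            ttracks[gid] = make_track(gid, counts, lib := 10**6)
            rtracks[gid] = make_track(gid, counts.copy(), lib)
        config = RateRunConfig(min_length=0, min_fpkm=0)
        df = call_transitions(genes, ttracks, rtracks, config)
        assert int(df["significant"].sum()) == 0

    def test_candidate_count_instrumentation(self):
        """SS evaluations per gene match the analytic two-stage count when the
        transition bin is interior and n divides evenly into bins."""
        n, m = 40_000, 40
        gene, t, r = step_tracks(n, break_base=20_500)
        config = RateRunConfig(window_num=m, min_length=0, min_fpkm=0)
        df = call_transitions([gene], {"g": t}, {"g": r}, config)
        assert int(df.iloc[0]["n_ss_evals"]) == count_candidates(n, m, two_stage=True)

    def test_no_genes_pass_filter_warns(self):
        gene, t, r = step_tracks(4000, 2000)
        config = RateRunConfig()  # default 40 kb length filter
        with pytest.warns(UserWarning, match="no genes pass"):
            df = call_transitions([gene], {"g": t}, {"g": r}, config)
        assert df.empty

    def test_output_schema(self):
        gene, t, r = step_tracks(4000, 2000)
        config = RateRunConfig(min_length=0, min_fpkm=0)
        df = call_transitions([gene], {"g": t}, {"g": r}, config)
        for col in ("gene_id", "chrom", "strand", "n", "method", "transition_bin",
                    "transition_base", "p_bin", "q_bin", "p_base", "q_base",
                    "significant", "rate_bp_per_min", "reference_fpkm"):
            assert col in df.columns
        assert df.iloc[0]["method"] == "LSS"


class TestTwoStageVsSingleStage:
    def test_oracle_equivalence_noiseless_steps(self):
        """On noiseless steps the two-stage search recovers the exhaustive
        single-stage base-level optimum whenever the chosen bin contains it."""
        agree = total = 0
        for break_base in (150, 500, 777, 1000, 1499, 1750):
            n, m = 2000, 10
            gene, t, r = step_tracks(n, break_base)
            full = base_ratios(t, r, gene, (1, n))
            single = ss_scan(full.values).argmin
            profile = bin_ratios(t, r, gene, m)
            tbin = ss_scan(profile.values).argmin
            region = expansion_region(n, m, tbin)
            total += 1
            if region[0] <= single <= region[1]:
                tbase, _, _ = refine_to_base(t, r, gene, tbin, m)
                agree += tbase == single == break_base
        assert agree == total
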