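"""HMM segmentation: emission/transition algebra, Viterbi versus an
exhaustive-path oracle, Bayes-factor arithmetic, and the probe-count /
merge / centromere boundary rules on constructed fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import arraycnv as ac
from arraycnv.cnv_hmm import (
    CN2_INDEX,
    STATE_NAMES,
    HmmParams,
    Segment,
    _log_transition_stack,
    baf_likelihood,
    emission_matrix,
    viterbi_path,
)
from arraycnv.core import centromere_table

from conftest import make_uniform_map

PARAMS = HmmParams()


class TestEmissions:
    def test_diploid_het_prefers_cn2_over_cn1(self):
        lrr, baf, pfb = 0.0, 0.5, 0.5
        assert ac.emission_loglik("CN2", lrr, baf, pfb) > ac.emission_loglik("CN1", lrr, baf, pfb)

    def test_trisomy_band_prefers_cn3(self):
        lrr = PARAMS.lrr_means["CN3"]
        assert ac.emission_loglik("CN3", lrr, 1 / 3, 0.5) > ac.emission_loglik("CN2", lrr, 1 / 3, 0.5)

    def test_outlier_component_bounds_baf_likelihood(self):
        # even a BAF impossible under every cluster keeps likelihood >= w * 1
        for state in STATE_NAMES:
            lik = baf_likelihood(state, np.array([0.25]), np.array([0.99]), PARAMS)
            assert lik[0] >= PARAMS.outlier_weight

    def test_boundary_baf_uses_truncation_mass(self):
        # BAF exactly 0 under CN1 with common B allele: mass ~ q
        lik0 = baf_likelihood("CN1", np.array([0.0]), np.array([0.2]), PARAMS)
        assert 0.3 < lik0[0] < 1.0


class TestTransitions:
    def test_zero_distance_is_identity(self):
        assert np.allclose(ac.transition_matrix(0.0), np.eye(6))

    @pytest.mark.parametrize("d", [1.0, 1e3, 1e6])
    def test_rows_sum_to_one(self, d):
        assert np.allclose(ac.transition_matrix(d).sum(axis=1), 1.0)

    def test_large_distance_off_diagonals_proportional_to_priors(self):
        t = ac.transition_matrix(1e12)
        pri = PARAMS.prior_vector
        off = t[0, 1:]  # from CN0 to the others
        assert np.allclose(off / pri[1:], PARAMS.rho_max)


# --------------------------------------------------------------- Viterbi oracle

def exhaustive_best_path_score(emissions, positions, params):
    """Independent maximum over all 6^n state paths.

    Paths up to length 6 are enumerated directly; longer instances are split
    in half and every (prefix, suffix) combination is joined across the
    junction transition, which is still an exhaustive enumeration of all
    paths.
    """
    logT = _log_transition_stack(np.diff(positions).astype(float), params)
    log_prior = np.log(params.prior_vector)
    n = len(positions)
    k = len(log_prior)

    def enumerate_scores(t0, t1, init):
        # score of every path over markers [t0, t1); init: per-state start score
        best = {}
        for path in itertools.product(range(k), repeat=t1 - t0):
            s = init[path[0]] + emissions[t0, path[0]]
            for i in range(1, len(path)):
                s += logT[t0 + i - 1, path[i - 1], path[i]] + emissions[t0 + i, path[i]]
            key = (path[0], path[-1])
            if key not in best or s > best[key]:
                best[key] = s
        return best

    if n <= 6:
        return max(enumerate_scores(0, n, log_prior).values())
    half = n // 2
    pre = enumerate_scores(0, half, log_prior)
    suf = enumerate_scores(half, n, np.zeros(k))
    best = -np.inf
    for (_, i), sp in pre.items():
        for (j, _), ss in suf.items():
            best = max(best, sp + logT[half - 1, i, j] + ss)
    return best


def _viterbi_score(emissions, positions, params):
    path = viterbi_path(emissions, positions, params)
    logT = _log_transition_stack(np.diff(positions).astype(float), params)
    s = np.log(params.prior_vector)[path[0]] + emissions[0, path[0]]
    for t in range(1, len(path)):
        s += logT[t - 1, path[t - 1], path[t]] + emissions[t, path[t]]
    return s


@pytest.mark.parametrize("n", range(2, 13))
def test_viterbi_equals_exhaustive_search(n):
    rng = np.random.default_rng(100 + n)
    positions = np.sort(rng.integers(1, 2_000_000, size=n))
    positions += np.arange(n)  # strictly increasing
    lrr = rng.normal(0, 1.0, n)
    baf = rng.random(n)
    pfb = rng.uniform(0.05, 0.95, n)
    em = emission_matrix(lrr, baf, pfb, PARAMS)
    assert _viterbi_score(em, positions, PARAMS) == pytest.approx(
        exhaustive_best_path_score(em, positions, PARAMS), rel=1e-12)


def test_viterbi_matches_hmmlearn_on_gaussian_subproblem():
    """Independent decoder check: a 2-state LRR-only Gaussian HMM with a
    fixed (constant-distance) transition matrix decoded by hmmlearn must
    give the same state path as our Viterbi fed the same log-densities."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(42)
    n = 300
    truth = np.zeros(n, dtype=int)
    truth[100:160] = 1
    means = np.array([0.0, -0.66])
    x = rng.normal(means[truth], 0.2)

    spacing = 5_000.0
    pri2 = np.array([0.97, 0.03])
    rho = PARAMS.rho_max * (1 - np.exp(-spacing / PARAMS.distance_scale_bp))
    T = np.array([[1 - rho * pri2[1], rho * pri2[1]],
                  [rho * pri2[0], 1 - rho * pri2[0]]])

    model = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
    model.startprob_ = pri2
    model.transmat_ = T
    model.means_ = means.reshape(-1, 1)
    model.covars_ = np.full((2, 1), 0.04)
    _, ref_path = model.decode(x.reshape(-1, 1))

    em = np.stack([norm.logpdf(x, m, 0.2) for m in means], axis=1)
    positions = (spacing * np.arange(n)).astype(int) + 1
    two_state = HmmParams(
        lrr_means={"CN0": 0, "CN1": 0, "CN2": 0, "CN2_LOH": 0, "CN3": 0, "CN4": 0},
        priors={"CN0": pri2[0], "CN1": pri2[1], "CN2": 0, "CN2_LOH": 0, "CN3": 0, "CN4": 0},
    )
    # embed the 2-state problem in the 6-state machinery: states 2..5 get
    # -inf emissions so only CN0/CN1 are reachable
    em6 = np.full((n, 6), -np.inf)
    em6[:, 0] = em[:, 0]
    em6[:, 1] = em[:, 1]
    path = viterbi_path(em6, positions, two_state)
    assert np.array_equal(path, ref_path)


# ----------------------------------------------------------------- Bayes factor

class TestBayesFactor:
    def test_probes_at_diploid_means_give_nonpositive_confidence(self):
        lrr = np.zeros(10)
        baf = np.tile([0.0, 0.5, 1.0], 4)[:10]
        pfb = np.full(10, 0.5)
        em = emission_matrix(lrr, baf, pfb, PARAMS)
        for s in ("CN1", "CN3"):
            assert ac.bayes_factor(em, np.arange(10), s) <= 0.0

    def test_confidence_additive_in_segment_length(self):
        rng = np.random.default_rng(9)
        lrr = rng.normal(PARAMS.lrr_means["CN1"], 0.1, 60)
        baf = rng.choice([0.0, 1.0], 60)
        pfb = np.full(60, 0.5)
        em = emission_matrix(lrr, baf, pfb, PARAMS)
        bfs = [ac.bayes_factor(em, np.arange(k), "CN1") for k in (10, 20, 40, 60)]
        assert np.all(np.diff(bfs) > 0)
        # additivity: confidence over [0,60) = [0,30) + [30,60)
        assert ac.bayes_factor(em, np.arange(60), "CN1") == pytest.approx(
            ac.bayes_factor(em, np.arange(30), "CN1")
            + ac.bayes_factor(em, np.arange(30, 60), "CN1"))

    def test_three_probe_hand_computation(self):
        lrr = np.array([-0.7, -0.6, -0.65])
        baf = np.array([0.0, 1.0, 0.02])
        pfb = np.array([0.3, 0.6, 0.5])
        em = emission_matrix(lrr, baf, pfb, PARAMS)
        expected = 0.0
        for i in range(3):
            l1 = ac.emission_loglik("CN1", lrr[i], baf[i], pfb[i])
            l2 = ac.emission_loglik("CN2", lrr[i], baf[i], pfb[i])
            expected += (l1 - l2) / np.log(10)
        assert ac.bayes_factor(em, np.arange(3), "CN1") == pytest.approx(float(expected))


# ------------------------------------------------------------------ rule suite

def _seg(state, start, end, n_probes, conf, chrom="1", sid="s"):
    return Segment(sid, chrom, start, end, state, n_probes, conf)


class TestFilterRules:
    def test_probe_count_boundaries(self):
        segs = [
            _seg("CN0", 1, 10_000, 3, 12.0),      # kept: hom-del minimum is 3
            _seg("CN1", 1, 10_000, 14, 50.0),     # dropped: < 15 probes
            _seg("CN1", 20_000, 40_000, 15, 50.0),  # kept: boundary
            _seg("CN3", 50_000, 90_000, 20, 9.9),   # dropped: confidence < 10
            _seg("CN3", 95_000, 99_000, 20, 10.0),  # kept: boundary
            _seg("CN2_LOH", 100_000, 200_000, 50, 99.0),  # routed out
        ]
        kept = ac.filter_calls(segs)
        assert [(s.state, s.start_bp) for s in kept] == [
            ("CN0", 1), ("CN1", 20_000), ("CN3", 95_000)]


@pytest.fixture(scope="module")
def merge_fixture():
    """Uniform 1 kb probe spacing; a diploid sample for recomputation."""
    m = make_uniform_map(600, spacing_bp=1_000, start=1_000_000)
    rng = np.random.default_rng(12)
    sample = ac.IntensitySample(
        "s", rng.normal(0, 0.2, 600),
        rng.choice([0.0, 0.5, 1.0], 600), np.ones(600, dtype=np.int8))
    return m, sample


class TestMergeRules:
    def test_gap_below_20pct_merges(self, merge_fixture):
        m, sample = merge_fixture
        # 100 kb call, 10 kb gap, 90 kb call: 10 < 0.2 * 90 = 18 -> merge
        a = _seg("CN1", 1_000_000, 1_099_999, 100, 40.0)
        b = _seg("CN1", 1_110_000, 1_199_999, 90, 40.0)
        merged = ac.merge_adjacent([a, b], sample, m)
        assert len(merged) == 1
        assert (merged[0].start_bp, merged[0].end_bp) == (1_000_000, 1_199_999)
        # probe count recounted from the map across the merged span
        assert merged[0].n_probes == len(m.region_index("1", 1_000_000, 1_199_999))

    def test_gap_at_or_above_20pct_does_not_merge(self, merge_fixture):
        m, sample = merge_fixture
        a = _seg("CN1", 1_000_000, 1_099_999, 100, 40.0)
        b = _seg("CN1", 1_120_000, 1_209_999, 90, 40.0)  # 20 kb gap > 18 kb
        assert len(ac.merge_adjacent([a, b], sample, m)) == 2
        # exactly 20%: strict '<' means no merge
        c = _seg("CN1", 1_000_000, 1_099_999, 100, 40.0)
        d = _seg("CN1", 1_118_000, 1_207_999, 90, 40.0)  # gap = 18,000 = 0.2*90k
        assert len(ac.merge_adjacent([c, d], sample, m)) == 2

    def test_different_copy_number_never_merges(self, merge_fixture):
        m, sample = merge_fixture
        a = _seg("CN1", 1_000_000, 1_099_999, 100, 40.0)
        b = _seg("CN3", 1_100_500, 1_199_999, 90, 40.0)
        assert len(ac.merge_adjacent([a, b], sample, m)) == 2

    def test_overlapping_input_is_error(self, merge_fixture):
        m, sample = merge_fixture
        a = _seg("CN1", 1_000_000, 1_099_999, 100, 40.0)
        b = _seg("CN1", 1_050_000, 1_199_999, 90, 40.0)
        with pytest.raises(ValueError, match="overlapping"):
            ac.merge_adjacent([a, b], sample, m)


@pytest.fixture(scope="module")
def centromere_fixture():
    """40 probes on the p side, 40 on the q side of a centromere gap."""
    rows = []
    for i in range(40):
        rows.append(("p", 1_000_000 + 10_000 * i))
    for i in range(40):
        rows.append(("q", 3_000_000 + 10_000 * i))
    m = ac.MarkerMap(pd.DataFrame({
        "marker_id": [f"c{i}" for i in range(80)],
        "chromosome": "1",
        "position_bp": [p for _, p in rows],
        "pfb": 0.5, "gc_frac": 0.5, "is_stable": True,
    }))
    cen = centromere_table({"1": (1_500_000, 2_900_000)})
    rng = np.random.default_rng(13)
    sample = ac.IntensitySample(
        "s", rng.normal(-0.66, 0.1, 80), rng.choice([0.0, 1.0], 80),
        np.zeros(80, dtype=np.int8))
    return m, cen, sample


class TestCentromereSplit:
    def test_call_on_one_arm_unchanged(self, centromere_fixture):
        m, cen, sample = centromere_fixture
        seg = _seg("CN1", 1_000_000, 1_200_000, 21, 30.0)
        out = ac.split_at_centromere([seg], cen, sample, m)
        assert len(out) == 1 and out[0].start_bp == 1_000_000

    def test_spanning_call_splits_at_flanking_probes(self, centromere_fixture):
        m, cen, sample = centromere_fixture
        seg = _seg("CN1", 1_100_000, 3_250_000, 60, 80.0)
        out = ac.split_at_centromere([seg], cen, sample, m)
        assert len(out) == 2
        p_arm, q_arm = out
        assert p_arm.end_bp == 1_390_000    # last probe before the gap
        assert q_arm.start_bp == 3_000_000  # first probe after the gap
        assert p_arm.start_bp == 1_100_000 and q_arm.end_bp == 3_250_000
        assert p_arm.n_probes == 30 and q_arm.n_probes == 26

    def test_short_q_side_dropped_by_probe_rule(self, centromere_fixture):
        m, cen, sample = centromere_fixture
        seg = _seg("CN1", 1_100_000, 3_010_000, 32, 80.0)  # 2 probes on q side
        out = ac.filter_calls(ac.split_at_centromere([seg], cen, sample, m))
        assert len(out) == 1 and out[0].end_bp == 1_390_000

    def test_call_inside_gap_dropped_with_warning(self, centromere_fixture):
        m, cen, sample = centromere_fixture
        seg = _seg("CN1", 1_600_000, 2_000_000, 1, 80.0)
        with pytest.warns(UserWarning, match="dropped"):
            out = ac.split_at_centromere([seg], cen, sample, m)
        assert out == []


# ----------------------------------------------------------- end-to-end checks

from arraycnv import benchmarks


def test_pure_diploid_sample_yields_no_calls(one_chrom_map, quiet_cohort):
    calls = ac.call_cnvs(quiet_cohort.samples[0], one_chrom_map)
    assert calls == []


def test_planted_events_recovered_small_cohort():
    precision, recall, _, _ = benchmarks.run_cnv_recovery(n_samples=12, seed=50)
    assert precision >= 0.9 and recall >= 0.9


def test_no_call_spans_centromere():
    m, cen, cohort = benchmarks.simulate_cnv_cohort(n_samples=8, seed=60)
    calls = []
    for s in cohort.samples:
        calls.extend(ac.call_cnvs(s, m, centromeres=cen))
    # also force a call across the centromere by planting one event over it
    ev = [ac.TruthEvent("case_0001", "cnv", "1", 22_000_000, 28_000_000, 1)]
    m2 = ac.generate_marker_map(3000, {"1": 60_000_000},
                                centromeres=centromere_table({"1": (24_000_000, 26_000_000)}),
                                seed=61)
    cohort2 = ac.simulate_cohort(m2, 1, 0, ev, seed=62)
    spanning = ac.call_cnvs(cohort2.samples[0], m2,
                            centromeres=centromere_table({"1": (24_000_000, 26_000_000)}))
    for c in spanning + calls:
        assert not (c.start_bp <= 24_000_000 and c.end_bp >= 26_000_000)
    assert len(spanning) == 2  # the planted event split into p and q calls


def test_merge_split_filter_pipeline_is_idempotent():
    m, cen, cohort = benchmarks.simulate_cnv_cohort(n_samples=6, seed=70)
    params = HmmParams()
    for s in cohort.samples[:3]:
        segs = ac.viterbi_segments(s, m, params)
        once = ac.filter_calls(
            ac.split_at_centromere(
                ac.merge_adjacent(segs, s, m, params), cen, s, m, params), params)
        twice = ac.filter_calls(
            ac.split_at_centromere(
                ac.merge_adjacent(once, s, m, params), cen, s, m, params), params)
        assert [vars(a) for a in once] == [vars(b) for b in twice]
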