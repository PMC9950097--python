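"""QC battery: LRR/BAF derivation identities, exact-HWE against a
brute-force enumeration oracle, outlier-sample screening, LD pruning,
relatedness recovery on simulated pedigrees and the ancestry/sex screens."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from sklearn.metrics import silhouette_score

import arraycnv as ac
from arraycnv.sample_qc import SampleQcMetrics, hwe_exact_p

CLUSTERS = ac.ClusterMedians(theta_aa=0.1, theta_ab=0.5, theta_bb=0.9,
                             r_aa=1.0, r_ab=1.2, r_bb=1.0)


def _xy_at(theta, r):
    # invert theta = (2/pi) atan2(y, x), r = x + y
    ang = theta * np.pi / 2
    x = r / (1 + np.tan(ang))
    return x, r - x


class TestComputeLrrBaf:
    def test_observation_at_ab_cluster_is_identity(self):
        x, y = _xy_at(0.5, 1.2)
        lrr, baf = ac.compute_lrr_baf([x], [y], CLUSTERS)
        assert lrr[0] == pytest.approx(0.0, abs=1e-12)
        assert baf[0] == pytest.approx(0.5, abs=1e-12)

    def test_observation_at_aa_cluster_gives_baf_zero(self):
        x, y = _xy_at(0.1, 1.0)
        lrr, baf = ac.compute_lrr_baf([x], [y], CLUSTERS)
        assert baf[0] == 0.0
        assert lrr[0] == pytest.approx(0.0, abs=1e-12)

    def test_doubled_intensity_gives_lrr_one(self):
        theta = 0.3  # between AA and AB: R_expected interpolates
        frac = (theta - 0.1) / 0.4
        r_exp = 1.0 + frac * 0.2
        x, y = _xy_at(theta, 2 * r_exp)
        lrr, baf = ac.compute_lrr_baf([x], [y], CLUSTERS)
        assert lrr[0] == pytest.approx(1.0, abs=1e-12)

    def test_theta_beyond_bb_clamps(self):
        x, y = _xy_at(0.95, 1.0)
        _, baf = ac.compute_lrr_baf([x], [y], CLUSTERS)
        assert baf[0] == 1.0


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct enumeration of the conditional distribution of
    the heterozygote count given the allele counts:
    P(h) ~ n! / (aa! h! bb!) * 2^h."""
    n = n_aa + n_ab + n_bb
    n_b = n_ab + 2 * n_bb
    logps = {}
    for h in range(n_b % 2, min(n_b, 2 * n - n_b) + 1, 2):
        bb = (n_b - h) // 2
        aa = n - h - bb
        logps[h] = (gammaln(n + 1) - gammaln(aa + 1) - gammaln(h + 1)
                    - gammaln(bb + 1) + h * math.log(2))
    tot = max(logps.values())
    probs = {h: math.exp(v - tot) for h, v in logps.items()}
    z = sum(probs.values())
    probs = {h: v / z for h, v in probs.items()}
    p_obs = probs[n_ab]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts",
    [(50, 50, 50), (1469, 138, 5), (0, 0, 100), (10, 0, 10), (3, 7, 190),
     (60, 80, 60), (1, 1, 1), (100, 0, 1), (0, 5, 95)],
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-9)


def test_hwe_exact_matches_enumeration_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(2, 200))
        aa = int(rng.integers(0, n + 1))
        ab = int(rng.integers(0, n - aa + 1))
        bb = n - aa - ab
        assert hwe_exact_p(aa, ab, bb) == pytest.approx(
            hwe_enumeration_oracle(aa, ab, bb), rel=1e-9)


def _metrics(sid, lrr_sd=0.15, baf_sd=0.03, call_rate=0.99):
    return SampleQcMetrics(sid, 0.0, lrr_sd, baf_sd, call_rate)


class TestSamplePassFilter:
    def test_identical_metrics_all_pass(self):
        report = ac.sample_pass_filter([_metrics(f"s{i}") for i in range(10)])
        assert report["pass"].all()

    def test_low_call_rate_fails_with_reason(self):
        ms = [_metrics(f"s{i}") for i in range(5)] + [_metrics("bad", call_rate=0.94)]
        report = ac.sample_pass_filter(ms)
        row = report[report.sample_id == "bad"].iloc[0]
        assert not row["pass"] and "call_rate" in row["reasons"]

    def test_noisy_sample_excluded_from_simulated_cohort(self):
        rng = np.random.default_rng(1)
        ms = [_metrics(f"s{i}", lrr_sd=0.15 + rng.normal(0, 0.01)) for i in range(49)]
        ms.append(_metrics("noisy", lrr_sd=0.75))
        report = ac.sample_pass_filter(ms)
        assert not report[report.sample_id == "noisy"]["pass"].iloc[0]
        assert report["pass"].sum() == 49

    def test_single_sample_cohort_rejected(self):
        with pytest.raises(ValueError):
            ac.sample_pass_filter([_metrics("s0")])


class TestMarkerPassFilter:
    def test_high_missingness_fails_call_rate(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.5, size=(100, 2)).astype(np.int8)
        g[:10, 0] = -1  # 10% missing on marker 0
        report = ac.marker_pass_filter(g)
        assert not report["pass"][0]
        assert report["pass"][1]

    def test_equal_missingness_by_sex_passes(self):
        g = np.ones((40, 1), dtype=np.int8)
        g[0, 0] = -1
        g[20, 0] = -1
        sexes = np.array(["male"] * 20 + ["female"] * 20)
        report = ac.marker_pass_filter(g, sexes)
        assert report["sex_miss_p"][0] == pytest.approx(1.0)

    def test_hwe_column_uses_exact_test(self):
        g = np.array([[0] * 50 + [1] * 50 + [2] * 50]).T.astype(np.int8)
        report = ac.marker_pass_filter(g.reshape(150, 1))
        assert report["hwe_p"][0] == pytest.approx(hwe_enumeration_oracle(50, 50, 50), rel=1e-9)

    def test_monomorphic_marker_has_hwe_p_one(self):
        g = np.zeros((50, 1), dtype=np.int8)
        assert ac.marker_pass_filter(g)["hwe_p"][0] == 1.0


class TestLdPrune:
    def test_duplicated_marker_removed(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, size=(100, 10)).astype(np.int8)
        g[:, 5] = g[:, 4]
        keep = ac.ld_prune(g, r2_threshold=0.9)
        assert not (keep[4] and keep[5])
        assert keep.sum() == 9

    def test_independent_markers_mostly_retained(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.5, size=(400, 200)).astype(np.int8)
        keep = ac.ld_prune(g, r2_threshold=0.2)
        assert keep.mean() > 0.95  # removals ~ type-I rate of the r^2 cut

    def test_stricter_threshold_removes_superset(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.5, size=(200, 60)).astype(np.int8)
        # induce correlation blocks
        for j in range(1, 60, 3):
            flip = rng.random(200) < 0.2
            base[:, j] = np.where(flip, rng.binomial(2, 0.5, 200), base[:, j - 1])
        keep_02 = ac.ld_prune(base, r2_threshold=0.2)
        keep_03 = ac.ld_prune(base, r2_threshold=0.3)
        assert np.all(keep_03 | ~keep_02 | ~keep_03)  # removed@0.3 => removed@0.2
        removed_02 = set(np.flatnonzero(~keep_02))
        removed_03 = set(np.flatnonzero(~keep_03))
        assert removed_03 <= removed_02

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ac.ld_prune(np.zeros((10, 10)), r2_threshold=1.5)


class TestPiHat:
    @staticmethod
    def _freqs_and_geno(rng, n=5000):
        p = rng.uniform(0.1, 0.9, size=n)
        return p, rng.binomial(2, p).astype(np.int8)

    def test_self_pair_is_one(self):
        rng = np.random.default_rng(5)
        p, g = self._freqs_and_geno(rng)
        est = ac.estimate_pi_hat(g, g, p)
        assert est.pi_hat == pytest.approx(1.0, abs=1e-9)
        assert est.ibs2 == len(g)

    def test_unrelated_pair_near_zero(self):
        rng = np.random.default_rng(6)
        p, g1 = self._freqs_and_geno(rng)
        g2 = rng.binomial(2, p).astype(np.int8)
        assert ac.estimate_pi_hat(g1, g2, p).pi_hat == pytest.approx(0.0, abs=0.05)

    def test_parent_offspring_near_half(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, size=5000)
        pa = rng.random((2, 5000)) < p
        other = rng.random(5000) < p
        parent = pa.sum(axis=0).astype(np.int8)
        transmitted = np.where(rng.random(5000) < 0.5, pa[0], pa[1])
        child = (transmitted.astype(int) + other.astype(int)).astype(np.int8)
        assert ac.estimate_pi_hat(parent, child, p).pi_hat == pytest.approx(0.5, abs=0.05)

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            ac.estimate_pi_hat(np.array([-1]), np.array([0]), np.array([0.5]))


class TestAncestryPca:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(8)
        n_markers = 500
        p1 = rng.uniform(0.1, 0.9, n_markers)
        shift = rng.choice([-0.3, 0.3], n_markers)
        p2 = np.clip(p1 + shift, 0.05, 0.95)
        g = np.vstack([
            rng.binomial(2, p1, size=(40, n_markers)),
            rng.binomial(2, p2, size=(40, n_markers)),
        ]).astype(np.int8)
        scores, var = ac.ancestry_pca(g, n_components=4)
        labels = np.array([0] * 40 + [1] * 40)
        assert silhouette_score(scores[:, :1], labels) > 0.8
        assert np.all(np.diff(var) <= 1e-12)  # non-increasing

    def test_identical_samples_have_zero_scores(self):
        g = np.tile(np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=np.int8), (6, 1))
        with pytest.warns(UserWarning):
            scores, _ = ac.ancestry_pca(g, n_components=10)
        assert np.allclose(scores, 0.0, atol=1e-8)


class TestSexScreen:
    @staticmethod
    def _sexed_cohort(y_shift=0.0, mislabel=False):
        lengths = {"1": 30_000_000, "X": 20_000_000, "Y": 8_000_000}
        m = ac.generate_marker_map(1500, lengths, seed=9)
        cohort = ac.simulate_cohort(m, 6, 6, seed=10, male_fraction=0.5)
        sexes = dict(zip(cohort.phenotypes.sample_id, cohort.phenotypes.sex))
        males = [s for s in cohort.samples if sexes[s.sample_id] == "male"]
        females = [s for s in cohort.samples if sexes[s.sample_id] == "female"]
        y_idx = m.chrom_index("Y")
        if y_shift:
            males[0].lrr[y_idx] += y_shift
        if mislabel:
            sexes[females[0].sample_id] = "male"
        return m, cohort.samples, sexes, males[0].sample_id, females[0].sample_id

    def test_concordant_males_unflagged(self):
        m, samples, sexes, _, _ = self._sexed_cohort()
        report = ac.sex_aneuploidy_screen(samples, m, sexes)
        assert (report["flags"] == "").all()

    def test_planted_mosaic_y_loss_flagged(self):
        m, samples, sexes, male0, _ = self._sexed_cohort(y_shift=-0.6)
        report = ac.sex_aneuploidy_screen(samples, m, sexes)
        assert "partial_y_loss" in report.set_index("sample_id").loc[male0, "flags"]

    def test_xx_labelled_male_flagged(self):
        m, samples, sexes, _, female0 = self._sexed_cohort(mislabel=True)
        report = ac.sex_aneuploidy_screen(samples, m, sexes)
        assert "sex_discordant" in report.set_index("sample_id").loc[female0, "flags"]

    def test_no_sex_markers_warns_and_skips(self, one_chrom_map, quiet_cohort):
        with pytest.warns(UserWarning, match="skipped"):
            report = ac.sex_aneuploidy_screen(quiet_cohort.samples, one_chrom_map)
        assert report.empty
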