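"""Allelic-discrimination cluster calling on simulated fluorescence."""

import random

import pytest

from hlatag import (
    ClusterError,
    ClusterOptions,
    FluorescencePoint,
    FluorescenceSpec,
    MarkerSpec,
    SimConfig,
    call_allelic_discrimination,
    default_panel,
    fit_cluster_model,
    simulate_cohort,
    simulate_fluorescence,
)

AS_CENTROIDS = {"negative": (3.0, 0.3), "positive": (3.0, 2.1)}
SNV_CENTROIDS = {
    "homo_allele1": (3.0, 0.3),
    "het": (2.2, 2.2),
    "homo_allele2": (0.3, 3.0),
}
SEPARATION = 1.8  # raw distance between allele-specific class centroids


@pytest.fixture(scope="module")
def assay():
    return default_panel().assays["5801A"]


@pytest.fixture(scope="module")
def snv_assay():
    return default_panel().assays["C__16222070_10"]


def as_cohort(sigma, seed=0, n=132, prevalence=18 / 132):
    cfg = SimConfig(
        n_samples=n, target="B*58:01",
        markers=(MarkerSpec("5801A", 1.0, 1.0),),
        carrier_prevalence=prevalence,
        fluorescence=FluorescenceSpec(centroids=AS_CENTROIDS, sigma=sigma, n_ntc=3),
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    points = simulate_fluorescence(cohort.marker_truth, cfg)
    truth = dict(zip(cohort.marker_truth.sample_id, cohort.marker_truth.class_label))
    return points, truth


def accuracy(calls, truth):
    """(full recovery incl. indeterminates-as-misses, determinate accuracy)."""
    det = [c for c in calls if c.is_determinate]
    det_ok = sum(c.alleles == (truth[c.sample_id],) for c in det)
    return det_ok / len(calls), (det_ok / len(det) if det else float("nan"))


class TestRecovery:
    def test_full_recovery_when_noise_far_below_separation(self, assay):
        # sigma << separation: every generating label recovered exactly
        points, truth = as_cohort(sigma=SEPARATION / 12)
        calls = call_allelic_discrimination(points, assay)
        full, det = accuracy(calls, truth)
        assert full == 1.0 and len(calls) == 132

    def test_no_wrong_determinate_calls_at_six_sigma(self, assay):
        points, truth = as_cohort(sigma=SEPARATION / 6)
        calls = call_allelic_discrimination(points, assay)
        _, det = accuracy(calls, truth)
        n_indet = sum(not c.is_determinate for c in calls)
        assert det == 1.0
        assert n_indet <= 0.08 * len(calls)  # only boundary rejections

    def test_accuracy_degrades_monotonically_with_separation(self, assay):
        fulls = []
        for k in (12, 6, 3, 1.5):
            points, truth = as_cohort(sigma=SEPARATION / k)
            calls = call_allelic_discrimination(points, assay)
            fulls.append(accuracy(calls, truth)[0])
        assert fulls == sorted(fulls, reverse=True)
        assert fulls[0] == 1.0 and fulls[-1] < 0.9

    def test_positive_class_share_tracks_prevalence(self, assay):
        from hlatag import clopper_pearson_ci

        points, _ = as_cohort(sigma=SEPARATION / 12, n=400, prevalence=0.10, seed=9)
        calls = call_allelic_discrimination(points, assay)
        n_pos = sum(c.alleles == ("positive",) for c in calls)
        lo, hi = clopper_pearson_ci(n_pos, len(calls))
        assert lo <= 0.10 <= hi


class TestInvariances:
    def test_permutation_invariance(self, assay):
        points, _ = as_cohort(sigma=SEPARATION / 6, seed=4)
        shuffled = points.copy()
        random.Random(99).shuffle(shuffled)
        a = {c.sample_id: c for c in call_allelic_discrimination(points, assay)}
        b = {c.sample_id: c for c in call_allelic_discrimination(shuffled, assay)}
        assert a == b

    def test_common_scale_invariance(self, assay):
        points, _ = as_cohort(sigma=SEPARATION / 6, seed=5)
        scaled = [
            FluorescencePoint(p.sample_id, p.assay_id, p.fam * 37.5, p.vic * 37.5, p.is_ntc)
            for p in points
        ]
        a = {c.sample_id: c for c in call_allelic_discrimination(points, assay)}
        b = {c.sample_id: c for c in call_allelic_discrimination(scaled, assay)}
        assert a == b

    def test_indeterminate_fraction_monotone_in_threshold(self, assay):
        points, _ = as_cohort(sigma=SEPARATION / 3, seed=6)
        fractions = []
        for thr in (0.0, 0.1, 0.2, 0.35, 0.5, 0.7):
            calls = call_allelic_discrimination(
                points, assay, ClusterOptions(undetermined_threshold=thr)
            )
            fractions.append(sum(not c.is_determinate for c in calls) / len(calls))
        assert fractions == sorted(fractions)


class TestDegenerateInputs:
    def test_origin_point_is_indeterminate(self, assay):
        points, _ = as_cohort(sigma=SEPARATION / 12)
        points.append(FluorescencePoint("ORIGIN", "5801A", 0.0, 0.0))
        calls = call_allelic_discrimination(points, assay)
        origin = next(c for c in calls if c.sample_id == "ORIGIN")
        assert not origin.is_determinate

    def test_reference_channel_failure_is_indeterminate(self, assay):
        # strong target signal but no reference amplification: failed well
        points, _ = as_cohort(sigma=SEPARATION / 12)
        points.append(FluorescencePoint("NOREF", "5801A", 0.0, 2.1))
        calls = call_allelic_discrimination(points, assay)
        noref = next(c for c in calls if c.sample_id == "NOREF")
        assert not noref.is_determinate

    def test_empty_positive_cluster_yields_zero_positives(self, assay):
        cfg = SimConfig(
            n_samples=60, target="B*58:01",
            markers=(MarkerSpec("5801A", 0.0, 1.0),),  # no marker ever fires
            carrier_prevalence=0.1,
            fluorescence=FluorescenceSpec(centroids=AS_CENTROIDS, sigma=0.15, n_ntc=3),
            seed=2,
        )
        cohort = simulate_cohort(cfg)
        points = simulate_fluorescence(cohort.marker_truth, cfg)
        calls = call_allelic_discrimination(points, assay)
        assert sum(c.alleles == ("positive",) for c in calls) == 0

    def test_ntc_wells_never_called(self, assay):
        points, _ = as_cohort(sigma=SEPARATION / 12)
        calls = call_allelic_discrimination(points, assay)
        assert not any(c.sample_id.startswith("NTC") for c in calls)

    def test_identical_points_rejected(self, assay):
        points = [FluorescencePoint(f"S{i}", "5801A", 2.0, 2.0) for i in range(10)]
        with pytest.raises(ClusterError, match="5801A"):
            fit_cluster_model(points, assay)

    def test_empty_and_all_ntc_rejected(self, assay):
        with pytest.raises(ClusterError):
            fit_cluster_model([], assay)
        ntc = [FluorescencePoint("N1", "5801A", 0.01, 0.01, is_ntc=True)]
        with pytest.raises(ClusterError):
            fit_cluster_model(ntc, assay)

    def test_mixed_assays_rejected(self, assay):
        points = [
            FluorescencePoint("S1", "5801A", 1.0, 1.0),
            FluorescencePoint("S2", "5801B", 1.0, 2.0),
        ]
        with pytest.raises(ClusterError):
            fit_cluster_model(points, assay)


class TestThreeClassFit:
    def _snv_points(self, sigma=0.15, seed=11, n=150):
        cfg = SimConfig(
            n_samples=n, target="B*57:01",
            markers=(MarkerSpec("C__16222070_10", 1.0, 1.0),),
            allele_frequency=0.3,
            fluorescence=FluorescenceSpec(centroids=SNV_CENTROIDS, sigma=sigma, n_ntc=3),
            seed=seed,
        )
        cohort = simulate_cohort(cfg)
        return simulate_fluorescence(cohort.marker_truth, cfg), cohort

    def test_centroids_recovered_within_three_sigma(self, snv_assay):
        sigma = 0.15
        points, _ = self._snv_points(sigma=sigma)
        model = fit_cluster_model(points, snv_assay)
        fmin, frange, vmin, vrange = model.norm
        for cname, (tx, ty) in SNV_CENTROIDS.items():
            cx, cy = model.centroids[cname]
            raw = (cx * frange + fmin, cy * vrange + vmin)
            assert abs(raw[0] - tx) < 3 * sigma and abs(raw[1] - ty) < 3 * sigma

    def test_genotype_labels_recovered(self, snv_assay):
        points, cohort = self._snv_points()
        calls = call_allelic_discrimination(points, snv_assay)
        truth = dict(zip(cohort.marker_truth.sample_id, cohort.marker_truth.class_label))
        class_alleles = {
            "homo_allele1": ("T", "T"), "het": ("G", "T"), "homo_allele2": ("G", "G"),
        }
        ok = sum(
            c.is_determinate and c.alleles == class_alleles[truth[c.sample_id]]
            for c in calls
        )
        assert ok / len(calls) > 0.97

    def test_separation_score_reported(self, snv_assay):
        points, _ = self._snv_points()
        model = fit_cluster_model(points, snv_assay)
        assert model.separation > 0.5
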