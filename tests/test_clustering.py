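"""Modified k-means: polarity invariance, GEV oracle equality, exhaustive
small-instance optimality, model-order diagnostics, template labeling."""

import itertools

import numpy as np
import pytest

from eegmicrostates import (
    PrototypeSet,
    assign_peaks,
    compute_gev,
    label_prototypes,
    modified_kmeans,
    scan_k,
    spatial_correlation,
)
from eegmicrostates.clustering import _dominant_eigenvector, within_dispersion
from eegmicrostates.containers import normalize_rows
from eegmicrostates.layout import canonical_templates


def noisy_peak_maps(prototypes, n, noise_sigma, seed, labels=None):
    """Peak-map sample: random class, random polarity, channel noise."""
    rng = np.random.default_rng(seed)
    k, nch = prototypes.maps.shape
    if labels is None:
        labels = rng.integers(0, k, n)
    signs = rng.choice([-1.0, 1.0], n)
    maps = prototypes.maps[labels] * signs[:, None]
    if noise_sigma > 0:
        maps = maps + rng.normal(0, noise_sigma / np.sqrt(nch), (n, nch))
    return maps, labels


class TestModifiedKmeans:
    def test_single_cluster_with_mixed_polarity(self):
        rng = np.random.default_rng(0)
        m = normalize_rows(rng.standard_normal((1, 16)))[0]
        peaks = np.vstack([m, -m, 2 * m])
        ps = modified_kmeans(peaks, 1, n_restarts=2, seed=0)
        assert abs(np.abs(spatial_correlation(ps.maps, m[None, :]))[0, 0] - 1) < 1e-12
        gev, _ = compute_gev(peaks, ps)
        assert abs(gev - 1.0) < 1e-12

    def test_two_orthogonal_generators_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = normalize_rows(rng.standard_normal((1, 32)))[0]
        b = rng.standard_normal(32)
        b = normalize_rows((b - (b - b.mean()) @ a * a)[None, :])[0]  # orthogonalize
        gen = PrototypeSet(maps=np.vstack([a, b]))
        peaks, labels = noisy_peak_maps(gen, 400, 0.0, seed=2)
        ps = modified_kmeans(peaks, 2, n_restarts=5, seed=3)
        corr = np.abs(spatial_correlation(ps.maps, gen.maps))
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-9)
        assignment, _ = assign_peaks(peaks, ps)
        mapping = corr.argmax(axis=1)
        assert np.array_equal(mapping[assignment], labels)

    def test_noisy_four_class_recovery(self, prototypes64):
        peaks, _ = noisy_peak_maps(prototypes64, 800, 0.3, seed=4)
        ps = modified_kmeans(peaks, 4, n_restarts=20, seed=5)
        corr = np.abs(spatial_correlation(ps.maps, prototypes64.maps))
        assert sorted(corr.argmax(axis=1)) == [0, 1, 2, 3]
        assert corr.max(axis=1).min() >= 0.95

    def test_polarity_invariance_of_fit(self, prototypes64):
        peaks, _ = noisy_peak_maps(prototypes64, 300, 0.3, seed=6)
        flip = np.random.default_rng(7).choice([-1.0, 1.0], len(peaks))
        ps1 = modified_kmeans(peaks, 4, n_restarts=5, seed=8)
        ps2 = modified_kmeans(peaks * flip[:, None], 4, n_restarts=5, seed=8)
        g1, _ = compute_gev(peaks, ps1)
        g2, _ = compute_gev(peaks * flip[:, None], ps2)
        assert abs(g1 - g2) < 1e-9
        a1, _ = assign_peaks(peaks, ps1)
        a2, _ = assign_peaks(peaks * flip[:, None], ps2)
        assert np.array_equal(a1, a2)
        assert np.allclose(np.diag(np.abs(spatial_correlation(ps1.maps, ps2.maps))),
                           1.0, atol=1e-9)

    def test_more_restarts_never_hurt(self, prototypes64):
        peaks, _ = noisy_peak_maps(prototypes64, 200, 0.5, seed=9)
        g1 = modified_kmeans(peaks, 4, n_restarts=1, seed=10).diagnostics["gev_total"]
        g20 = modified_kmeans(peaks, 4, n_restarts=20, seed=10).diagnostics["gev_total"]
        assert g20 >= g1 - 1e-12   # restart 0 is the same seed child

    def test_exhaustive_two_cluster_optimality(self):
        """On 10 maps with k = 2 the fit attains the best of all 2-partitions."""
        rng = np.random.default_rng(11)
        peaks = rng.standard_normal((10, 12))
        ps = modified_kmeans(peaks, 2, n_restarts=50, seed=12, tol=1e-12)
        gev_fit, _ = compute_gev(peaks, ps)
        best = 0.0
        for bits in itertools.product([0, 1], repeat=9):
            part = np.array((0,) + bits)
            if part.min() == part.max():
                continue
            proto = np.vstack([
                _dominant_eigenvector(peaks[part == j] - (peaks[part == j]).mean(axis=1, keepdims=True))
                for j in (0, 1)
            ])
            gev, _ = compute_gev(peaks, PrototypeSet(maps=proto), part)
            best = max(best, gev)
        assert gev_fit >= best - 1e-9
        assert gev_fit <= best + 1e-9

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            modified_kmeans(np.random.default_rng(0).standard_normal((3, 8)), 4, seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            modified_kmeans(np.random.default_rng(0).standard_normal((9, 8)), 2)


class TestComputeGEV:
    def test_perfect_fit_gives_one(self, prototypes64):
        peaks, labels = noisy_peak_maps(prototypes64, 50, 0.0, seed=0)
        gev, per_class = compute_gev(peaks, prototypes64, labels)
        assert abs(gev - 1.0) < 1e-12
        assert abs(per_class.sum() - 1.0) < 1e-12

    def test_orthogonal_prototypes_give_zero(self):
        peaks = np.vstack([np.tile([1.0, -1.0], 4)])
        proto = PrototypeSet(maps=np.tile([1.0, 1.0, -1.0, -1.0], 2)[None, :])
        gev, _ = compute_gev(peaks, proto, np.zeros(1, dtype=int))
        assert abs(gev) < 1e-12

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(13)
        peaks = rng.standard_normal((20, 8))
        proto = PrototypeSet(maps=normalize_rows(rng.standard_normal((3, 8))))
        assignment, _ = assign_peaks(peaks, proto)
        gev, per_class = compute_gev(peaks, proto, assignment)
        # independent summation, term by term
        num = np.zeros(3)
        den = 0.0
        for x, a in zip(peaks, assignment):
            xc = x - x.mean()
            g2 = np.mean(xc**2)
            r = spatial_correlation(xc[None, :], proto.maps[a][None, :])[0, 0]
            num[a] += g2 * r**2
            den += g2
        assert abs(gev - num.sum() / den) < 1e-12
        assert np.allclose(per_class, num / den, atol=1e-12)


@pytest.fixture(scope="module")
def scan(prototypes64):
    peaks, _ = noisy_peak_maps(prototypes64, 600, 0.2, seed=14)
    return scan_k(peaks, k_range=range(3, 7), n_restarts=8, seed=15)


class TestScanK:
    def test_gev_increases_with_elbow_at_true_k(self, scan):
        gev = {ps.k: ps.diagnostics["gev_total"] for ps in scan}
        assert gev[3] < gev[4] <= gev[5] <= gev[6] + 1e-9
        assert gev[4] - gev[3] > gev[5] - gev[4]

    def test_dispersion_non_increasing(self, scan):
        w = [ps.diagnostics["w"] for ps in scan]
        assert all(a >= b - 1e-9 for a, b in zip(w, w[1:]))

    def test_krzanowski_lai_peaks_at_true_k(self, scan):
        kl = {ps.k: ps.diagnostics["kl"] for ps in scan}
        assert max(kl, key=kl.get) == 4

    def test_cv_reported_finite(self, scan):
        assert all(np.isfinite(ps.diagnostics["cv"]) for ps in scan)


class TestLabelPrototypes:
    def test_identity_recovered_from_shuffled_signed_templates(self):
        templates = canonical_templates(64)
        perm = [2, 0, 3, 1]
        signs = np.array([1.0, -1.0, 1.0, -1.0])
        shuffled = PrototypeSet(maps=templates.maps[perm] * signs[:, None])
        labeled = label_prototypes(shuffled)
        assert labeled.labels == ["A", "B", "C", "D"]
        corr = np.abs(spatial_correlation(labeled.maps, templates.maps))
        assert np.allclose(np.diag(corr), 1.0, atol=1e-12)

    def test_perturbed_templates_usually_labeled_correctly(self):
        templates = canonical_templates(64)
        hits = 0
        n_trials = 40
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            noisy = templates.maps + rng.normal(0, 0.2 / np.sqrt(64), (4, 64))
            labeled = label_prototypes(PrototypeSet(maps=noisy))
            corr = np.abs(spatial_correlation(labeled.maps, templates.maps))
            hits += np.all(corr.argmax(axis=1) == np.arange(4))
        assert hits / n_trials >= 0.95

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            label_prototypes(PrototypeSet(maps=np.eye(5)[:3]))


def test_within_dispersion_zero_for_identical_members(prototypes64):
    peaks = np.repeat(prototypes64.maps, 5, axis=0)
    assert within_dispersion(peaks, prototypes64) < 1e-9
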