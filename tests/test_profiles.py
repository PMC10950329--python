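"""STED line profiles: extraction, alignment, integration, KI masking."""

import numpy as np
import pytest

from synapkit import (LineSpec, PresynapticWindow, SynapseLayout,
                      align_and_orient, extract_line_profile,
                      integrate_presynaptic_level, ki_cluster_intensity,
                      localization_profile, normalize_levels,
                      simulate_sted_synapse)
from synapkit.profiles import RawProfile, SynapseProfile


def center_line(img):
    return LineSpec(center=((img.shape[-2] - 1) / 2, (img.shape[-1] - 1) / 2))


def render(off=40.0, amp=1.0, seed=0, **kw):
    lay = SynapseLayout(poi_offset=off, poi_amplitude=amp, **kw)
    img, _ = simulate_sted_synapse(lay, seed=seed)
    return img


class TestExtraction:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((3, 64, 64), 7.25)
        prof = extract_line_profile(img, LineSpec(center=(31.5, 31.5)))
        np.testing.assert_allclose(prof.intensities, 7.25)

    def test_default_line_has_53_samples(self):
        line = LineSpec(center=(31.5, 31.5))
        assert line.n_samples == 53
        prof = extract_line_profile(np.zeros((1, 64, 64)), line)
        assert prof.intensities.shape == (1, 53)

    def test_blob_argmax_on_line(self):
        img = render(off=0.0, seed=None)
        prof = extract_line_profile(img, center_line(img))
        i = np.argmax(prof.intensities[2])
        assert abs(prof.positions[i]) <= prof.positions[1] - prof.positions[0]

    def test_footprint_outside_image_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            extract_line_profile(np.zeros((1, 30, 30)), LineSpec(center=(5, 5)))


class TestAlignOrient:
    def test_reference_maximum_at_zero(self):
        img = render(seed=3, bassoon_position=2 * 18.9)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        ref = prof.raw[prof.reference_channel]
        assert prof.positions[np.argmax(ref)] == 0.0

    def test_postsynaptic_peak_flipped_to_negative(self):
        img = render(seed=None, homer_offset=+150.0, off=0.0)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        assert prof.orientation_flipped
        post = prof.raw[prof.post_channel]
        assert prof.positions[np.argmax(post)] == pytest.approx(-151.2,
                                                                abs=1e-6)

    def test_alignment_idempotent(self):
        img = render(seed=5)
        p1 = align_and_orient(extract_line_profile(img, center_line(img)))
        p2 = align_and_orient(RawProfile(positions=p1.positions,
                                         intensities=p1.raw, line=None))
        assert p2.orientation_flipped is False
        np.testing.assert_array_equal(p1.raw, p2.raw)
        np.testing.assert_array_equal(p1.positions, p2.positions)

    def test_horizontal_image_flip_leaves_positions_unchanged(self):
        """The orientation convention absorbs a mirrored field of view."""
        img = render(seed=None, off=40.0)
        p1 = align_and_orient(extract_line_profile(img, center_line(img)))
        p2 = align_and_orient(extract_line_profile(img[:, :, ::-1],
                                                   center_line(img)))
        i1 = np.argmax(p1.raw[2])
        i2 = np.argmax(p2.raw[2])
        assert p1.positions[i1] == pytest.approx(p2.positions[i2], abs=1e-9)

    def test_flat_reference_rejected(self):
        prof = RawProfile(positions=np.arange(5) * 18.9,
                          intensities=np.ones((3, 5)), line=None)
        with pytest.raises(ValueError, match="flat"):
            align_and_orient(prof)


class TestLocalization:
    def test_normalized_channels_unit_max(self):
        img = render(seed=2)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        assert np.allclose(prof.normalized().max(axis=1), 1.0)

    def test_identical_profiles_zero_sem(self):
        img = render(seed=4)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        table = localization_profile([prof] * 5)
        assert np.all(table["sem"] <= 1e-12)
        assert set(table["n"]) == {5}

    def test_planted_offset_recovered_from_noisy_population(self):
        profs = []
        for i in range(100):
            rng = np.random.default_rng(i)
            img = render(off=40.0, seed=900 + i,
                         bassoon_position=float(rng.uniform(-38, 38)),
                         homer_offset=float(rng.choice([-150.0, 150.0])))
            profs.append(align_and_orient(
                extract_line_profile(img, center_line(img))))
        tab = localization_profile(profs)
        ch2 = tab[tab["channel"] == 2]
        peak = ch2.loc[ch2["mean"].idxmax(), "position_nm"]
        assert abs(peak - 40.0) <= 18.9


class TestPresynapticLevel:
    def test_default_window_holds_eleven_samples(self):
        img = render(seed=None)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        flat = SynapseProfile(positions=prof.positions,
                              raw=np.vstack([prof.raw[:2],
                                             np.ones_like(prof.raw[2:])]),
                              reference_channel=0, post_channel=1,
                              orientation_flipped=False)
        assert integrate_presynaptic_level(flat) == pytest.approx(11.0)

    def test_window_membership_on_grid(self):
        img = render(seed=None)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        eps = 1e-6
        sel = ((prof.positions >= -37.8 - eps)
               & (prof.positions <= 151.4 + eps))
        inside = prof.positions[sel]
        assert 151.2 in np.round(inside, 1)
        assert 170.1 not in np.round(inside, 1)
        assert -37.8 in np.round(inside, 1)

    def test_integration_is_linear(self):
        img = render(seed=6)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        doubled = SynapseProfile(positions=prof.positions,
                                 raw=prof.raw * np.array([1, 1, 2])[:, None],
                                 reference_channel=0, post_channel=1,
                                 orientation_flipped=False)
        assert integrate_presynaptic_level(doubled) == pytest.approx(
            2 * integrate_presynaptic_level(prof))

    def test_halved_amplitude_halves_the_level(self):
        imgs = [render(amp=a, seed=None) for a in (1.0, 0.5)]
        levels = [integrate_presynaptic_level(align_and_orient(
            extract_line_profile(im, center_line(im)))) for im in imgs]
        assert levels[1] / levels[0] == pytest.approx(0.5, rel=0.02)

    def test_window_outside_profile_rejected(self):
        img = render(seed=None)
        prof = align_and_orient(extract_line_profile(img, center_line(img)))
        with pytest.raises(ValueError, match="window"):
            integrate_presynaptic_level(prof,
                                        window=PresynapticWindow(-37.8, 5000.0))


class TestNormalizeLevels:
    def test_percent_of_control(self):
        tab = normalize_levels({"ctrl": [2.0, 2.0, 2.0], "treat": [1.0, 3.0]},
                               "ctrl")
        ctrl = tab[tab["condition"] == "ctrl"]["percent_of_control"]
        treat = tab[tab["condition"] == "treat"]["percent_of_control"]
        assert ctrl.mean() == pytest.approx(100.0)
        assert sorted(treat) == [50.0, 150.0]

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            normalize_levels({"ctrl": [0.0, 0.0], "t": [1.0]}, "ctrl")


class TestKIClusterIntensity:
    def _blobs(self):
        marker = np.full((64, 64), 10.0)
        actin = np.full((64, 64), 10.0)
        sted = np.full((64, 64), 50.0)
        marker[20:30, 20:30] = 200.0
        actin[24:34, 24:34] = 200.0
        return marker, actin, sted

    def test_otsu_mask_matches_bruteforce_oracle(self):
        """skimage's Otsu equals exhaustive search over the 256-bin histogram."""
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(0)
        img = np.concatenate([rng.normal(10, 2, 2000),
                              rng.normal(200, 10, 500)])
        hist, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best, best_var = None, -1.0
        for k in range(1, 256):
            w0, w1 = hist[:k].sum(), hist[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:k] * centers[:k]).sum() / w0
            m1 = (hist[k:] * centers[k:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best, best_var = centers[k - 1], var
        thr = threshold_otsu(img)
        assert 10 < thr < 200 and abs(thr - best) < (edges[1] - edges[0]) * 2

    def test_mask_is_intersection_with_uniform_sted_mean(self):
        marker, actin, sted = self._blobs()
        res = ki_cluster_intensity(marker, actin, sted)
        assert not res.no_rois
        assert len(res.table) == 1
        assert res.table["mean_sted"].iloc[0] == pytest.approx(50.0)

    def test_disjoint_clusters_flagged_not_crash(self):
        marker, actin, sted = self._blobs()
        actin[:] = 10.0
        actin[50:60, 50:60] = 200.0
        res = ki_cluster_intensity(marker, actin, sted)
        assert res.no_rois and len(res.table) == 0
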