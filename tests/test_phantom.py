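import numpy as np
import pytest

import multiseg as ms
from multiseg import phantom as ph


def noiseless_spec(**kwargs):
    """Spec with zero tissue jitter and no measurement noise."""
    table = {
        k: {m: (v[0], 0.0) for m, v in d.items()}
        for k, d in ph.DEFAULT_CONTRAST.items()
    }
    kwargs.setdefault("contrast_table", table)
    kwargs.setdefault("noise_model", "none")
    return ms.PhantomSpec(**kwargs)


class TestGeometry:
    def test_all_labels_present(self):
        truth = ms.build_labels(ms.PhantomSpec(shape=(48, 48, 48), seed=0))
        counts = truth.counts()
        assert all(counts[name] > 0 for name in counts), counts

    def test_zero_dura_arc(self):
        spec = ms.PhantomSpec(shape=(32, 32, 32), seed=0, dura_arc_fraction=0.0)
        assert ms.build_labels(spec).counts()["DURA"] == 0

    def test_gm_ribbon_thickness_by_ray_marching(self):
        spec = ms.PhantomSpec(shape=(48, 48, 48), seed=0, gm_thickness=3.0)
        labels = ms.build_labels(spec).labels.data
        c = (np.asarray(spec.shape) - 1) // 2
        # march along the three positive axes and count GM run lengths
        runs = [
            int(np.sum(labels[c[0]:, c[1], c[2]] == ph.GM)),
            int(np.sum(labels[c[0], c[1]:, c[2]] == ph.GM)),
            int(np.sum(labels[c[0], c[1], c[2]:] == ph.GM)),
        ]
        for r in runs:
            assert abs(r - spec.gm_thickness) <= 1.0, runs

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            ms.build_labels(
                ms.PhantomSpec(shape=(24, 24, 24), gm_thickness=9, csf_margin=5)
            )

    def test_missing_contrast_label_rejected(self):
        table = {k: dict(v) for k, v in ph.DEFAULT_CONTRAST.items()}
        del table["DURA"]
        with pytest.raises(ValueError, match="missing labels"):
            ms.PhantomSpec(contrast_table=table)


class TestRendering:
    def test_noiseless_render_equals_label_means(self):
        spec = noiseless_spec(shape=(32, 32, 32), seed=1)
        stack, _, truth = ms.generate(spec)
        labels = truth.labels.data
        for ch in ("t1w", "flair"):
            img = stack.channel(ch).data
            for name, code in ph.LABEL_CODES.items():
                sel = labels == code
                if sel.any():
                    np.testing.assert_allclose(
                        img[sel], truth.contrast_table[name][ch][0],
                        rtol=1e-10, err_msg=f"{name}/{ch}",
                    )

    def test_confound_contrast_contracts(self):
        stack, _, truth = ms.generate(ms.PhantomSpec(shape=(40, 40, 40), seed=2))
        labels = truth.labels.data
        t1w, flair = stack.channel("t1w").data, stack.channel("flair").data
        gm = labels == ph.GM
        for code in (ph.DURA, ph.CONNECTIVE):
            sel = labels == code
            # isointense to GM on T1w (within 2%), dark on FLAIR (< 50%)
            assert abs(t1w[sel].mean() - t1w[gm].mean()) <= 0.02 * t1w[gm].mean()
            assert flair[sel].mean() < 0.5 * flair[gm].mean()
        vessel = labels == ph.VESSEL
        assert t1w[vessel].mean() >= 1.25 * t1w[gm].mean()
        suscept = labels == ph.SUSCEPT_GM
        assert t1w[suscept].mean() < 0.7 * t1w[gm].mean()
        assert abs(flair[suscept].mean() - flair[gm].mean()) < 0.05 * flair[gm].mean()

    def test_multiecho_relaxometry_roundtrip(self):
        spec = noiseless_spec(shape=(32, 32, 32), seed=0)
        stack, series, truth = ms.generate(spec)
        r2map = ms.fit_r2star(series)
        wm = truth.labels.data == ph.WM
        np.testing.assert_allclose(r2map.rate.data[wm], 0.045, rtol=1e-8)
        gm = truth.labels.data == ph.GM
        np.testing.assert_allclose(r2map.rate.data[gm], 0.04, rtol=1e-8)

    def test_echo_average_matches_contrast_table(self):
        spec = noiseless_spec(shape=(32, 32, 32), seed=0)
        stack, series, truth = ms.generate(spec)
        t1w = stack.channel("t1w").data
        gm = truth.labels.data == ph.GM
        np.testing.assert_allclose(t1w[gm], 400.0, rtol=1e-10)

    def test_nearest_mean_label_conservation(self):
        # noiseless intensities classify back to their own labels exactly
        spec = noiseless_spec(shape=(32, 32, 32), seed=1)
        stack, _, truth = ms.generate(spec)
        labels = truth.labels.data
        means = np.array([
            [truth.contrast_table[name][ch][0] for ch in ("t1w", "flair")]
            for name in ph.LABEL_NAMES.values()
        ])
        X = np.stack([stack.channel("t1w").data, stack.channel("flair").data], -1)
        d2 = ((X[..., None, :] - means) ** 2).sum(-1)
        assert np.array_equal(np.argmin(d2, axis=-1), labels)

    def test_rician_high_snr_converges_to_gaussian(self):
        spec = ms.PhantomSpec(shape=(32, 32, 32), seed=4, snr=50,
                              noise_model="rician")
        stack, _, truth = ms.generate(spec)
        gm = truth.labels.data == ph.GM
        for ch in ("t1w", "flair"):
            mean = stack.channel(ch).data[gm].mean()
            assert abs(mean - 400.0) < 0.01 * 400.0

    def test_deterministic_given_seed(self):
        a = ms.generate(ms.PhantomSpec(shape=(24, 24, 24), seed=9))
        b = ms.generate(ms.PhantomSpec(shape=(24, 24, 24), seed=9))
        assert np.array_equal(a[2].labels.data, b[2].labels.data)
        for va, vb in zip(a[0].channels, b[0].channels):
            assert np.array_equal(va.data, vb.data)

    def test_different_seeds_differ(self):
        a = ms.generate(ms.PhantomSpec(shape=(24, 24, 24), seed=1))
        b = ms.generate(ms.PhantomSpec(shape=(24, 24, 24), seed=2))
        assert not np.array_equal(a[0].channels[0].data, b[0].channels[0].data)


class TestPriorsAndSuite:
    def test_priors_sum_to_one(self, dura_phantom):
        P = np.stack([p.data for p in dura_phantom["priors"]])
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)
        assert (P > 0).all()

    def test_gm_prior_bleeds_onto_dura(self, dura_phantom):
        # the atlas analog: adjacent GM prior support covers the dura sheet
        dura = dura_phantom["truth"].mask("DURA").data.astype(bool)
        gm_prior = dura_phantom["priors"][0].data
        assert gm_prior[dura].mean() > 0.2

    def test_default_suite_contents(self):
        suite = ms.make_default_suite(seed=0, shape=(24, 24, 24))
        assert len(suite) >= 4
        assert {"dura", "vessel", "susceptibility",
                "occipital-low-contrast"} <= set(suite)
        again = ms.make_default_suite(seed=0, shape=(24, 24, 24))
        for name in suite:
            for va, vb in zip(suite[name][0].channels, again[name][0].channels):
                assert np.array_equal(va.data, vb.data)

    def test_low_contrast_sector_collapses_t1w_contrast(self):
        spec = noiseless_spec(
            shape=(40, 40, 40), seed=0,
            low_contrast_sector=0.25, low_contrast_factor=0.05,
            suscept_radius=0.0,
        )
        stack, _, truth = ms.generate(spec)
        labels = truth.labels.data
        sector = ph._sector_mask(spec)
        wm_in = labels == ph.WM
        t1w = stack.channel("t1w").data
        flair = stack.channel("flair").data
        # inside the sector WM sits within 5% of GM on t1w, FLAIR keeps contrast
        assert abs(t1w[wm_in & sector].mean() - 420.0) < 1.0
        assert abs(flair[wm_in & sector].mean() - 250.0) < 1.0

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = ms.PhantomSpec(shape=(24, 24, 24), seed=5, snr=17.5)
        path = spec.to_yaml(tmp_path / "spec.yaml")
        back = ms.PhantomSpec.from_yaml(path)
        assert back == spec
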