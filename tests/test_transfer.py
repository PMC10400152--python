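"""Spike partitioning, extra-weighting, schemes, and the size sweep."""

import numpy as np
import pytest

import leafspec as ls
from leafspec.transfer import (
    SCHEMES,
    draw_spike,
    extra_weight,
    replication_factor,
    run_scheme,
    spike_size_sweep,
    spike_weights,
)

GRID12 = range(1, 13)


class TestDrawSpike:
    @pytest.mark.parametrize("n_ext,n_spike,n_test", [(96, 20, 76), (126, 20, 106)])
    def test_partition_sizes(self, demo_study, n_ext, n_spike, n_test):
        _, ext = demo_study
        pool = ext["soybean"].samples + ext["camelina"].samples
        external = ls.SpectralLibrary(pool[:n_ext])
        part = draw_spike(external, n_spike, seed=0)
        assert len(part.spike_ids) == n_spike
        assert len(part.test_ids) == n_test
        assert not set(part.spike_ids) & set(part.test_ids)

    def test_deterministic_and_uniform_without_replacement(self, demo_study):
        _, ext = demo_study
        soy = ext["soybean"]
        a = draw_spike(soy, 20, seed=5)
        b = draw_spike(soy, 20, seed=5)
        assert a.spike_ids == b.spike_ids
        assert len(set(a.spike_ids)) == 20

    def test_zero_or_full_spike_rejected(self, demo_study):
        _, ext = demo_study
        soy = ext["soybean"]
        with pytest.raises(ValueError):
            draw_spike(soy, 0, seed=0)
        with pytest.raises(ValueError):
            draw_spike(soy, len(soy), seed=0)


class TestExtraWeight:
    def test_library_2460_spike_20_replicates_123_times(self):
        assert replication_factor(2460, 20) == 123

    @pytest.mark.parametrize("n_lib,n_spike,r", [(100, 30, 3), (50, 50, 1), (10, 20, 1)])
    def test_rounding_rule(self, n_lib, n_spike, r):
        assert replication_factor(n_lib, n_spike) == r

    def test_augmented_size_accounting(self, demo_study):
        lib, ext = demo_study
        spike = ext["soybean"].samples[:20]
        aug = extra_weight(lib, spike)
        r = replication_factor(len(lib), 20)
        assert len(aug) == len(lib) + r * 20
        copies = [s for s in aug if "__rep" in s.id]
        assert len(copies) == r * 20

    def test_balanced_case_is_concatenation(self, demo_study):
        lib, ext = demo_study
        sub = ls.SpectralLibrary(lib.samples[:20])
        aug = extra_weight(sub, ext["soybean"].samples[:20])
        assert len(aug) == 40

    def test_weights_variant_matches_replication_coefficients(self, demo_study):
        lib, ext = demo_study
        small = ls.SpectralLibrary(lib.samples[:60])
        spike = ext["soybean"].samples[:15]
        aug = extra_weight(small, spike)
        cal_w, w = spike_weights(small, spike)
        sub_aug = aug.with_trait("N")
        sub_w = cal_w.with_trait("N")
        m_rep = ls.fit_plsr(sub_aug.spectra_matrix(), sub_aug.trait_values("N"), n_lv=5)
        m_w = ls.fit_plsr(
            sub_w.spectra_matrix(), sub_w.trait_values("N"), n_lv=5, sample_weight=w
        )
        np.testing.assert_allclose(m_rep.coef, m_w.coef, atol=1e-8)

    def test_grid_mismatch_rejected(self, demo_study, tiny_library):
        lib, _ = demo_study
        with pytest.raises(Exception, match="grid"):
            extra_weight(lib, tiny_library.samples)

    def test_empty_spike_rejected(self, demo_study):
        lib, _ = demo_study
        with pytest.raises(ValueError):
            extra_weight(lib, [])


class TestRunScheme:
    def test_library_only_model_invariant_to_spike_seed(self, demo_study):
        """library_only ignores the spike samples: the calibrated model (and
        hence its predictions on any fixed spectra) does not depend on which
        samples were drawn as the spike set."""
        lib, ext = demo_study
        soy = ext["soybean"]
        preds = []
        probe = soy.spectra_matrix()[:10]
        for spike_seed in (1, 2):
            part = draw_spike(soy, 20, seed=spike_seed)
            res = run_scheme(lib, soy, part, "N", grid=GRID12, scheme="library_only", seed=0)
            preds.append(res.model.predict(probe))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_missing_trait_marked_unavailable_not_zero(self, demo_study):
        lib, ext = demo_study
        cam = ext["camelina"]
        part = draw_spike(cam, 20, seed=0)
        res = run_scheme(lib, cam, part, "CHL", grid=GRID12, scheme="spiked_library", seed=0)
        assert not res.available
        assert res.report is None

    def test_no_test_id_in_any_calibration_set(self, demo_study):
        lib, ext = demo_study
        soy = ext["soybean"]
        part = draw_spike(soy, 20, seed=3)
        for scheme in SCHEMES:
            res = run_scheme(lib, soy, part, "N", grid=GRID12, scheme=scheme, seed=0)
            if res.model is None:
                continue
            # the guard is asserted inside run_scheme; re-check externally
            cal_n = res.model.cv.n
            if scheme == "library_only":
                assert cal_n == len(lib.with_trait("N"))
            elif scheme == "spike_only":
                assert cal_n == 20
            else:
                r = replication_factor(len(lib), 20)
                assert cal_n == len(lib.with_trait("N")) + r * 20

    def test_replication_factor_recorded(self, demo_study):
        lib, ext = demo_study
        soy = ext["soybean"]
        part = draw_spike(soy, 20, seed=1)
        res = run_scheme(lib, soy, part, "N", grid=[4], scheme="spiked_library", seed=0)
        assert res.replication == replication_factor(len(lib), 20)

    def test_unknown_scheme_rejected(self, demo_study):
        lib, ext = demo_study
        part = draw_spike(ext["soybean"], 20, seed=0)
        with pytest.raises(ValueError, match="scheme"):
            run_scheme(lib, ext["soybean"], part, "N", scheme="bogus")


class TestSchemeProperties:
    def test_spiking_improves_transfer_on_shifted_external(self):
        """Mean R2 of the extra-weighted spiked library beats library-only
        calibration for most traits on a species outside the library."""
        means = {s: [] for s in SCHEMES}
        for seed in range(5):
            cfg = ls.demo_config(seed=200 + seed)
            lib, ext = ls.generate_study(cfg)
            bin10 = lambda L: L.map_spectra(lambda s: ls.window_average(s, 10.0))
            lib, soy = bin10(lib), bin10(ext["soybean"])
            part = draw_spike(soy, 20, seed=seed)
            for scheme in SCHEMES:
                res = run_scheme(lib, soy, part, "LWC", grid=GRID12, scheme=scheme, seed=seed)
                means[scheme].append(res.report.r2)
        assert np.mean(means["spiked_library"]) > np.mean(means["library_only"])
        assert np.mean(means["spiked_library"]) > np.mean(means["spike_only"])

    def test_zero_shift_schemes_agree_within_noise(self):
        """Null control: without archetype shift the three schemes perform
        comparably on the external set."""
        diffs = []
        for seed in range(5):
            cfg = ls.demo_config(seed=300 + seed, shift_magnitude=0.0)
            lib, ext = ls.generate_study(cfg)
            bin10 = lambda L: L.map_spectra(lambda s: ls.window_average(s, 10.0))
            lib, soy = bin10(lib), bin10(ext["soybean"])
            part = draw_spike(soy, 20, seed=seed)
            r2 = {}
            for scheme in ("library_only", "spiked_library"):
                res = run_scheme(lib, soy, part, "N", grid=GRID12, scheme=scheme, seed=seed)
                r2[scheme] = res.report.r2
            diffs.append(r2["spiked_library"] - r2["library_only"])
        assert abs(np.mean(diffs)) < 0.05

    def test_no_harm_to_internal_cv_at_zero_shift(self):
        """Spiking an unshifted library does not degrade internal CV beyond
        sampling noise."""
        deltas = []
        for seed in range(5):
            cfg = ls.demo_config(seed=400 + seed, shift_magnitude=0.0)
            lib, ext = ls.generate_study(cfg)
            bin10 = lambda L: L.map_spectra(lambda s: ls.window_average(s, 10.0))
            lib, soy = bin10(lib), bin10(ext["soybean"])
            spike = soy.samples[:20]
            aug = extra_weight(lib, spike)
            cv_plain = ls.cross_validate(lib, "N", "plsr", grid=[6], k=10, seed=seed)
            cv_aug = ls.cross_validate(aug, "N", "plsr", grid=[6], k=10, seed=seed)
            deltas.append(cv_aug.chosen_r2_cv - cv_plain.chosen_r2_cv)
        assert np.mean(deltas) > -0.05


class TestSpikeSweep:
    def test_sweep_accounting_and_bounds(self, demo_study):
        lib, ext = demo_study
        soy = ext["soybean"]
        df = spike_size_sweep(
            lib, soy, sizes=(5, 10), pool_size=10, traits=("N",), grid=[4], seed=0
        )
        assert sorted(df["size"].unique()) == [5, 10]
        assert (df["n_test"] == len(soy) - 10).all()
        with pytest.raises(ValueError, match="pool"):
            spike_size_sweep(lib, soy, sizes=(60,), pool_size=50, traits=("N",), seed=0)
        with pytest.raises(ValueError):
            spike_size_sweep(lib, soy, sizes=(10,), pool_size=len(soy), traits=("N",), seed=0)

    def test_size_equal_to_pool_uses_whole_pool(self, demo_study):
        lib, ext = demo_study
        soy = ext["soybean"]
        a = spike_size_sweep(lib, soy, sizes=(10,), pool_size=10, traits=("N",), grid=[4], seed=8)
        b = spike_size_sweep(lib, soy, sizes=(10,), pool_size=10, traits=("N",), grid=[4], seed=8)
        assert a["r2"].iloc[0] == pytest.approx(b["r2"].iloc[0], abs=1e-12)

    def test_missing_trait_rows_are_null_not_zero(self, demo_study):
        lib, ext = demo_study
        cam = ext["camelina"]
        df = spike_size_sweep(
            lib, cam, sizes=(5,), pool_size=10, traits=("CHL",), grid=[4], seed=0
        )
        assert df["r2"].isna().all()
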