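import json

import numpy as np
import pytest
import yaml

from _synth import analytic_auc, delta_for_auc, gaussian_outputs
from marbench.config import ConfigError, PRESETS, load_config
from marbench.study import (
    AntlerFit,
    StudyCondition,
    antler,
    auc_holdout,
    auc_resubstitution,
    extrapolate,
    run_study,
)


# --- conditions -----------------------------------------------------------


def test_study_condition_validation():
    with pytest.raises(ValueError, match="amplitude"):
        StudyCondition(signal_amplitude=1.2, dose=1e6)
    with pytest.raises(ValueError, match="50"):
        StudyCondition(signal_amplitude=1.03, dose=1e6, n_images_per_class=10)
    with pytest.raises(ValueError, match="method"):
        StudyCondition(signal_amplitude=1.03, dose=1e6, method="sart")


# --- ensemble determinism -------------------------------------------------


def test_roi_ensembles_bit_identical_for_same_seed(desk_pipeline):
    a = desk_pipeline.simulate_rois(1.03, 8e6, ["fbp"], 3, master_seed=5)
    b = desk_pipeline.simulate_rois(1.03, 8e6, ["fbp"], 3, master_seed=5)
    np.testing.assert_array_equal(a["fbp"][0], b["fbp"][0])
    np.testing.assert_array_equal(a["fbp"][1], b["fbp"][1])
    c = desk_pipeline.simulate_rois(1.03, 8e6, ["fbp"], 3, master_seed=6)
    assert not np.array_equal(a["fbp"][0], c["fbp"][0])


def test_paired_classes_share_background(desk_pipeline):
    """In paired-seed mode the class maps differ only inside the signal
    disk (plus its suppressed lump tails)."""
    from dataclasses import replace

    from marbench.phantom import build_phantom, pixel_grid, rasterize
    from marbench.study import ImagingPipeline

    pipe = desk_pipeline
    rng_a = pipe._image_rng(3, 0, 0)
    paired = ImagingPipeline.__new__(ImagingPipeline)
    paired.__dict__.update(pipe.__dict__)
    paired.settings = replace(pipe.settings, paired_classes=True)
    r0 = paired._image_rng(3, 0, 0)
    r1 = paired._image_rng(3, 1, 0)
    a0, a1 = r0.uniform(0, 2 * np.pi), r1.uniform(0, 2 * np.pi)
    assert a0 == a1  # same acquisition randomness for both classes
    m_abs = rasterize(build_phantom(a0, False, 1.0, lump_field=pipe.lump_field), 257, 26.0)
    m_pre = rasterize(build_phantom(a1, True, 1.04, lump_field=pipe.lump_field), 257, 26.0)
    x, y = pixel_grid(257, 26.0)
    outside = x**2 + y**2 > (0.5 + 26.0 / 257) ** 2
    assert np.all(m_abs["water"][outside] == m_pre["water"][outside])


# --- finite-sample estimators --------------------------------------------


@pytest.fixture(scope="module")
def gaussian_ensemble():
    """Synthetic channel outputs with analytic AUC 0.80, N=1000/class."""
    rng = np.random.default_rng(12)
    delta = delta_for_auc(0.80, 10)
    return gaussian_outputs(rng, 1000, delta)


def test_resubstitution_with_full_set_ignores_seed(gaussian_ensemble):
    a = auc_resubstitution(gaussian_ensemble, 1000, seed=1)
    b = auc_resubstitution(gaussian_ensemble, 1000, seed=99)
    assert a.auc == b.auc


def test_resubstitution_positively_biased(gaussian_ensemble):
    aucs = [auc_resubstitution(gaussian_ensemble, 50, seed=s).auc for s in range(200)]
    assert np.mean(aucs) > 0.80


def test_holdout_negatively_biased(gaussian_ensemble):
    aucs = [auc_holdout(gaussian_ensemble, 50, seed=s).auc for s in range(200)]
    assert np.mean(aucs) < 0.80


def test_null_case_resubstitution_exceeds_chance():
    rng = np.random.default_rng(13)
    out = gaussian_outputs(rng, 400, np.zeros(10))
    aucs = [auc_resubstitution(out, 40, seed=s).auc for s in range(100)]
    assert np.mean(aucs) > 0.5


def test_holdout_determinism_and_boundaries(gaussian_ensemble):
    a = auc_holdout(gaussian_ensemble, 100, seed=3)
    b = auc_holdout(gaussian_ensemble, 100, seed=3)
    assert a.auc == b.auc and a.n_test == 900
    # NT = N - 1 leaves a single test image per class: legal but extreme
    with pytest.raises(ValueError):
        auc_holdout(gaussian_ensemble, 1000, seed=0)
    with pytest.raises(ValueError):
        auc_resubstitution(gaussian_ensemble, 2000, seed=0)


# --- antler + extrapolation ----------------------------------------------


def test_antler_grid_and_bias_ordering(gaussian_ensemble):
    fit = antler(gaussian_ensemble, NT_values=(25, 50, 100, 200, 500, 1000),
                 repetitions=50, seed=0)
    # 1000 is trimmed (hold-out needs a nonempty test set)
    assert fit.NT_values == (25, 50, 100, 200, 500)
    assert fit.repetitions == 50
    assert np.all(fit.resub_mean >= fit.holdout_mean)
    frame = fit.as_frame()
    assert set(frame["arm"]) == {"resubstitution", "holdout"}


def test_extrapolation_flat_arms():
    nts = (25, 50, 100)
    fit = AntlerFit(nts, resub=np.full((3, 10), 0.9), holdout=np.full((3, 10), 0.9),
                    repetitions=10)
    ext = extrapolate(fit)
    assert ext.auc_inf == pytest.approx(0.9)
    assert ext.eps_b == pytest.approx(0.0, abs=1e-12)


def test_extrapolation_intercept_arithmetic():
    nts = np.array([25, 50, 100])
    inv = 1.0 / nts
    resub = (0.92 - 0.5 * inv)[:, None] * np.ones((3, 8))
    hold = (0.90 + 0.3 * inv)[:, None] * np.ones((3, 8))
    ext = extrapolate(AntlerFit(tuple(nts), resub, hold, repetitions=8))
    assert ext.auc_inf_resub == pytest.approx(0.92)
    assert ext.auc_inf_holdout == pytest.approx(0.90)
    assert ext.auc_inf == pytest.approx(0.91)
    assert ext.eps_b == pytest.approx(0.01)
    assert ext.eps == pytest.approx(np.hypot(ext.eps_b, ext.eps_v))


def test_extrapolation_recovers_known_auc():
    rng = np.random.default_rng(14)
    delta = delta_for_auc(0.85, 10)
    n = 1000
    out = gaussian_outputs(rng, n, delta)
    fit = antler(out, NT_values=(25, 50, 100, 200, 500), repetitions=50, seed=0)
    ext = extrapolate(fit)
    # eps omits ensemble-level variance; allow the binomial bound on it
    tol = 3 * np.hypot(ext.eps, np.sqrt(0.85 * 0.15 / n))
    assert abs(ext.auc_inf - 0.85) < tol


def test_bias_gap_shrinks_with_ensemble_size():
    rng = np.random.default_rng(15)
    delta = delta_for_auc(0.85, 10)
    gaps = []
    for n in (250, 1000):
        out = gaussian_outputs(rng, n, delta)
        fit = antler(out, NT_values=(25, 50, 100, 200), repetitions=50, seed=0)
        ext = extrapolate(fit)
        gaps.append(abs(ext.auc_inf_resub - ext.auc_inf_holdout))
    assert gaps[1] < gaps[0]


def test_degenerate_antler_rejected(gaussian_ensemble):
    with pytest.raises(ValueError, match="at least 3"):
        antler(gaussian_ensemble, NT_values=(25, 50), repetitions=5, seed=0)
    fit = AntlerFit((50, 50, 50), np.full((3, 5), 0.9), np.full((3, 5), 0.9), 5)
    with pytest.raises(ValueError, match="degenerate"):
        extrapolate(fit)


# --- config + full run ----------------------------------------------------


def _smoke_config(tmp_path, **study_overrides):
    study = dict(
        dose=8.0e6,
        amplitude_sweep=[1.03],
        dose_sweep=[8.0e6],
        methods=["fbp"],
        n_images_per_class=50,
        nt_values=[25, 30, 40],
        repetitions=4,
        master_seed=0,
    )
    study.update(study_overrides)
    cfg = {
        "preset": "desk",
        "settings": {"image_size": 64, "grid_size": 129, "roi_side": 31},
        "study": study,
    }
    path = tmp_path / "study.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


def test_config_unknown_keys_named(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump({
        "preset": "desk",
        "settings": {"image_size": 64, "bogus_knob": 1},
        "study": {"dose": 1e6},
    }))
    with pytest.raises(ConfigError, match="bogus_knob"):
        load_config(path)


def test_config_missing_dose_named(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump({"preset": "desk", "study": {"repetitions": 5}}))
    with pytest.raises(ConfigError, match="dose"):
        load_config(path)


def test_full_scale_preset_defaults():
    full = PRESETS["full"]
    assert (full.image_size, full.roi_side) == (512, 121)
    assert (full.n_views, full.n_bins) == (720, 729)


def test_run_study_smoke_and_rerun_identical(tmp_path):
    """A minimal end-to-end study completes and is bit-reproducible."""
    cfg = _smoke_config(tmp_path)
    out1 = run_study(cfg, tmp_path / "r1", progress=False)
    out2 = run_study(cfg, tmp_path / "r2", progress=False)
    for name in ("detectability_amplitude.csv", "detectability_dose.csv"):
        assert (out1 / name).exists()
        assert (out1 / name).read_text() == (out2 / name).read_text()
    manifest = json.loads((out1 / "manifest.json").read_text())
    assert "thresholds" in manifest and "settings" in manifest
    assert (out1 / "detectability_amplitude.png").exists()
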