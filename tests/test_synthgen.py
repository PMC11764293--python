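"""Generator checks: HRF shape, seed determinism, label balance, noise-free
templates, separability floor, and the between/within subject distance
behaviour of the domain-shift levels."""

import numpy as np
import pytest

from fnirsda import preprocess as pp
from fnirsda import synthgen as sg


class TestDoubleGammaHrf:
    def test_zero_amplitude_gives_zero_curve(self):
        t = np.linspace(0, 30, 301)
        h = sg.double_gamma_hrf(t, sg.HrfParams(amplitude=0.0))
        assert np.all(h == 0.0)

    def test_peak_location_matches_dense_grid_search(self):
        p = sg.HrfParams()
        t = np.arange(0, 30, 0.1)
        h = sg.double_gamma_hrf(t, p)
        assert h[0] == pytest.approx(0.0, abs=1e-12)
        assert abs(t[np.argmax(h)] - p.peak_time) <= 0.1 + 1e-9

    def test_linearity_in_amplitude(self):
        t = np.arange(0, 30, 0.5)
        h1 = sg.double_gamma_hrf(t, sg.HrfParams(amplitude=1.0))
        h2 = sg.double_gamma_hrf(t, sg.HrfParams(amplitude=2.0))
        assert np.allclose(h2, 2 * h1, rtol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sg.HrfParams(peak_time=20.0, undershoot_time=6.0)


class TestDeterminism:
    def test_same_seed_identical_datasets(self):
        cfg = sg.GeneratorConfig(n_subjects=2, trials_per_class=3, seed=9)
        d1 = sg.make_dataset(cfg, shift_level="strong")
        d2 = sg.make_dataset(cfg, shift_level="strong")
        assert len(d1.trials) == len(d2.trials)
        for a, b in zip(d1.trials, d2.trials):
            assert np.array_equal(a.data, b.data)
            assert a.class_label == b.class_label

    def test_different_seed_differs(self):
        c1 = sg.GeneratorConfig(n_subjects=1, trials_per_class=2, seed=1)
        c2 = sg.GeneratorConfig(n_subjects=1, trials_per_class=2, seed=2)
        d1, d2 = sg.make_dataset(c1), sg.make_dataset(c2)
        assert not np.array_equal(d1.trials[0].data, d2.trials[0].data)


class TestStructure:
    def test_trial_count(self):
        cfg = sg.GeneratorConfig(n_subjects=2, trials_per_class=3, seed=0)
        ds = sg.make_dataset(cfg)
        assert len(ds.trials) == 2 * 3 * 3

    def test_label_balance_per_subject(self, small_dataset):
        cfg = small_dataset.generator_config
        for sid in small_dataset.subject_ids():
            labels = [t.class_label for t in small_dataset.trials if t.subject_id == sid]
            for cls in cfg.classes:
                assert labels.count(cls) == cfg.trials_per_class

    def test_epoch_window_and_channels(self, small_dataset):
        for t in small_dataset.trials:
            assert t.data.shape == (40, 300)
            assert t.fs == 10.0

    def test_shift_none_profiles_identical(self):
        cfg = sg.GeneratorConfig(n_subjects=3, trials_per_class=1, seed=3)
        ds = sg.make_dataset(cfg, shift_level="none")
        p0 = ds.subjects[0]
        for p in ds.subjects[1:]:
            assert np.array_equal(p.gain, p0.gain)
            assert p.latency_shift == p0.latency_shift
            assert p.noise_sd == p0.noise_sd
            for cls in cfg.classes:
                assert np.array_equal(p.topography[cls], p0.topography[cls])


def noise_free_config(**kw):
    return sg.GeneratorConfig(noise_sd=0.0, physio_amp=0.0, drift_sd=0.0, **kw)


class TestNoiseFreeLimit:
    def test_first_trial_equals_template(self):
        # later trials overlap the tail of the previous trial's hemodynamic
        # response, so only the session's first epoch is template-exact
        cfg = noise_free_config(n_subjects=1, trials_per_class=1, seed=11)
        profile = sg.draw_profile("S01", cfg, "none", np.random.default_rng(0))
        hemo, epochs = sg.synthesize_subject(profile, cfg, np.random.default_rng(1))
        first = epochs[0]
        tpl = sg.trial_template(profile, cfg, first.class_label)
        assert np.allclose(first.data, tpl, atol=1e-12)

    def test_nearest_template_classifier_is_perfect(self):
        """Sanity floor: a noise-free dataset is perfectly separable."""
        cfg = noise_free_config(n_subjects=2, trials_per_class=4, seed=21)
        ds = sg.make_dataset(cfg, shift_level="none")
        profile = ds.subjects[0]
        templates = {c: sg.trial_template(profile, cfg, c) for c in cfg.classes}
        correct = 0
        for t in ds.trials:
            dists = {c: np.linalg.norm(t.data - tpl) for c, tpl in templates.items()}
            correct += min(dists, key=dists.get) == t.class_label
        assert correct == len(ds.trials)

    def test_hbr_is_scaled_delayed_hbo(self):
        cfg = noise_free_config(n_subjects=1, trials_per_class=1, seed=2)
        profile = sg.draw_profile("S01", cfg, "none", np.random.default_rng(0))
        hemo, _ = sg.synthesize_subject(profile, cfg, np.random.default_rng(1))
        delay = int(round(cfg.hbr_delay_s * cfg.fs))
        assert np.allclose(hemo.dHbR[:, delay:],
                           cfg.hbr_ratio * hemo.dHbO[:, :-delay], atol=1e-12)


def task_window_features(ds):
    """Per-trial, per-channel task-window means of the *preprocessed* trials.

    The raw epochs carry slow drift and physiological oscillations that the
    band-pass removes; feature statements about subjects and classes are made
    on the pipeline's output, as downstream consumers see it.
    """
    X, y, subjects = sg.dataset_to_arrays(ds)
    task = X[:, :, 0:100]  # 0..10 s after onset in the cropped window
    return task.mean(axis=2), y, subjects


class TestClassContrast:
    def test_active_channels_separate_classes(self):
        """Class-mean difference over active channels exceeds the difference
        over inactive channels (averaged over 25 trials)."""
        cfg = sg.GeneratorConfig(n_subjects=1, trials_per_class=25, seed=33)
        ds = sg.make_dataset(cfg, shift_level="none")
        feats, y, _ = task_window_features(ds)
        topo = sg.default_topography()
        means = {cls: feats[y == i][:, :20].mean(axis=0)
                 for i, cls in enumerate(("left", "right", "feet"))}
        diff = np.abs(means["left"] - means["right"])
        active = np.union1d(np.where(topo["left"] > 0.9)[0],
                            np.where(topo["right"] > 0.9)[0])
        inactive = np.setdiff1d(np.arange(20), np.union1d(
            np.where(topo["left"] > 0.2)[0], np.where(topo["right"] > 0.2)[0]))
        assert diff[active].mean() > diff[inactive].mean()


def subject_feature_distances(ds):
    """Class-conditional between- vs within-subject distances.

    For each class: centroids per subject, the mean pairwise centroid
    distance (between) and the mean trial-to-own-centroid distance (within);
    both averaged over classes.  Conditioning on class keeps task-related
    variation out of the within-subject term.
    """
    feats, y, subs = task_window_features(ds)
    betweens, withins = [], []
    for cls in np.unique(y):
        m = y == cls
        f, s = feats[m], subs[m]
        cents = {sid: f[s == sid].mean(axis=0) for sid in np.unique(s)}
        withins.append(np.mean([np.linalg.norm(f[i] - cents[s[i]])
                                for i in range(len(f))]))
        cl = np.stack(list(cents.values()))
        n = len(cl)
        betweens.append(np.mean([np.linalg.norm(cl[i] - cl[j])
                                 for i in range(n) for j in range(i + 1, n)]))
    return float(np.mean(betweens)), float(np.mean(withins))


class TestShiftLevels:
    def test_shift_none_ratio_small(self):
        ratios = []
        for seed in range(5):
            cfg = sg.GeneratorConfig(n_subjects=4, trials_per_class=8, seed=seed)
            b, w = subject_feature_distances(sg.make_dataset(cfg, "none"))
            ratios.append(b / w)
        assert np.median(ratios) < 1.2

    def test_shift_strong_ratio_large(self):
        ratios = []
        for seed in range(5):
            cfg = sg.GeneratorConfig(n_subjects=4, trials_per_class=8, seed=seed)
            b, w = subject_feature_distances(sg.make_dataset(cfg, "strong"))
            ratios.append(b / w)
        assert np.median(ratios) > 2.0

    def test_unknown_shift_level_rejected(self):
        with pytest.raises(ValueError, match="shift_level"):
            sg.make_dataset(sg.GeneratorConfig(n_subjects=1, trials_per_class=1), "huge")


def test_dataset_to_arrays_runs_full_chain(small_dataset):
    X, y, subjects = sg.dataset_to_arrays(small_dataset)
    assert X.shape == (36, 40, 256)
    assert set(y) == {0, 1, 2}
    assert len(np.unique(subjects)) == 3
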