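"""Generator correctness: curve shapes, cohort structure, phantoms, augmentation."""

import numpy as np
import pytest

from stratify.datatypes import FrameStack, InvalidArgumentError
from stratify.features import detect_landmarks
from stratify.synthetic import (
    AnimalRecord,
    CohortSpec,
    Ellipse,
    GroupSpec,
    KineticParams,
    PhantomLayout,
    augment_records,
    augment_stack,
    default_cohort_spec,
    default_phantom_layout,
    fatpad_param_distribution,
    generate_cohort,
    group_param_distribution,
    render_stack,
    simulate_curve,
)


def flat_distribution(**overrides):
    """A zero-spread parameter distribution for deterministic draws."""
    base = {
        "latency_s": (10.0, 0.0),
        "ttp_s": (5.0, 0.0),
        "peak_amp": (1.0, 0.0),
        "fast_decay_rate": (0.05, 0.0),
        "slow_decay_rate": (0.01, 0.0),
        "retention_frac": (0.4, 0.0),
        "noise_sd": (0.0, 0.0),
        "resp_amp": (0.0, 0.0),
        "resp_freq": (1.0, 0.0),
    }
    base.update(overrides)
    return base


class TestSimulateCurve:
    def test_zero_decay_plateau(self):
        p = KineticParams(
            latency_s=2, ttp_s=3, peak_amp=2.0,
            fast_decay_rate=0.0, slow_decay_rate=0.0, retention_frac=1.0,
        )
        s = simulate_curve(p, 200, 10.0, seed=0)
        after_peak = s.times >= 5.0
        assert np.allclose(s.values[after_peak], 2.0)
        assert np.all(s.values[s.times < 2.0] == 0.0)

    def test_single_exponential_closed_form(self):
        r = 0.1
        p = KineticParams(
            latency_s=2, ttp_s=3, peak_amp=1.5,
            fast_decay_rate=r, slow_decay_rate=0.0, retention_frac=0.0,
        )
        s = simulate_curve(p, 300, 10.0, seed=0)
        dt = s.times - 5.0
        mask = dt > 0
        assert np.allclose(s.values[mask], 1.5 * np.exp(-r * dt[mask]))

    def test_monotone_rise_unique_peak(self):
        p = KineticParams(latency_s=3, ttp_s=4, fast_decay_rate=0.05,
                          slow_decay_rate=0.01, retention_frac=0.3)
        s = simulate_curve(p, 500, 10.0, seed=0)
        rise = s.values[(s.times >= 3) & (s.times <= 7)]
        assert np.all(np.diff(rise) >= 0)
        assert np.argmax(s.values) == 70  # latency + ttp at 10 fps
        assert np.sum(s.values == s.values.max()) == 1

    def test_same_seed_reproducible(self):
        p = KineticParams(latency_s=2, ttp_s=3, noise_sd=0.05, resp_amp=0.03)
        a = simulate_curve(p, 200, 10.0, seed=42)
        b = simulate_curve(p, 200, 10.0, seed=42)
        c = simulate_curve(p, 200, 10.0, seed=43)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize("n_frames,fps", [(0, 10.0), (-5, 10.0), (100, 0.0)])
    def test_invalid_arguments(self, n_frames, fps):
        p = KineticParams(latency_s=1, ttp_s=1)
        with pytest.raises(InvalidArgumentError):
            simulate_curve(p, n_frames, fps)

    def test_peak_beyond_series_end_rejected(self):
        p = KineticParams(latency_s=10, ttp_s=10)
        with pytest.raises(InvalidArgumentError):
            simulate_curve(p, 100, 10.0)  # peak at frame 200

    def test_latency_recovery_monte_carlo(self):
        """The latency detector recovers the generating value (MAE < 0.5 s)."""
        p = KineticParams(
            latency_s=10, ttp_s=5, fast_decay_rate=0.05,
            slow_decay_rate=0.01, retention_frac=0.4, noise_sd=0.01,
        )
        errors = []
        for seed in range(100):
            s = simulate_curve(p, 1000, 10.0, seed=seed)
            lm = detect_landmarks(s)
            errors.append(abs(lm.latency_frame / 10.0 - 10.0))
        assert np.mean(errors) < 0.5


class TestKineticParamsValidation:
    def test_slow_rate_must_not_exceed_fast(self):
        with pytest.raises(InvalidArgumentError):
            KineticParams(latency_s=1, ttp_s=1, fast_decay_rate=0.01,
                          slow_decay_rate=0.05)

    @pytest.mark.parametrize("frac", [-0.1, 1.1])
    def test_retention_fraction_bounds(self, frac):
        with pytest.raises(InvalidArgumentError):
            KineticParams(latency_s=1, ttp_s=1, retention_frac=frac)


class TestGenerateCohort:
    def test_published_cohort_totals(self, default_cohort):
        assert len(default_cohort) == 133
        by_group = {}
        for rec in default_cohort:
            by_group[rec.group] = by_group.get(rec.group, 0) + 1
        assert by_group == {
            "Dll4+": 8, "Dll4-": 17, "CG1": 19, "CG2": 2, "CG3": 26,
            "CG4": 12, "CG5": 28, "CG6": 12, "CG7": 5, "CG8": 4,
        }
        assert all(rec.n_fatpads in (3, 4) for rec in default_cohort)

    def test_zero_spread_single_record_is_deterministic(self):
        spec = CohortSpec(
            groups=(GroupSpec("G", 1, "high", flat_distribution()),),
            fatpad_distribution=flat_distribution(),
            n_fatpads_range=(3, 3),
            n_frames=600,
            fps=10.0,
            seed=5,
        )
        rec = generate_cohort(spec)[0]
        assert rec.params.latency_s == 10.0 and rec.params.ttp_s == 5.0
        rec2 = generate_cohort(spec)[0]
        assert np.array_equal(rec.tumor.values, rec2.tumor.values)

    def test_two_class_ttp_gap_is_realized(self):
        """A planted 3 s TTP gap is realized within its standard-error bound."""
        spec = CohortSpec(
            groups=(
                GroupSpec("hi", 30, "high", flat_distribution(ttp_s=(8.0, 0.5))),
                GroupSpec("lo", 30, "low", flat_distribution(ttp_s=(5.0, 0.5))),
            ),
            fatpad_distribution=fatpad_param_distribution(),
            n_frames=600,
            fps=10.0,
            seed=1,
        )
        recs = generate_cohort(spec)
        hi = [r.params.ttp_s for r in recs if r.group == "hi"]
        lo = [r.params.ttp_s for r in recs if r.group == "lo"]
        assert abs((np.mean(hi) - np.mean(lo)) - 3.0) < 0.6

    def test_seed_reproducibility(self):
        spec = default_cohort_spec(seed=3, n_frames=400)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert all(
            np.array_equal(x.tumor.values, y.tumor.values) for x, y in zip(a, b)
        )


def _tiny_record(n_frames=200, fps=10.0, n_fatpads=3, noise=0.0):
    tumor_p = KineticParams(latency_s=3, ttp_s=3, fast_decay_rate=0.05,
                            slow_decay_rate=0.01, retention_frac=0.4, noise_sd=noise)
    fp_p = KineticParams(latency_s=2.5, ttp_s=2, peak_amp=0.6,
                         fast_decay_rate=0.08, slow_decay_rate=0.01,
                         retention_frac=0.25, noise_sd=noise)
    return AnimalRecord(
        animal_id="t0",
        group="G",
        dll4_label="high",
        tumor=simulate_curve(tumor_p, n_frames, fps, 0),
        fatpads=[simulate_curve(fp_p, n_frames, fps, i) for i in range(n_fatpads)],
        params=tumor_p,
    )


class TestRenderStack:
    def test_background_only_before_injection(self):
        rec = _tiny_record()
        layout = default_phantom_layout(48, 48, n_fatpads=3, seed=0)
        stack = render_stack(rec, layout, 48, 48, n_background_frames=20, seed=0)
        assert stack.n_frames == 20 + rec.tumor.n
        assert np.allclose(stack.data[:20], layout.background_level)

    def test_mask_mean_recovers_curve_exactly(self):
        rec = _tiny_record()
        layout = default_phantom_layout(48, 48, n_fatpads=3, seed=1)
        stack = render_stack(rec, layout, 48, 48, n_background_frames=10, seed=0)
        mask = layout.tumor.mask(48, 48)
        series = stack.data[10:, mask].mean(axis=1)
        assert np.allclose(series, rec.tumor.values + layout.background_level)

    def test_energy_conservation_per_ellipse(self):
        """Noise-free rendering preserves |mask|*(curve + background) per frame."""
        rec = _tiny_record()
        layout = default_phantom_layout(48, 48, n_fatpads=3, seed=2)
        stack = render_stack(rec, layout, 48, 48, n_background_frames=0, seed=0)
        for ell, series in [(layout.tumor, rec.tumor)] + list(
            zip(layout.fatpads, rec.fatpads)
        ):
            mask = ell.mask(48, 48)
            total = stack.data[:, mask].sum(axis=1)
            expected = mask.sum() * (series.values + layout.background_level)
            assert np.allclose(total, expected)

    def test_overlapping_tumor_fatpad_rejected(self):
        ell = Ellipse(20, 20, 5, 5)
        layout = PhantomLayout(
            tumor=ell,
            fatpads=(Ellipse(22, 22, 4, 4), Ellipse(40, 10, 3, 3), Ellipse(40, 40, 3, 3)),
            liver=Ellipse(8, 24, 4, 8),
        )
        with pytest.raises(InvalidArgumentError):
            layout.validate(48, 48)

    def test_fatpad_count_mismatch_rejected(self):
        rec = _tiny_record(n_fatpads=3)
        layout = default_phantom_layout(48, 48, n_fatpads=4, seed=3)
        with pytest.raises(InvalidArgumentError):
            render_stack(rec, layout, 48, 48)


class TestAugmentation:
    def _stack(self):
        rng = np.random.default_rng(0)
        return FrameStack(rng.uniform(0, 1, (5, 32, 32)), fps=10.0)

    def test_degenerate_transform_is_identity(self):
        stack = self._stack()
        out = augment_stack(stack, seed=0, max_rescale=0.0, rotation_range_deg=0.0)
        assert np.array_equal(out.data, stack.data)

    def test_hflip_is_an_involution(self):
        stack = self._stack()
        once = augment_stack(stack, seed=0, max_rescale=0.0,
                             rotation_range_deg=0.0, hflip=True)
        twice = augment_stack(once, seed=0, max_rescale=0.0,
                              rotation_range_deg=0.0, hflip=True)
        assert np.array_equal(twice.data, stack.data)
        assert not np.array_equal(once.data, stack.data)

    def test_shape_preserved_and_seeded(self):
        stack = self._stack()
        a = augment_stack(stack, seed=7)
        b = augment_stack(stack, seed=7)
        c = augment_stack(stack, seed=8)
        assert a.data.shape == stack.data.shape
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_negative_rescale_rejected(self):
        with pytest.raises(InvalidArgumentError):
            augment_stack(self._stack(), seed=0, max_rescale=-0.1)

    def test_augmented_cohort_reaches_606_points(self):
        """68 base records augmented k times and truncated give 606 points."""
        base = [_tiny_record() for _ in range(68)]
        out = augment_records(base, 606, seed=0)
        assert len(out) == 606
        # base records come first, untouched
        assert out[0] is base[0]


class TestClassSeparationMonotonicity:
    def test_auc_non_decreasing_in_effect_scale(self):
        """Separability grows with the configured between-class gap."""
        from sklearn.model_selection import cross_val_predict
        from sklearn.metrics import roc_auc_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        from stratify.features import cohort_feature_table

        def mean_auc(scale, n_reps=20):
            aucs = []
            for rep in range(n_reps):
                spec = CohortSpec(
                    groups=(
                        GroupSpec("hi", 12, "high",
                                  group_param_distribution(1.0, scale)),
                        GroupSpec("lo", 12, "low",
                                  group_param_distribution(-1.0, scale)),
                    ),
                    fatpad_distribution=fatpad_param_distribution(),
                    n_frames=1200,
                    fps=10.6,
                    seed=1000 * rep + int(scale * 100),
                )
                table = cohort_feature_table(generate_cohort(spec))
                X = table.iloc[:, 3:].fillna(0.0).to_numpy()
                y = (table["group"] == "hi").astype(int).to_numpy()
                clf = make_pipeline(StandardScaler(), SVC(kernel="linear"))
                scores = cross_val_predict(
                    clf, X, y, cv=4, method="decision_function"
                )
                aucs.append(roc_auc_score(y, scores))
            return float(np.mean(aucs))

        aucs = [mean_auc(s) for s in (0.1, 0.4, 1.0)]
        assert aucs[0] <= aucs[1] <= aucs[2]
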