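"""Šidák correction, channel t-tests, mixed models and the cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest

from gaitpe import (
    bca_bootstrap_ci,
    channel_t_tests,
    fit_lmm_gait_index,
    fit_lmm_gmfcs,
    fit_lmm_speed_condition,
    sidak_threshold,
    t_test_frame,
)
from gaitpe.channels import CHANNELS

CH = "hip_flexion_extension"


def make_tables(per_subject, n_cycles=4, channel=CH):
    """Build a feature table + subject frame from per-subject parameters.

    ``per_subject`` is a list of dicts with subject-level metadata and a
    callable or constant ``pe`` giving per-cycle entropy values.
    """
    rows_t, rows_s = [], []
    for spec in per_subject:
        sid = spec["subject_id"]
        rows_s.append({k: v for k, v in spec.items() if k != "pe"})
        pe = spec["pe"]
        for c in range(n_cycles):
            val = pe(c) if callable(pe) else pe
            rows_t.append(
                {"subject_id": sid, "cycle_id": f"c{c}", "channel": channel, "pe": val}
            )
    return pd.DataFrame(rows_t), pd.DataFrame(rows_s)


def simulate_gmfcs(betas, n_per_level, n_cycles, subj_sd, resid_sd, seed):
    """Direct response simulation for the stage model: y = b0 + beta + u + e."""
    rng = np.random.default_rng(seed)
    levels = ("none", "I", "II", "III", "IV")
    spec = []
    sid = 0
    for lv, n in zip(levels, n_per_level):
        for _ in range(n):
            sid += 1
            u = rng.normal(0, subj_sd)
            mu = 0.5 + betas[levels.index(lv)] + u
            spec.append(
                {
                    "subject_id": f"s{sid:03d}",
                    "condition": "control" if lv == "none" else "cp",
                    "gmfcs": lv,
                    "normalized_speed": 1.5,
                    "gdi": 90.0,
                    "gps": 6.0,
                    "pe": (lambda mu=mu: lambda c: mu + rng.normal(0, resid_sd))(),
                }
            )
    return make_tables(spec, n_cycles=n_cycles)


class TestSidak:
    def test_printed_family_threshold(self):
        assert sidak_threshold(0.01, 15) == pytest.approx(6.70e-4, rel=5e-3)

    def test_single_test_is_family_alpha(self):
        assert sidak_threshold(0.037, 1) == pytest.approx(0.037, abs=1e-15)

    def test_closed_form_at_five_percent(self):
        assert sidak_threshold(0.05, 15) == pytest.approx(
            1 - 0.95 ** (1 / 15), abs=1e-15
        )

    def test_monotone_in_alpha_and_m(self):
        alphas = np.linspace(0.001, 0.2, 10)
        vals = [sidak_threshold(a, 15) for a in alphas]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        ms = range(1, 30)
        vals = [sidak_threshold(0.01, m) for m in ms]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("alpha, m", [(0.0, 5), (1.0, 5), (0.05, 0)])
    def test_out_of_range_rejected(self, alpha, m):
        with pytest.raises(ValueError):
            sidak_threshold(alpha, m)


class TestChannelTTests:
    def test_identical_groups_give_t_zero_p_one(self):
        spec = []
        for i, val in enumerate((0.3, 0.4, 0.5)):
            spec.append(
                {"subject_id": f"c{i}", "condition": "control", "gmfcs": "none", "pe": val}
            )
            spec.append(
                {"subject_id": f"p{i}", "condition": "cp", "gmfcs": "II", "pe": val}
            )
        table, subj = make_tables(spec)
        (res,) = channel_t_tests(table, subj)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        assert not res.significant

    def test_strong_synthetic_effect_flags_all_channels(self, strong_pe_table, strong_cohort):
        results = channel_t_tests(strong_pe_table, strong_cohort)
        assert len(results) == 15
        assert all(r.significant for r in results)
        assert all(r.mean_cp > r.mean_control for r in results)

    def test_invariant_to_row_order(self, small_cohort):
        from gaitpe import pe_feature_table

        table = pe_feature_table(small_cohort)
        shuffled = table.sample(frac=1.0, random_state=3)
        a = t_test_frame(channel_t_tests(table, small_cohort))
        b = t_test_frame(channel_t_tests(shuffled, small_cohort))
        pd.testing.assert_frame_equal(a, b)

    def test_group_with_single_unit_rejected(self):
        spec = [
            {"subject_id": "c1", "condition": "control", "gmfcs": "none", "pe": 0.3},
            {"subject_id": "p1", "condition": "cp", "gmfcs": "II", "pe": 0.5},
            {"subject_id": "p2", "condition": "cp", "gmfcs": "II", "pe": 0.6},
        ]
        table, subj = make_tables(spec)
        with pytest.raises(ValueError, match="2 units"):
            channel_t_tests(table, subj)

    def test_familywise_error_under_label_permutation(self, strong_pe_table, strong_cohort):
        # permuting condition labels breaks any real association; the
        # Sidak-corrected family should then fire in about 1% of permutations
        from gaitpe import subject_mean_pe

        means = subject_mean_pe(strong_pe_table)
        subj = strong_cohort.subject_frame().set_index("subject_id")
        labels = subj.loc[means.index, "condition"].to_numpy()
        alpha = sidak_threshold(0.01, 15)
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        X = means.to_numpy()
        hits = 0
        n_perm = 100
        for _ in range(n_perm):
            lab = rng.permutation(labels)
            cp, ctrl = X[lab == "cp"], X[lab == "control"]
            p = sps.ttest_ind(cp, ctrl, equal_var=False).pvalue
            hits += bool((p < alpha).any())
        assert hits / n_perm <= 0.01 + 0.025


class TestBCaBootstrap:
    def test_close_to_percentile_for_symmetric_mean(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(40)], "y": rng.normal(size=40)}
        )

        def stat(d):
            return np.array([d["y"].mean()])

        ci = bca_bootstrap_ci(stat, data, n_replicates=2000, rng=3)[0]
        boot_rng = np.random.default_rng(3)
        reps = [
            data["y"]
            .to_numpy()[boot_rng.choice(40, 40, replace=True)]
            .mean()
            for _ in range(2000)
        ]
        perc = np.quantile(reps, [0.025, 0.975])
        width = perc[1] - perc[0]
        assert abs((ci[1] - ci[0]) - width) < 0.1 * width

    def test_identical_data_gives_zero_width_interval(self):
        data = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(12)], "y": 5.0}
        )
        ci = bca_bootstrap_ci(
            lambda d: np.array([d["y"].mean()]), data, n_replicates=50, rng=0
        )
        assert ci[0].tolist() == [5.0, 5.0]

    def test_too_few_subjects_rejected(self):
        data = pd.DataFrame({"subject_id": list("abcde"), "y": range(5)})
        with pytest.raises(ValueError, match="10 subjects"):
            bca_bootstrap_ci(lambda d: np.array([0.0]), data, n_replicates=10)

    def test_subjects_resampled_as_whole_clusters(self):
        # every replicate must consist of complete subjects: the multiset
        # of cycles under each resampled id matches one original subject
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{i}" for i in range(12)], 3),
                "y": rng.normal(size=36),
            }
        )
        originals = {
            sid: tuple(sorted(grp["y"])) for sid, grp in data.groupby("subject_id")
        }
        seen = []

        def stat(d):
            for sid, grp in d.groupby("subject_id"):
                seen.append(tuple(sorted(grp["y"])))
            return np.array([d["y"].mean()])

        bca_bootstrap_ci(stat, data, n_replicates=10, rng=1)
        assert seen and all(block in originals.values() for block in seen)

    def test_excess_failures_raise(self):
        data = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(12)], "y": np.arange(12.0)}
        )
        calls = {"n": 0}

        def flaky(d):
            calls["n"] += 1
            if calls["n"] > 1:  # every bootstrap replicate fails
                raise ValueError("no convergence")
            return np.array([d["y"].mean()])

        with pytest.raises(RuntimeError, match="failed to converge"):
            bca_bootstrap_ci(flaky, data, n_replicates=20, rng=0)


class TestGmfcsModel:
    def test_recovers_known_stage_effects(self):
        table, subj = simulate_gmfcs(
            [0.0, 0.02, 0.05, 0.08, 0.12], (27, 5, 19, 23, 6), 7, 0.01, 0.02, 42
        )
        fit = fit_lmm_gmfcs(table, subj, n_replicates=0)[CH]
        truth = {"gmfcs_I": 0.02, "gmfcs_II": 0.05, "gmfcs_III": 0.08, "gmfcs_IV": 0.12}
        for name, expected in truth.items():
            assert fit.fixed_effects[name].beta == pytest.approx(expected, abs=0.02)
        assert fit.fixed_effects["intercept"].beta == pytest.approx(0.5, abs=0.02)

    def test_noiseless_data_reproduces_group_mean_differences(self):
        table, subj = simulate_gmfcs(
            [0.0, 0.02, 0.05, 0.08, 0.12], (5, 3, 3, 3, 3), 3, 0.0, 0.0, 1
        )
        fit = fit_lmm_gmfcs(table, subj, n_replicates=0)[CH]
        assert fit.fixed_effects["gmfcs_III"].beta == pytest.approx(0.08, abs=1e-6)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-8)

    def test_single_subject_level_rejected(self):
        table, subj = simulate_gmfcs([0.0] * 5, (5, 1, 3, 3, 3), 3, 0.01, 0.02, 2)
        with pytest.raises(ValueError, match="'I'"):
            fit_lmm_gmfcs(table, subj, n_replicates=0)


class TestSpeedConditionModel:
    def test_recovers_speed_slope_within_ci(self):
        rng = np.random.default_rng(4)
        spec = []
        for i in range(60):
            cond = "cp" if i >= 30 else "control"
            speed = rng.uniform(0.8, 2.6)
            u = rng.normal(0, 0.01)
            spec.append(
                {
                    "subject_id": f"s{i:02d}",
                    "condition": cond,
                    "gmfcs": "II" if cond == "cp" else "none",
                    "normalized_speed": speed,
                    "gdi": 90.0,
                    "gps": 6.0,
                    "pe": (
                        lambda s=speed, u=u: lambda c: 0.8
                        - 0.1 * s
                        + u
                        + rng.normal(0, 0.02)
                    )(),
                }
            )
        table, subj = make_tables(spec, n_cycles=5)
        fit = fit_lmm_speed_condition(table, subj, n_replicates=200, seed=5)[CH]
        speed_fe = fit.fixed_effects["speed"]
        assert speed_fe.ci_lo <= -0.1 <= speed_fe.ci_hi
        cond_fe = fit.fixed_effects["condition_cp"]
        assert cond_fe.ci_lo <= 0.0 <= cond_fe.ci_hi

    def test_condition_only_effect_detected_without_interaction(self):
        rng = np.random.default_rng(9)
        spec = []
        for i in range(50):
            cond = "cp" if i >= 25 else "control"
            speed = rng.uniform(1.0, 2.5)
            u = rng.normal(0, 0.01)
            shift = 0.1 if cond == "cp" else 0.0
            spec.append(
                {
                    "subject_id": f"s{i:02d}",
                    "condition": cond,
                    "gmfcs": "II" if cond == "cp" else "none",
                    "normalized_speed": speed,
                    "gdi": 90.0,
                    "gps": 6.0,
                    "pe": (
                        lambda u=u, shift=shift: lambda c: 0.5
                        + shift
                        + u
                        + rng.normal(0, 0.02)
                    )(),
                }
            )
        table, subj = make_tables(spec, n_cycles=4)
        fit = fit_lmm_speed_condition(table, subj, n_replicates=200, seed=6)[CH]
        cond_fe = fit.fixed_effects["condition_cp"]
        assert cond_fe.beta > 0 and cond_fe.ci_lo > 0
        inter = fit.fixed_effects["speed_x_condition"]
        assert inter.ci_lo <= 0.0 <= inter.ci_hi

    def test_cp_speed_coupling_yields_negative_interaction(self):
        # patients who walk slower get extra jitter, so the entropy-speed
        # slope is steeper (more negative) in the cp group
        from gaitpe import pe_feature_table
        from gaitpe.synthetic import SyntheticConfig, generate_cohort

        cfg = SyntheticConfig(
            seed=13, jitter_gain=0.0, speed_jitter_gain=0.6, speed_sd=0.25
        )
        cohort = generate_cohort(cfg)
        table = pe_feature_table(cohort)
        fit = fit_lmm_speed_condition(
            table, cohort, channels=[CH], n_replicates=0
        )[CH]
        assert fit.fixed_effects["speed_x_condition"].beta < 0

    def test_constant_speed_rejected(self):
        table, subj = simulate_gmfcs([0.0] * 5, (5, 2, 2, 2, 2), 3, 0.01, 0.02, 3)
        with pytest.raises(ValueError):
            fit_lmm_speed_condition(table, subj, n_replicates=0)


class TestGaitIndexModel:
    def _cp_tables(self, index_fn, n=15, seed=0, n_cycles=3):
        rng = np.random.default_rng(seed)
        spec = []
        for i in range(n):
            pe = 0.4 + 0.03 * i
            spec.append(
                {
                    "subject_id": f"cp_{i:02d}",
                    "condition": "cp",
                    "gmfcs": "II",
                    "normalized_speed": 1.4,
                    "gdi": index_fn(pe, rng),
                    "gps": 5.0,
                    "map_hip_flexion": 6.0,
                    "pe": pe,
                }
            )
        return make_tables(spec, n_cycles=n_cycles)

    def test_noiseless_linear_index_recovers_slope_exactly(self):
        table, subj = self._cp_tables(lambda pe, rng: 100.0 - 40.0 * pe)
        fit = fit_lmm_gait_index(table, subj, response="gdi", n_replicates=0)[CH]
        assert fit.fixed_effects["pe"].beta == pytest.approx(-40.0, abs=1e-6)

    def test_independent_index_ci_covers_zero_in_most_replications(self):
        # a 95% interval misses occasionally by construction; over ten
        # independent draws at least seven must cover the true zero slope
        covered = 0
        for rep in range(10):
            table, subj = self._cp_tables(
                lambda pe, rng: 90.0 + rng.normal(0, 3.0), n=20, seed=rep
            )
            fit = fit_lmm_gait_index(
                table, subj, response="gdi", n_replicates=100, seed=rep
            )[CH]
            fe = fit.fixed_effects["pe"]
            covered += fe.ci_lo <= 0.0 <= fe.ci_hi
        assert covered >= 7

    def test_severity_structure_gives_negative_gdi_slope(self, strong_pe_table, strong_cohort):
        fit = fit_lmm_gait_index(
            strong_pe_table, strong_cohort, response="gdi",
            channels=[CH], n_replicates=0,
        )[CH]
        assert fit.fixed_effects["pe"].beta < 0

    def test_map_item_uses_paired_channel(self):
        table, subj = self._cp_tables(lambda pe, rng: 90.0)
        fit = fit_lmm_gait_index(
            table, subj, response="map_hip_flexion", n_replicates=0
        )
        assert fit.channel == CH
        assert fit.response == "map_hip_flexion"

    def test_control_only_data_rejected(self):
        spec = [
            {
                "subject_id": f"c{i}",
                "condition": "control",
                "gmfcs": "none",
                "normalized_speed": 2.0,
                "gdi": 95.0,
                "gps": 5.0,
                "pe": 0.3,
            }
            for i in range(5)
        ]
        table, subj = make_tables(spec)
        with pytest.raises(ValueError, match="cp"):
            fit_lmm_gait_index(table, subj, response="gdi", n_replicates=0)
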