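"""Synthetic cohort generator: VAR processes, grouping, outcomes, I/O."""

import numpy as np
import pandas as pd
import pytest

from delaynet.connectivity import (
    antisymmetric_decomposition,
    build_directed_network,
    delayed_correlation,
)
from delaynet.stats import fit_quadratic_model
from delaynet.synthetic import (
    CouplingSpec,
    GroupSpec,
    QuadraticLink,
    attach_quadratic_outcome,
    classify_group,
    companion_spectral_radius,
    design_from_config,
    lag_matrices,
    read_cohort,
    reduced_design_config,
    ring_lattice_couplings,
    simulate_cohort,
    simulate_var_timeseries,
    write_cohort,
)

from oracles import lagged_pearson


class TestVarSimulation:
    def test_null_process_is_deterministic_iid_noise(self):
        ts1 = simulate_var_timeseries(5, 300, (), 1.0, seed=7)
        ts2 = simulate_var_timeseries(5, 300, (), 1.0, seed=7)
        assert ts1.data.shape == (5, 300)
        assert np.array_equal(ts1.data, ts2.data)
        assert not np.array_equal(
            ts1.data, simulate_var_timeseries(5, 300, (), 1.0, seed=8).data
        )

    def test_lagged_coupling_shows_up_at_its_lag(self):
        c = CouplingSpec(source=0, target=1, lag=2, strength=0.9)
        ts = simulate_var_timeseries(2, 500, (c,), 0.1, seed=3)
        r_lag2 = lagged_pearson(ts.data[0], ts.data[1], 2)
        r_lag0 = lagged_pearson(ts.data[0], ts.data[1], 0)
        assert r_lag2 > abs(r_lag0)
        assert r_lag2 > 0.5

    def test_unstable_coupling_rejected_with_spectral_radius(self):
        loop = (
            CouplingSpec(0, 1, 1, 1.2),
            CouplingSpec(1, 0, 1, 1.2),
        )
        with pytest.raises(ValueError, match="spectral radius"):
            simulate_var_timeseries(2, 100, loop, 1.0, seed=0)

    def test_excessive_lag_rejected(self):
        c = CouplingSpec(0, 1, 50, 0.5)
        with pytest.raises(ValueError, match="lag"):
            simulate_var_timeseries(2, 50, (c,), 1.0, seed=0)

    def test_companion_radius_matches_eigen_analysis_var1(self):
        # for a pure VAR(1), the companion matrix is B1 itself
        c = (CouplingSpec(0, 1, 1, 0.4), CouplingSpec(1, 0, 1, 0.5))
        mats = lag_matrices(2, c)
        B = np.array([[0.0, 0.5], [0.4, 0.0]])
        assert companion_spectral_radius(mats, 2) == pytest.approx(
            np.max(np.abs(np.linalg.eigvals(B)))
        )

    def test_null_antisymmetric_weights_centred_on_zero(self):
        """Without couplings, upper-triangle anti-symmetric entries have
        mean 0 (within 3 standard errors over 50 subjects)."""
        means = []
        for seed in range(50):
            ts = simulate_var_timeseries(10, 150, (), 1.0, seed=seed)
            _, K = antisymmetric_decomposition(delayed_correlation(ts, 1).matrix)
            means.append(K[np.triu_indices(10, k=1)].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean()) < 3 * se + 1e-12


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "diagnosis,suvr,expected",
        [
            ("CN", 1.0, "CN_Abeta_neg"),
            ("CN", 1.11, "CN_Abeta_neg"),  # strict inequality at the cut-off
            ("CN", 1.12, "CN_Abeta_pos"),
            ("MCI", 1.05, "excluded"),
            ("MCI", 1.3, "MCI_Abeta_pos"),
            ("AD", 1.11, "excluded"),
            ("AD", 1.4, "AD_Abeta_pos"),
        ],
    )
    def test_cutoff_rule(self, diagnosis, suvr, expected):
        assert classify_group(diagnosis, suvr) == expected

    def test_unknown_diagnosis_rejected(self):
        with pytest.raises(ValueError, match="diagnosis"):
            classify_group("SCD", 1.2)

    def test_nonpositive_suvr_rejected(self):
        with pytest.raises(ValueError, match="SUVR"):
            classify_group("CN", 0.0)


class TestSimulateCohort:
    def test_full_design_group_sizes(self):
        """Design mirroring the published counts gives exactly 81/36/31/18."""
        cfg = reduced_design_config(n_regions=200, n_per_group=(81, 36, 31, 18),
                                    n_timepoints=60)
        cohort = simulate_cohort(design_from_config(cfg, 0), 200, 60, seed=0)
        counts = pd.Series([s.group for s in cohort.subjects]).value_counts()
        assert len(cohort.subjects) == 166
        assert counts["CN_Abeta_neg"] == 81
        assert counts["CN_Abeta_pos"] == 36
        assert counts["MCI_Abeta_pos"] == 31
        assert counts["AD_Abeta_pos"] == 18

    def test_single_group_shapes(self):
        tmpl = ring_lattice_couplings(10, 2, 0.1, 0.2, 1, seed=0)
        g = GroupSpec("CN_Abeta_neg", 3, tmpl, self_coupling=0.1)
        cohort = simulate_cohort([g], 10, 80, seed=5)
        assert len(cohort.subjects) == 3
        assert all(ts.data.shape == (10, 80) for ts in cohort.timeseries.values())

    def test_two_seeds_differ_but_sizes_match(self):
        tmpl = ring_lattice_couplings(8, 2, 0.2, 0.2, 1, seed=0)
        g = GroupSpec("MCI_Abeta_pos", 4, tmpl, self_coupling=0.1)
        c1 = simulate_cohort([g], 8, 60, seed=1)
        c2 = simulate_cohort([g], 8, 60, seed=2)
        assert len(c1.subjects) == len(c2.subjects)
        sid = c1.subject_ids[0]
        assert not np.array_equal(c1.timeseries[sid].data, c2.timeseries[sid].data)

    def test_suvr_consistent_with_group(self):
        cfg = reduced_design_config(n_regions=10, n_per_group=(3, 3, 3, 3),
                                    n_timepoints=50)
        cohort = simulate_cohort(design_from_config(cfg, 2), 10, 50, seed=2)
        for s in cohort.subjects:
            if s.group == "CN_Abeta_neg":
                assert s.global_abeta_suvr <= 1.11
            else:
                assert s.global_abeta_suvr > 1.11
            assert classify_group(s.diagnosis, s.global_abeta_suvr) == s.group

    def test_direction_recovery_majority(self):
        """A strong lag-2 coupling orients the anti-symmetric edge
        correctly in nearly all seeds."""
        c = CouplingSpec(source=1, target=3, lag=2, strength=0.6)
        hits = 0
        for seed in range(30):
            ts = simulate_var_timeseries(5, 500, (c,), 0.2, seed=seed)
            _, K = antisymmetric_decomposition(delayed_correlation(ts, 2).matrix)
            W = build_directed_network(K, 2).weights
            hits += W[1, 3] > 0
        assert hits >= 29


class TestQuadraticOutcome:
    def _tiny_cohort(self, n=4, seed=9):
        tmpl = ring_lattice_couplings(6, 2, 0.0, 0.2, 1, seed=0)
        g = GroupSpec("CN_Abeta_pos", n, tmpl, self_coupling=0.1)
        return simulate_cohort([g], 6, 40, seed=seed)

    def test_exact_arithmetic_square(self):
        cohort = self._tiny_cohort()
        m = {sid: 2.0 for sid in cohort.subject_ids}
        link = QuadraticLink(intercept=0, linear_coef=0, quadratic_coef=1, noise_sd=0)
        out = attach_quadratic_outcome(cohort, m, link, "y", seed=0)
        assert all(v == pytest.approx(4.0) for v in out.outcomes["y"].values())

    def test_exact_arithmetic_linear(self):
        cohort = self._tiny_cohort()
        m = {sid: 3.0 for sid in cohort.subject_ids}
        link = QuadraticLink(intercept=1, linear_coef=-2, quadratic_coef=0, noise_sd=0)
        out = attach_quadratic_outcome(cohort, m, link, "y", seed=0)
        assert all(v == pytest.approx(-5.0) for v in out.outcomes["y"].values())

    def test_missing_measure_value_rejected(self):
        cohort = self._tiny_cohort()
        m = {sid: 1.0 for sid in cohort.subject_ids[:-1]}
        with pytest.raises(ValueError, match="missing measure"):
            attach_quadratic_outcome(cohort, m, QuadraticLink(), "y", seed=0)

    def test_quadratic_coefficient_recovered_by_refit(self):
        """OLS refit covers the generating quadratic coefficient in its
        95% CI for most replicate seeds."""
        cohort = self._tiny_cohort(n=200, seed=3)
        rng = np.random.default_rng(0)
        m = {sid: float(v) for sid, v in zip(cohort.subject_ids, rng.normal(1, 1, 200))}
        link = QuadraticLink(0.5, 1.0, -1.0, noise_sd=0.5)
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            out = attach_quadratic_outcome(cohort, m, link, "y", seed=seed)
            y = np.array([out.outcomes["y"][sid] for sid in out.subject_ids])
            mv = np.array([m[sid] for sid in out.subject_ids])
            fit = fit_quadratic_model(y, mv, include_square=True, measure_name="m")
            lo, hi = fit.coef_ci("m_sq")
            hits += lo <= -1.0 <= hi
        assert hits >= int(0.9 * n_rep)


class TestCohortIO:
    def test_manifest_and_roundtrip(self, tmp_path):
        tmpl = ring_lattice_couplings(6, 2, 0.0, 0.2, 1, seed=0)
        g = GroupSpec("AD_Abeta_pos", 3, tmpl, self_coupling=0.1)
        cohort = simulate_cohort([g], 6, 40, seed=4)
        cohort = attach_quadratic_outcome(
            cohort,
            {sid: 1.0 for sid in cohort.subject_ids},
            QuadraticLink(intercept=2.0),
            "planted_y",
            seed=0,
        )
        manifest = write_cohort(cohort, tmp_path / "c")
        assert len(manifest) == 4  # 3 TSVs + subjects.csv
        back = read_cohort(tmp_path / "c")
        assert back.subject_ids == cohort.subject_ids
        for sid in cohort.subject_ids:
            assert np.array_equal(
                back.timeseries[sid].data, cohort.timeseries[sid].data
            )
        assert back.outcomes["planted_y"] == cohort.outcomes["planted_y"]
        pd.testing.assert_frame_equal(back.metadata_frame(), cohort.metadata_frame())

    def test_unwritable_directory_errors_with_path(self, tmp_path):
        blocker = tmp_path / "blocker"
        blocker.write_text("")  # a plain file where a directory is needed
        tmpl = ring_lattice_couplings(6, 2, 0.0, 0.2, 1, seed=0)
        g = GroupSpec("CN_Abeta_neg", 1, tmpl, self_coupling=0.1)
        cohort = simulate_cohort([g], 6, 40, seed=4)
        with pytest.raises(OSError, match="blocker"):
            write_cohort(cohort, blocker / "sub")

    def test_missing_timeseries_names_subject(self, tmp_path):
        tmpl = ring_lattice_couplings(6, 2, 0.0, 0.2, 1, seed=0)
        g = GroupSpec("CN_Abeta_neg", 2, tmpl, self_coupling=0.1)
        cohort = simulate_cohort([g], 6, 40, seed=4)
        write_cohort(cohort, tmp_path / "c")
        (tmp_path / "c" / "sub-0002_ts.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="sub-0002"):
            read_cohort(tmp_path / "c")


def test_coupling_spec_invariants():
    with pytest.raises(ValueError, match="differ"):
        CouplingSpec(2, 2, 1, 0.5)
    with pytest.raises(ValueError, match="lag"):
        CouplingSpec(0, 1, 0, 0.5)
    with pytest.raises(ValueError, match="noise_sd"):
        QuadraticLink(noise_sd=-1.0)
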