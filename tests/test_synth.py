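"""Tests for the synthetic cohort generator and its closed-form targets."""

import numpy as np
import pandas as pd
import pytest

from ignidyn.errors import ParameterError
from ignidyn.ignition import IgnitionProfile, ignition_profile, detect_events, zscore
from ignidyn.synth import (
    BurdenCoefficients,
    SyntheticSpec,
    clique_metastability_target,
    event_integration_sd_target,
    generate_burden_tables,
    generate_cohort,
    generate_event_raster,
    hrf_kernel,
    raster_to_bold,
)


def big_spec(**kw):
    base = dict(n_regions=100, n_timepoints=8000, event_rate=0.5, noise_sd=0.0)
    base.update(kw)
    return SyntheticSpec(**base)


class TestEventRaster:
    def test_full_recruitment_gives_zero_metastability(self):
        # Beta(a→∞ at mean 1) limit: f ≡ 1, every region active at every event
        spec = SyntheticSpec(n_regions=20, n_timepoints=200, event_rate=0.2,
                             recruit_alpha=1e9, recruit_beta=1e-9, seed=5)
        raster, truth = generate_event_raster(spec)
        assert np.allclose(truth.recruit_fractions, 1.0)
        prof, _ = ignition_profile(raster, window_trs=1)
        active = prof.n_events >= 2
        assert active.all()
        assert np.allclose(prof.node_metastability[active], 0.0)
        assert np.allclose(prof.ignition[active], 1.0)

    def test_recruited_fraction_sd_matches_closed_form(self):
        spec = big_spec(seed=11)
        raster, truth = generate_event_raster(spec)
        assert truth.event_times.size >= 2000
        frac = raster.events[:, truth.event_times].mean(axis=0)
        target = event_integration_sd_target(2, 2, 100)
        # Monte-Carlo error on an sd from ~4000 events is ~1.1%
        assert frac.std() == pytest.approx(target, rel=0.04)

    def test_driver_always_active(self):
        spec = SyntheticSpec(n_regions=10, n_timepoints=300, event_rate=0.2,
                             recruit_alpha=0.2, recruit_beta=5.0, seed=2)
        raster, truth = generate_event_raster(spec)
        for t, d in zip(truth.event_times, truth.drivers):
            assert raster.events[d, t] == 1

    def test_seed_changes_raster_not_distribution(self):
        r1, t1 = generate_event_raster(big_spec(seed=1))
        r2, t2 = generate_event_raster(big_spec(seed=2))
        assert not np.array_equal(r1.events, r2.events)
        # same generative law: recruitment fraction means agree within MC error
        assert np.mean(t1.recruit_fractions) == pytest.approx(
            np.mean(t2.recruit_fractions), abs=4 * 0.2236 * np.sqrt(2 / 4000)
        )

    def test_severity_shrinks_variability_not_mean(self):
        r0, t0 = generate_event_raster(big_spec(seed=3, severity=0.0))
        r1, t1 = generate_event_raster(big_spec(seed=3, severity=0.6))
        assert t1.recruit_fractions.std() < 0.5 * t0.recruit_fractions.std()
        assert np.mean(t1.recruit_fractions) == pytest.approx(0.5, abs=0.01)

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            SyntheticSpec(severity=1.5)
        with pytest.raises(ParameterError):
            SyntheticSpec(recruit_alpha=0.0)
        with pytest.raises(ParameterError):
            SyntheticSpec(n_timepoints=20, event_rate=0.1)  # <10 expected events


class TestClosedForms:
    def test_metastability_target_matches_independent_simulation(self, rng):
        """Size-biased closed form vs a transparent event-loop simulation."""
        n, n_events = 100, 60_000
        f = rng.beta(2, 2, n_events)
        active = rng.random((n_events, n)) < f[:, None]
        frac = active.mean(axis=1)
        sds = [frac[active[:, i]].std() for i in range(n)]
        assert clique_metastability_target(2, 2, n) == pytest.approx(
            float(np.mean(sds)), rel=0.01
        )

    def test_severity_scales_target_down(self, rng):
        t0 = clique_metastability_target(2, 2, 100, severity=0.0)
        t5 = clique_metastability_target(2, 2, 100, severity=0.5)
        assert t5 < t0
        # closed form at severity 0.5 vs the transparent event-loop simulation
        n, n_events = 100, 60_000
        f = 0.5 + 0.5 * (rng.beta(2, 2, n_events) - 0.5)
        active = rng.random((n_events, n)) < f[:, None]
        frac = active.mean(axis=1)
        sds = [frac[active[:, i]].std() for i in range(n)]
        assert t5 == pytest.approx(float(np.mean(sds)), rel=0.01)


class TestBold:
    def test_zero_raster_zero_noise_is_silent(self):
        spec = SyntheticSpec(n_regions=3, n_timepoints=100, event_rate=0.2, noise_sd=0.0, seed=0)
        raster, _ = generate_event_raster(
            SyntheticSpec(n_regions=3, n_timepoints=100, event_rate=0.2, seed=0)
        )
        raster.events[:] = 0
        bold = raster_to_bold(raster, spec)
        assert np.allclose(bold.data, 0.0)

    def test_single_event_peaks_at_kernel_mode(self):
        spec = SyntheticSpec(n_regions=2, n_timepoints=60, event_rate=0.2, noise_sd=0.0, seed=0)
        raster, _ = generate_event_raster(spec)
        raster.events[:] = 0
        raster.events[0, 10] = 1
        bold = raster_to_bold(raster, spec)
        # kernel mode is 6 s = 2 TRs after the event at TR=3
        assert bold.data[0].argmax() == 10 + 2
        assert bold.data[0].max() == pytest.approx(1.0)
        assert np.allclose(bold.data[1], 0.0)

    def test_kernel_mode_is_at_peak_seconds(self):
        h = hrf_kernel(1.0)
        assert h.argmax() == 6
        assert h.min() < 0  # undershoot present

    def test_event_recovery_from_noiseless_bold(self):
        """Planted events are recovered by thresholding the z-scored BOLD."""
        spec = SyntheticSpec(n_regions=30, n_timepoints=400, event_rate=0.05,
                             noise_sd=0.0, seed=7)
        raster, truth = generate_event_raster(spec)
        bold = raster_to_bold(raster, spec)
        detected = detect_events(zscore(bold), theta=0.5).events
        hits = total = 0
        for i in range(spec.n_regions):
            for t in np.flatnonzero(raster.events[i]):
                total += 1
                lo, hi = max(0, t - 1), min(spec.n_timepoints, t + 2)
                hits += detected[i, lo:hi].any()
        assert total > 100
        assert hits / total >= 0.95


class TestBurdenTables:
    def _profiles(self, n_subj=8, n_regions=20):
        ids = [f"R{i:03d}" for i in range(n_regions)]
        return [
            IgnitionProfile(ids, np.full(n_regions, 0.09), np.full(n_regions, 0.09),
                            np.full(n_regions, 10, dtype=int), subject_id=f"S{j:02d}")
            for j in range(n_subj)
        ]

    def test_zero_coefficients_zero_residual(self, rng):
        coef = BurdenCoefficients(beta_abeta=0, beta_tau=0, beta_interaction=0,
                                  residual_sd=0, random_intercept_sd=0.01)
        burdens, meta, truth = generate_burden_tables(self._profiles(), coef, rng=rng)
        for sid, grp in meta.groupby("subject_id"):
            expected = coef.intercept + truth.random_intercepts[sid]
            assert np.allclose(grp["metastability"], expected)

    def test_doubling_residual_inflates_slope_se(self):
        from ignidyn.lme import build_long_table, fit_wholebrain_lme

        ses = []
        for resid in (0.004, 0.008):
            rng = np.random.default_rng(99)
            coef = BurdenCoefficients(residual_sd=resid)
            profs = self._profiles(n_subj=15, n_regions=30)
            groups = {p.subject_id: g for p, g in zip(profs, ["HC", "MCI", "AD"] * 5)}
            burdens, meta, _ = generate_burden_tables(profs, coef, groups=groups, rng=rng)
            labels = pd.Series("CNT", index=pd.Index([f"R{i:03d}" for i in range(30)]))
            res = fit_wholebrain_lme(build_long_table(meta, burdens, labels))
            ses.append(res.fixed.loc["abeta_suvr", "std_error"])
        assert ses[1] > ses[0]

    def test_group_means_order_burden_levels(self, rng):
        profs = self._profiles(n_subj=6)
        groups = {"S00": "HC", "S01": "HC", "S02": "MCI", "S03": "MCI", "S04": "AD", "S05": "AD"}
        burdens, _, _ = generate_burden_tables(profs, BurdenCoefficients(), groups=groups, rng=rng)
        mean_ab = {g: np.mean([burdens[s]["abeta_suvr"].mean() for s in burdens if groups[s] == g])
                   for g in ("HC", "AD")}
        assert mean_ab["AD"] > mean_ab["HC"]


class TestCohort:
    def test_severity_ordering_of_cohort_means(self):
        """HC > MCI > AD mean node-metastability in each of 10 seeded replicates."""
        spec = SyntheticSpec(n_regions=100, n_timepoints=1182, event_rate=0.3)
        for rep in range(10):
            subjects, groups, _ = generate_cohort(spec, seed=rep, sizes={"HC": 5, "MCI": 5, "AD": 5})
            means = {}
            for g in ("HC", "MCI", "AD"):
                vals = [
                    np.nanmean(ignition_profile(r, 1)[0].node_metastability)
                    for s, r in subjects.items() if groups[s] == g
                ]
                means[g] = np.mean(vals)
            assert means["HC"] > means["MCI"] > means["AD"]

    def test_cohort_is_seed_deterministic(self):
        spec = SyntheticSpec(n_regions=10, n_timepoints=120, event_rate=0.2)
        s1, g1, _ = generate_cohort(spec, seed=4, sizes={"HC": 2, "AD": 2})
        s2, g2, _ = generate_cohort(spec, seed=4, sizes={"HC": 2, "AD": 2})
        assert g1 == g2
        for sid in s1:
            assert np.array_equal(s1[sid].events, s2[sid].events)
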