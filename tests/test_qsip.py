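"""Isotope-inference chain: copy allocation, weighted densities, EAF, CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fjordsip import (
    DEFAULT_CONSTANTS,
    bulk_weighted_density,
    call_incorporators,
    eaf_per_replicate,
    estimate_eaf,
    estimate_eaf_table,
    gc_from_density,
    molecular_weights,
    taxon_copies,
    taxon_density_profiles,
    treatment_bulk_density,
    weighted_mean_density,
)
from fjordsip.simulate import labeled_density, unlabeled_density
from conftest import make_gradient, make_matrix
from oracles import naive_eaf_chain


class TestTaxonCopies:
    def test_proportional_split_of_sq(self):
        m = make_matrix(np.array([[30], [70]]), fractions=["F01"])
        rep = make_gradient(densities=[1.68, 1.70], copies=[1000.0, 1.0],
                            sequenced=[True, False])
        table = taxon_copies(m, rep)
        assert list(table["F01"]) == [300.0, 700.0]

    def test_absent_asv_gets_zero_copies(self):
        m = make_matrix(np.array([[10, 0], [10, 20]]))
        rep = make_gradient(densities=[1.68, 1.686], copies=[100.0, 60.0])
        table = taxon_copies(m, rep)
        assert table.loc["ASV1", "F02"] == 0.0

    def test_conservation_column_sums_equal_sq(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 50, size=(12, 10))
        m = make_matrix(counts)
        sq = rng.uniform(10, 1e5, 10)
        rep = make_gradient(copies=list(sq))
        table = taxon_copies(m, rep)
        got = table.sum(axis=0).to_numpy()
        want = np.where(counts.sum(axis=0) > 0, sq, 0.0)
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestWeightedDensity:
    def test_hand_arithmetic(self):
        m = make_matrix(np.array([[1, 3]]))
        rep = make_gradient(densities=[1.68, 1.70], copies=[100.0, 300.0])
        prof = weighted_mean_density(taxon_copies(m, rep), rep)
        assert prof.loc["ASV1", "W"] == pytest.approx(1.695)

    def test_single_occupied_fraction_returns_that_density(self):
        m = make_matrix(np.array([[0, 7], [5, 5]]))
        rep = make_gradient(densities=[1.68, 1.70], copies=[50.0, 50.0])
        prof = weighted_mean_density(taxon_copies(m, rep), rep)
        assert prof.loc["ASV1", "W"] == pytest.approx(1.70)

    def test_all_zero_asv_yields_missing_not_zero(self):
        m = make_matrix(np.array([[0, 0], [5, 5]]))
        rep = make_gradient(densities=[1.68, 1.70], copies=[50.0, 50.0])
        prof = weighted_mean_density(taxon_copies(m, rep), rep)
        assert np.isnan(prof.loc["ASV1", "W"])
        assert prof.loc["ASV1", "total_copies"] == 0.0

    def test_w_within_replicate_density_bounds(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.integers(0, 30, size=(8, 10)))
        rep = make_gradient(copies=list(rng.uniform(1, 1000, 10)))
        prof = weighted_mean_density(taxon_copies(m, rep), rep).dropna()
        assert ((prof["W"] >= rep.densities.min()) & (prof["W"] <= rep.densities.max())).all()


class TestBulkDensity:
    def test_uniform_sq_gives_midpoint(self):
        rep = make_gradient(densities=[1.68, 1.69, 1.70], copies=[10.0, 10.0, 10.0])
        assert bulk_weighted_density(rep) == pytest.approx(1.69)

    def test_dominant_fraction_pulls_mean(self):
        rep = make_gradient(densities=[1.68, 1.69, 1.70], copies=[1e6, 1.0, 1.0])
        assert bulk_weighted_density(rep) == pytest.approx(1.68, abs=1e-4)

    def test_zero_total_copies_errors(self):
        rep = make_gradient(densities=[1.68, 1.69], copies=[0.0, 0.0])
        with pytest.raises(ValueError, match="zero total"):
            bulk_weighted_density(rep)

    def test_treatment_summary_mean_and_sd(self):
        reps = [
            make_gradient(replicate=j, densities=[1.68, 1.70], copies=[1.0, 1.0])
            for j in (1, 2, 3)
        ]
        mean, sd, per = treatment_bulk_density(reps)
        assert mean == pytest.approx(1.69) and sd == pytest.approx(0.0)


class TestGCAndMolecularWeights:
    @pytest.mark.parametrize(
        "w, expected",
        [(1.646057, 0.0), (1.729563, 1.0), (1.6880, 0.50227)],
    )
    def test_gc_from_density(self, w, expected):
        assert gc_from_density(w) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize(
        "g, m_light, m_heavy",
        [(0.0, 307.691, 317.665564), (0.5, 307.939, 317.664200)],
    )
    def test_molecular_weight_arithmetic(self, g, m_light, m_heavy):
        ml, mh = molecular_weights(g)
        assert ml == pytest.approx(m_light, abs=1e-9)
        assert mh == pytest.approx(m_heavy, abs=1e-6)

    def test_heavy_light_gap_near_ten_and_decreasing_in_gc(self):
        gaps = [np.subtract(*molecular_weights(g)[::-1]) for g in (0.0, 0.3, 0.7, 1.0)]
        assert all(9.4 < gap < 10.0 for gap in gaps)
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestEAFPerReplicate:
    def test_no_shift_gives_zero(self):
        assert eaf_per_replicate(1.6880, 1.6880) == 0.0

    def test_fully_labeled_hits_upper_bound(self):
        c = DEFAULT_CONSTANTS
        g = gc_from_density(1.6880)
        m_light, m_heavy = molecular_weights(g)
        w_lab = 1.6880 * m_heavy / m_light
        assert eaf_per_replicate(w_lab, 1.6880) == pytest.approx(
            1.0 - c.nat13c, abs=1e-9
        )

    def test_matches_independent_step_by_step_script(self):
        # scalar arithmetic, no shared code with the pipeline
        w_light, w_lab = 1.6880, 1.6980
        gc = (w_light - 1.646057) / 0.083506
        m_light = 0.496 * gc + 307.691
        m_heavy = -0.4987282 * gc + 9.974564 + m_light
        m_lab = (w_lab / w_light) * m_light
        expected = (m_lab - m_light) / (m_heavy - m_light) * (1 - 0.01111233)
        assert eaf_per_replicate(w_lab, w_light) == pytest.approx(expected, abs=1e-12)

    def test_negative_shifts_not_clamped(self):
        assert eaf_per_replicate(1.6800, 1.6880) < 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        w_light=st.floats(1.67, 1.71),
        shift_a=st.floats(0.0005, 0.02),
        shift_b=st.floats(0.0005, 0.02),
    )
    def test_strictly_monotone_in_labeled_density(self, w_light, shift_a, shift_b):
        lo, hi = sorted([shift_a, shift_b])
        if hi - lo < 1e-6:
            hi = lo + 1e-6
        assert eaf_per_replicate(w_light + hi, w_light) > eaf_per_replicate(
            w_light + lo, w_light
        )


def _profiles(asv, treatment, ws):
    return pd.DataFrame(
        {
            "asv_id": asv,
            "treatment_id": treatment,
            "replicate_id": range(1, len(ws) + 1),
            "W": ws,
            "total_copies": 1.0,
        }
    )


class TestEstimateEAF:
    def test_identical_labeled_and_unlabeled_not_incorporator(self):
        est = estimate_eaf("a", "t", [1.688, 1.688, 1.688], [1.688, 1.688, 1.688], seed=0)
        assert est.median_eaf == 0.0
        assert est.ci_low <= 0.0 <= est.ci_high
        assert not est.is_incorporator

    def test_constant_shift_zero_variance_degenerate_ci(self):
        est = estimate_eaf("a", "t", [1.698] * 3, [1.688] * 3, seed=0)
        assert est.ci_low == est.ci_high == pytest.approx(est.median_eaf)
        assert est.median_eaf > 0 and est.is_incorporator

    def test_seeded_and_reproducible(self):
        args = (["a", "t", [1.697, 1.698, 1.699], [1.6878, 1.688, 1.6882]])
        e1 = estimate_eaf(*args, seed=7)
        e2 = estimate_eaf(*args, seed=7)
        e3 = estimate_eaf(*args, seed=8)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)
        assert (e1.ci_low, e1.ci_high) != (e3.ci_low, e3.ci_high)

    def test_ci_brackets_median_for_nondegenerate_replicates(self):
        est = estimate_eaf("a", "t", [1.6965, 1.698, 1.700], [1.6878, 1.688, 1.6882], seed=1)
        assert est.ci_low <= est.median_eaf <= est.ci_high

    def test_recovers_true_eaf_across_seeded_runs(self):
        """Known 0.20 labeling, 3+3 replicates: within 0.05 in >= 90% of runs."""
        gc = 0.5
        w_light = unlabeled_density(gc)
        w_lab = labeled_density(gc, 0.2)
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            lab = w_lab + rng.normal(0, 0.001, 3)
            unl = w_light + rng.normal(0, 0.001, 3)
            est = estimate_eaf("a", "t", lab, unl, n_boot=200, seed=rng)
            hits += abs(est.median_eaf - 0.2) <= 0.05
        assert hits >= 90

    def test_eaf_invariant_under_sq_rescaling(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 40, size=(6, 10))
        sq = rng.uniform(100, 1e4, 10)
        labs, labs_scaled = [], []
        for scale, out in ((1.0, labs), (37.5, labs_scaled)):
            for j in (1, 2, 3):
                m = make_matrix(counts, replicate=j)
                rep = make_gradient(replicate=j, copies=list(sq * scale))
                out.append(weighted_mean_density(taxon_copies(m, rep), rep)["W"])
        for a, b in zip(labs, labs_scaled):
            pd.testing.assert_series_equal(a, b)

    def test_missing_from_unlabeled_excluded_with_reason(self, caplog):
        lab = _profiles(["x", "y"], "t", [1.698, 1.698])
        unl = _profiles(["x"], "t", [1.688])
        with caplog.at_level("INFO", logger="fjordsip"):
            ests = estimate_eaf_table(lab, unl, "t", n_boot=50, seed=0)
        assert [e.asv_id for e in ests] == ["x"]
        assert any("absent from all unlabeled" in r.message for r in caplog.records)

    def test_table_estimates_independent_of_row_order(self):
        lab = pd.concat([_profiles("b", "t", [1.697, 1.698]), _profiles("a", "t", [1.699, 1.700])])
        unl = pd.concat([_profiles("b", "t", [1.688, 1.6882]), _profiles("a", "t", [1.688, 1.6881])])
        e1 = estimate_eaf_table(lab, unl, "t", n_boot=100, seed=5)
        e2 = estimate_eaf_table(
            lab.iloc[::-1].reset_index(drop=True),
            unl.iloc[::-1].reset_index(drop=True),
            "t", n_boot=100, seed=5,
        )
        assert [(e.asv_id, e.ci_low, e.ci_high) for e in e1] == [
            (e.asv_id, e.ci_low, e.ci_high) for e in e2
        ]


class TestOracleEquivalence:
    def test_naive_loop_chain_agrees_on_random_fixtures(self):
        """Vectorized pipeline vs scalar-loop oracle, 50 fixtures, 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n_asv, n_frac = 5, 8
            reads_l = rng.integers(1, 60, size=(n_asv, n_frac))
            reads_u = rng.integers(1, 60, size=(n_asv, n_frac))
            sq_l = rng.uniform(100, 1e5, n_frac)
            sq_u = rng.uniform(100, 1e5, n_frac)
            dens = np.sort(rng.uniform(1.67, 1.72, n_frac))
            dens += np.arange(n_frac) * 1e-4  # ensure strictly increasing
            m_l = make_matrix(reads_l, treatment="L")
            m_u = make_matrix(reads_u, treatment="U")
            rep_l = make_gradient(treatment="L", densities=list(dens), copies=list(sq_l))
            rep_u = make_gradient(treatment="U", densities=list(dens), copies=list(sq_u))
            prof_l = weighted_mean_density(taxon_copies(m_l, rep_l), rep_l)
            prof_u = weighted_mean_density(taxon_copies(m_u, rep_u), rep_u)
            asvs = [f"ASV{i+1}" for i in range(n_asv)]
            rd_l = {a: list(map(float, reads_l[i])) for i, a in enumerate(asvs)}
            rd_u = {a: list(map(float, reads_u[i])) for i, a in enumerate(asvs)}
            for a in asvs:
                expected = naive_eaf_chain(
                    rd_l, list(sq_l), list(dens), rd_u, list(sq_u), list(dens), a
                )
                got = eaf_per_replicate(prof_l.loc[a, "W"], prof_u.loc[a, "W"])
                assert got == pytest.approx(expected, abs=1e-10)


class TestCallIncorporators:
    def test_boundary_ci_low_zero_is_not_called(self):
        from fjordsip.qsip import EAFEstimate

        ests = [
            EAFEstimate("a", "t", (0.1,), 0.1, 0.0, 0.2, False),
            EAFEstimate("b", "t", (0.1,), 0.1, 0.01, 0.2, True),
        ]
        table, summary = call_incorporators(ests)
        assert list(table["is_incorporator"]) == [False, True]
        assert summary["n_incorporators"] == 1

    def test_mixed_ci_levels_rejected(self):
        from fjordsip.qsip import EAFEstimate

        ests = [
            EAFEstimate("a", "t", (0.1,), 0.1, 0.0, 0.2, False, ci_level=0.9),
            EAFEstimate("b", "t", (0.1,), 0.1, 0.0, 0.2, False, ci_level=0.95),
        ]
        with pytest.raises(ValueError, match="ci_level"):
            call_incorporators(ests)

    def test_summary_relative_abundance_of_incorporators(self):
        from fjordsip.qsip import EAFEstimate

        m = make_matrix(np.array([[60, 80], [40, 20]]))
        ests = [EAFEstimate("ASV1", "hypoxic_13C-taurine", (0.2,), 0.2, 0.1, 0.3, True)]
        _, summary = call_incorporators(ests, m, "hypoxic_13C-taurine")
        assert summary["incorporator_relative_abundance"] == pytest.approx(0.7)

    def test_simulated_truth_recovered_exactly_for_strong_labels(self):
        """3 of 10 ASVs labeled at EAF 0.3 are exactly the ones called."""
        rng = np.random.default_rng(77)
        gcs = rng.uniform(0.4, 0.6, 10)
        labeled = {"ASV2", "ASV5", "ASV9"}
        lab_frames, unl_frames = [], []
        for j in (1, 2, 3):
            wl = unlabeled_density(gcs) + rng.normal(0, 3e-4, 10)
            eafs = np.array([0.3 if f"ASV{i+1}" in labeled else 0.0 for i in range(10)])
            wlab = labeled_density(gcs, eafs) + rng.normal(0, 3e-4, 10)
            ids = [f"ASV{i+1}" for i in range(10)]
            lab_frames.append(_profiles(ids, "t", wlab).assign(replicate_id=j))
            unl_frames.append(_profiles(ids, "u", wl).assign(replicate_id=j))
        ests = estimate_eaf_table(
            pd.concat(lab_frames), pd.concat(unl_frames), "t", n_boot=500, seed=4
        )
        called = {e.asv_id for e in ests if e.is_incorporator}
        assert called == labeled
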