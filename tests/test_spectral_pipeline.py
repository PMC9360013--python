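"""Spectral pipeline: usability rules, constrained multi-start fitting,
best-fit selection, aggregation, and the table-level driver."""

import numpy as np
import pandas as pd
import pytest

from osdensity.forward_model import DEFAULT_WAVELENGTHS_NM, simulate_spectrum
from osdensity.records import (FitResult, MeasuredSpectrum,
                               ScatteringParams, TissueComposition,
                               geometry_for_cup)
from osdensity.spectral_pipeline import (REASON_NO_905_940, REASON_NO_985,
                                         REASON_TOO_FEW, aggregate_participant,
                                         fit_spectrum, qc_filter,
                                         run_spectral_pipeline, select_best_fit,
                                         spectra_from_frame)
from osdensity.synthetic_cohort import sample_interior_truth

FULL_GRID = list(DEFAULT_WAVELENGTHS_NM)


def make_spectrum(usable_wavelengths, pid="P1", side="left", offset=10.0, pos=0):
    """Spectrum on the default grid with the given wavelengths usable."""
    lam = np.array(DEFAULT_WAVELENGTHS_NM)
    usable = np.isin(lam, np.asarray(usable_wavelengths, dtype=float))
    signals = np.where(usable, 1e-7, np.nan)
    return MeasuredSpectrum(pid, side, "B", offset, lam, signals, usable,
                            position=pos)


def qc_fixture_12():
    """12 spectra with known availability: 3 fail the >=7 rule, 2 miss
    985 nm, 2 miss both 905 and 940 nm, 5 pass everything."""
    too_few = [
        [650, 675, 700, 730, 760, 785],          # 6 wavelengths
        [905, 985],                               # 2, despite key wavelengths
        [650, 760, 905, 985],                     # 4
    ]
    no_985 = [
        [650, 675, 700, 730, 760, 785, 905],
        [650, 675, 700, 730, 760, 810, 905, 940],
    ]
    no_905_940 = [
        [650, 675, 700, 730, 760, 785, 985],
        [650, 675, 700, 730, 810, 840, 985, 1020],
    ]
    passing = [
        FULL_GRID,
        [650, 675, 700, 730, 760, 905, 985],
        [650, 675, 700, 730, 760, 940, 985],
        [650, 700, 760, 840, 905, 940, 985, 1060],
        [675, 730, 785, 870, 925, 905, 985],
    ]
    spectra, expected = [], []
    for group, reason in ((too_few, REASON_TOO_FEW), (no_985, REASON_NO_985),
                          (no_905_940, REASON_NO_905_940), (passing, None)):
        for wl in group:
            spectra.append(make_spectrum(wl, pid=f"S{len(spectra):02d}"))
            expected.append(reason)
    return spectra, expected


class TestQcFilter:
    def test_named_rule_examples(self):
        # 6 usable wavelengths: excluded for count even though none of the
        # key wavelengths is the problem
        _, log = qc_filter([make_spectrum([650, 675, 730, 760, 810, 840])])
        assert log[0]["reason"] == REASON_TOO_FEW
        retained, _ = qc_filter([make_spectrum([650, 675, 730, 760, 810, 905, 985])])
        assert len(retained) == 1
        _, log = qc_filter([make_spectrum([650, 675, 730, 760, 810, 840, 905])])
        assert log[0]["reason"] == REASON_NO_985

    def test_twelve_spectrum_fixture_exact(self):
        spectra, expected = qc_fixture_12()
        retained, log = qc_filter(spectra)
        assert len(retained) == 5
        reasons = {e["spectrum_key"]: e["reason"] for e in log}
        for s, want in zip(spectra, expected):
            if want is None:
                assert s.key() not in reasons
            else:
                assert reasons[s.key()] == want

    def test_permutation_invariance(self, rng):
        spectra, _ = qc_fixture_12()
        base_retained, base_log = qc_filter(spectra)
        order = rng.permutation(len(spectra))
        perm_retained, perm_log = qc_filter([spectra[i] for i in order])
        assert {s.key() for s in base_retained} == {s.key() for s in perm_retained}
        assert {(e["spectrum_key"], e["reason"]) for e in base_log} == \
            {(e["spectrum_key"], e["reason"]) for e in perm_log}

    def test_empty_input(self):
        assert qc_filter([]) == ([], [])


def _fit_result(sse, n_at_bounds, start_index=0, converged=True):
    comp = TissueComposition(17.0, 46.0, 21.0, 0.4, 0.2)
    return FitResult(comp, ScatteringParams(1.7, 1.3), sse, n_at_bounds,
                     start_index, converged)


class TestSelectBestFit:
    def test_bound_rule_then_min_sse(self):
        cands = [_fit_result(3.0, 0, 0), _fit_result(1.0, 3, 1), _fit_result(2.0, 1, 2)]
        best = select_best_fit(cands)
        assert best.sse == 2.0 and best.n_at_bounds == 1

    def test_singleton_passthrough(self):
        only = _fit_result(5.0, 2)
        assert select_best_fit([only]) is only

    def test_all_disqualified_returns_failure(self):
        cands = [_fit_result(1.0, 3), _fit_result(0.5, 4),
                 _fit_result(0.1, 2, converged=False)]
        assert select_best_fit(cands) is None

    def test_tie_breaks_deterministic(self):
        cands = [_fit_result(1.0, 2, 1), _fit_result(1.0, 0, 2), _fit_result(1.0, 0, 0)]
        best = select_best_fit(cands)
        assert best.n_at_bounds == 0 and best.start_index == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_fit([])


class TestAggregateParticipant:
    def test_single_fit_identity(self):
        f = _fit_result(1.0, 0)
        agg = aggregate_participant([(f, "left")], "P1")
        assert agg.composition == f.composition
        assert agg.n_spectra_used == 1

    def test_two_fit_mean(self):
        a = FitResult(TissueComposition(16, 46, 21, 0.4, 0.2),
                      ScatteringParams(1.5, 1.0), 1.0, 0, 0, True)
        b = FitResult(TissueComposition(18, 48, 23, 0.6, 0.4),
                      ScatteringParams(2.5, 2.0), 1.0, 0, 1, True)
        agg = aggregate_participant([(a, "left"), (b, "right")], "P1")
        assert agg.composition.water_pct == pytest.approx(17.0)
        assert agg.scattering.amplitude == pytest.approx(2.0)
        assert agg.n_left == 1 and agg.n_right == 1

    def test_matches_independent_column_means(self, rng):
        fits = []
        rows = []
        for i in range(5):
            w, l, c = rng.uniform(10, 30), rng.uniform(30, 50), rng.uniform(5, 25)
            o, d = rng.uniform(0.2, 0.6), rng.uniform(0.05, 0.3)
            A, b = rng.uniform(0.5, 3.0), rng.uniform(0.3, 2.0)
            fits.append((FitResult(TissueComposition(w, l, c, o, d),
                                   ScatteringParams(A, b), 1.0, 0, i, True), "left"))
            rows.append([w, l, c, o, d, A, b])
        want = np.mean(rows, axis=0)
        agg = aggregate_participant(fits, "P9")
        got = [agg.composition.water_pct, agg.composition.lipid_pct,
               agg.composition.collagen_pct, agg.composition.oxyhb_pct,
               agg.composition.deoxyhb_pct, agg.scattering.amplitude,
               agg.scattering.power]
        assert np.allclose(got, want, atol=1e-12)

    def test_no_fits_flagged(self):
        with pytest.raises(ValueError, match="no usable spectra"):
            aggregate_participant([], "P1")


class TestFitSpectrum:
    def test_noise_free_round_trip(self, basis, bounds):
        """The full fit recovers interior truths from noise-free spectra."""
        rng = np.random.default_rng(3)
        geo = geometry_for_cup("B")
        for i in range(3):
            comp, scat = sample_interior_truth(rng)
            sp = simulate_spectrum(comp, scat, geo, 20.0, basis=basis)
            best = select_best_fit(fit_spectrum(sp, bounds, basis, geo,
                                                n_starts=8, seed=i))
            assert best is not None
            assert best.composition.water_pct == pytest.approx(comp.water_pct, abs=1.0)
            assert best.composition.lipid_pct == pytest.approx(comp.lipid_pct, abs=1.0)
            assert best.composition.collagen_pct == pytest.approx(comp.collagen_pct, abs=1.0)
            assert best.composition.total_hb_pct == pytest.approx(comp.total_hb_pct, abs=0.05)
            assert best.scattering.power == pytest.approx(scat.power, abs=0.05)
            assert bounds.contains(best.composition, best.scattering)

    def test_boundary_truth_flags_at_bounds(self, fast_basis, bounds):
        geo = geometry_for_cup("B")
        comp = TissueComposition(20.0, 40.0, 30.0, 0.4, 0.2)  # collagen at cap
        sp = simulate_spectrum(comp, ScatteringParams(1.5, 1.2), geo, 10.0,
                               basis=fast_basis)
        fits = fit_spectrum(sp, bounds, fast_basis, geo, n_starts=4, seed=0)
        assert fits[0].n_at_bounds >= 1

    def test_deterministic_given_seed(self, fast_basis, bounds):
        geo = geometry_for_cup("B")
        rng = np.random.default_rng(5)
        comp, scat = sample_interior_truth(rng)
        sp = simulate_spectrum(comp, scat, geo, 30.0, basis=fast_basis)
        a = fit_spectrum(sp, bounds, fast_basis, geo, n_starts=3, seed=7)
        b = fit_spectrum(sp, bounds, fast_basis, geo, n_starts=3, seed=7)
        assert a == b

    def test_qc_failing_spectrum_rejected(self, fast_basis, bounds):
        sp = make_spectrum([650, 675, 700])
        with pytest.raises(ValueError, match="usability"):
            fit_spectrum(sp, bounds, fast_basis, geometry_for_cup("B"))

    def test_recovery_improves_with_tolerance(self, fast_basis, bounds):
        """Round-trip error shrinks monotonically as the optimizer tolerance
        tightens (single start, fixed seed)."""
        geo = geometry_for_cup("B")
        comp, scat = sample_interior_truth(np.random.default_rng(11))
        sp = simulate_spectrum(comp, scat, geo, 20.0, basis=fast_basis)
        errs = []
        for tol in (1e-2, 1e-6, 1e-10):
            fits = fit_spectrum(sp, bounds, fast_basis, geo, n_starts=8, seed=2,
                                tol=tol)
            best = select_best_fit(fits)
            errs.append(abs(best.composition.water_pct - comp.water_pct)
                        + abs(best.composition.lipid_pct - comp.lipid_pct)
                        + abs(best.composition.collagen_pct - comp.collagen_pct))
        assert errs[2] <= errs[1] + 1e-9 <= errs[0] + 2e-9

    def test_grid_oracle_two_free_parameters(self, fast_basis, bounds):
        """With 5 parameters pinned at truth, the fitter's best SSE cannot
        exceed the minimum over a dense grid of the 2 free parameters."""
        from osdensity.spectral_pipeline import _bounds_arrays
        geo = geometry_for_cup("B")
        rng = np.random.default_rng(17)
        lo, hi = _bounds_arrays(bounds)
        for _ in range(3):
            comp, scat = sample_interior_truth(rng)
            truth = np.array([comp.water_pct, comp.lipid_pct, comp.collagen_pct,
                              comp.total_hb_pct,
                              comp.oxyhb_pct / comp.total_hb_pct,
                              scat.amplitude, scat.power])
            sp = simulate_spectrum(comp, scat, geo, 20.0, basis=fast_basis)
            free = np.zeros(7, bool)
            free[list(rng.choice(7, size=2, replace=False))] = True
            fits = fit_spectrum(sp, bounds, fast_basis, geo, n_starts=4, seed=3,
                                free_mask=free, truth_params=truth)
            grid_min = _grid_min_sse(sp, truth, free, lo, hi, fast_basis, geo, 21)
            assert min(f.sse for f in fits) <= grid_min

    def test_all_starts_reported_and_sorted(self, fast_basis, bounds):
        geo = geometry_for_cup("B")
        comp, scat = sample_interior_truth(np.random.default_rng(19))
        sp = simulate_spectrum(comp, scat, geo, 0.0, basis=fast_basis)
        fits = fit_spectrum(sp, bounds, fast_basis, geo, n_starts=5, seed=1)
        assert len(fits) == 5
        assert all(fits[i].sse <= fits[i + 1].sse for i in range(4))


def _grid_min_sse(sp, truth, free, lo, hi, basis, geo, n_grid):
    """Independent exhaustive search over the two free parameters."""
    from osdensity.forward_model import reduced_scattering, slab_transmittance
    i, j = np.where(free)[0]
    gi = np.linspace(lo[i], hi[i], n_grid)
    gj = np.linspace(lo[j], hi[j], n_grid)
    ok = sp.usable
    lam = sp.wavelengths[ok]
    target = np.log(sp.signals[ok])
    eps = basis.specific_absorption(lam)
    best = np.inf
    for vi in gi:
        for vj in gj:
            p = truth.copy()
            p[i], p[j] = vi, vj
            if p[:4].sum() >= 100.0:
                continue
            conc = np.array([p[0], p[1], p[2], p[4] * p[3], (1 - p[4]) * p[3]])
            mus = reduced_scattering(ScatteringParams(p[5], max(p[6], 1e-9)), lam)
            sim = slab_transmittance(eps @ conc, mus, geo, sp.offset_mm)
            r = np.log(sim) - target
            best = min(best, float(r @ r))
    return best


@pytest.fixture(scope="module")
def tiny_cohort_frame():
    """Two participants' noise-free spectra plus one all-unusable participant."""
    rng = np.random.default_rng(23)
    geo = geometry_for_cup("B")
    rows = []
    truths = {}
    from osdensity.basis import toy_basis
    basis = toy_basis()
    for pid in ("A1", "A2"):
        comp, scat = sample_interior_truth(rng)
        truths[pid] = (comp, scat)
        for side in ("left", "right"):
            for off in (10.0, 30.0):
                sp = simulate_spectrum(comp, scat, geo, off, basis=basis,
                                       participant_id=pid, side=side)
                for lam, sig in zip(sp.wavelengths, sp.signals):
                    rows.append((pid, side, "B", off, 0, lam, sig, 1))
    # participant with every spectrum unusable at 985
    for lam in DEFAULT_WAVELENGTHS_NM:
        rows.append(("BAD", "left", "B", 10.0, 0, lam, 1e-8,
                     int(lam != 985.0)))
    return pd.DataFrame(rows, columns=["participant_id", "side", "cup_size",
                                       "offset_mm", "position",
                                       "wavelength_nm", "signal", "usable"]), truths


class TestRunPipeline:
    def test_round_trip_and_exclusions(self, tiny_cohort_frame, fast_basis):
        df, truths = tiny_cohort_frame
        comp_df, excl = run_spectral_pipeline(df, basis=fast_basis, n_starts=6,
                                              seed=42)
        assert set(comp_df["participant_id"]) == {"A1", "A2"}
        assert (excl["participant_id"] == "BAD").all()
        assert (excl["reason"] == REASON_NO_985).all()
        for pid in ("A1", "A2"):
            row = comp_df.set_index("participant_id").loc[pid]
            want = truths[pid][0]
            assert row["water_pct"] == pytest.approx(want.water_pct, abs=1.0)
            assert row["lipid_pct"] == pytest.approx(want.lipid_pct, abs=1.0)
            assert row["n_spectra_used"] == 4

    def test_row_order_does_not_change_results(self, tiny_cohort_frame, fast_basis):
        df, _ = tiny_cohort_frame
        a, _ = run_spectral_pipeline(df, basis=fast_basis, n_starts=3, seed=9)
        shuffled = df.sample(frac=1, random_state=13).reset_index(drop=True)
        b, _ = run_spectral_pipeline(shuffled, basis=fast_basis, n_starts=3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_malformed_table_rejected(self, fast_basis):
        with pytest.raises(ValueError, match="missing columns"):
            run_spectral_pipeline(pd.DataFrame({"participant_id": ["x"]}),
                                  basis=fast_basis)

    def test_spectra_from_frame_round_trip(self, tiny_cohort_frame):
        df, _ = tiny_cohort_frame
        spectra = spectra_from_frame(df)
        assert len(spectra) == 9
        assert all(s.wavelengths.size == len(DEFAULT_WAVELENGTHS_NM)
                   for s in spectra)
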