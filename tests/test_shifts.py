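"""CSP significance, open-state populations, fast-limit exchange rates."""

import numpy as np
import pytest

from nmrbind.binding import ExchangeParams, TitrationCondition, binding_state
from nmrbind.exchange import cpmg_r2eff_profile, snap_nu_cpmg
from nmrbind.shifts import (
    ShiftTriplet,
    analyse_csps,
    combined_csp,
    corrected_sd_cutoff,
    kex_from_rex,
    open_population,
)
from nmrbind.synth import gen_csp


class TestCombinedCsp:
    @pytest.mark.parametrize("dh,dn,want", [
        (0.0, 0.0, 0.0),
        (0.1, 0.5, 0.14142),
        (0.0, 1.0, 0.2),
        (-0.1, 0.5, 0.14142),  # magnitudes only
    ])
    def test_examples(self, dh, dn, want):
        assert combined_csp(dh, dn) == pytest.approx(want, abs=1e-5)

    def test_vectorized(self):
        out = combined_csp([0.0, 0.1], [1.0, 0.5])
        assert np.allclose(out, [0.2, 0.14142], atol=1e-5)


class TestCorrectedSd:
    def test_planted_outlier_removed_from_estimate(self, rng):
        vals = np.abs(rng.normal(0.015, 0.003, 19))
        data = np.append(vals, 0.5)
        sigma, cutoff, sig = corrected_sd_cutoff(data)
        # brute-force reference: trim at mean+3sd until stable, sd-to-zero
        keep = np.ones(20, bool)
        while True:
            v = data[keep]
            new = keep & (data <= v.mean() + 3 * v.std())
            if new.sum() == keep.sum():
                break
            keep = new
        assert not keep[-1]  # the 0.5 value was trimmed
        assert sigma == pytest.approx(float(np.sqrt(np.mean(data[keep] ** 2))))
        assert cutoff == 2 * sigma
        assert sig[-1]  # and flagged significant

    def test_no_trimming_equals_plain_sd(self, rng):
        vals = np.abs(rng.normal(0.015, 0.002, 15))
        sigma, _, _ = corrected_sd_cutoff(vals)
        assert sigma == pytest.approx(float(np.sqrt(np.mean(vals**2))))
        # and about the mean when configured so
        sigma_m, _, _ = corrected_sd_cutoff(vals, final_center="mean")
        assert sigma_m == pytest.approx(float(np.std(vals)))

    def test_idempotent_on_survivors(self, rng):
        df, _ = gen_csp(7, n=25, n_outliers=2)
        comb = combined_csp(df["dH_ppm"], df["dN_ppm"])
        sigma1, cutoff1, _ = corrected_sd_cutoff(comb)
        survivors = comb[comb <= cutoff1 * 10]  # keep all; re-run on trimmed set
        # re-running on the set that survived trimming changes nothing
        keep = np.ones(len(comb), bool)
        while True:
            v = comb[keep]
            new = keep & (comb <= v.mean() + 3 * v.std())
            if new.sum() == keep.sum():
                break
            keep = new
        sigma2, _, _ = corrected_sd_cutoff(comb[keep])
        assert sigma2 == pytest.approx(sigma1, rel=1e-12)

    def test_permutation_invariance(self, rng):
        df, _ = gen_csp(9, n=30, n_outliers=2)
        comb = np.asarray(combined_csp(df["dH_ppm"], df["dN_ppm"]))
        _, cutoff, sig = corrected_sd_cutoff(comb)
        perm = rng.permutation(len(comb))
        _, cutoff_p, sig_p = corrected_sd_cutoff(comb[perm])
        assert cutoff_p == pytest.approx(cutoff)
        assert set(np.flatnonzero(sig)) == set(perm[np.flatnonzero(sig_p)])

    def test_identical_values_flagged_zero(self, caplog):
        with caplog.at_level("WARNING"):
            sigma, cutoff, _ = corrected_sd_cutoff([0.0] * 6)
        assert sigma == 0.0 and cutoff == 0.0
        assert "zero" in caplog.text

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            corrected_sd_cutoff([0.1, 0.2])

    def test_table_interface_flags_planted_outlier(self):
        df, manifest = gen_csp(5, n=20, n_outliers=1)
        out, cutoff = analyse_csps(df)
        planted = manifest["outlier_residues"][0]
        assert bool(out.loc[out.residue_id == planted, "significant"].iloc[0])
        assert cutoff > 0


class TestOpenPopulation:
    def test_linear_interpolation(self):
        p, _ = open_population([ShiftTriplet(1, 120.0, 118.0, 119.2)])
        assert p == pytest.approx(0.40, abs=1e-6)

    def test_end_members(self):
        assert open_population([ShiftTriplet(1, 120.0, 118.0, 120.0)])[0] == 0.0
        assert open_population([ShiftTriplet(1, 120.0, 118.0, 118.0)])[0] == 1.0

    def test_inverse_variance_weighting(self):
        # wider reference separation dominates the aggregate
        trip = [
            ShiftTriplet(1, 120.0, 118.0, 119.0, sigma=0.01),  # p=0.5, sep 2
            ShiftTriplet(2, 120.0, 119.9, 119.92, sigma=0.01),  # p=0.8, sep 0.1
        ]
        p, tab = open_population(trip, noise_floor=0.05)
        assert len(tab) == 2
        assert abs(p - 0.5) < abs(p - 0.8)

    def test_small_separation_excluded(self, caplog):
        trip = [
            ShiftTriplet(1, 120.0, 118.0, 119.0),
            ShiftTriplet(2, 120.0, 120.001, 120.0),
        ]
        with caplog.at_level("WARNING"):
            p, tab = open_population(trip)
        assert len(tab) == 1 and "excluded" in caplog.text
        with pytest.raises(ValueError):
            open_population([ShiftTriplet(1, 120.0, 120.001, 120.0)])

    def test_exact_on_synthetic_fast_exchange_positions(self, rng):
        # fast-exchange observed position is the population-weighted average
        p_true = 0.7
        trips = []
        for i in range(5):
            closed = rng.uniform(110, 125)
            open_ = closed + rng.uniform(0.5, 3.0)
            trips.append(ShiftTriplet(i, closed, open_,
                                      (1 - p_true) * closed + p_true * open_))
        p, _ = open_population(trips)
        assert p == pytest.approx(p_true, abs=1e-10)


class TestKexFromRex:
    def test_direct_evaluation(self):
        assert kex_from_rex(0.7, 1000.0, 10.0) == pytest.approx(21000.0)

    def test_large_rex_gives_small_kex(self):
        assert kex_from_rex(0.5, 1000.0, 1e6) < 1.0

    def test_nonpositive_rex_rejected(self):
        with pytest.raises(ValueError):
            kex_from_rex(0.5, 1000.0, 0.0)

    def test_round_trip_with_simulated_fast_exchange(self):
        # simulate low-nu Rex at a known fast kex, invert, recover within 10%
        kex_true, p = 20000.0, 0.7
        dw = 1200.0  # rad/s
        kab, kba = kex_true * p, kex_true * (1 - p)  # open fraction p
        nu = snap_nu_cpmg(np.array([25.0, 16000.0]), 0.04)
        r2 = cpmg_r2eff_profile(dw, 12.0, 12.0, kab, kba, nu, 0.04)
        rex = float(r2[0] - r2[1])
        assert kex_from_rex(p, dw, rex) == pytest.approx(kex_true, rel=0.1)
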