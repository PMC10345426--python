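import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_assignment
from phnmr.csp import (
    Peak,
    TitrationSeries,
    call_perturbed,
    delta_delta,
    read_peaklist_tsv,
    track_peaks,
    write_peaklist_tsv,
)
from phnmr.exceptions import PhnmrError
from phnmr.synthetic import make_titration

finite = st.floats(min_value=-5, max_value=5, allow_nan=False)


class TestDeltaDelta:
    @pytest.mark.parametrize("dh,dn,expected", [
        (0.0, 0.0, 0.0),
        (0.1, 0.0, 0.1),
        (0.0, 0.5, 0.1),
        (0.03, 0.25, 0.05831),  # sqrt(0.0009 + 0.0025)
    ])
    def test_combined_shift_formula(self, dh, dn, expected):
        assert delta_delta(dh, dn) == pytest.approx(expected, abs=5e-6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(finite, finite)
    def test_even_in_both_arguments(self, dh, dn):
        v = delta_delta(dh, dn)
        assert v >= 0
        assert delta_delta(-dh, -dn) == pytest.approx(v)
        assert delta_delta(-dh, dn) == pytest.approx(v)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            delta_delta(float("nan"), 0.0)


class TestTrackPeaks:
    def test_small_shifts_give_identity_mapping(self):
        ref = [Peak(1, 8.0, 110.0), Peak(2, 9.0, 120.0), Peak(3, 7.2, 125.0)]
        moved = [Peak(None, 8.01, 110.05), Peak(None, 9.0, 120.0),
                 Peak(None, 7.21, 124.95)]
        series = TitrationSeries((0.0, 1.0), (tuple(ref), tuple(moved)))
        table = track_peaks(series)
        assert table.deltas[1][1] == pytest.approx(
            math.hypot(0.01, 0.01), abs=1e-9)
        assert table.deltas[2][1] == 0.0

    def test_matching_equals_brute_force_assignment(self, rng):
        # crowded region: 6 peaks moving into each other's neighborhoods
        ref = [Peak(i + 1, float(h), float(n))
               for i, (h, n) in enumerate(rng.uniform([7, 115], [7.4, 117],
                                                      size=(6, 2)))]
        moved = [Peak(None, p.delta_h + rng.normal(0, 0.08),
                      p.delta_n + rng.normal(0, 0.4)) for p in ref]
        series = TitrationSeries((0.0, 1.0), (tuple(ref), tuple(moved)))
        table = track_peaks(series, max_step=10.0)
        prev = np.array([p.scaled for p in ref])
        cur = np.array([p.scaled for p in moved])
        cost = np.linalg.norm(prev[:, None] - cur[None, :], axis=2)
        mapping, _ = brute_force_assignment(cost)
        for row, col in mapping.items():
            res = ref[row].residue
            expected = math.hypot(cur[col][0] - prev[row][0],
                                  cur[col][1] - prev[row][1])
            assert table.deltas[res][1] == pytest.approx(expected, abs=1e-9)

    def test_vanished_peak_flagged_missing_not_zero(self):
        series, _truth = make_titration(seed=5, lost_residues=(12,))
        table = track_peaks(series)
        assert table.deltas[12][-1] is None
        finals = table.final_deltas()
        assert finals[12] is None

    def test_duplicate_reference_assignment_rejected(self):
        ref = (Peak(1, 8.0, 110.0), Peak(1, 9.0, 120.0))
        series = TitrationSeries((0.0, 1.0), (ref, ref))
        with pytest.raises(PhnmrError):
            track_peaks(series)

    def test_unassigned_reference_rejected(self):
        ref = (Peak(None, 8.0, 110.0),)
        series = TitrationSeries((0.0, 1.0), (ref, ref))
        with pytest.raises(PhnmrError):
            track_peaks(series)

    def test_monotone_delta_on_fast_exchange_synthetic(self):
        series, truth = make_titration(seed=8, background_sigma=0.0)
        table = track_peaks(series)
        for res in truth.site_residues:
            traj = table.deltas[res]
            assert all(b >= a - 1e-12 for a, b in zip(traj, traj[1:]))


class TestCallPerturbed:
    def test_all_zero_gives_empty_set(self):
        series, _ = make_titration(seed=2, site_residues={},
                                   background_sigma=0.0)
        table = track_peaks(series)
        perturbed, _bins = call_perturbed(table)
        assert perturbed == set()

    def test_exact_threshold_excluded(self):
        from phnmr.csp import CspTable
        table = CspTable(ratios=(0.0, 1.0),
                         deltas={1: (0.0, 0.100), 2: (0.0, 0.1001)})
        perturbed, _ = call_perturbed(table, threshold=0.100)
        assert perturbed == {2}

    def test_planted_site_recovered_exactly(self):
        series, truth = make_titration(seed=3)
        table = track_peaks(series)
        perturbed, bins = call_perturbed(table)
        assert perturbed == set(truth.site_residues)
        assert all(bins[r] >= 1 for r in perturbed)

    def test_monotone_in_threshold(self):
        series, _ = make_titration(seed=4)
        table = track_peaks(series)
        low, _ = call_perturbed(table, threshold=0.05)
        high, _ = call_perturbed(table, threshold=0.2)
        assert high <= low


class TestTitrationSeries:
    def test_ratios_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            TitrationSeries((0.25, 0.5), ((), ()))
        with pytest.raises(ValueError):
            TitrationSeries((0.0, 0.5, 0.5), ((), (), ()))


def test_peaklist_tsv_round_trip(tmp_path):
    peaks = [Peak(1, 8.1234, 110.5678, 1.0), Peak(None, 7.0, 120.0, 0.5)]
    path = tmp_path / "peaks.tsv"
    write_peaklist_tsv(peaks, path)
    back = read_peaklist_tsv(path)
    assert back[0].residue == 1
    assert back[1].residue is None
    assert back[0].delta_h == pytest.approx(8.1234)
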