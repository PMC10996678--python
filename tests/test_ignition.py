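"""Unit and property tests for the ignition pipeline core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ignidyn.errors import ContractError, DegenerateSignalError, ParameterError
from ignidyn.ignition import (
    EventRaster,
    ParcelTimeSeries,
    bandpass,
    coactivation_matrix,
    detect_events,
    ignition_profile,
    integration,
    zscore,
)

from conftest import raster_from_events


def _amplitude(x):
    # steady-state amplitude, ignoring filtfilt edge transients
    core = x[50:-50]
    return (core.max() - core.min()) / 2


class TestBandpass:
    def test_zero_input_stays_zero(self):
        s = ParcelTimeSeries("z", np.zeros((3, 100)), 3.0)
        assert np.allclose(bandpass(s, 0.01, 0.09).data, 0.0)

    def test_inband_tone_preserved_outband_attenuated(self, sine_series):
        out = bandpass(sine_series, 0.01, 0.09)
        assert _amplitude(out.data[0]) == pytest.approx(1.0, rel=0.05)
        assert _amplitude(out.data[1]) < 1.0 / 5

    def test_infeasible_band_rejected(self):
        s = ParcelTimeSeries("z", np.zeros((2, 50)), 3.0)
        with pytest.raises(ParameterError):
            bandpass(s, 0.01, 0.2)  # above Nyquist for TR=3


class TestZscore:
    def test_moments(self):
        s = ParcelTimeSeries("s", np.array([[1.0, 2.0, 3.0]]), 1.0)
        z = zscore(s).data[0]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        s = ParcelTimeSeries("s", rng.normal(size=(4, 60)), 1.0)
        once = zscore(s)
        assert np.allclose(zscore(once).data, once.data)

    @given(a=st.floats(0.1, 50), b=st.floats(-20, 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.sin(np.arange(30.0))[None, :]
        s = ParcelTimeSeries("s", x, 1.0)
        t = ParcelTimeSeries("t", a * x + b, 1.0)
        assert np.allclose(zscore(s).data, zscore(t).data, atol=1e-9)

    def test_constant_region_named(self):
        s = ParcelTimeSeries("s", np.vstack([np.arange(5.0), np.ones(5)]), 1.0, ["good", "flat"])
        with pytest.raises(DegenerateSignalError, match="flat"):
            zscore(s)


class TestDetectEvents:
    def test_upcrossings_only(self):
        z = ParcelTimeSeries("z", np.array([[-1.0, 2.0, 2.0, -1.0, 3.0]]), 1.0)
        ev = detect_events(z, theta=1.0).events[0]
        assert list(ev) == [0, 1, 0, 0, 1]

    def test_subthreshold_row_has_no_events(self):
        z = ParcelTimeSeries("z", np.full((1, 20), 0.5), 1.0)
        assert detect_events(z, 1.0).events.sum() == 0

    def test_first_sample_never_event(self):
        z = ParcelTimeSeries("z", np.array([[5.0, 5.0, 5.0]]), 1.0)
        assert detect_events(z, 1.0).events[0, 0] == 0

    def test_matches_bruteforce_scan(self, rng):
        x = rng.normal(size=(3, 500))
        ev = detect_events(ParcelTimeSeries("z", x, 1.0), 1.0).events
        for i in range(3):
            expected = [
                t for t in range(1, 500) if x[i, t] > 1.0 and x[i, t - 1] <= 1.0
            ]
            assert list(np.flatnonzero(ev[i])) == expected


class TestCoactivation:
    def test_lone_driver_gives_empty_graph(self):
        raster = raster_from_events({0: [2]}, 5, 10)
        adj = coactivation_matrix(raster, driver=0, t=2, window_trs=4)
        assert adj.sum() == 0

    def test_three_active_regions_form_clique(self):
        raster = raster_from_events({0: [1], 1: [2], 2: [4]}, 5, 10)
        adj = coactivation_matrix(raster, driver=0, t=1, window_trs=4)
        expected = np.zeros((5, 5), dtype=int)
        for j in (0, 1, 2):
            for k in (0, 1, 2):
                if j != k:
                    expected[j, k] = 1
        assert np.array_equal(adj, expected)

    def test_equals_outer_product_of_window_activity(self, rng):
        ev = (rng.random((8, 30)) < 0.15).astype(np.uint8)
        raster = EventRaster(events=ev, theta=1.0)
        for t in (0, 5, 20):
            for driver in (0, 3):
                v = ev[:, t : t + 4].any(axis=1).astype(int)
                v[driver] = 1
                expected = np.outer(v, v)
                np.fill_diagonal(expected, 0)
                got = coactivation_matrix(raster, driver, t, 4)
                assert np.array_equal(got, expected)

    def test_window_past_scan_end_rejected(self):
        raster = raster_from_events({0: [8]}, 3, 10)
        with pytest.raises(ContractError):
            coactivation_matrix(raster, 0, 8, 4)


def _union_find_fraction(adj):
    """Independent connected-components oracle (union-find, no scipy/networkx)."""
    n = adj.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        for k in range(j + 1, n):
            if adj[j, k]:
                parent[find(j)] = find(k)
    sizes = {}
    for j in range(n):
        r = find(j)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values()) / n


class TestIntegration:
    def test_empty_graph_is_one_singleton(self):
        assert integration(np.zeros((5, 5), dtype=int)) == pytest.approx(1 / 5)

    def test_complete_graph_is_full(self):
        adj = 1 - np.eye(5, dtype=int)
        assert integration(adj) == pytest.approx(1.0)

    def test_two_components(self):
        adj = np.zeros((6, 6), dtype=int)
        for j, k in [(0, 1), (1, 2), (3, 4)]:
            adj[j, k] = adj[k, j] = 1
        assert integration(adj) == pytest.approx(0.5)

    @pytest.mark.parametrize("bad", [np.zeros((3, 4)), np.triu(np.ones((4, 4)), 1)])
    def test_contract_violations(self, bad):
        with pytest.raises(ContractError):
            integration(bad.astype(int))

    def test_matches_union_find_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 21))
            adj = (rng.random((n, n)) < 0.2).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            assert integration(adj) == pytest.approx(_union_find_fraction(adj))


class TestIgnitionProfile:
    def test_constant_integration_has_zero_metastability(self):
        # region 0 drives twice; both windows contain regions {0,1} of 5 → 0.4
        raster = raster_from_events({0: [1, 6], 1: [2, 7]}, 5, 12)
        prof, _ = ignition_profile(raster, window_trs=4)
        assert prof.ignition[0] == pytest.approx(0.4)
        assert prof.node_metastability[0] == pytest.approx(0.0)

    def test_hand_computed_population_sd(self):
        # region 0's three events see 1, 2 and 3 of 5 regions active (w=1)
        raster = raster_from_events({0: [1, 4, 8], 1: [4, 8], 2: [8]}, 5, 12)
        prof, _ = ignition_profile(raster, window_trs=1)
        assert prof.ignition[0] == pytest.approx(0.4)
        assert prof.node_metastability[0] == pytest.approx(np.sqrt(0.08 / 3))

    def test_matches_explicit_matrix_route(self, rng):
        """Vectorised profile equals the per-event coactivation+integration path."""
        ev = (rng.random((7, 40)) < 0.12).astype(np.uint8)
        raster = EventRaster(events=ev, theta=1.0)
        w = 4
        prof, records = ignition_profile(raster, w)
        slow = {i: [] for i in range(7)}
        for i in range(7):
            for t in np.flatnonzero(ev[i]):
                if t + w <= 40:
                    adj = coactivation_matrix(raster, i, int(t), w)
                    slow[i].append(integration(adj))
        for i in range(7):
            if len(slow[i]) == 0:
                assert np.isnan(prof.ignition[i])
            else:
                assert prof.ignition[i] == pytest.approx(np.mean(slow[i]))
            if len(slow[i]) >= 2:
                assert prof.node_metastability[i] == pytest.approx(np.std(slow[i]))
            else:
                assert np.isnan(prof.node_metastability[i])

    def test_events_near_scan_end_dropped(self):
        raster = raster_from_events({0: [9], 1: [2, 5]}, 3, 12)
        prof, records = ignition_profile(raster, window_trs=4)
        assert prof.n_events[0] == 0  # window [9,12] exceeds the scan
        assert np.isnan(prof.ignition[0])
        assert set(records["driver_region"]) == {"R001"}

    def test_single_event_region_has_missing_metastability(self):
        raster = raster_from_events({0: [1], 1: [1, 5]}, 4, 12)
        prof, _ = ignition_profile(raster, 4)
        assert prof.n_events[0] == 1
        assert np.isfinite(prof.ignition[0])
        assert np.isnan(prof.node_metastability[0])

    def test_label_equivariance_under_region_shuffle(self, rng):
        ev = (rng.random((6, 50)) < 0.15).astype(np.uint8)
        perm = rng.permutation(6)
        r1 = EventRaster(events=ev, theta=1.0)
        r2 = EventRaster(events=ev[perm], theta=1.0)
        p1, _ = ignition_profile(r1, 4)
        p2, _ = ignition_profile(r2, 4)
        assert np.allclose(p1.ignition[perm], p2.ignition, equal_nan=True)
        assert np.allclose(
            p1.node_metastability[perm], p2.node_metastability, equal_nan=True
        )

    def test_deterministic(self, rng):
        ev = (rng.random((5, 60)) < 0.1).astype(np.uint8)
        p1, _ = ignition_profile(EventRaster(events=ev, theta=1.0), 4)
        p2, _ = ignition_profile(EventRaster(events=ev.copy(), theta=1.0), 4)
        assert np.array_equal(p1.ignition, p2.ignition, equal_nan=True)


@pytest.mark.parametrize("n_regions", range(2, 9))
def test_clique_equivalence_exhaustive(n_regions):
    """integration(coactivation) == active fraction, for every activity vector."""
    for bits in range(2**n_regions):
        v = np.array([(bits >> i) & 1 for i in range(n_regions)], dtype=np.uint8)
        raster = EventRaster(events=v[:, None] * np.ones((1, 1), dtype=np.uint8), theta=1.0)
        drivers = np.flatnonzero(v)
        if drivers.size == 0:
            continue
        adj = coactivation_matrix(raster, int(drivers[0]), 0, 1)
        assert integration(adj) == pytest.approx(v.sum() / n_regions)
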