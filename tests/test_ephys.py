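"""Tests for spike-train analysis, classification and the ratio test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliaquant.ephys import (
    FILAMENT_FORCE_G,
    CellRecording,
    StimulusEpoch,
    adaptive_ratio,
    classify_cohort,
    evoked_response,
    firing_rate,
    kmeans_boundary,
    ratio_binomial_test,
    receptive_field_area,
    vf_threshold,
)
from gliaquant.synthdata import SpikeSimSpec, gen_spike_recording


def make_recording(spikes, epochs=(), **kw):
    return CellRecording(np.asarray(spikes, float), list(epochs), **kw)


def vf_epoch(onset, filament, trial=0, duration=2.0):
    return StimulusEpoch(kind="vf", onset=onset, duration=duration, trial=trial,
                         filament_index=filament)


def make_vf_recording(rates_by_filament, n_trials=3, gap=10.0):
    """Recording with `n_trials` 2-s epochs per filament, each epoch containing
    `rate` spikes uniformly in its first second (and none after)."""
    epochs, spikes = [], []
    t = 0.0
    for filament, rate in rates_by_filament.items():
        for trial in range(n_trials):
            epochs.append(vf_epoch(t, filament, trial))
            spikes.extend(np.linspace(t, t + 0.999, int(round(rate)), endpoint=True))
            t += gap
    return make_recording(sorted(spikes), epochs)


# ---------------------------------------------------------------------------
# filament table


def test_filament_forces_strictly_increasing():
    forces = [FILAMENT_FORCE_G[i] for i in range(1, 11)]
    assert forces == sorted(forces)
    assert len(set(forces)) == 10
    assert forces[0] == 0.008 and forces[-1] == 2.0


# ---------------------------------------------------------------------------
# firing_rate / evoked_response


def test_firing_rate_uniform():
    rec = make_recording(np.linspace(0, 599.999, 600))
    assert firing_rate(rec, 0.0, 600.0) == pytest.approx(1.0)


def test_firing_rate_no_spikes():
    assert firing_rate(make_recording([]), 0.0, 10.0) == 0.0


def test_firing_rate_empty_window_errors():
    with pytest.raises(ValueError):
        firing_rate(make_recording([1.0]), 5.0, 5.0)


def test_firing_rate_window_split_additivity():
    rng = np.random.default_rng(0)
    rec = make_recording(np.sort(rng.uniform(0, 100, 500)))
    whole = firing_rate(rec, 0.0, 100.0)
    r1 = firing_rate(rec, 0.0, 30.0)
    r2 = firing_rate(rec, 30.0, 100.0)
    assert (30 * r1 + 70 * r2) / 100 == pytest.approx(whole)


def test_evoked_response_mean_over_trials():
    epochs = [vf_epoch(0.0, 5, 0), vf_epoch(10.0, 5, 1), vf_epoch(20.0, 5, 2)]
    spikes = np.concatenate(
        [np.linspace(0, 0.99, 10), np.linspace(10, 10.99, 20), np.linspace(20, 20.99, 30)]
    )
    rec = make_recording(spikes, epochs)
    assert evoked_response(rec, "vf", 5) == pytest.approx(20.0)


def test_evoked_response_zero_spikes():
    rec = make_recording([], [vf_epoch(0.0, 3, t) for t in range(3)])
    assert evoked_response(rec, "vf", 3) == 0.0


def test_evoked_response_warns_on_nonstandard_trial_count():
    rec = make_recording([], [vf_epoch(0.0, 3, 0)])
    with pytest.warns(UserWarning, match="3 expected"):
        evoked_response(rec, "vf", 3)


def test_evoked_response_no_matching_epochs_errors():
    with pytest.raises(ValueError, match="no epochs"):
        evoked_response(make_recording([1.0]), "vf", 9)


def test_evoked_response_simulated_nonadapting_rate():
    spec = SpikeSimSpec(cell_class="nonadapting", peak_rate=40.0, spontaneous_rate=0.0,
                        n_trials=200, seed=3)
    rec = gen_spike_recording(spec)
    with pytest.warns(UserWarning):
        r = evoked_response(rec, "vf", spec.filament_index)
    assert abs(r - 40.0) < 3 * math.sqrt(40.0 / 200)


# ---------------------------------------------------------------------------
# vf_threshold


def test_vf_threshold_first_qualifying_filament():
    rec = make_vf_recording({1: 2, 2: 4, 3: 6, 4: 12, 5: 20})
    assert vf_threshold(rec) == 4


def test_vf_threshold_inclusive_at_10hz():
    rec = make_vf_recording({1: 9, 2: 10})
    assert vf_threshold(rec) == 2


def test_vf_threshold_none_when_all_below():
    rec = make_vf_recording({1: 2, 2: 3})
    assert vf_threshold(rec) is None


def test_vf_threshold_requires_vf_epochs():
    with pytest.raises(ValueError, match="vf"):
        vf_threshold(make_recording([1.0]))


# ---------------------------------------------------------------------------
# adaptive_ratio


def test_adaptive_ratio_all_first_half():
    epochs = [vf_epoch(0.0, 5)]
    rec = make_recording(np.linspace(0, 0.49, 8), epochs)
    assert adaptive_ratio(rec, 5) == 0.0


def test_adaptive_ratio_balanced():
    epochs = [vf_epoch(0.0, 5)]
    spikes = np.concatenate([np.linspace(0, 0.49, 5), np.linspace(0.5, 0.99, 5)])
    rec = make_recording(spikes, epochs)
    assert adaptive_ratio(rec, 5) == pytest.approx(1.0)


def test_adaptive_ratio_half_open_split():
    """A spike exactly at onset+0.5 belongs to the second half-window."""
    rec = make_recording([0.1, 0.5], [vf_epoch(0.0, 5)])
    assert adaptive_ratio(rec, 5) == pytest.approx(1.0)


def test_adaptive_ratio_pools_across_trials():
    epochs = [vf_epoch(0.0, 5, 0), vf_epoch(10.0, 5, 1)]
    # trial 1: 0 first-half spikes; pooled ratio still defined
    spikes = [0.1, 0.2, 0.7, 10.6]
    rec = make_recording(spikes, epochs)
    assert adaptive_ratio(rec, 5) == pytest.approx(2 / 2)


def test_adaptive_ratio_undefined_when_denominator_zero():
    rec = make_recording([0.7, 0.8], [vf_epoch(0.0, 5)])
    with pytest.warns(UserWarning, match="excluded"):
        assert adaptive_ratio(rec, 5) is None


def test_adaptive_ratio_short_epoch_errors():
    rec = make_recording([0.1], [StimulusEpoch("vf", 0.0, 0.8, 0, 5)])
    with pytest.raises(ValueError, match="1 s"):
        adaptive_ratio(rec, 5)


# ---------------------------------------------------------------------------
# kmeans_boundary


def _bruteforce_two_means(values):
    """Oracle: exhaustive sorted-split SSE minimization."""
    s = np.sort(np.asarray(values, float))
    best, best_sse = None, np.inf
    for k in range(1, s.size):
        sse = ((s[:k] - s[:k].mean()) ** 2).sum() + ((s[k:] - s[k:].mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, k
    return best, 0.5 * (s[:best].mean() + s[best:].mean())


def test_kmeans_symmetric_clusters():
    boundary, labels = kmeans_boundary([0.0, 0.0, 1.0, 1.0])
    assert boundary == pytest.approx(0.5)
    assert labels == ("adapting", "adapting", "nonadapting", "nonadapting")


def test_kmeans_matches_bruteforce_on_bimodal(rng):
    values = np.concatenate([rng.normal(0.10, 0.05, 50), rng.normal(0.80, 0.10, 25)])
    boundary, labels = kmeans_boundary(values)
    k_star, b_star = _bruteforce_two_means(values)
    assert boundary == pytest.approx(b_star)
    assert sum(lab == "adapting" for lab in labels) == k_star


def test_kmeans_translation_equivariance(rng):
    values = rng.random(40)
    b1, _ = kmeans_boundary(values)
    b2, _ = kmeans_boundary(values + 3.7)
    assert b2 == pytest.approx(b1 + 3.7)


def test_kmeans_identical_values_error():
    with pytest.raises(ValueError, match="identical"):
        kmeans_boundary([0.5, 0.5, 0.5])


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=2, max_size=200)
)
def test_kmeans_equals_exhaustive_scan_property(values):
    """Spec invariant: global SSE minimizer on every input <= 200 values."""
    if np.unique(values).size < 2:
        return
    boundary, labels = kmeans_boundary(values)
    _, b_star = _bruteforce_two_means(values)
    s = np.sort(np.asarray(values))
    # the achieved SSE must equal the brute-force optimum (split may tie)
    def sse_at(b):
        lo = s[s < b]
        hi = s[s >= b]
        out = 0.0
        if lo.size:
            out += ((lo - lo.mean()) ** 2).sum()
        if hi.size:
            out += ((hi - hi.mean()) ** 2).sum()
        return out

    assert sse_at(boundary) == pytest.approx(sse_at(b_star), rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# ratio_binomial_test


def _enumerate_minlike_p(k, n, p0):
    """Oracle: pure-python full enumeration with math.comb."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    pk = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= pk * (1 + 1e-12)))


def test_binomial_p_control_cells():
    # 8 nonadapting of 30 vs 1/3 -> 0.56 at 2 d.p.
    assert round(ratio_binomial_test(8, 30, 1 / 3), 2) == 0.56


def test_binomial_p_cko_cells():
    # 5 nonadapting of 28 vs 1/3 -> 0.11 at 2 d.p.
    assert round(ratio_binomial_test(5, 28, 1 / 3), 2) == 0.11


def test_binomial_p_modal_outcome_is_one():
    assert ratio_binomial_test(10, 30, 1 / 3) == pytest.approx(1.0)


def test_binomial_p_invalid_inputs():
    with pytest.raises(ValueError):
        ratio_binomial_test(5, 4)
    with pytest.raises(ValueError):
        ratio_binomial_test(1, 4, p0=0.0)


@settings(max_examples=100, deadline=None)
@given(
    n=st.integers(min_value=1, max_value=200),
    kf=st.floats(min_value=0, max_value=1),
    p0=st.floats(min_value=0.05, max_value=0.95),
)
def test_binomial_p_equals_enumeration_property(n, kf, p0):
    k = int(round(kf * n))
    p = ratio_binomial_test(k, n, p0)
    assert p == pytest.approx(_enumerate_minlike_p(k, n, p0), rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# receptive_field_area


def test_rf_area_unit_square():
    assert receptive_field_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(1.0)


def test_rf_area_orientation_independent():
    verts = [(0, 0), (2, 0), (2, 1), (0, 1)]
    assert receptive_field_area(verts) == receptive_field_area(verts[::-1])


def test_rf_area_too_few_vertices():
    with pytest.raises(ValueError):
        receptive_field_area([(0, 0), (1, 1)])


def test_rf_area_self_intersecting_errors():
    with pytest.raises(ValueError):
        receptive_field_area([(0, 0), (1, 1), (1, 0), (0, 1)])  # bow-tie


def test_rf_area_matches_monte_carlo(rng):
    """Oracle: point-in-polygon sampling over the bounding box."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, 7))
    verts = [(2 + 1.5 * np.cos(a), 2 + 1.5 * np.sin(a)) for a in angles]
    area = receptive_field_area(verts)

    from shapely.geometry import Point, Polygon

    poly = Polygon(verts)
    xs = rng.uniform(0.5, 3.5, 200_000)
    ys = rng.uniform(0.5, 3.5, 200_000)
    frac = np.mean([poly.contains(Point(x, y)) for x, y in zip(xs, ys)])
    mc_area = frac * 9.0
    assert area == pytest.approx(mc_area, rel=0.01)


# ---------------------------------------------------------------------------
# classify_cohort


def _simulated_cohort(n_adapting=20, n_nonadapting=10, tau=0.1, peak=40.0, seed=42):
    rng = np.random.default_rng(seed)
    recs, truth = [], []
    for cls, n in (("adapting", n_adapting), ("nonadapting", n_nonadapting)):
        for _ in range(n):
            spec = SpikeSimSpec(
                cell_class=cls, peak_rate=peak, decay_tau=tau, spontaneous_rate=0.0,
                n_trials=3, seed=int(rng.integers(2**31)),
            )
            recs.append(gen_spike_recording(spec))
            truth.append(cls)
    return recs, truth


def test_classify_cohort_recovers_simulated_labels():
    recs, truth = _simulated_cohort()
    clf, table = classify_cohort(recs, filament=5)
    included = [i for i in range(len(recs)) if i not in clf.excluded]
    correct = sum(truth[i] == lab for i, lab in zip(included, clf.labels))
    assert correct / len(recs) >= 0.9


def test_classify_cohort_fixed_boundary_inclusive():
    """R exactly at the boundary classifies as nonadapting."""
    epochs = [vf_epoch(0.0, 5)]
    recs = []
    # cell with R = 1/3 exactly: 3 spikes first half, 1 second half... use counts 3,1 -> 1/3
    recs.append(make_recording([0.1, 0.2, 0.3, 0.7], epochs))  # R = 1/3
    recs.append(make_recording(np.linspace(0.0, 0.49, 12), epochs))  # R = 0
    with pytest.warns(UserWarning):
        clf, _ = classify_cohort(recs, boundary=1 / 3, filament=5)
    assert clf.labels[0] == "nonadapting"
    assert clf.labels[1] == "adapting"
    assert clf.boundary_mode == "fixed"


def test_classify_cohort_partition_exhaustive_exclusive():
    recs, _ = _simulated_cohort(seed=7)
    clf, table = classify_cohort(recs, filament=5)
    assert len(clf.labels) + len(clf.excluded) == len(recs)
    assert set(clf.labels) <= {"adapting", "nonadapting"}
    labeled = table["label"].notna().sum()
    assert labeled == len(clf.labels)


def test_classify_empty_cohort_errors():
    with pytest.raises(ValueError, match="empty"):
        classify_cohort([])


def test_depth_qc_flag():
    rec = make_recording([], [vf_epoch(0.0, 5)], depth=100.0)
    assert rec.depth_in_range is False
    rec2 = make_recording([], [vf_epoch(0.0, 5)], depth=300.0)
    assert rec2.depth_in_range is True
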