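"""Flow-statistics tests: intervals, flow rate, power-law fitting, burst/clog
decomposition, flowing parameter, bulk observables, resonance curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oscidisk import (MeasurementRegion, bulk_observables,
                      decompose_bursts_clogs, exit_intervals, fit_power_law,
                      flow_rate, flowing_parameter, resonance_amplitude,
                      resonance_peak_frequency, sample_power_law)
from oscidisk.errors import (DegenerateSampleError, InsufficientDataError)


# -- exit intervals ------------------------------------------------------

def test_exit_intervals_examples():
    np.testing.assert_allclose(exit_intervals([1.0, 2.0, 4.0]), [1.0, 2.0])
    uniform = np.arange(100) * 0.5
    np.testing.assert_allclose(exit_intervals(uniform), np.full(99, 0.5))
    with pytest.raises(InsufficientDataError):
        exit_intervals([3.0])


# -- flow rate -----------------------------------------------------------

def test_flow_rate_uniform_flow():
    events = np.arange(1, 201) * 0.5
    fr = flow_rate(events, t_start=0.0)
    assert fr.Q == pytest.approx(2.0, rel=1e-12)
    assert fr.q_identity == pytest.approx(2.0, rel=1e-12)
    # identity: Q * spanned time == exit count - 1
    span = events[-1] - events[0]
    assert fr.q_identity * span == pytest.approx(len(events) - 1)


def test_flow_rate_arrested_half_window():
    # flow in first half then nothing: regression slope (anchored at t_end)
    # is below the identity estimator computed on the flowing part
    events = np.arange(1, 101) * 0.5  # flows until t=50
    fr = flow_rate(events, t_start=0.0, t_end=100.0)
    assert fr.Q < fr.q_identity


def test_flow_rate_poisson_recovery(rng):
    rate, t_end = 3.0, 333.0
    times = np.cumsum(rng.exponential(1 / rate, size=1500))
    times = times[times <= t_end]
    fr = flow_rate(times, t_start=0.0, t_end=t_end)
    se = rate / np.sqrt(len(times))
    assert fr.Q == pytest.approx(rate, abs=3 * se)
    assert fr.q_identity == pytest.approx(rate, abs=3 * se)


def test_flow_rate_empty_window_flagged():
    fr = flow_rate([], t_start=0.0, t_end=10.0)
    assert fr.empty and fr.Q == 0.0
    fr = flow_rate([5.0], t_start=0.0, t_end=10.0)
    assert fr.empty and fr.Q == 0.0


# -- power-law fitting ---------------------------------------------------

def test_mle_closed_form_two_samples():
    # alpha = 1 + n / sum(ln(x/x_min)) = 1 + 2/3 for {e, e^2}, x_min=1
    fit = fit_power_law([np.e, np.e ** 2], x_min=1.0)
    assert fit.alpha == pytest.approx(1.0 + 2.0 / 3.0, rel=1e-12)
    assert fit.n_tail == 2


def test_mle_matches_closed_form_on_random_tail(rng):
    x = sample_power_law(2.5, 1.0, 500, seed=9)
    fit = fit_power_law(x, x_min=1.0)
    closed = 1.0 + len(x) / np.log(x / 1.0).sum()
    assert fit.alpha == pytest.approx(closed, rel=1e-12)


def test_estimator_recovery_alpha_2_5():
    fits = [fit_power_law(sample_power_law(2.5, 1.0, 5000, seed=s))
            for s in range(20)]
    alphas = np.array([f.alpha for f in fits])
    assert abs(alphas.mean() - 2.5) < 0.05
    assert np.all((alphas > 2.3) & (alphas < 2.7))


def test_ks_distance_orders_power_law_vs_exponential(rng):
    n = 5000
    pl = sample_power_law(2.5, 1.0, n, seed=1)
    expo = 1.0 + rng.exponential(1.0, size=n)
    fit_pl = fit_power_law(pl)
    fit_ex = fit_power_law(expo)
    assert fit_pl.ks_distance < fit_ex.ks_distance


def test_fit_errors():
    with pytest.raises(DegenerateSampleError):
        fit_power_law(np.full(100, 2.0))
    with pytest.raises(InsufficientDataError):
        fit_power_law([1.0, 2.0, 3.0], min_tail=10)


# -- bursts, clogs, flowing parameter ------------------------------------

def test_decompose_example():
    bursts, clogs = decompose_bursts_clogs(
        np.array([0.1, 0.1, 5.0, 0.1]), dt_out_min=1.0)
    np.testing.assert_allclose(bursts, [0.2, 0.1])
    np.testing.assert_allclose(clogs, [5.0])


def test_decompose_partitions_span(rng):
    times = np.cumsum(rng.uniform(0.05, 3.0, size=200))
    intervals = np.diff(times)
    bursts, clogs = decompose_bursts_clogs(intervals, dt_out_min=1.0)
    assert bursts.sum() + clogs.sum() == pytest.approx(
        times[-1] - times[0], rel=1e-12)


def test_decompose_all_below_cutoff_is_one_burst():
    bursts, clogs = decompose_bursts_clogs(np.full(50, 0.1), dt_out_min=1.0)
    assert len(bursts) == 1 and len(clogs) == 0
    assert flowing_parameter(bursts, clogs).phi == 1.0


def test_decompose_all_above_cutoff_no_bursts():
    bursts, clogs = decompose_bursts_clogs(np.full(5, 2.0), dt_out_min=1.0)
    assert len(bursts) == 0 and len(clogs) == 5
    assert flowing_parameter(bursts, clogs, alpha=3.0).phi == 0.0


def test_flowing_parameter_examples():
    cls = flowing_parameter([1.0], [1.0], alpha=3.0)
    assert cls.phi == pytest.approx(0.5) and cls.label == "intermittent"
    # diverging mean clog time forces a clogged classification
    cls = flowing_parameter([1.0, 2.0], [0.5], alpha=1.9)
    assert cls.phi == 0.0 and cls.label == "clogged"
    cls = flowing_parameter([3.0, 4.0], [], alpha=None)
    assert cls.phi == 1.0 and cls.label == "flowing"


@settings(derandomize=True, max_examples=100)
@given(
    bursts=st.lists(st.floats(0.01, 10), min_size=1, max_size=20),
    clogs=st.lists(st.floats(0.01, 50), min_size=0, max_size=20),
    extra=st.floats(0.01, 100),
)
def test_phi_bounded_and_monotone_in_clog_duration(bursts, clogs, extra):
    """Phi stays in [0,1]; lengthening a clog never increases it; a first
    clog always lowers it from 1. (Adding a clog *shorter* than the current
    mean clog legitimately raises the mean-based Phi, so no monotonicity in
    the number of clogs is asserted.)"""
    phi = flowing_parameter(bursts, clogs, alpha=3.0).phi
    assert 0.0 <= phi <= 1.0
    if clogs:
        longer = clogs.copy()
        longer[0] += extra
        phi_longer = flowing_parameter(bursts, longer, alpha=3.0).phi
        assert phi_longer <= phi + 1e-12
    else:
        phi_first = flowing_parameter(bursts, [extra], alpha=3.0).phi
        assert phi_first < phi == 1.0


# -- bulk observables ----------------------------------------------------

def _frame(rows):
    return pd.DataFrame(rows, columns=["t", "id", "x", "y", "vx", "vy", "r"])


def test_bulk_observables_hand_computed_frame():
    frame = _frame([
        (0.0, 0, 10.0, 10.0, 0, 0, 1.0),   # contacts particle 1
        (0.0, 1, 11.8, 10.0, 0, 0, 1.0),   # overlap 0.2
        (0.0, 2, 5.0, 20.0, 0, 0, 1.0),    # free
    ])
    obs = bulk_observables(frame)
    assert obs.p_free == pytest.approx(1.0 / 3.0)
    assert obs.rho == pytest.approx(3.0 / 448.0)
    assert obs.n_c == pytest.approx(2.0)
    assert obs.xi_c == pytest.approx(0.2)
    assert obs.frames_used == 1 and obs.frames_skipped == 0


def test_bulk_contact_with_partner_outside_region_counts():
    frame = _frame([
        (0.0, 0, 2.9, 10.0, 0, 0, 1.0),    # inside region
        (0.0, 1, 1.2, 10.0, 0, 0, 1.0),    # outside (x < 2), overlap 0.3
    ])
    obs = bulk_observables(frame)
    assert obs.p_free == 0.0
    assert obs.n_c == 1.0
    assert obs.xi_c == pytest.approx(0.3)


def test_bulk_empty_region_frames_skipped():
    frames = pd.concat([
        _frame([(0.0, 0, 10.0, 10.0, 0, 0, 1.0)]),
        _frame([(0.5, 0, 10.0, 100.0, 0, 0, 1.0)]),  # outside region
    ])
    obs = bulk_observables(frames)
    assert obs.frames_used == 1 and obs.frames_skipped == 1
    assert obs.p_free == 1.0
    with pytest.raises(InsufficientDataError):
        bulk_observables(_frame([]))


def test_region_area():
    region = MeasurementRegion()
    assert region.area == 16 * 28 == 448


# -- driven-oscillator resonance curve -----------------------------------

def test_resonance_amplitude_curve():
    w0 = 22.4
    # undamped resonance diverges
    assert resonance_amplitude(w0, w0, 0.0) == np.inf
    # amplitude vanishes at high frequency
    assert resonance_amplitude(1e6, w0, 0.1) < 1e-9
    # damped peak location matches the closed form, via dense grid search
    for zeta in (0.1, 0.3, 0.6):
        grid = np.linspace(0.01, 3 * w0, 200001)
        amp = resonance_amplitude(grid, w0, zeta)
        peak = grid[np.argmax(amp)]
        assert peak == pytest.approx(resonance_peak_frequency(w0, zeta),
                                     abs=2 * (grid[1] - grid[0]))


def test_pooled_intervals_concatenates_not_merges():
    """Pooling replicate clogged runs keeps per-run intervals only: no
    spurious interval spans the gap between two runs' timelines."""
    from oscidisk import pooled_intervals
    log_a = [0.0, 1.0, 2.0]          # intervals 1, 1
    log_b = [100.0, 100.5]           # interval 0.5
    pooled = pooled_intervals([log_a, log_b])
    np.testing.assert_allclose(np.sort(pooled), [0.5, 1.0, 1.0])
    assert 98.0 not in pooled        # no cross-run interval
    pooled = pooled_intervals([log_a, [7.0]])  # singleton contributes nothing
    np.testing.assert_allclose(pooled, [1.0, 1.0])
    with pytest.raises(InsufficientDataError):
        pooled_intervals([[1.0], []])
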