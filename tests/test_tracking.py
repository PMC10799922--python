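"""Track simulation statistics, filters vs a predicate oracle, MSD theory
recovery, and intensity-based scenario discrimination."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from iabkit.errors import InsufficientLags, NoDisplacements, NoIntensities
from iabkit.tracking import (
    MSDCurve,
    SimParams,
    Track,
    TrackSet,
    estimate_D,
    filter_tracks,
    intensity_distribution,
    max_step_to_pixels,
    min_lifetime_ms,
    msd_curve,
    simulate_tracks,
)


def _track(tid, xs, ys, intensity=None):
    xs = np.asarray(xs, float)
    return Track(track_id=tid, frames=np.arange(len(xs)), x_nm=xs,
                 y_nm=np.asarray(ys, float),
                 intensity=None if intensity is None else np.asarray(intensity, float))


def test_stationary_simulation():
    ts = simulate_tracks(SimParams(D_um2_s=0.0, sigma_nm=0.0, n_particles=5,
                                   n_frames=10, seed=0))
    for t in ts.tracks:
        assert np.all(t.steps_nm() == 0.0)


def test_simulation_determinism():
    a = simulate_tracks(SimParams(seed=123, n_particles=10, n_frames=20))
    b = simulate_tracks(SimParams(seed=123, n_particles=10, n_frames=20))
    for ta, tb in zip(a.tracks, b.tracks):
        assert np.array_equal(ta.x_nm, tb.x_nm)
        assert np.array_equal(ta.intensity, tb.intensity)


def test_step_variance_matches_theory():
    """Empirical per-axis step variance over ~1e5 steps is within 2% of
    2 D dt (Monte-Carlo check of the Brownian propagator)."""
    p = SimParams(D_um2_s=0.1, n_particles=1000, n_frames=101, sigma_nm=0.0, seed=1)
    ts = simulate_tracks(p)
    steps = np.concatenate([np.diff(t.x_nm) for t in ts.tracks])
    assert len(steps) == 100000
    expected = 2.0 * p.D_um2_s * p.frame_interval_s * 1e6  # nm^2
    assert np.var(steps) == pytest.approx(expected, rel=0.02)


def test_filter_matches_predicate_oracle():
    tracks = [
        _track(0, [0, 100, 200, 300], [0, 0, 0, 0]),          # steps 100, keep
        _track(1, [0, 500, 600, 700], [0, 0, 0, 0]),          # first step 500 > 390
        _track(2, [0, 100], [0, 0]),                          # too short
        _track(3, [0, 0, 0], [0, 380, 760]),                  # steps 380, keep
        _track(4, [0, 300, 0, 300, 900], [0, 0, 0, 0, 0]),    # last step 600
    ]
    ts = TrackSet(tracks=tuple(tracks))
    kept = filter_tracks(ts, max_step_nm=390.0, min_frames=3)
    oracle = {
        t.track_id for t in tracks
        if len(t) >= 3 and (len(t) < 2 or t.steps_nm().max() <= 390.0)
    }
    assert {t.track_id for t in kept.tracks} == oracle == {0, 3}
    assert len(filter_tracks(TrackSet(tracks=()), 390.0, 3)) == 0


def test_filter_monotonicity():
    ts = simulate_tracks(SimParams(D_um2_s=0.3, n_particles=50, n_frames=30, seed=2))
    n = [len(filter_tracks(ts, max_step_nm=s, min_frames=3)) for s in (600, 390, 200)]
    assert n[0] >= n[1] >= n[2]
    m = [len(filter_tracks(ts, max_step_nm=390, min_frames=k)) for k in (2, 5, 20)]
    assert m[0] >= m[1] >= m[2]


def test_filter_parameter_unit_consistency():
    assert max_step_to_pixels(390.0, 130.0) == pytest.approx(3.0)
    assert min_lifetime_ms(3, 0.05) == pytest.approx(150.0)


def test_msd_zero_for_stationary_tracks():
    ts = TrackSet(tracks=(_track(0, [5] * 10, [5] * 10),))
    curve = msd_curve(ts)
    assert np.all(curve.msd_nm2 == 0.0)


def test_msd_pair_count_bookkeeping():
    ts = simulate_tracks(SimParams(n_particles=7, n_frames=15, seed=3))
    curve = msd_curve(ts, max_lag=10)
    for lag_s, n in zip(curve.lags_s, curve.n_pairs):
        k = int(round(lag_s / ts.frame_interval_s))
        assert n == sum(max(0, len(t) - k) for t in ts.tracks)


def test_msd_noise_plateau():
    """Stationary particles with localization noise sigma give an MSD
    plateau at 4 sigma^2 (independent errors at both time points)."""
    sigma = 30.0
    ts = simulate_tracks(SimParams(D_um2_s=0.0, sigma_nm=sigma, n_particles=500,
                                   n_frames=60, seed=4))
    curve = msd_curve(ts, max_lag=6)
    assert np.allclose(curve.msd_nm2, 4 * sigma ** 2, rtol=0.05)


def test_msd_slope_recovers_diffusion_coefficient():
    """Brownian tracks at D = 0.1 um^2/s, no localization error: OLS slope
    over the first four lags recovers 4D within 10%."""
    p = SimParams(D_um2_s=0.1, n_particles=1000, n_frames=100, sigma_nm=0.0, seed=5)
    curve = msd_curve(simulate_tracks(p), max_lag=8)
    d_est, intercept = estimate_D(curve)
    assert d_est == pytest.approx(0.1, rel=0.10)


def test_estimate_D_exact_line():
    d_true, c_true = 0.25, 1800.0  # um^2/s, nm^2
    lags = np.array([0.05, 0.10, 0.15, 0.20])
    msd = MSDCurve(lags_s=lags, msd_nm2=4 * d_true * 1e6 * lags + c_true,
                   n_pairs=np.array([40, 30, 20, 10]))
    d_est, c_est = estimate_D(msd)
    assert d_est == pytest.approx(d_true, rel=1e-9)
    assert c_est == pytest.approx(c_true, rel=1e-9)
    with pytest.raises(InsufficientLags):
        estimate_D(msd, n_lags=5)


def test_msd_requires_displacements():
    with pytest.raises(NoDisplacements):
        msd_curve(TrackSet(tracks=(_track(0, [0.0], [0.0]),)))


def test_intensity_background_modes():
    ts = TrackSet(tracks=(
        _track(0, [0, 0, 0], [0, 0, 0], intensity=[100, 100, 100]),
        _track(1, [0, 0, 0], [0, 0, 0], intensity=[450, 450, 450]),
    ))
    per_track, summary = intensity_distribution(ts, background=100.0)
    vals = dict(zip(per_track["track_id"], per_track["mean_intensity"]))
    assert vals[0] == 0.0 and vals[1] == 350.0
    _, auto = intensity_distribution(ts, background="auto")
    assert auto["background"] == pytest.approx(np.percentile([100] * 3 + [450] * 3, 10))
    with pytest.raises(NoIntensities):
        intensity_distribution(TrackSet(tracks=(_track(0, [0, 0], [0, 0]),)))


def test_monomer_vs_tetramer_intensity_ratio():
    """With equal unit intensity and no noise, pure 4-mer tracks average 4x
    the background-subtracted intensity of monomer tracks."""
    mono = simulate_tracks(SimParams(multimer_fraction=0.0, n_particles=50,
                                     n_frames=20, background=50.0, seed=6))
    tetra = simulate_tracks(SimParams(multimer_fraction=1.0, multimer_size=4,
                                      n_particles=50, n_frames=20,
                                      background=50.0, seed=7))
    _, s1 = intensity_distribution(mono, background=50.0)
    _, s4 = intensity_distribution(tetra, background=50.0)
    assert s4["mean"] / s1["mean"] == pytest.approx(4.0, rel=0.15)


def test_clustered_condition_shifts_intensity_distribution():
    """Across 20 replicate seed pairs, the half-4-mer condition's median
    track intensity exceeds the all-monomer condition's (rank test)."""
    mono_medians, clus_medians = [], []
    for seed in range(20):
        mono = simulate_tracks(SimParams(multimer_fraction=0.0, n_particles=60,
                                         n_frames=30, seed=1000 + seed))
        clus = simulate_tracks(SimParams(multimer_fraction=0.5, multimer_size=4,
                                         n_particles=60, n_frames=30, seed=2000 + seed))
        mono_medians.append(intensity_distribution(mono, background=50.0)[1]["median"])
        clus_medians.append(intensity_distribution(clus, background=50.0)[1]["median"])
    stat = mannwhitneyu(clus_medians, mono_medians, alternative="greater")
    assert stat.pvalue < 0.01
    assert np.median(clus_medians) > np.median(mono_medians)


def test_trackset_csv_roundtrip(tmp_path):
    ts = simulate_tracks(SimParams(n_particles=4, n_frames=6, seed=8))
    path = tmp_path / "tracks.csv"
    ts.to_csv(path)
    back = TrackSet.from_csv(path)
    assert len(back) == len(ts)
    for ta, tb in zip(ts.tracks, back.tracks):
        assert np.allclose(ta.x_nm, tb.x_nm, atol=1e-5)
        assert np.allclose(ta.intensity, tb.intensity, atol=1e-5)
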