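"""Extraction of subthreshold and action-potential features from sweeps.

Implements the standard current-clamp analysis battery for CA1 pyramidal
neurons:

* passive properties from the −25 pA step (input resistance, membrane time
  constant, resting potential);
* sag quantification on the sweep hyperpolarizing the cell closest to
  3 mV below baseline (delta sag peak, steady state, sag ratio);
* the impedance amplitude profile (ZAP) from a chirp sweep, via the ratio
  of voltage and current spectra, giving the resonance frequency F_res and
  the resonant classification (F_res > 1 Hz);
* spike detection and AP features from the first spike of the rheobase
  sweep: threshold at the 23 mV/ms slope crossing, amplitude, halfwidth,
  and mean up/downstroke between 30% and 70% of the AP amplitude.

Numerical conventions: baseline = mean of the 100 ms before stimulus
onset; steady state = mean of the final 200 ms of the step; sag peak
searched in the first 300 ms after onset; dV/dt by central differences at
native sampling; the ZAP is smoothed with a 0.25 Hz moving average before
the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .sweeps import Sweep, SweepSet

SPIKE_SLOPE_MV_PER_MS = 23.0
SPIKE_PEAK_MIN_MV = -20.0
SPIKE_PEAK_WINDOW_MS = 5.0
RESONANT_MIN_HZ = 1.0
SAG_TARGET_MV = -3.0
STEADY_STATE_WINDOW_S = 0.2
SAG_PEAK_WINDOW_S = 0.3
ZAP_SMOOTH_HZ = 0.25

# the 10-feature electrophysiology list of the morpho-electric table:
# passive/subthreshold (Rin, tau, sag ratio, F_res, rheobase) plus the five
# AP features of the first rheobase spike.  Resting potential is extracted
# too but not tabled (the protocol imposes −70 mV).
EPHYS_FEATURE_NAMES = (
    "input_resistance", "tau", "sag_ratio", "resonance_frequency",
    "rheobase", "ap_threshold", "ap_amplitude", "ap_halfwidth",
    "ap_upstroke", "ap_downstroke",
)


@dataclass
class PassiveFeatures:
    resting_potential_mv: float
    input_resistance_mohm: float
    tau_ms: float


@dataclass
class SagFeatures:
    delta_sag_peak_mv: float
    delta_steady_state_mv: float
    sag_ratio: float


@dataclass
class ResonanceProfile:
    f_hz: np.ndarray
    impedance_mohm: np.ndarray
    f_res_hz: float
    resonant: bool


@dataclass
class APFeatures:
    rheobase_pa: float
    threshold_mv: float
    amplitude_mv: float
    halfwidth_ms: float
    upstroke_mv_per_ms: float
    downstroke_mv_per_ms: float
    inst_freq_hz: float | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

def passive_features(sweeps: SweepSet, target_pa: float = -25.0) -> PassiveFeatures:
    """Input resistance, membrane time constant and resting potential.

    Uses the −25 pA sweep (or the nearest-amplitude hyperpolarizing sweep,
    with a warning).  R = |ΔV_ss|/|ΔI|; tau from a single-exponential least
    squares fit to the onset transient over [onset+2 ms, onset+150 ms].
    """
    hyper = sweeps.hyperpolarizing()
    if not hyper:
        raise ValueError("no hyperpolarizing sweep available for passive properties")
    sweep = min(hyper, key=lambda s: abs(s.step_amplitude() - target_pa))
    if abs(sweep.step_amplitude() - target_pa) > 1.0:
        warnings.warn(
            f"no {target_pa:g} pA sweep; using nearest amplitude "
            f"{sweep.step_amplitude():.0f} pA", UserWarning, stacklevel=2)

    baseline = sweep.baseline_voltage()
    amp = sweep.step_amplitude()
    ss = _steady_state_voltage(sweep)
    r_mohm = abs(ss - baseline) / abs(amp) * 1000.0

    # single-exponential fit to the charging transient
    mask = sweep.window(sweep.onset + 0.002, sweep.onset + 0.150)
    t_fit = (sweep.t[mask] - sweep.onset) * 1000.0  # ms
    v_fit = sweep.v[mask]
    tau = np.nan
    try:
        popt, _ = curve_fit(
            lambda t, v_inf, dv, tau: v_inf + dv * np.exp(-t / tau),
            t_fit, v_fit, p0=(ss, baseline - ss, 20.0),
            bounds=((-200, -200, 0.1), (100, 200, 1000)), maxfev=5000,
        )
        tau = float(popt[2])
    except RuntimeError:
        warnings.warn("tau fit failed; time constant recorded as missing",
                      UserWarning, stacklevel=2)
    return PassiveFeatures(resting_potential_mv=baseline,
                           input_resistance_mohm=float(r_mohm), tau_ms=tau)


def _steady_state_voltage(sweep: Sweep) -> float:
    mask = sweep.window(sweep.offset - STEADY_STATE_WINDOW_S, sweep.offset)
    return float(np.mean(sweep.v[mask]))


# ---------------------------------------------------------------------------
# sag
# ---------------------------------------------------------------------------

def select_sag_sweep(sweeps: SweepSet, baseline_mv: float | None = None) -> Sweep:
    """Sweep whose steady-state deviation is closest to −3 mV from baseline.

    Ties break toward the larger-magnitude current injection.
    """
    hyper = sweeps.hyperpolarizing()
    if not hyper:
        raise ValueError("no hyperpolarizing sweep available for sag analysis")

    def deviation(s: Sweep) -> float:
        base = baseline_mv if baseline_mv is not None else s.baseline_voltage()
        return _steady_state_voltage(s) - base

    return min(hyper, key=lambda s: (abs(deviation(s) - SAG_TARGET_MV),
                                     -abs(s.step_amplitude())))


def sag_features(sweep: Sweep) -> SagFeatures:
    """Delta sag peak, delta steady state and their ratio for one step sweep.

    Steady state = mean of the final 200 ms of the step; sag peak = voltage
    minimum within the first 300 ms after onset (window widened with a
    warning if the minimum sits on the window edge).
    """
    baseline = sweep.baseline_voltage()
    ss = _steady_state_voltage(sweep)
    delta_ss = baseline - ss  # positive for hyperpolarization
    window_s = SAG_PEAK_WINDOW_S
    while True:
        mask = sweep.window(sweep.onset, sweep.onset + window_s)
        idx = np.flatnonzero(mask)
        k = idx[int(np.argmin(sweep.v[mask]))]
        if k != idx[-1] or sweep.onset + window_s >= sweep.offset:
            break
        window_s = min(window_s * 2.0, sweep.offset - sweep.onset)
        warnings.warn("sag peak on search-window edge; window widened",
                      UserWarning, stacklevel=2)
    peak = float(sweep.v[k])
    delta_peak = max((baseline - peak) - delta_ss, 0.0)
    ratio = delta_peak / delta_ss if delta_ss != 0 else np.nan
    return SagFeatures(delta_sag_peak_mv=float(delta_peak),
                       delta_steady_state_mv=float(delta_ss),
                       sag_ratio=float(ratio))


# ---------------------------------------------------------------------------
# impedance / resonance
# ---------------------------------------------------------------------------

def impedance_profile(
    sweep: Sweep,
    f_lo_hz: float = 0.5,
    f_hi_hz: float | None = None,
) -> ResonanceProfile:
    """Impedance amplitude profile |FFT(V)/FFT(I)| over the chirp band.

    The band maximum defaults to the stimulated band recorded in the sweep
    metadata (or the highest frequency with appreciable stimulus power).
    F_res is the argmax after a 0.25 Hz moving-average smoothing; the cell
    is classified resonant when F_res exceeds 1 Hz.
    """
    if sweep.protocol != "chirp":
        raise ValueError("impedance profile requires a chirp sweep")
    # transform the full trace so the post-stimulus response tail is captured
    # (truncating at offset leaks the residual transient into the ratio)
    v = sweep.v - sweep.baseline_voltage()
    i = sweep.i - np.mean(sweep.i[sweep.window(0.0, sweep.onset)] if sweep.onset > 0
                          else 0.0)
    n = len(v)
    freqs = np.fft.rfftfreq(n, d=1.0 / sweep.fs)
    vf = np.fft.rfft(v)
    if_ = np.fft.rfft(i)

    if f_hi_hz is None:
        f_hi_hz = sweep.meta.get("f1_hz")
    if f_hi_hz is None:
        power = np.abs(if_)
        strong = freqs[power > 0.1 * power.max()]
        f_hi_hz = float(strong.max()) if len(strong) else freqs[-1]
    if f_lo_hz >= f_hi_hz:
        raise ValueError("requested band edges lie outside the stimulus band")

    band = (freqs >= f_lo_hz) & (freqs <= f_hi_hz)
    if not band.any():
        raise ValueError("no FFT bins inside the stimulated band")
    f_band = freqs[band]
    z = np.abs(vf[band] / if_[band]) * 1000.0  # mV/pA -> MΩ

    df = f_band[1] - f_band[0] if len(f_band) > 1 else ZAP_SMOOTH_HZ
    width = max(int(round(ZAP_SMOOTH_HZ / df)), 1)
    if width % 2 == 0:
        width += 1
    if width > 1:
        kernel = np.ones(width) / width
        z_smooth = np.convolve(z, kernel, mode="same")
        # fix up edge bias from the truncated kernel
        counts = np.convolve(np.ones_like(z), kernel, mode="same")
        z_smooth = z_smooth / counts
    else:
        z_smooth = z

    k = int(np.argmax(z_smooth))
    f_res = float(f_band[k])
    if k == 0:  # monotone-decreasing (low-pass) profile
        f_res = float(f_band[0])
    return ResonanceProfile(f_hz=f_band, impedance_mohm=z,
                            f_res_hz=f_res, resonant=bool(f_res > RESONANT_MIN_HZ))


# ---------------------------------------------------------------------------
# spikes and AP features
# ---------------------------------------------------------------------------

def detect_spikes(sweep: Sweep) -> np.ndarray:
    """Spike peak times (s): sustained 23 mV/ms dV/dt crossings followed by
    a voltage peak above −20 mV within 5 ms."""
    dt_ms = 1000.0 / sweep.fs
    dvdt = np.gradient(sweep.v, dt_ms)
    above = dvdt > SPIKE_SLOPE_MV_PER_MS
    # sustained: at least 2 consecutive samples above the slope criterion
    sustained = above & np.roll(above, -1)
    sustained[-1] = False
    crossings = np.flatnonzero(sustained & ~np.roll(sustained, 1))
    win = int(round(SPIKE_PEAK_WINDOW_MS / dt_ms))
    peaks = []
    last_peak = -np.inf
    for c in crossings:
        if c <= last_peak:
            continue
        seg = sweep.v[c:c + win]
        if len(seg) == 0:
            continue
        p = c + int(np.argmax(seg))
        if sweep.v[p] > SPIKE_PEAK_MIN_MV:
            peaks.append(p)
            last_peak = p
    return sweep.t[np.array(peaks, dtype=int)] if peaks else np.array([])


def _first_ap_features(sweep: Sweep, spike_times: np.ndarray) -> dict:
    dt_ms = 1000.0 / sweep.fs
    dvdt = np.gradient(sweep.v, dt_ms)
    peak_idx = int(round(spike_times[0] * sweep.fs))
    # refine to the local maximum
    lo = max(peak_idx - 2, 0)
    peak_idx = lo + int(np.argmax(sweep.v[lo:peak_idx + 3]))

    # threshold: start of the sustained slope-criterion run leading into the
    # peak, with the exact crossing interpolated between samples
    above = dvdt[:peak_idx] > SPIKE_SLOPE_MV_PER_MS
    run_end = int(np.flatnonzero(above)[-1])
    k = run_end
    while k > 0 and above[k - 1]:
        k -= 1
    if k > 0 and dvdt[k] != dvdt[k - 1]:
        frac = (SPIKE_SLOPE_MV_PER_MS - dvdt[k - 1]) / (dvdt[k] - dvdt[k - 1])
        frac = min(max(frac, 0.0), 1.0)
        threshold = float(sweep.v[k - 1] + frac * (sweep.v[k] - sweep.v[k - 1]))
    else:
        threshold = float(sweep.v[k])
    peak_v = float(sweep.v[peak_idx])
    amp = peak_v - threshold

    half_v = threshold + amp / 2.0
    up = np.flatnonzero(sweep.v[:peak_idx + 1] >= half_v)
    t_up = np.interp(half_v, sweep.v[up[0] - 1:up[0] + 1], sweep.t[up[0] - 1:up[0] + 1])
    after = sweep.v[peak_idx:]
    down = np.flatnonzero(after <= half_v)
    j = peak_idx + down[0]
    t_down = np.interp(-half_v, -sweep.v[j - 1:j + 1], sweep.t[j - 1:j + 1])
    halfwidth_ms = (t_down - t_up) * 1000.0

    # mean rising/falling speed between 30% and 70% of the AP: the band mean
    # of dV/dt equals ΔV/Δt between the interpolated band-crossing times
    lo_v, hi_v = threshold + 0.3 * amp, threshold + 0.7 * amp
    rise_t = sweep.t[k:peak_idx + 1] * 1000.0
    rise_v = sweep.v[k:peak_idx + 1]
    t30_up = float(np.interp(lo_v, rise_v, rise_t))
    t70_up = float(np.interp(hi_v, rise_v, rise_t))
    upstroke = 0.4 * amp / (t70_up - t30_up) if t70_up > t30_up else np.nan
    tail = min(peak_idx + int(round(10.0 / dt_ms)), len(sweep.v))
    fall_t = sweep.t[peak_idx:tail] * 1000.0
    fall_v = sweep.v[peak_idx:tail]
    t70_dn = float(np.interp(-hi_v, -fall_v, fall_t))
    t30_dn = float(np.interp(-lo_v, -fall_v, fall_t))
    downstroke = -0.4 * amp / (t30_dn - t70_dn) if t30_dn > t70_dn else np.nan
    return {
        "threshold_mv": threshold, "peak_mv": peak_v, "amplitude_mv": amp,
        "halfwidth_ms": float(halfwidth_ms),
        "upstroke_mv_per_ms": upstroke, "downstroke_mv_per_ms": downstroke,
    }


def rheobase_and_ap_features(sweeps: SweepSet) -> APFeatures:
    """AP features from the first spike of the rheobase sweep.

    The rheobase is the smallest depolarizing step amplitude that elicits
    at least one spike.  All missing (NaN) with a warning when no sweep up
    to the protocol maximum spikes.
    """
    depol = sorted(sweeps.depolarizing(), key=lambda s: s.step_amplitude())
    if not depol:
        raise ValueError("no depolarizing sweeps available")
    for sweep in depol:
        times = detect_spikes(sweep)
        if len(times) > 0:
            feats = _first_ap_features(sweep, times)
            inst = None
            if len(times) >= 2:
                inst = float(1.0 / (times[1] - times[0]))
            return APFeatures(
                rheobase_pa=float(sweep.step_amplitude()),
                threshold_mv=feats["threshold_mv"],
                amplitude_mv=feats["amplitude_mv"],
                halfwidth_ms=feats["halfwidth_ms"],
                upstroke_mv_per_ms=feats["upstroke_mv_per_ms"],
                downstroke_mv_per_ms=feats["downstroke_mv_per_ms"],
                inst_freq_hz=inst,
                meta={"peak_mv": feats["peak_mv"],
                      "n_spikes": int(len(times)),
                      "burst_candidate": bool(inst is not None and inst > 100.0)},
            )
    warnings.warn("no spike up to the maximal current injection; AP features missing",
                  UserWarning, stacklevel=2)
    return APFeatures(rheobase_pa=np.nan, threshold_mv=np.nan, amplitude_mv=np.nan,
                      halfwidth_ms=np.nan, upstroke_mv_per_ms=np.nan,
                      downstroke_mv_per_ms=np.nan, inst_freq_hz=None)


# ---------------------------------------------------------------------------
# one-call cell summary
# ---------------------------------------------------------------------------

def extract_ephys_features(step_sweeps: SweepSet, chirp: Sweep | None) -> dict[str, float]:
    """The 10-feature electrophysiology record for one cell."""
    passive = passive_features(step_sweeps)
    sag = sag_features(select_sag_sweep(step_sweeps))
    f_res = np.nan
    if chirp is not None:
        f_res = impedance_profile(chirp).f_res_hz
    try:
        ap = rheobase_and_ap_features(step_sweeps)
    except ValueError:
        ap = APFeatures(*([np.nan] * 6))
    return {
        "input_resistance": passive.input_resistance_mohm,
        "tau": passive.tau_ms,
        "sag_ratio": sag.sag_ratio,
        "resonance_frequency": f_res,
        "rheobase": ap.rheobase_pa,
        "ap_threshold": ap.threshold_mv,
        "ap_amplitude": ap.amplitude_mv,
        "ap_halfwidth": ap.halfwidth_ms,
        "ap_upstroke": ap.upstroke_mv_per_ms,
        "ap_downstroke": ap.downstroke_mv_per_ms,
        "resting_potential": passive.resting_potential_mv,
    }
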