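"""Linearized resonant membrane model with closed-form impedance.

The subthreshold membrane is modelled as the minimal linear resonator:

    C dv/dt    = -g_L v - g_h w + I(t)
    tau_h dw/dt = v - w

where ``v`` is the voltage deviation from rest (mV), ``w`` a slow
h-current (HCN) activation variable, ``C`` capacitance (pF), ``g_L`` leak
conductance (nS), ``g_h`` the linearized h-conductance (nS) and ``tau_h``
its activation time constant (ms).  This is the standard phenomenological
linearization of I_h around rest: the slow feedback opposing voltage
deviations produces both the depolarizing "sag" rebound during
hyperpolarizing steps and subthreshold resonance under chirp stimulation.

The model has the closed-form impedance

    Z(omega) = 1 / (g_L + i omega C + g_h / (1 + i omega tau_h))

which serves as the independent oracle for every subthreshold feature the
extraction pipeline measures.  Simulation uses exact matrix-exponential
stepping (zero-order hold on the current), so there is no integration
error beyond the stimulus sampling itself.

Units: pF/nS give time in ms and pA/nS give mV; impedances are reported
in MΩ (1 mV/pA = 1000 MΩ).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.optimize import brentq, minimize_scalar

from .sweeps import Sweep, SweepSet, chirp_current, step_current

BASELINE_MV = -70.0


@dataclass
class MembraneParams:
    c_pf: float = 500.0
    g_l_ns: float = 25.0
    e_l_mv: float = BASELINE_MV
    g_h_ns: float = 15.0
    tau_h_ms: float = 50.0
    noise_sd_mv: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.c_pf <= 0 or self.g_l_ns <= 0 or self.tau_h_ms <= 0:
            raise ValueError("C, g_L and tau_h must be positive")
        if self.g_h_ns < 0:
            raise ValueError("g_h must be non-negative")

    @property
    def input_resistance_mohm(self) -> float:
        """DC input resistance |Z(0)| = 1/(g_L + g_h) in MΩ."""
        return 1000.0 / (self.g_l_ns + self.g_h_ns)


def analytic_impedance(params: MembraneParams, f_hz) -> np.ndarray:
    """Closed-form complex impedance Z(f) in MΩ."""
    w = 2.0 * np.pi * np.asarray(f_hz, dtype=float) * 1e-3  # rad/ms
    y_ns = (params.g_l_ns + 1j * w * params.c_pf
            + params.g_h_ns / (1.0 + 1j * w * params.tau_h_ms))
    return 1000.0 / y_ns


def resonance_argmax(params: MembraneParams, f_max_hz: float = 100.0) -> float:
    """Frequency (Hz) maximizing |Z|, by dense grid + golden refinement."""
    grid = np.linspace(0.0, f_max_hz, 4001)
    mags = np.abs(analytic_impedance(params, grid))
    k = int(np.argmax(mags))
    if k == 0:
        return 0.0
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda f: -np.abs(analytic_impedance(params, f)),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def calibrate_h_conductance(
    target_f_res_hz: float,
    base: MembraneParams,
    g_h_max_ns: float = 2000.0,
) -> MembraneParams:
    """Find g_h so the analytic |Z| peaks at ``target_f_res_hz``.

    The peak frequency is monotone increasing in g_h at fixed C, g_L and
    tau_h; a target of 0 (non-resonant) returns g_h = 0.  Raises
    ``ValueError`` with the achievable range for unattainable targets.
    """
    if target_f_res_hz <= 0:
        return replace(base, g_h_ns=0.0)

    def peak(g_h):
        return resonance_argmax(replace(base, g_h_ns=g_h))

    f_hi = peak(g_h_max_ns)
    if target_f_res_hz > f_hi:
        raise ValueError(
            f"target {target_f_res_hz} Hz unachievable; range is (0, {f_hi:.2f}] Hz "
            f"for g_h <= {g_h_max_ns} nS at tau_h = {base.tau_h_ms} ms"
        )
    g = brentq(lambda g_h: peak(g_h) - target_f_res_hz, 1e-9, g_h_max_ns, xtol=1e-6)
    return replace(base, g_h_ns=float(g))


# ---------------------------------------------------------------------------
# closed-form step response (eigen-decomposition oracle)
# ---------------------------------------------------------------------------

def _state_matrices(params: MembraneParams):
    a = np.array([
        [-params.g_l_ns / params.c_pf, -params.g_h_ns / params.c_pf],
        [1.0 / params.tau_h_ms, -1.0 / params.tau_h_ms],
    ])
    b = np.array([1.0 / params.c_pf, 0.0])
    return a, b


def analytic_step_response(params: MembraneParams, i_pa: float, t_ms) -> np.ndarray:
    """Voltage deviation (mV) to a current step of ``i_pa`` starting at t = 0.

    Computed from the eigen-decomposition of the 2-variable system:
    v(t) = v_inf + sum_i c_i exp(lambda_i t).  This is the two-exponential
    closed form used as the sag-feature oracle.
    """
    t = np.asarray(t_ms, dtype=float)
    a, b = _state_matrices(params)
    x_inf = np.linalg.solve(a, -b * i_pa)
    lam, vecs = np.linalg.eig(a.astype(complex))
    coef = np.linalg.solve(vecs, -x_inf.astype(complex))
    v = x_inf[0] + np.real(vecs[0, :] @ (coef[:, None] * np.exp(lam[:, None] * t[None, :])))
    return v


def analytic_sag_ratio(
    params: MembraneParams,
    peak_window_ms: float = 300.0,
    t_end_ms: float = 1000.0,
) -> float:
    """Sag ratio of the closed-form hyperpolarizing step response.

    (peak deviation − steady-state deviation) / steady-state deviation;
    amplitude-independent for a linear model.
    """
    t = np.linspace(0.0, t_end_ms, 20001)
    v = analytic_step_response(params, -100.0, t)
    ss = v[-1]
    peak = np.min(v[t <= peak_window_ms])
    return float((peak - ss) / ss)


def calibrate_sag_ratio(
    target_ratio: float,
    base: MembraneParams,
    g_h_max_ns: float = 2000.0,
) -> MembraneParams:
    """Find g_h so the closed-form step response has the target sag ratio."""
    if target_ratio <= 0:
        return replace(base, g_h_ns=0.0)

    def ratio(g_h):
        return analytic_sag_ratio(replace(base, g_h_ns=g_h))

    hi = ratio(g_h_max_ns)
    if target_ratio > hi:
        raise ValueError(
            f"target sag ratio {target_ratio} unachievable; max {hi:.3f} "
            f"for g_h <= {g_h_max_ns} nS at tau_h = {base.tau_h_ms} ms"
        )
    g = brentq(lambda g_h: ratio(g_h) - target_ratio, 1e-9, g_h_max_ns, xtol=1e-8)
    return replace(base, g_h_ns=float(g))


# ---------------------------------------------------------------------------
# simulation (exact discrete stepping)
# ---------------------------------------------------------------------------

def simulate_membrane(
    params: MembraneParams,
    t_s: np.ndarray,
    i_pa: np.ndarray,
    onset_s: float,
    offset_s: float,
    protocol: str = "step",
    fs_hz: float | None = None,
) -> Sweep:
    """Integrate the linear model exactly over a sampled current stimulus.

    The two-variable system is diagonalized and each mode advanced with the
    exact zero-order-hold update z[n+1] = e^{λ dt} z[n] + (e^{λ dt}−1)/λ β u[n],
    implemented as a first-order recursive filter, so accuracy does not
    depend on the sampling rate beyond the stimulus discretization itself.
    Additive Gaussian voltage noise (``noise_sd_mv``, by ``seed``) is applied
    after integration.
    """
    t_s = np.asarray(t_s, float)
    i_pa = np.asarray(i_pa, float)
    if fs_hz is None:
        fs_hz = 1.0 / (t_s[1] - t_s[0])
    dt_ms = 1000.0 / fs_hz

    a, b = _state_matrices(params)
    lam, vecs = np.linalg.eig(a.astype(complex))
    beta = np.linalg.solve(vecs, b.astype(complex))
    v = np.zeros(len(t_s))
    for k in range(2):
        ed = np.exp(lam[k] * dt_ms)
        bd = (ed - 1.0) / lam[k] * beta[k]
        # z[n] response with one-step input delay: z[0]=0, z[n+1]=ed z[n]+bd u[n]
        zi = signal.lfilter([0.0, bd], [1.0, -ed], i_pa)
        v = v + np.real(vecs[0, k] * zi)

    if params.noise_sd_mv > 0:
        rng = np.random.default_rng(params.seed)
        v = v + rng.normal(0.0, params.noise_sd_mv, size=len(v))

    return Sweep(t=t_s, i=i_pa.copy(), v=params.e_l_mv + v, fs=fs_hz,
                 onset=onset_s, offset=offset_s, protocol=protocol)


def simulate_step_family(
    params: MembraneParams,
    amps_pa=None,
    fs_hz: float = 20000.0,
    pre_s: float = 0.2,
    dur_s: float = 1.0,
    post_s: float = 0.3,
) -> SweepSet:
    """The standard hyperpolarizing step protocol: −150 pA rising by +25 pA."""
    if amps_pa is None:
        amps_pa = np.arange(-150.0, 0.0, 25.0)
    sweeps = []
    for k, amp in enumerate(amps_pa):
        t, i, onset, offset = step_current(amp, fs_hz, pre_s, dur_s, post_s)
        p = params if params.seed is None else replace(params, seed=params.seed + k)
        sweeps.append(simulate_membrane(p, t, i, onset, offset, "step", fs_hz))
    return SweepSet(sweeps)


def simulate_chirp(
    params: MembraneParams,
    amp_pa: float = 100.0,
    f0_hz: float = 0.5,
    f1_hz: float = 30.0,
    dur_s: float = 10.0,
    fs_hz: float = 20000.0,
) -> Sweep:
    t, i, onset, offset = chirp_current(amp_pa, f0_hz, f1_hz, dur_s, fs_hz)
    sweep = simulate_membrane(params, t, i, onset, offset, "chirp", fs_hz)
    sweep.meta.update({"f0_hz": f0_hz, "f1_hz": f1_hz, "dur_s": dur_s})
    return sweep


# ---------------------------------------------------------------------------
# action-potential templates
# ---------------------------------------------------------------------------

@dataclass
class APTemplate:
    """Stereotyped spike waveform added onto a subthreshold sweep.

    Gaussian rising and falling flanks of widths ``rise_w_ms`` / ``fall_w_ms``
    carry the voltage from the local baseline to ``peak_mv``.  The waveform
    is analytic, so ground-truth features can be evaluated on an arbitrarily
    dense time grid.
    """

    peak_mv: float = 35.0
    rise_w_ms: float = 0.45
    fall_w_ms: float = 0.9
    span_sd: float = 4.0  # half-duration of the template in flank widths

    def duration_ms(self) -> float:
        return self.span_sd * (self.rise_w_ms + self.fall_w_ms)

    def waveform(self, t_ms: np.ndarray, baseline_mv: float) -> np.ndarray:
        """Voltage (mV) at times relative to the spike peak (t = 0)."""
        amp = self.peak_mv - baseline_mv
        w = np.where(t_ms < 0, self.rise_w_ms, self.fall_w_ms)
        return baseline_mv + amp * np.exp(-((t_ms / w) ** 2))


def template_ground_truth(template: APTemplate, baseline_mv: float,
                          oversample: int = 100, fs_hz: float = 20000.0) -> dict:
    """Reference AP features from a densely sampled template evaluation.

    Threshold is the voltage where dV/dt first exceeds 23 mV/ms on the
    rising flank; amplitude = peak − threshold; halfwidth by linear
    interpolation at half-amplitude; up/downstroke are mean dV/dt where the
    voltage lies between 30% and 70% of the amplitude above threshold.
    """
    dt = 1000.0 / (fs_hz * oversample)
    half = template.duration_ms() / 2.0
    t = np.arange(-half, half + dt, dt)
    v = template.waveform(t, baseline_mv)
    dvdt = np.gradient(v, dt)
    peak_idx = int(np.argmax(v))
    rising = np.flatnonzero((dvdt[: peak_idx] > 23.0))
    thr_idx = rising[0]
    threshold = float(v[thr_idx])
    peak = float(v[peak_idx])
    amp = peak - threshold
    half_v = threshold + amp / 2.0
    up_t = float(np.interp(half_v, v[: peak_idx + 1], t[: peak_idx + 1]))
    down_t = float(np.interp(-half_v, -v[peak_idx:], t[peak_idx:]))
    lo, hi = threshold + 0.3 * amp, threshold + 0.7 * amp
    up_band = (v[: peak_idx] >= lo) & (v[: peak_idx] <= hi)
    down_band = (v[peak_idx:] >= lo) & (v[peak_idx:] <= hi)
    return {
        "threshold_mv": threshold,
        "peak_mv": peak,
        "amplitude_mv": amp,
        "halfwidth_ms": down_t - up_t,
        "upstroke_mv_per_ms": float(np.mean(dvdt[: peak_idx][up_band])),
        "downstroke_mv_per_ms": float(np.mean(dvdt[peak_idx:][down_band])),
    }


def inject_ap_templates(
    sweep: Sweep,
    template: APTemplate,
    spike_times_s,
) -> tuple[Sweep, dict]:
    """Add template spikes to a sweep at the given times (of the peaks).

    Returns the new sweep and the dense-evaluation ground-truth features
    (computed at ×100 oversampling).  Spike times closer together than the
    template duration raise ``ValueError``.
    """
    spike_times_s = np.sort(np.asarray(spike_times_s, float))
    min_gap = template.duration_ms() / 1000.0
    if len(spike_times_s) > 1 and np.min(np.diff(spike_times_s)) < min_gap:
        raise ValueError("overlapping AP templates: spike times closer than the template duration")
    v = sweep.v.copy()
    baselines = []
    for ts in spike_times_s:
        k = int(round(ts * sweep.fs))
        base = float(sweep.v[k])
        baselines.append(base)
        rel_ms = (sweep.t - ts) * 1000.0
        mask = np.abs(rel_ms) <= template.duration_ms() / 2.0
        v[mask] = template.waveform(rel_ms[mask], base)
    out = Sweep(t=sweep.t, i=sweep.i, v=v, fs=sweep.fs, onset=sweep.onset,
                offset=sweep.offset, protocol=sweep.protocol,
                meta={**sweep.meta, "spike_times_s": list(map(float, spike_times_s))})
    truth = template_ground_truth(template, baselines[0] if baselines else BASELINE_MV,
                                  fs_hz=sweep.fs)
    truth["spike_times_s"] = list(map(float, spike_times_s))
    return out, truth
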