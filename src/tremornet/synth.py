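"""Synthetic labelled LFP+EMG recordings and benchmark signals.

The generator encodes exactly the dynamical premise the detection method
tests: atremorous (NT) subthalamic activity is a linear stochastic process
(band-limited 10-30 Hz Gaussian background plus white measurement noise),
overt tremor (T) activity is a nonlinear oscillator (a Roessler
system rescaled so its dominant frequency equals the tremor frequency)
mixed into the linear background, and the tremor-onset transition (TO)
cross-fades between the two following a sigmoid nonlinearity ramp, so the
LFP's nonlinearity rises before the tremor is fully established. The EMG is
a >30 Hz band-limited carrier whose amplitude is modulated by tremor-locked
bursts that only start midway through TO -- the electrophysiological change
leads the symptom, which is the property a demand-driven stimulator
exploits. Tremor offset is abrupt. Ground-truth labels follow the
construction exactly and all randomness flows from one seeded generator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import LabelTrack, Recording, ValidationError

#: Dominant cyclic frequency (cycles per unit time) of the canonical
#: Roessler system (a=b=0.2, c=5.7); used to rescale time so the x-component
#: oscillates at the requested tremor frequency.
ROESSLER_BASE_FREQ = 0.1720
#: Same for the Lorenz system's dominant oscillation around one lobe.
LORENZ_PARAMS = (10.0, 28.0, 8.0 / 3.0)


@dataclass
class ScenarioSpec:
    """Construction plan for one labelled synthetic recording.

    Durations are seconds of NT, TO, T and trailing NT (``post_s``); the NT
    segment must be non-empty, the others may be zero. ``snr_db`` is the
    power ratio of the structured LFP to the added white noise.
    """

    nt_s: float = 15.0
    to_s: float = 10.0
    t_s: float = 15.0
    post_s: float = 10.0
    rate: float = 1000.0
    tremor_freq: float = 5.0
    snr_db: float = 10.0
    ramp: str = "sigmoid"          # or "linear"
    tremor_mix: float = 0.8        # nonlinear-source weight reached in T
    tremor_gain: float = 2.0       # amplitude of tremor source vs NT source
    emg_burst_gain: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nt_s <= 0:
            raise ValidationError("nt_s must be positive")
        for name in ("to_s", "t_s", "post_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 2 < self.tremor_freq < 45:
            raise ValidationError("tremor_freq must lie in (2, 45) Hz")
        if self.rate <= 4 * self.tremor_freq:
            raise ValidationError("rate too low for the requested tremor frequency")
        if self.ramp not in ("sigmoid", "linear"):
            raise ValidationError("ramp must be 'sigmoid' or 'linear'")

    @property
    def duration(self) -> float:
        return self.nt_s + self.to_s + self.t_s + self.post_s


def _rk4(deriv, state: np.ndarray, dt: float, n_steps: int,
         keep_every: int, n_discard: int) -> np.ndarray:
    out = np.empty(((n_steps - n_discard) // keep_every, len(state)))
    j = 0
    for i in range(n_steps):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= n_discard and (i - n_discard) % keep_every == 0 and j < out.shape[0]:
            out[j] = state
            j += 1
    return out[:j]


def _roessler_x(n: int, samples_per_cycle: float, rng: np.random.Generator,
                a: float = 0.2, b: float = 0.2, c: float = 5.7) -> np.ndarray:
    """x-component of the Roessler system, ``samples_per_cycle`` per orbit."""
    dt_sample = 1.0 / (ROESSLER_BASE_FREQ * samples_per_cycle)
    substeps = max(1, int(np.ceil(dt_sample / 0.03)))
    dt = dt_sample / substeps
    x0 = np.array([1.0, 1.0, 0.0]) + 0.5 * rng.standard_normal(3)

    def deriv(s):
        x, y, z = s
        return np.array([-y - z, x + a * y, b + z * (x - c)])

    n_discard = int(50 / dt)  # 50 time units of transient
    traj = _rk4(deriv, x0, dt, n_steps=n_discard + n * substeps + substeps,
                keep_every=substeps, n_discard=n_discard)
    return traj[:n, 0]


def _lorenz_x(n: int, dt: float, rng: np.random.Generator | None) -> np.ndarray:
    sig, rho, beta = LORENZ_PARAMS
    x0 = np.array([1.0, 1.0, 20.0])
    if rng is not None:
        x0 = x0 + 0.5 * rng.standard_normal(3)

    def deriv(s):
        x, y, z = s
        return np.array([sig * (y - x), x * (rho - z) - y, x * y - beta * z])

    n_discard = int(20 / dt)
    traj = _rk4(deriv, x0, dt, n_steps=n_discard + n + 1,
                keep_every=1, n_discard=n_discard)
    return traj[:n, 0]


def _ar2(n: int, rate: float, rng: np.random.Generator,
         peak_hz: float = 20.0, pole_radius: float = 0.95) -> np.ndarray:
    """Second-order autoregression resonating at ``peak_hz``."""
    w = 2 * np.pi * peak_hz / rate
    coeffs = [1.0, -2 * pole_radius * np.cos(w), pole_radius ** 2]
    x = sps.lfilter([1.0], coeffs, rng.standard_normal(n + int(rate)))
    return x[int(rate):]  # drop filter warm-up


def _bandlimited_noise(n: int, rate: float, rng: np.random.Generator,
                       band: tuple[float, float] = (10.0, 30.0)) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` by a Hamming-window FIR.

    The atremorous LFP background: a broad beta-range linear stochastic
    process. A plain low-order autoregression cannot realise a clean
    10-30 Hz band at these sampling rates -- a moderate pole radius leaks
    most of its power below 8 Hz while a near-unit radius degenerates into a
    quasi-sinusoid whose windows mimic low-dimensional structure -- so the
    band is imposed directly in the frequency domain.
    """
    order = 300
    taps = sps.firwin(order + 1, band, pass_zero=False, fs=rate,
                      window="hamming")
    x = sps.lfilter(taps, 1.0, rng.standard_normal(n + order + 1))
    return x[order + 1:]


def _unit_std(x: np.ndarray) -> np.ndarray:
    s = np.std(x)
    return x / s if s > 0 else x


def _mix_schedule(spec: ScenarioSpec, n: int) -> np.ndarray:
    """Nonlinear-source weight alpha(t): 0 in NT, ramp in TO, tremor_mix in T."""
    t = np.arange(n) / spec.rate
    alpha = np.zeros(n)
    to_start, t_start = spec.nt_s, spec.nt_s + spec.to_s
    t_end = t_start + spec.t_s
    in_to = (t >= to_start) & (t < t_start)
    if spec.to_s > 0:
        u = (t[in_to] - to_start) / spec.to_s
        if spec.ramp == "sigmoid":
            alpha[in_to] = 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))
        else:
            alpha[in_to] = u
    alpha[(t >= t_start) & (t < t_end)] = 1.0
    return spec.tremor_mix * alpha


def generate_recording(spec: ScenarioSpec) -> tuple[Recording, Recording, LabelTrack]:
    """Labelled synthetic LFP + EMG pair; bit-identical under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    nt_src = _unit_std(_bandlimited_noise(n, spec.rate, rng))
    alpha = _mix_schedule(spec, n)
    if spec.to_s + spec.t_s > 0:
        ross = _unit_std(_roessler_x(
            n, samples_per_cycle=spec.rate / spec.tremor_freq, rng=rng))
        clean = (1 - alpha) * nt_src + alpha * spec.tremor_gain * ross
    else:
        clean = nt_src
    noise_std = np.std(clean) * 10 ** (-spec.snr_db / 20)
    lfp = clean + noise_std * rng.standard_normal(n)

    # EMG: band-limited >30 Hz carrier, tremor-locked bursts from mid-TO to T end
    carrier_taps = sps.firwin(251, [35.0, min(150.0, spec.rate / 2 - 1)],
                              pass_zero=False, fs=spec.rate)
    carrier = _unit_std(sps.lfilter(carrier_taps, 1.0, rng.standard_normal(n)))
    t = np.arange(n) / spec.rate
    burst_start = spec.nt_s + spec.to_s / 2
    burst_end = spec.nt_s + spec.to_s + spec.t_s
    gate = ((t >= burst_start) & (t < burst_end)).astype(float)
    burst = np.maximum(0.0, np.sin(2 * np.pi * spec.tremor_freq * t)) ** 2
    emg = (1.0 + spec.emg_burst_gain * gate * burst) * carrier

    segs = []
    cursor = 0.0
    for dur, state in ((spec.nt_s, "NT"), (spec.to_s, "TO"),
                       (spec.t_s, "T"), (spec.post_s, "NT")):
        if dur > 0:
            segs.append((cursor, cursor + dur, state))
            cursor += dur
    return (
        Recording(lfp, rate=spec.rate, role="LFP"),
        Recording(emg, rate=spec.rate, role="EMG"),
        LabelTrack(segs),
    )


def generate_benchmark_signals(kind: str, n: int, seed: int = 0,
                               **kwargs) -> np.ndarray:
    """Canonical test signals: sine, white_noise, lorenz, rossler or ar2.

    The chaotic systems are integrated with a fixed-step 4th-order
    Runge-Kutta scheme and transients are discarded; ``seed`` perturbs their
    initial condition (and seeds the stochastic kinds) deterministically.
    """
    rng = np.random.default_rng(seed)
    if kind == "sine":
        period = kwargs.get("period", 40)
        amp = kwargs.get("amplitude", 1.0)
        return amp * np.sin(2 * np.pi * np.arange(n) / period)
    if kind == "white_noise":
        return rng.standard_normal(n)
    if kind == "lorenz":
        return _lorenz_x(n, dt=kwargs.get("dt", 0.01), rng=rng)
    if kind == "rossler":
        return _roessler_x(n, samples_per_cycle=kwargs.get("samples_per_cycle", 100),
                           rng=rng)
    if kind == "ar2":
        rate = kwargs.get("rate", 125.0)
        return _ar2(n, rate, rng, peak_hz=kwargs.get("peak_hz", 20.0))
    raise ValidationError(f"unknown benchmark kind {kind!r}")
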