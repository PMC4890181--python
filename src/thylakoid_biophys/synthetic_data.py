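"""Synthetic-data generators with known ground truth for every analysis stage.

Each generator emulates one measurement type of the thylakoid channel study:

* stochastically gated single-channel currents in a planar bilayer
  (two-state Markov gating with voltage-dependent opening, conductance
  substates and independent multi-channel superposition),
* electrochromic-shift (ECS) traces with single-turnover flashes and
  600-ms dark-interval relaxation toward an inverted quasi-stable level,
* PAM fluorescence traces with periodic saturating pulses built by inverting
  the NPQ and Phi_II definitions,
* SANS curves following the lamellar model
  I(q) = I0 + A q^(-p) + B exp(-(q-q*)^2 / (2 c^2)) with multiplicative
  counting-like noise,
* CD spectra as Gaussian bands on a polynomial baseline.

All randomness flows from one integer seed per generator call through
``numpy.random.default_rng``; per-trace substreams are spawned with
``numpy.random.SeedSequence`` so fixed seeds give bit-identical output.
Ground-truth parameters are recorded in the ``metadata`` of every output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np

from .datatypes import (
    CdSpectrum,
    CurrentTrace,
    EcsProtocol,
    EcsTrace,
    FluorTrace,
    IonicCondition,
    SansCurve,
    symmetric_kcl,
    thermal_voltage_mv,
)


# --------------------------------------------------------------------------
# Single-channel gating
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGatingParams:
    """Two-state (closed/open) Markov gating model of a voltage-dependent
    anion channel.

    The opening rate carries the voltage dependence through a Boltzmann
    factor, ``k_open(V) = k_open_0 * exp(z_gate * V / (RT/F))`` with V in mV,
    so a positive ``z_gate`` makes the channel more active at positive
    voltages; the closing rate is voltage independent. The unitary current is
    ``i(V) = gamma(V) * (V - v_rev) / 1000`` pA with the conductance branch
    chosen by the sign of ``V - v_rev``. Each opening is a substate (current
    scaled by ``substate_fraction``) with probability ``substate_prob``.
    ``n_channels`` independent copies superpose to emulate cooperative
    multi-channel records.
    """

    gamma_pos_ps: float = 96.1  # conductance at V > v_rev
    gamma_neg_ps: float = 60.0  # conductance at V < v_rev
    v_rev_mv: float = 0.0
    k_open_0: float = 50.0  # opening rate at 0 mV, 1/s
    z_gate: float = 0.3  # dimensionless voltage sensitivity of opening
    k_close: float = 50.0  # 1/s, voltage independent
    n_channels: int = 1
    substate_fraction: float = 0.5
    substate_prob: float = 0.0

    def __post_init__(self):
        if not (self.gamma_pos_ps > 0 and self.gamma_neg_ps > 0):
            raise ValueError("conductances must be > 0")
        if self.k_open_0 < 0 or self.k_close < 0:
            raise ValueError("rates must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for name in ("substate_fraction", "substate_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def k_open(self, v_mv: float, temperature_k: float = 298.15) -> float:
        """Opening rate at holding potential ``v_mv``."""
        return self.k_open_0 * np.exp(self.z_gate * v_mv / thermal_voltage_mv(temperature_k))

    def unitary_current_pa(self, v_mv: float) -> float:
        """Full-open unitary current at ``v_mv`` (0 at the reversal potential)."""
        dv = v_mv - self.v_rev_mv
        gamma = self.gamma_pos_ps if dv > 0 else self.gamma_neg_ps
        return gamma * dv / 1000.0

    def open_probability(self, v_mv: float, temperature_k: float = 298.15) -> float:
        """Stationary open probability of one channel at ``v_mv``."""
        ko = self.k_open(v_mv, temperature_k)
        if ko == 0.0:
            return 0.0
        if self.k_close == 0.0:
            return 1.0
        return ko / (ko + self.k_close)


@dataclass(frozen=True)
class RecordingConfig:
    """Recording conditions shared by a set of simulated sweeps."""

    ionic: IonicCondition = field(default_factory=symmetric_kcl)
    holding_potentials_mv: tuple = (40.0, 60.0, 80.0)
    duration_s: float = 60.0
    sampling_rate_hz: float = 5000.0
    noise_sd_pa: float = 0.8
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "holding_potentials_mv",
            tuple(float(v) for v in self.holding_potentials_mv),
        )
        if self.duration_s * self.sampling_rate_hz < 10:
            raise ValueError("trace must contain at least 10 samples")
        if self.noise_sd_pa < 0:
            raise ValueError("noise_sd_pa must be >= 0")


def _gating_segments(rng, k_open, k_close, duration_s, substate_fraction,
                     substate_prob):
    """Gillespie simulation of one channel; returns (segment starts, levels).

    Segment i spans [starts[i], starts[i+1]) at open-fraction ``levels[i]``
    (0 closed, 1 open, substate_fraction for a substate opening); the last
    segment extends to the end of the sweep.
    """
    if k_open == 0.0:
        p_open0 = 0.0
    elif k_close == 0.0:
        p_open0 = 1.0
    else:
        p_open0 = k_open / (k_open + k_close)
    is_open = rng.random() < p_open0
    starts = [0.0]
    levels = []
    while starts[-1] < duration_s:
        if is_open:
            frac = substate_fraction if (
                substate_prob > 0.0 and rng.random() < substate_prob
            ) else 1.0
            levels.append(frac)
            rate = k_close
        else:
            levels.append(0.0)
            rate = k_open
        if rate <= 0.0:
            break  # absorbing state: segment runs to the end
        starts.append(starts[-1] + rng.exponential(1.0 / rate))
        is_open = not is_open
    return np.asarray(starts[: len(levels)]), np.asarray(levels)


def simulate_channel_trace(
    params: ChannelGatingParams, config: RecordingConfig
) -> list:
    """Simulate one :class:`CurrentTrace` per holding potential.

    Each channel gates as a continuous-time Markov chain started from its
    stationary distribution and is sampled onto the uniform recording grid;
    open samples contribute the unitary current (scaled for substates),
    channels superpose independently, and Gaussian recording noise of
    standard deviation ``config.noise_sd_pa`` is added.
    """
    n_samples = int(round(config.duration_s * config.sampling_rate_hz))
    t = np.arange(n_samples) / config.sampling_rate_hz
    children = np.random.SeedSequence(config.seed).spawn(
        len(config.holding_potentials_mv)
    )
    temperature_k = config.ionic.temperature_k
    traces = []
    for v_mv, child in zip(config.holding_potentials_mv, children):
        rng = np.random.default_rng(child)
        k_open = params.k_open(v_mv, temperature_k)
        i_unit = params.unitary_current_pa(v_mv)
        level = np.zeros(n_samples)
        for _ in range(params.n_channels):
            starts, levels = _gating_segments(
                rng, k_open, params.k_close, config.duration_s,
                params.substate_fraction, params.substate_prob,
            )
            idx = np.searchsorted(starts, t, side="right") - 1
            level += levels[idx]
        current = level * i_unit
        if config.noise_sd_pa > 0:
            current = current + rng.normal(0.0, config.noise_sd_pa, n_samples)
        truth = {
            "gating": asdict(params),
            "unitary_current_pa": i_unit,
            "k_open": k_open,
            "open_probability": params.open_probability(v_mv, temperature_k),
            "noise_sd_pa": config.noise_sd_pa,
            "seed": config.seed,
        }
        traces.append(
            CurrentTrace(
                time=t,
                current=current,
                holding_potential_mv=v_mv,
                ionic=config.ionic,
                sampling_rate_hz=config.sampling_rate_hz,
                metadata={"truth": truth},
                true_level=level,
            )
        )
    return traces


# --------------------------------------------------------------------------
# ECS / dark-interval relaxation
# --------------------------------------------------------------------------

def default_ecs_protocol() -> EcsProtocol:
    """Dark baseline, three single-turnover flashes, light, one 600-ms
    dark interval."""
    return EcsProtocol(
        baseline=(0.0, 0.8),
        flash_times=(1.0, 1.4, 1.8),
        light_on=2.5,
        dark_intervals=((7.5, 0.6),),
        duration_s=9.0,
    )


@dataclass(frozen=True)
class EcsSimParams:
    """Phenomenological ECS generator parameters.

    The dark baseline sits at 0. During illumination the signal rises to
    ``s_light``; switching the light off lets the signal relax
    single-exponentially (time constant ``tau_decay_ms``) toward an inverted
    quasi-stable level ``s_inv`` such that ``s_light - s_inv`` equals the
    total ECS amplitude ECS_t and ``(s_light - 0)/ECS_t`` equals the
    delta-psi fraction ``f_dpsi``. Single-turnover flashes are instantaneous
    steps of ``ecs_st_amp`` that decay with the same time constant. ECS_t is
    derived as ``s_light / f_dpsi``; pass ``ecs_t`` explicitly to allow
    ``f_dpsi = 0`` (pure delta-pH storage, the overexpressor-like case).
    """

    s_light: float = 1.0
    f_dpsi: float = 0.6
    tau_decay_ms: float = 25.0
    ecs_st_amp: float = 0.5
    noise_sd: float = 0.0
    protocol: EcsProtocol = field(default_factory=default_ecs_protocol)
    seed: int = 0
    sampling_rate_hz: float = 1000.0
    ecs_t: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.f_dpsi <= 1.0:
            raise ValueError("f_dpsi must lie in [0, 1]")
        if not self.tau_decay_ms > 0:
            raise ValueError("tau_decay_ms must be > 0")
        if not self.ecs_st_amp > 0:
            raise ValueError("ecs_st_amp must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ecs_t is None and self.f_dpsi == 0.0:
            raise ValueError("f_dpsi = 0 requires an explicit ecs_t")
        if self.ecs_t is not None:
            if not np.isclose(self.s_light, self.f_dpsi * self.ecs_t):
                raise ValueError("s_light must equal f_dpsi * ecs_t")

    @property
    def total_ecs(self) -> float:
        return self.ecs_t if self.ecs_t is not None else self.s_light / self.f_dpsi


def simulate_ecs_trace(params: EcsSimParams) -> EcsTrace:
    """Generate an ECS trace following ``params.protocol``.

    Light-on and post-interval recoveries relax toward ``s_light`` with the
    same time constant as the decay; within each dark interval the signal is
    ``s_inv + (S(t0) - s_inv) * exp(-(t - t0)/tau)``.
    """
    proto = params.protocol
    n = int(round(proto.duration_s * params.sampling_rate_hz))
    t = np.arange(n) / params.sampling_rate_hz
    tau = params.tau_decay_ms / 1000.0
    ecs_t = params.total_ecs
    s_inv = params.s_light - ecs_t

    signal = np.zeros(n)
    # Single-turnover flashes: step up, exponential return to baseline.
    for tf in proto.flash_times:
        after = t >= tf - 1e-12
        signal[after] += params.ecs_st_amp * np.exp(-(t[after] - tf) / tau)

    # Actinic-light portion, built segment by segment so each dark interval
    # starts from the analytic level reached at the previous boundary.
    def relax(t_seg, t0, start_level, target):
        return target + (start_level - target) * np.exp(-(t_seg - t0) / tau)

    level = 0.0
    seg_start = proto.light_on
    for d_start, d_len in proto.dark_intervals:
        sel = (t >= seg_start) & (t < d_start)
        signal[sel] += relax(t[sel], seg_start, level, params.s_light)
        level = relax(np.array([d_start]), seg_start, level, params.s_light)[0]
        sel = (t >= d_start) & (t < d_start + d_len)
        signal[sel] += relax(t[sel], d_start, level, s_inv)
        level = relax(np.array([d_start + d_len]), d_start, level, s_inv)[0]
        seg_start = d_start + d_len
    sel = t >= seg_start
    signal[sel] += relax(t[sel], seg_start, level, params.s_light)

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, n)
    truth = {
        "s_light": params.s_light,
        "f_dpsi": params.f_dpsi,
        "ecs_t": ecs_t,
        "s_inv": s_inv,
        "tau_decay_ms": params.tau_decay_ms,
        "ecs_st_amp": params.ecs_st_amp,
        "noise_sd": params.noise_sd,
        "seed": params.seed,
    }
    return EcsTrace(time=t, signal=signal, protocol=proto, metadata={"truth": truth})


# --------------------------------------------------------------------------
# PAM fluorescence
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PamSimParams:
    """Saturating-pulse fluorescence generator.

    The target quenching and yield courses are inverted into fluorescence
    levels: at each pulse ``F_m' = f_m / (1 + NPQ)`` and the preceding steady
    state ``F = F_m' * (1 - Phi_II)``, so analysing the noiseless trace
    returns the courses exactly.
    """

    f_m: float = 2.0
    npq_course: tuple = (0.5, 1.0, 1.5)
    phi_course: tuple = (0.6, 0.5, 0.4)
    pulse_times_s: tuple = (5.0, 10.0, 15.0)
    baseline_noise_sd: float = 0.0
    seed: int = 0
    sampling_rate_hz: float = 200.0
    pulse_width_s: float = 0.3

    def __post_init__(self):
        object.__setattr__(self, "npq_course", tuple(float(x) for x in self.npq_course))
        object.__setattr__(self, "phi_course", tuple(float(x) for x in self.phi_course))
        object.__setattr__(self, "pulse_times_s", tuple(float(x) for x in self.pulse_times_s))
        if not self.f_m > 0:
            raise ValueError("f_m must be > 0")
        if len(self.npq_course) != len(self.pulse_times_s) or len(
            self.phi_course
        ) != len(self.pulse_times_s):
            raise ValueError("courses must be defined at each pulse time")
        if any(x < 0 for x in self.npq_course):
            raise ValueError("npq_course must be >= 0")
        if any(not 0.0 <= x <= 1.0 for x in self.phi_course):
            raise ValueError("phi_course must lie in [0, 1]")
        if len(self.pulse_times_s) == 0:
            raise ValueError("at least one pulse required")
        diffs = np.diff(self.pulse_times_s)
        if np.any(diffs < self.pulse_width_s + 1.0):
            raise ValueError("pulses too closely spaced for steady-state windows")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")


def simulate_pam_trace(params: PamSimParams) -> FluorTrace:
    """Generate a :class:`FluorTrace` realizing the target NPQ/Phi courses."""
    pulses = np.asarray(params.pulse_times_s)
    half = params.pulse_width_s / 2.0
    duration = pulses[-1] + 1.0
    n = int(round(duration * params.sampling_rate_hz))
    t = np.arange(n) / params.sampling_rate_hz

    fm_prime = params.f_m / (1.0 + np.asarray(params.npq_course))
    f_steady = fm_prime * (1.0 - np.asarray(params.phi_course))

    # Steady level k applies up to pulse k; the last level persists afterwards.
    fluor = np.empty(n)
    prev_end = 0.0
    for k, tp in enumerate(pulses):
        sel = (t >= prev_end) & (t < tp - half)
        fluor[sel] = f_steady[k]
        sel = (t >= tp - half) & (t < tp + half)
        fluor[sel] = fm_prime[k]
        prev_end = tp + half
    fluor[t >= prev_end] = f_steady[-1]

    rng = np.random.default_rng(params.seed)
    if params.baseline_noise_sd > 0:
        fluor = fluor + rng.normal(0.0, params.baseline_noise_sd, n)
    truth = {
        "f_m": params.f_m,
        "npq_course": list(params.npq_course),
        "phi_course": list(params.phi_course),
        "f_m_prime": fm_prime.tolist(),
        "f_steady": f_steady.tolist(),
        "seed": params.seed,
    }
    return FluorTrace(
        time=t,
        fluorescence=fluor,
        pulse_times=pulses,
        f_m=params.f_m,
        metadata={"truth": truth},
    )


# --------------------------------------------------------------------------
# SANS
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SansSimParams:
    """Lamellar Bragg-peak model parameters (constant + power law + Gaussian).

    Defaults place the peak near the granum repeat distance of Arabidopsis
    leaves (q* = 0.025 1/A, RD about 251 A) inside the leaf fit window.
    """

    i0: float = 1.0
    a_const: float = 1e-4
    b_const: float = 5.0
    p_exp: float = 3.0
    q_star: float = 0.025  # 1/Angstrom
    c_width: float = 0.004  # 1/Angstrom
    q_grid: tuple = tuple(np.linspace(0.012, 0.045, 120))
    rel_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "q_grid", tuple(float(q) for q in self.q_grid))
        q = np.asarray(self.q_grid)
        if q.size == 0 or np.any(q <= 0):
            raise ValueError("q grid must be non-empty and strictly positive")
        if not (q[0] <= self.q_star <= q[-1]):
            raise ValueError("q_star must lie inside the q grid")
        if not self.c_width > 0:
            raise ValueError("c_width must be > 0")
        if not self.p_exp > 0:
            raise ValueError("p_exp must be > 0")
        if self.rel_noise < 0:
            raise ValueError("rel_noise must be >= 0")


def sans_model(q, i0, a_const, p_exp, b_const, q_star, c_width):
    """Lamellar scattering model: I(q) = I0 + A q^-p + B exp(-(q-q*)^2/(2c^2))."""
    q = np.asarray(q, dtype=float)
    return (
        i0
        + a_const * q ** (-p_exp)
        + b_const * np.exp(-((q - q_star) ** 2) / (2.0 * c_width**2))
    )


def simulate_sans_curve(params: SansSimParams) -> SansCurve:
    """Evaluate the lamellar model and add multiplicative Gaussian noise
    (relative sd ``rel_noise``, a desk-scale proxy for counting statistics)."""
    q = np.asarray(params.q_grid)
    ideal = sans_model(q, params.i0, params.a_const, params.p_exp,
                       params.b_const, params.q_star, params.c_width)
    rng = np.random.default_rng(params.seed)
    if params.rel_noise > 0:
        intensity = ideal * (1.0 + rng.normal(0.0, params.rel_noise, q.size))
        sigma = params.rel_noise * ideal
    else:
        intensity = ideal.copy()
        sigma = None
    truth = {k: getattr(params, k) for k in
             ("i0", "a_const", "b_const", "p_exp", "q_star", "c_width",
              "rel_noise", "seed")}
    return SansCurve(q=q, intensity=intensity, sigma=sigma, metadata={"truth": truth})


# --------------------------------------------------------------------------
# CD spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CdSimParams:
    """Psi-type CD spectrum generator: Gaussian bands + polynomial baseline.

    Default bands emulate the (+)505, (-)675 and (+)690 nm psi-type bands of
    intact leaves.
    """

    bands: tuple = ((505.0, 4.0, 12.0), (675.0, -6.0, 9.0), (690.0, 8.0, 7.0))
    baseline_poly: tuple = (0.0,)  # numpy polyval coefficients, highest first
    wavelength_grid: tuple = tuple(np.arange(400.0, 801.0, 1.0))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "bands",
            tuple((float(c), float(a), float(w)) for c, a, w in self.bands),
        )
        object.__setattr__(
            self, "wavelength_grid",
            tuple(float(w) for w in self.wavelength_grid),
        )
        wl = np.asarray(self.wavelength_grid)
        if wl.size == 0:
            raise ValueError("empty wavelength grid")
        for center, _amp, width in self.bands:
            if not (wl[0] <= center <= wl[-1]):
                raise ValueError(f"band center {center} nm outside grid")
            if not width > 0:
                raise ValueError("band width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_cd_spectrum(params: CdSimParams) -> CdSpectrum:
    """Sum of Gaussian bands plus a polynomial baseline plus Gaussian noise."""
    wl = np.asarray(params.wavelength_grid)
    signal = np.polyval(params.baseline_poly, wl)
    for center, amp, width in params.bands:
        signal = signal + amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, wl.size)
    truth = {
        "bands": [list(b) for b in params.bands],
        "baseline_poly": list(params.baseline_poly),
        "noise_sd": params.noise_sd,
        "seed": params.seed,
    }
    return CdSpectrum(wavelength_nm=wl, cd_signal=signal, metadata={"truth": truth})
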