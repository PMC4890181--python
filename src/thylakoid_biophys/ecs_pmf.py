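"""Dark-interval relaxation analysis of the electrochromic shift (ECS).

The ECS (550-515 nm absorbance difference) tracks the transmembrane electric
field, so brief dark intervals during steady illumination decompose the
proton motive force (PMF): the light steady-state level relaxes past the
dark baseline to an inverted quasi-stable level. The light-minus-inverted
amplitude ECS_t measures total PMF; the light-minus-baseline fraction of it
is the delta-psi share, the undershoot below baseline the delta-pH share.
The initial decay time constant gives the proton conductivity of the
membrane (mainly ATP synthase), g_H+ = 1/tau.

Level estimation reduces to three window means (light steady state, dark
baseline, end-of-interval inverted level) with configurable window lengths;
the decay is fitted single-exponentially over the first 100 ms after
light-off. Flash (ECS_ST) amplitudes normalize ECS_t across leaves via the
factor max(ECS_ST)/ECS_ST.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import EcsTrace
from .errors import NoDecayError, NoPmfSignalError, ProtocolError

__all__ = [
    "PmfPartition",
    "measure_ecs_st",
    "normalize_ecs_t",
    "partition_pmf",
    "fit_gh_plus",
]


@dataclass
class PmfPartition:
    """Per-dark-interval PMF decomposition.

    ``f_dpsi + f_dph = 1`` by construction. ``tau_ms`` / ``g_h`` are filled
    when the exponential fit succeeds (``g_h = 1000/tau_ms``, in 1/s);
    ``ecs_t_norm`` is filled by :func:`normalize_ecs_t`.
    """

    ecs_t_raw: float
    f_dpsi: float
    f_dph: float
    s_light: float
    s_base: float
    s_inv: float
    ecs_st: float | None = None
    ecs_t_norm: float | None = None
    tau_ms: float | None = None
    g_h: float | None = None


def _window_mean(trace: EcsTrace, t0: float, t1: float, label: str,
                 include_end: bool = True) -> float:
    upper = (trace.time <= t1 + 1e-12) if include_end else (trace.time < t1 - 1e-12)
    sel = (trace.time >= t0 - 1e-12) & upper
    if not np.any(sel):
        raise ProtocolError(f"{label} window [{t0}, {t1}] s contains no samples")
    return float(trace.signal[sel].mean())


def measure_ecs_st(
    trace: EcsTrace,
    peak_window_ms: float = 5.0,
    baseline_window_ms: float = 10.0,
) -> float:
    """Single-turnover flash amplitude ECS_ST, averaged over all flashes.

    For each annotated flash the amplitude is the signal peak within
    ``peak_window_ms`` after the flash minus the mean of the
    ``baseline_window_ms`` immediately before it.
    """
    flashes = trace.protocol.flash_times
    if not flashes:
        raise ProtocolError("no flashes annotated in protocol")
    amps = []
    for tf in flashes:
        if tf < trace.time[0] or tf + peak_window_ms / 1000.0 > trace.time[-1]:
            raise ProtocolError(f"flash at {tf} s outside trace")
        pre = (trace.time >= tf - baseline_window_ms / 1000.0) & (trace.time < tf)
        post = (trace.time >= tf) & (trace.time <= tf + peak_window_ms / 1000.0)
        if not np.any(pre) or not np.any(post):
            raise ProtocolError(f"flash at {tf} s has empty analysis windows")
        amps.append(float(trace.signal[post].max() - trace.signal[pre].mean()))
    return float(np.mean(amps))


def normalize_ecs_t(measurements) -> list:
    """Cross-leaf normalization of ECS_t values.

    ``measurements`` is a sequence of ``(ecs_t_raw, ecs_st)``; each ECS_t is
    multiplied by ``max_j(ecs_st_j) / ecs_st_i`` so the measurement with the
    largest flash response is unchanged. Idempotent once the ecs_st values
    are equalized, and invariant under a common rescaling of all ecs_st.
    """
    pairs = list(measurements)
    if not pairs:
        raise ValueError("empty measurement list")
    sts = [st for _, st in pairs]
    if any(st <= 0 for st in sts):
        raise ValueError("all ecs_st must be > 0")
    max_st = max(sts)
    return [ecs_t * (max_st / st) for ecs_t, st in pairs]


def _resolve_interval(trace: EcsTrace, interval) -> tuple:
    if isinstance(interval, (int, np.integer)):
        intervals = trace.protocol.dark_intervals
        if not intervals:
            raise ProtocolError("no dark intervals annotated")
        start, length = intervals[int(interval)]
    else:
        start, length = interval
    if length < 0.3:
        raise ProtocolError("dark interval must be >= 300 ms for partitioning")
    return float(start), float(length)


def partition_pmf(
    trace: EcsTrace,
    interval=0,
    light_window_ms: float = 20.0,
    inv_window_ms: float = 50.0,
    fit_gh: bool = True,
) -> PmfPartition:
    """Partition the PMF from one dark interval of an ECS trace.

    ``interval`` is either an index into the protocol's dark intervals or an
    explicit ``(start_s, length_s)`` window. Levels: light steady state from
    the last ``light_window_ms`` before light-off, inverted level from the
    last ``inv_window_ms`` of the interval, dark baseline from the protocol's
    baseline window. ``f_dpsi = (S_light - S_base)/ECS_t`` is clipped to
    [0, 1] with a warning (mirroring possible ECS_t underestimation when the
    undershoot fails to develop). When ``fit_gh`` the exponential decay fit
    fills ``tau_ms`` and ``g_h``; its failure leaves them None.
    """
    start, length = _resolve_interval(trace, interval)
    b0, b1 = trace.protocol.baseline
    s_base = _window_mean(trace, b0, b1, "baseline")
    # Half-open window: the sample at light-off already belongs to the dark
    # relaxation.
    s_light = _window_mean(
        trace, start - light_window_ms / 1000.0, start, "light", include_end=False
    )
    s_inv = _window_mean(
        trace, start + length - inv_window_ms / 1000.0, start + length, "inverted"
    )
    ecs_t = s_light - s_inv
    if ecs_t <= 0:
        raise NoPmfSignalError(
            f"no PMF signal: ECS_t = {ecs_t:.4g} is not positive"
        )
    f_dpsi = (s_light - s_base) / ecs_t
    if 1.0 < f_dpsi <= 1.0 + 1e-9 or -1e-9 <= f_dpsi < 0.0:
        f_dpsi = float(np.clip(f_dpsi, 0.0, 1.0))  # numerical grazing
    if not 0.0 <= f_dpsi <= 1.0:
        warnings.warn(
            f"f_dpsi = {f_dpsi:.3f} outside [0, 1]; clipping "
            "(possible ECS_t underestimation)",
            stacklevel=2,
        )
        f_dpsi = float(np.clip(f_dpsi, 0.0, 1.0))
    result = PmfPartition(
        ecs_t_raw=ecs_t,
        f_dpsi=f_dpsi,
        f_dph=1.0 - f_dpsi,
        s_light=s_light,
        s_base=s_base,
        s_inv=s_inv,
    )
    if fit_gh:
        try:
            result.tau_ms, result.g_h = fit_gh_plus(trace, (start, length))
        except NoDecayError:
            pass
    return result


def _exp_decay(t, s_inf, ds, tau):
    return s_inf + ds * np.exp(-t / tau)


def fit_gh_plus(trace: EcsTrace, interval=0, fit_window_ms: float = 100.0) -> tuple:
    """Fit the initial ECS decay and return ``(tau_ms, g_h)``.

    Nonlinear least squares of ``S(t) = S_inf + dS exp(-t/tau)`` over the
    first ``fit_window_ms`` after light-off, initialized from a log-linear
    fit with ``S_inf`` seeded by the last-5-ms mean of the window. The proton
    conductivity is ``g_h = 1/tau`` with tau in seconds.

    Raises :class:`NoDecayError` when the segment does not decay
    (``tau <= 0`` or ``dS <= 0`` at the optimum).
    """
    start, length = _resolve_interval(trace, interval)
    window_s = fit_window_ms / 1000.0
    sel = (trace.time > start) & (trace.time <= start + min(window_s, length))
    t = trace.time[sel] - start
    s = trace.signal[sel]
    if t.size < 20:
        raise NoDecayError(
            f"only {t.size} samples in the {fit_window_ms:.0f}-ms fit window; "
            ">= 20 required"
        )
    s_inf0 = float(s[t >= t[-1] - 0.005].mean())
    ds0 = float(s[0] - s_inf0)
    if ds0 <= 0:
        raise NoDecayError("segment does not decay from the light level")
    resid = s - s_inf0
    pos = resid > 0.05 * ds0
    if np.count_nonzero(pos) >= 3:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else 0.025
    else:
        tau0 = 0.025
    tau0 = float(np.clip(tau0, 1e-4, 10.0))
    try:
        popt, _ = curve_fit(
            _exp_decay, t, s, p0=[s_inf0, ds0, tau0], maxfev=20000
        )
    except RuntimeError as exc:
        raise NoDecayError("exponential fit did not converge") from exc
    s_inf, ds, tau = popt
    if tau <= 0 or ds <= 0:
        raise NoDecayError("fitted decay is non-decaying")
    return float(tau * 1000.0), float(1.0 / tau)
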