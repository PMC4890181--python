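"""Single-channel electrophysiology analysis.

Amplitude histograms, unitary-current estimation by a two-component Gaussian
fit, half-amplitude threshold idealization, branch-wise slope conductance,
and Goldman-Hodgkin-Katz (GHK) selectivity: the forward voltage equation,
its closed-form inversion for the K+/Cl- permeability ratio, and the GHK
current (constant-field flux) model used to synthesize I-V curves.

Sign conventions follow the planar-bilayer experiment: voltages are cis-side
relative to trans, positive current is carried by cations flowing cis ->
trans.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .datatypes import ION_VALENCE, CurrentTrace, IonicCondition, thermal_voltage_mv
from .errors import (
    InsufficientDataError,
    NoOpenEventsError,
    UnidentifiableError,
)

__all__ = [
    "AmplitudeHistogram",
    "Idealization",
    "ConductanceFit",
    "SelectivityResult",
    "build_amplitude_histogram",
    "estimate_unitary_current",
    "idealize_half_amplitude",
    "fit_branch_conductance",
    "ghk_reversal_potential",
    "fit_permeability_ratio",
    "ghk_current",
    "estimate_reversal_potential",
    "interpolate_reversal_potential",
]


# --------------------------------------------------------------------------
# Amplitude histogram
# --------------------------------------------------------------------------

@dataclass
class AmplitudeHistogram:
    """All-points amplitude histogram of a current trace."""

    bin_edges: np.ndarray  # pA, length n_bins + 1
    counts: np.ndarray  # integer counts
    bin_width: float  # pA

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def build_amplitude_histogram(trace: CurrentTrace, bin_width: float = 0.1) -> AmplitudeHistogram:
    """Bin every sample of ``trace`` into bins of width ``bin_width`` pA.

    The edges start at the data minimum and extend far enough to cover the
    maximum, so the counts conserve the sample number exactly.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    cur = trace.current
    if cur.size == 0:
        raise ValueError("empty trace")
    lo = float(cur.min())
    hi = float(cur.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(cur, bins=edges)
    return AmplitudeHistogram(bin_edges=edges, counts=counts, bin_width=bin_width)


# --------------------------------------------------------------------------
# Unitary current from the histogram
# --------------------------------------------------------------------------

def _gauss(x, amp, mu, sd):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def _two_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return _gauss(x, a1, mu1, s1) + _gauss(x, a2, mu2, s2)


def _signed_separation(mu_a: float, mu_b: float) -> float:
    """Open-level mode minus closed-level mode; the open level is the mode
    farther from 0 pA. Magnitude equals the mode separation."""
    near, far = sorted((mu_a, mu_b), key=abs)
    return far - near


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, x[order]))


def estimate_unitary_current(hist: AmplitudeHistogram) -> float:
    """Estimate the unitary current (pA) from a two-level amplitude histogram.

    A two-component Gaussian fit of the binned counts yields the closed and
    full-open modes; the returned value is the signed mode separation
    (open minus closed, see :func:`_signed_separation`). Substate modes are
    excluded because the two dominant components capture the closed and
    full-open levels. Initialization uses the two highest histogram peaks
    (ties broken toward larger separation), falling back to weighted
    25th/75th percentiles when the modes merge into a shoulder.

    Raises
    ------
    NoOpenEventsError
        When the histogram is unimodal (a single-Gaussian model describes it
        essentially as well as the two-Gaussian model), i.e. the trace shows
        no resolvable openings.
    """
    counts = hist.counts.astype(float)
    centers = hist.bin_centers
    occupied = counts > 0
    if occupied.sum() < 2:
        raise NoOpenEventsError("amplitude histogram occupies a single bin")

    if occupied.sum() <= 5:
        # Essentially noiseless record: modes are the occupied bins themselves.
        occ_centers = centers[occupied]
        occ_counts = counts[occupied]
        order = np.argsort(occ_counts)[::-1]
        dominant = occ_centers[order[0]]
        rest = order[1:]
        best = max(
            rest,
            key=lambda i: (occ_counts[i], abs(occ_centers[i] - dominant)),
        )
        return _signed_separation(dominant, occ_centers[best])

    smooth = uniform_filter1d(counts, size=5)
    peaks, _ = find_peaks(smooth, prominence=0.05 * smooth.max())
    sd0 = max(
        np.sqrt(np.average((centers - np.average(centers, weights=counts)) ** 2,
                           weights=counts)) / 2.0,
        hist.bin_width,
    )
    if len(peaks) >= 2:
        order = sorted(
            range(len(peaks)), key=lambda i: smooth[peaks[i]], reverse=True
        )
        first = peaks[order[0]]
        # Tie-break toward larger separation among near-equal secondary peaks.
        second = max(
            (peaks[i] for i in order[1:]),
            key=lambda p: (round(smooth[p] / (0.05 * smooth.max())),
                           abs(centers[p] - centers[first])),
        )
        mu1_0, mu2_0 = centers[first], centers[second]
        a1_0, a2_0 = smooth[first], smooth[second]
    else:
        mu1_0 = _weighted_quantile(centers, counts, 0.25)
        mu2_0 = _weighted_quantile(centers, counts, 0.75)
        a1_0 = a2_0 = counts.max()

    span = centers[-1] - centers[0]
    bounds = (
        [0.0, centers[0], hist.bin_width / 4.0] * 2,
        [np.inf, centers[-1], span] * 2,
    )
    p0_two = [a1_0, mu1_0, sd0, a2_0, mu2_0, sd0]

    try:
        popt1, _ = curve_fit(
            _gauss, centers, counts,
            p0=[counts.max(), float(np.average(centers, weights=counts)), sd0],
            bounds=([0.0, centers[0], hist.bin_width / 4.0],
                    [np.inf, centers[-1], span]),
            maxfev=20000,
        )
        sse1 = float(np.sum((counts - _gauss(centers, *popt1)) ** 2))
    except RuntimeError:
        sse1 = np.inf

    try:
        popt2, _ = curve_fit(
            _two_gauss, centers, counts, p0=p0_two, bounds=bounds, maxfev=40000
        )
    except RuntimeError as exc:
        raise NoOpenEventsError("two-component fit did not converge") from exc
    sse2 = float(np.sum((counts - _two_gauss(centers, *popt2)) ** 2))

    if not sse2 < 0.7 * sse1:
        raise NoOpenEventsError(
            "histogram is unimodal: no open events resolvable"
        )
    a1, mu1, s1, a2, mu2, s2 = popt2
    w1, w2 = a1 * s1, a2 * s2  # component masses
    if min(w1, w2) < 0.005 * (w1 + w2):
        raise NoOpenEventsError("minor histogram component is negligible")
    if abs(mu2 - mu1) < hist.bin_width:
        raise NoOpenEventsError("fitted modes coincide")
    return _signed_separation(mu1, mu2)


# --------------------------------------------------------------------------
# Idealization
# --------------------------------------------------------------------------

LEVEL_NAMES = ("closed", "substate", "open")


@dataclass
class Idealization:
    """Dwell-segment representation of a trace plus the open probability.

    ``segments`` is a list of ``(level, start_s, duration_s)`` with level in
    {"closed", "substate", "open"}; the segments tile the trace exactly.
    ``labels`` carries the per-sample level index (0/1/2) for convenience.
    """

    segments: list
    open_probability: float
    labels: np.ndarray

    @property
    def total_time_s(self) -> float:
        return float(sum(d for _, _, d in self.segments))


def idealize_half_amplitude(
    trace: CurrentTrace,
    unitary_current: float,
    closed_level: float = 0.0,
    substate_fraction: float | None = None,
    prefilter_samples: int | None = None,
) -> Idealization:
    """Half-amplitude threshold idealization.

    A sample is open when its current, projected on the open direction,
    exceeds half the unitary current: ``(I - closed_level)/i_u > 0.5``. With
    ``substate_fraction`` f set, a third level is resolved with thresholds
    midway between neighbouring levels (f/2 and (1+f)/2). An optional
    moving-average prefilter (off by default) can be applied before
    thresholding. Open probability counts substate dwell time as open.
    """
    if unitary_current == 0:
        raise ValueError("unitary_current must be nonzero")
    current = trace.current
    if prefilter_samples:
        current = uniform_filter1d(current, size=int(prefilter_samples))
    r = (current - closed_level) / unitary_current
    if substate_fraction is None:
        labels = np.where(r > 0.5, 2, 0).astype(np.int8)
    else:
        f = substate_fraction
        labels = np.zeros(r.size, dtype=np.int8)
        labels[r > f / 2.0] = 1
        labels[r > (1.0 + f) / 2.0] = 2

    # Run-length encode into dwell segments tiling the trace.
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    dt = 1.0 / trace.sampling_rate_hz
    t0 = trace.time[0]
    segments = [
        (LEVEL_NAMES[labels[s]], t0 + s * dt, (e - s) * dt)
        for s, e in zip(starts, ends)
    ]
    open_probability = float(np.count_nonzero(labels > 0)) / labels.size
    return Idealization(segments=segments, open_probability=open_probability,
                        labels=labels)


# --------------------------------------------------------------------------
# Branch conductance
# --------------------------------------------------------------------------

@dataclass
class ConductanceFit:
    """Slope conductances from unitary-current / voltage pairs.

    ``gamma_pos_ps``/``gamma_neg_ps`` are least-squares slopes constrained
    through the reversal point, in pS; a branch without data is None. In
    ``mode="single"`` one slope is fitted across all voltages (the KNO3-style
    analysis) and reported on both branches.
    """

    gamma_pos_ps: float | None
    gamma_neg_ps: float | None
    v_rev_mv: float
    mode: str
    residuals: dict = field(default_factory=dict)
    n_points: dict = field(default_factory=dict)


def _through_origin_slope(dv: np.ndarray, i: np.ndarray) -> tuple:
    slope = float(np.sum(dv * i) / np.sum(dv * dv))  # pA/mV = nS
    resid = i - slope * dv
    return slope * 1000.0, resid  # pS


def fit_branch_conductance(
    points, v_rev_mv: float = 0.0, mode: str = "per-branch"
) -> ConductanceFit:
    """Fit slope conductance(s) from ``points`` = [(V_mV, i_pA), ...].

    Per-branch mode splits the points by the sign of ``V - v_rev_mv`` and
    fits each branch separately through the reversal point; a branch with no
    points is marked unavailable, a branch with a single point raises
    :class:`InsufficientDataError`. Single mode fits one slope to all points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (V_mV, i_pA) pairs")
    dv = pts[:, 0] - v_rev_mv
    i = pts[:, 1]

    if mode == "single":
        if pts.shape[0] < 2:
            raise InsufficientDataError("single-branch fit needs >= 2 points")
        gamma, resid = _through_origin_slope(dv, i)
        return ConductanceFit(
            gamma_pos_ps=gamma, gamma_neg_ps=gamma, v_rev_mv=v_rev_mv,
            mode="single", residuals={"all": resid},
            n_points={"all": pts.shape[0]},
        )
    if mode != "per-branch":
        raise ValueError(f"unknown mode {mode!r}")

    out = {"pos": None, "neg": None}
    residuals, n_points = {}, {}
    for name, sel in (("pos", dv > 0), ("neg", dv < 0)):
        n = int(np.count_nonzero(sel))
        n_points[name] = n
        if n == 0:
            continue
        if n == 1:
            raise InsufficientDataError(
                f"{name} branch has a single point; >= 2 required"
            )
        out[name], residuals[name] = _through_origin_slope(dv[sel], i[sel])
    if out["pos"] is None and out["neg"] is None:
        raise InsufficientDataError("no points on either branch")
    return ConductanceFit(
        gamma_pos_ps=out["pos"], gamma_neg_ps=out["neg"], v_rev_mv=v_rev_mv,
        mode="per-branch", residuals=residuals, n_points=n_points,
    )


# --------------------------------------------------------------------------
# GHK selectivity
# --------------------------------------------------------------------------

@dataclass
class SelectivityResult:
    """Reversal potential and P_K/P_Cl permeability ratio.

    The field convention follows anion-channel reporting: the paper-style
    statement "P_Cl : P_K = 1 : x" corresponds to ``p_ratio = x``.
    """

    v_rev_mv: float
    p_ratio: float  # P_K / P_Cl


def _kcl_concentrations(ionic: IonicCondition) -> tuple:
    try:
        return (ionic.cis("K"), ionic.trans("K"), ionic.cis("Cl"), ionic.trans("Cl"))
    except KeyError as exc:
        raise ValueError("GHK selectivity requires K and Cl on both sides") from exc


def ghk_reversal_potential(p_ratio: float, ionic: IonicCondition) -> float:
    """GHK voltage equation for a K+/Cl- bath (anion convention).

    ``V_rev = (RT/F) ln[(p [K]_trans + [Cl]_cis) / (p [K]_cis + [Cl]_trans)]``
    in mV, cis relative to trans, with ``p = P_K/P_Cl``. For ``p = 0`` this
    reduces to the Nernst potential of Cl-.
    """
    if p_ratio < 0:
        raise ValueError("p_ratio must be >= 0")
    kc, kt, clc, clt = _kcl_concentrations(ionic)
    num = p_ratio * kt + clc
    den = p_ratio * kc + clt
    if num == 0 or den == 0:
        raise ValueError("degenerate concentrations in GHK equation")
    return thermal_voltage_mv(ionic.temperature_k) * np.log(num / den)


def fit_permeability_ratio(v_rev_mv: float, ionic: IonicCondition) -> SelectivityResult:
    """Closed-form inversion of :func:`ghk_reversal_potential`.

    Raises :class:`UnidentifiableError` for a symmetric bath (any permeability
    ratio gives 0 mV) and ``ValueError`` when ``v_rev_mv`` lies outside the
    attainable range bounded by the Cl- and K+ Nernst potentials.
    """
    kc, kt, clc, clt = _kcl_concentrations(ionic)
    if ionic.is_symmetric():
        raise UnidentifiableError(
            "permeability ratio is unidentifiable in a symmetric bath"
        )
    rt_f = thermal_voltage_mv(ionic.temperature_k)
    u = np.exp(v_rev_mv / rt_f)
    num = clc - u * clt
    den = u * kc - kt
    # Float rounding can push an exactly-attainable boundary (the Cl- Nernst
    # potential, p = 0) marginally outside; clamp within relative epsilon.
    if -1e-9 * clc < num < 0.0:
        num = 0.0
    v_cl = rt_f * np.log(clc / clt)  # p -> 0 limit
    v_k = rt_f * np.log(kt / kc)  # p -> inf limit
    if den <= 0 or num < 0:
        raise ValueError(
            f"v_rev {v_rev_mv:.2f} mV outside attainable range "
            f"[{min(v_cl, v_k):.2f}, {max(v_cl, v_k):.2f}] mV"
        )
    return SelectivityResult(v_rev_mv=v_rev_mv, p_ratio=float(num / den))


def ghk_current(v_mv, ionic: IonicCondition, permeabilities: dict) -> np.ndarray:
    """GHK (constant-field) current for the given relative permeabilities.

    ``I = sum_X P_X z^2 u ([X]_cis - [X]_trans e^{-z u}) / (1 - e^{-z u})``
    with ``u = V/(RT/F)``; units are arbitrary (relative permeabilities times
    mM), adequate for synthesizing I-V curves whose zero crossing sits at the
    GHK reversal potential.
    """
    v = np.atleast_1d(np.asarray(v_mv, dtype=float))
    u = v / thermal_voltage_mv(ionic.temperature_k)
    u = np.where(np.abs(u) < 1e-9, 1e-9, u)  # removable singularity at 0 mV
    total = np.zeros_like(u)
    for species, perm in permeabilities.items():
        z = ION_VALENCE[species]
        c_cis = ionic.cis(species)
        c_trans = ionic.trans(species)
        ez = np.exp(-z * u)
        total += perm * z**2 * u * (c_cis - c_trans * ez) / (1.0 - ez)
    return total if np.ndim(v_mv) else float(total[0])


def estimate_reversal_potential(
    v_mv, current, ionic: IonicCondition, method: str = "ghk-shape"
) -> float:
    """Zero-current potential from a (possibly noisy) I-V curve.

    ``method="ghk-shape"`` fits the two-parameter constant-field I-V shape
    (overall scale and P_K/P_Cl) to all points and returns its zero
    crossing; this uses the whole curve and is the low-variance choice for
    noisy data. ``method="linear"`` falls back to
    :func:`interpolate_reversal_potential`.
    """
    if method == "linear":
        return interpolate_reversal_potential(v_mv, current)
    if method != "ghk-shape":
        raise ValueError(f"unknown method {method!r}")
    v = np.asarray(v_mv, dtype=float)
    i = np.asarray(current, dtype=float)

    def shape(vv, scale, p):
        return scale * ghk_current(vv, ionic, {"K": p, "Cl": 1.0})

    span_data = np.ptp(i)
    span_model = np.ptp(ghk_current(v, ionic, {"K": 0.5, "Cl": 1.0}))
    popt, _ = curve_fit(
        shape, v, i, p0=[max(span_data / span_model, 1e-6), 0.5],
        bounds=([1e-9, 0.0], [np.inf, 100.0]), maxfev=20000,
    )
    return ghk_reversal_potential(popt[1], ionic)


def interpolate_reversal_potential(v_mv, current) -> float:
    """Zero-current potential by linear interpolation on an I-V curve.

    Points are sorted by voltage; with several noise-induced sign changes the
    crossing with the smallest bracketing |I| is used.
    """
    v = np.asarray(v_mv, dtype=float)
    i = np.asarray(current, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    crossings = np.flatnonzero(np.sign(i[:-1]) * np.sign(i[1:]) <= 0)
    crossings = [k for k in crossings if not (i[k] == 0 and i[k + 1] == 0)]
    if not crossings:
        if np.any(i == 0):
            return float(v[np.argmin(np.abs(i))])
        raise ValueError("I-V curve has no zero crossing")
    k = min(crossings, key=lambda k: abs(i[k]) + abs(i[k + 1]))
    if i[k] == i[k + 1]:
        return float(0.5 * (v[k] + v[k + 1]))
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))
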