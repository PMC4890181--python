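"""Core data containers and physical constants.

Units are fixed package-wide: time in seconds, current in pA, voltage in mV,
conductance in pS, concentration in mM, scattering vector q in 1/Angstrom,
repeat distance in Angstrom, wavelength in nm. Containers validate their
invariants at construction time so the analysis functions can assume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ProtocolError

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Ion species the electrophysiology layer understands, with valences.
ION_VALENCE = {"K": +1, "Cl": -1, "NO3": -1}


def thermal_voltage_mv(temperature_k: float = 298.15) -> float:
    """RT/F in millivolts (25.693 mV at 298.15 K)."""
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class IonicCondition:
    """Bath composition on the two sides of a planar lipid bilayer.

    The *cis* chamber is the protein-addition side; voltages elsewhere in the
    package are cis-side voltages relative to trans, and positive current is
    carried by cations flowing cis -> trans.

    Parameters
    ----------
    cis_mm, trans_mm
        Per-species concentrations in mM, keyed by ``"K"``, ``"Cl"``,
        ``"NO3"``. A species present on one side must be declared on both.
    temperature_k
        Bath temperature; must lie in [273, 320] K.
    """

    cis_mm: Mapping[str, float]
    trans_mm: Mapping[str, float]
    temperature_k: float = 298.15

    def __post_init__(self):
        object.__setattr__(self, "cis_mm", dict(self.cis_mm))
        object.__setattr__(self, "trans_mm", dict(self.trans_mm))
        for side_name, side in (("cis", self.cis_mm), ("trans", self.trans_mm)):
            for species, conc in side.items():
                if species not in ION_VALENCE:
                    raise ValueError(f"unsupported ionic species {species!r}")
                if not conc > 0:
                    raise ValueError(
                        f"{side_name} [{species}] must be > 0 mM, got {conc}"
                    )
        if set(self.cis_mm) != set(self.trans_mm):
            raise ValueError("cis and trans must declare the same species")
        if not 273.0 <= self.temperature_k <= 320.0:
            raise ValueError("temperature_k must lie in [273, 320]")

    @property
    def species(self) -> tuple:
        return tuple(sorted(self.cis_mm))

    def cis(self, species: str) -> float:
        return self.cis_mm[species]

    def trans(self, species: str) -> float:
        return self.trans_mm[species]

    def is_symmetric(self) -> bool:
        return all(
            np.isclose(self.cis_mm[s], self.trans_mm[s]) for s in self.cis_mm
        )

    def to_dict(self) -> dict:
        return {
            "cis_mm": dict(self.cis_mm),
            "trans_mm": dict(self.trans_mm),
            "temperature_k": self.temperature_k,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IonicCondition":
        return cls(d["cis_mm"], d["trans_mm"], d.get("temperature_k", 298.15))


# Convenient standard baths from the bilayer experiments.
def symmetric_kcl(conc_mm: float = 100.0, temperature_k: float = 298.15) -> IonicCondition:
    return IonicCondition({"K": conc_mm, "Cl": conc_mm}, {"K": conc_mm, "Cl": conc_mm},
                          temperature_k)


def symmetric_kno3(conc_mm: float = 100.0, temperature_k: float = 298.15) -> IonicCondition:
    return IonicCondition({"K": conc_mm, "NO3": conc_mm}, {"K": conc_mm, "NO3": conc_mm},
                          temperature_k)


def kcl_gradient(cis_mm: float = 300.0, trans_mm: float = 100.0,
                 temperature_k: float = 298.15) -> IonicCondition:
    """Asymmetric KCl bath (default 300 mM cis / 100 mM trans)."""
    return IonicCondition({"K": cis_mm, "Cl": cis_mm}, {"K": trans_mm, "Cl": trans_mm},
                          temperature_k)


@dataclass
class CurrentTrace:
    """Sampled single-channel current recording at one holding potential.

    ``true_level`` optionally carries the generator's noise-free summed open
    fraction per sample (0 closed, 1 full open, substate fraction for
    substates, >1 for simultaneous multi-channel openings); analysis code
    never reads it, tests do.
    """

    time: np.ndarray  # s
    current: np.ndarray  # pA
    holding_potential_mv: float
    ionic: IonicCondition
    sampling_rate_hz: float
    metadata: dict = field(default_factory=dict)
    true_level: np.ndarray | None = None

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.current = _as_float_array(self.current, "current")
        if self.time.size == 0:
            raise ValueError("zero-length trace")
        if self.time.size != self.current.size:
            raise ValueError("time and current must have equal length")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        dt = 1.0 / self.sampling_rate_hz
        if self.time.size > 1 and not np.allclose(
            np.diff(self.time), dt, rtol=1e-9, atol=1e-12
        ):
            raise ValueError("time grid inconsistent with sampling_rate_hz")
        if self.true_level is not None:
            self.true_level = _as_float_array(self.true_level, "true_level")
            if self.true_level.size != self.time.size:
                raise ValueError("true_level length mismatch")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class EcsProtocol:
    """Light/flash protocol annotating an ECS recording.

    Timeline (all seconds from trace start): a dark ``baseline`` window,
    single-turnover ``flash_times`` in the dark period, actinic light from
    ``light_on``, and one or more ``dark_intervals`` (start, length) during
    which the light is switched off and the ECS relaxation is recorded.
    """

    baseline: tuple  # (t0, t1)
    flash_times: tuple
    light_on: float
    dark_intervals: tuple  # of (start, length)
    duration_s: float

    def __post_init__(self):
        object.__setattr__(self, "baseline", tuple(float(t) for t in self.baseline))
        object.__setattr__(
            self, "flash_times", tuple(sorted(float(t) for t in self.flash_times))
        )
        object.__setattr__(
            self,
            "dark_intervals",
            tuple((float(a), float(b)) for a, b in self.dark_intervals),
        )
        b0, b1 = self.baseline
        if not 0.0 <= b0 < b1:
            raise ProtocolError("baseline window must satisfy 0 <= t0 < t1")
        if b1 > self.light_on:
            raise ProtocolError("baseline window must end before light_on")
        for tf in self.flash_times:
            if not 0.0 <= tf < self.light_on:
                raise ProtocolError("flashes must precede light_on")
        if not 0.0 < self.light_on < self.duration_s:
            raise ProtocolError("light_on must lie inside the trace")
        prev_end = self.light_on
        for start, length in self.dark_intervals:
            if length <= 0:
                raise ProtocolError("dark interval length must be > 0")
            if start < prev_end:
                raise ProtocolError("dark intervals overlap or precede light_on")
            prev_end = start + length
        if prev_end > self.duration_s:
            raise ProtocolError("protocol extends beyond trace duration")

    def to_dict(self) -> dict:
        return {
            "baseline": list(self.baseline),
            "flash_times": list(self.flash_times),
            "light_on": self.light_on,
            "dark_intervals": [list(w) for w in self.dark_intervals],
            "duration_s": self.duration_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EcsProtocol":
        return cls(
            tuple(d["baseline"]),
            tuple(d["flash_times"]),
            d["light_on"],
            tuple(tuple(w) for w in d["dark_intervals"]),
            d["duration_s"],
        )


@dataclass
class EcsTrace:
    """Electrochromic-shift (550-515 nm absorbance difference) time series."""

    time: np.ndarray  # s
    signal: np.ndarray  # relative units
    protocol: EcsProtocol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.signal = _as_float_array(self.signal, "signal")
        if self.time.size == 0:
            raise ValueError("zero-length trace")
        if self.time.size != self.signal.size:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.protocol.duration_s > self.time[-1] + 1e-9 + (
            self.time[1] - self.time[0] if self.time.size > 1 else 0.0
        ):
            raise ProtocolError("protocol duration exceeds trace time range")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class FluorTrace:
    """PAM chlorophyll-fluorescence time series with saturating-pulse markers.

    ``f_m`` is the dark-adapted maximal fluorescence measured before the
    actinic period; it is carried as metadata because NPQ references it.
    """

    time: np.ndarray  # s
    fluorescence: np.ndarray  # arbitrary units
    pulse_times: np.ndarray  # s
    f_m: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.fluorescence = _as_float_array(self.fluorescence, "fluorescence")
        self.pulse_times = _as_float_array(np.atleast_1d(self.pulse_times), "pulse_times")
        if self.time.size != self.fluorescence.size:
            raise ValueError("time and fluorescence must have equal length")
        if not self.f_m > 0:
            raise ValueError("f_m must be > 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.diff(self.pulse_times) < 0):
            raise ValueError("pulse_times must be sorted")
        if self.pulse_times.size and (
            self.pulse_times[0] < self.time[0] or self.pulse_times[-1] > self.time[-1]
        ):
            raise ValueError("pulse_times outside trace time range")


@dataclass
class SansCurve:
    """1-D small-angle neutron scattering curve I(q)."""

    q: np.ndarray  # 1/Angstrom
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = _as_float_array(self.sigma, "sigma")
            if self.sigma.size != self.q.size:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be >= 0")


@dataclass
class CdSpectrum:
    """Circular-dichroism spectrum on a 400-800 nm wavelength grid.

    ``normalization`` records the red-most absorption-peak value the signal
    has been divided by (None when the spectrum is raw).
    """

    wavelength_nm: np.ndarray
    cd_signal: np.ndarray
    normalization: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength_nm = _as_float_array(self.wavelength_nm, "wavelength_nm")
        self.cd_signal = _as_float_array(self.cd_signal, "cd_signal")
        if self.wavelength_nm.size == 0:
            raise ValueError("empty wavelength grid")
        if self.wavelength_nm.size != self.cd_signal.size:
            raise ValueError("wavelength and signal must have equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
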