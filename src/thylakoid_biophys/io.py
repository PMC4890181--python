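"""Columnar text formats and the pipeline runner.

All data travel as tab-separated text with a ``#``-prefixed header: a format
line, a ``kind`` line, one JSON ``meta`` line (sorted keys, so output bytes
are deterministic), and a column-name line. Floats are written with %.17g,
which round-trips float64 exactly; writing the same object twice yields
byte-identical files and read(write(x)) reproduces x losslessly.

``run_pipeline`` executes simulate -> analyze chains from a validated
configuration mapping and emits a machine-readable summary with provenance
(stage parameters, seeds, file paths) for every derived quantity.
"""
from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datatypes import (
    CdSpectrum,
    CurrentTrace,
    EcsProtocol,
    EcsTrace,
    FluorTrace,
    IonicCondition,
    SansCurve,
)
from .errors import ConfigError, TraceFormatError

logger = logging.getLogger("thylakoid_biophys")

FORMAT_LINE = "# thylakoid-biophys/1"

_KIND_COLUMNS = {
    "current_trace": ("time_s", "current_pa"),
    "ecs_trace": ("time_s", "ecs_signal"),
    "fluor_trace": ("time_s", "fluorescence"),
    "sans_curve": ("q_inv_angstrom", "intensity"),
    "cd_spectrum": ("wavelength_nm", "cd_signal"),
}


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _meta_json(meta: dict) -> str:
    return json.dumps(meta, sort_keys=True, separators=(",", ":"))


def _columns_and_meta(obj):
    """Return (kind, column names, column arrays, metadata dict)."""
    if isinstance(obj, CurrentTrace):
        cols = [obj.time, obj.current]
        names = list(_KIND_COLUMNS["current_trace"])
        if obj.true_level is not None:
            names.append("true_level")
            cols.append(obj.true_level)
        meta = {
            "holding_potential_mv": obj.holding_potential_mv,
            "sampling_rate_hz": obj.sampling_rate_hz,
            "ionic": obj.ionic.to_dict(),
            "metadata": obj.metadata,
        }
        return "current_trace", names, cols, meta
    if isinstance(obj, EcsTrace):
        return (
            "ecs_trace",
            list(_KIND_COLUMNS["ecs_trace"]),
            [obj.time, obj.signal],
            {"protocol": obj.protocol.to_dict(), "metadata": obj.metadata},
        )
    if isinstance(obj, FluorTrace):
        return (
            "fluor_trace",
            list(_KIND_COLUMNS["fluor_trace"]),
            [obj.time, obj.fluorescence],
            {
                "pulse_times_s": obj.pulse_times.tolist(),
                "f_m": obj.f_m,
                "metadata": obj.metadata,
            },
        )
    if isinstance(obj, SansCurve):
        cols = [obj.q, obj.intensity]
        names = list(_KIND_COLUMNS["sans_curve"])
        if obj.sigma is not None:
            names.append("sigma")
            cols.append(obj.sigma)
        return "sans_curve", names, cols, {"metadata": obj.metadata}
    if isinstance(obj, CdSpectrum):
        return (
            "cd_spectrum",
            list(_KIND_COLUMNS["cd_spectrum"]),
            [obj.wavelength_nm, obj.cd_signal],
            {"normalization": obj.normalization, "metadata": obj.metadata},
        )
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def write_trace(obj, path) -> Path:
    """Write any trace/curve/spectrum object to a columnar text file.

    Deterministic byte output for a fixed object; ground-truth metadata is
    preserved verbatim inside the JSON ``meta`` header line. Objects are
    validated by their own constructors, so an invariant-violating object
    cannot reach this function.
    """
    kind, names, cols, meta = _columns_and_meta(obj)
    path = Path(path)
    lines = [
        FORMAT_LINE,
        f"# kind: {kind}",
        f"# meta: {_meta_json(meta)}",
        "# columns: " + "\t".join(names),
    ]
    rows = np.column_stack(cols)
    body = "\n".join("\t".join(_fmt(v) for v in row) for row in rows)
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def _parse_header(text: str):
    header = {}
    data_start = 0
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        data_start += 1
        stripped = line[1:].strip()
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            header[key.strip()] = value.strip()
    return header, data_start


def read_trace(path):
    """Read a columnar file back into its typed object.

    Dispatches on the ``kind`` header; validates units/metadata presence,
    monotone time and finiteness (through the container constructors).
    """
    path = Path(path)
    text = path.read_text()
    header, n_header = _parse_header(text)
    if "kind" not in header:
        raise TraceFormatError(f"{path}: missing 'kind' header")
    kind = header["kind"]
    if kind not in _KIND_COLUMNS:
        raise TraceFormatError(f"{path}: unknown trace kind {kind!r}")
    try:
        meta = json.loads(header.get("meta", "{}"))
    except json.JSONDecodeError as exc:
        raise TraceFormatError(f"{path}: malformed meta header") from exc
    names = header.get("columns", "").split("\t")
    body = text.splitlines()[n_header:]
    try:
        data = np.array(
            [[float(v) for v in line.split("\t")] for line in body if line],
            dtype=float,
        )
    except ValueError as exc:
        raise TraceFormatError(f"{path}: malformed data block") from exc
    if data.size == 0 or data.shape[1] != len(names):
        raise TraceFormatError(f"{path}: column count mismatch")
    if np.any(~np.isfinite(data)):
        raise TraceFormatError(f"{path}: non-finite value in data block")
    cols = {name: data[:, k] for k, name in enumerate(names)}

    try:
        if kind == "current_trace":
            if np.any(np.diff(cols["time_s"]) <= 0):
                raise TraceFormatError(f"{path}: time not strictly increasing")
            return CurrentTrace(
                time=cols["time_s"],
                current=cols["current_pa"],
                holding_potential_mv=meta["holding_potential_mv"],
                ionic=IonicCondition.from_dict(meta["ionic"]),
                sampling_rate_hz=meta["sampling_rate_hz"],
                metadata=meta.get("metadata", {}),
                true_level=cols.get("true_level"),
            )
        if kind == "ecs_trace":
            return EcsTrace(
                time=cols["time_s"],
                signal=cols["ecs_signal"],
                protocol=EcsProtocol.from_dict(meta["protocol"]),
                metadata=meta.get("metadata", {}),
            )
        if kind == "fluor_trace":
            return FluorTrace(
                time=cols["time_s"],
                fluorescence=cols["fluorescence"],
                pulse_times=np.asarray(meta["pulse_times_s"], dtype=float),
                f_m=meta["f_m"],
                metadata=meta.get("metadata", {}),
            )
        if kind == "sans_curve":
            return SansCurve(
                q=cols["q_inv_angstrom"],
                intensity=cols["intensity"],
                sigma=cols.get("sigma"),
                metadata=meta.get("metadata", {}),
            )
        return CdSpectrum(
            wavelength_nm=cols["wavelength_nm"],
            cd_signal=cols["cd_signal"],
            normalization=meta.get("normalization"),
            metadata=meta.get("metadata", {}),
        )
    except KeyError as exc:
        raise TraceFormatError(f"{path}: missing mandatory metadata {exc}") from exc
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# Pipeline runner
# --------------------------------------------------------------------------

_TOP_KEYS = {"seed", "out_dir", "stages", "log_level"}
_STAGE_KEYS = {
    "channel": {"kind", "name", "gating", "recording", "bin_width"},
    "ecs": {"kind", "name", "params"},
    "pam": {"kind", "name", "params"},
    "sans": {"kind", "name", "params", "q_window"},
    "cd": {"kind", "name", "params"},
    "selectivity": {"kind", "name", "p_ratio", "ionic", "voltages_mv",
                    "noise_rel", "n_replicates"},
}


def _check_keys(mapping, allowed, where):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {where}")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute simulate -> analyze chains and return a summary dict.

    ``config`` maps: ``seed`` (mandatory), optional ``out_dir`` and
    ``log_level``, and ``stages`` (list of stage mappings with a ``kind`` out
    of channel/ecs/pam/sans/cd/selectivity). Unknown keys anywhere are
    rejected by name. Each stage derives an independent child seed from the
    top-level seed, simulates its inputs, runs the matching analysis and
    contributes its derived quantities (with provenance) to the summary.
    Fixed (config, seed) gives a bit-identical summary.
    """
    # Imports here keep module import light and avoid cycles.
    from . import ecs_pmf, ephys, sans, spectroscopy, synthetic_data as synth

    _check_keys(config, _TOP_KEYS, "top level")
    if "seed" not in config:
        raise ConfigError("seed is mandatory")
    seed = int(config["seed"])
    if config.get("log_level"):
        logger.setLevel(config["log_level"])
    out_dir = Path(out_dir or config.get("out_dir") or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    children = np.random.SeedSequence(seed).spawn(max(len(stages), 1))

    summary = {"package_version": __version__, "seed": seed, "stages": []}
    t_start = _time.perf_counter()
    for idx, stage in enumerate(stages):
        if "kind" not in stage:
            raise ConfigError(f"stage {idx}: missing 'kind'")
        kind = stage["kind"]
        if kind not in _STAGE_KEYS:
            raise ConfigError(f"stage {idx}: unknown stage kind {kind!r}")
        _check_keys(stage, _STAGE_KEYS[kind], f"stage {idx} ({kind})")
        name = stage.get("name", f"{kind}_{idx}")
        child_seed = int(children[idx].generate_state(1)[0] % (2**31))
        logger.info("running stage %s (%s)", name, kind)
        t0 = _time.perf_counter()
        try:
            if kind == "channel":
                gating = synth.ChannelGatingParams(**stage.get("gating", {}))
                rec_kw = dict(stage.get("recording", {}))
                ionic_kw = rec_kw.pop("ionic", None)
                if ionic_kw is not None:
                    rec_kw["ionic"] = IonicCondition.from_dict(ionic_kw)
                rec = synth.RecordingConfig(seed=child_seed, **rec_kw)
                traces = synth.simulate_channel_trace(gating, rec)
                points = []
                files = []
                for trace in traces:
                    fname = out_dir / f"{name}_{trace.holding_potential_mv:+.0f}mV.tsv"
                    write_trace(trace, fname)
                    files.append(str(fname))
                    hist = ephys.build_amplitude_histogram(
                        trace, stage.get("bin_width", 0.1)
                    )
                    points.append(
                        (trace.holding_potential_mv,
                         ephys.estimate_unitary_current(hist))
                    )
                fit = ephys.fit_branch_conductance(points, gating.v_rev_mv)
                result = {
                    "gamma_pos_ps": fit.gamma_pos_ps,
                    "gamma_neg_ps": fit.gamma_neg_ps,
                    "truth_gamma_pos_ps": gating.gamma_pos_ps,
                    "truth_gamma_neg_ps": gating.gamma_neg_ps,
                    "unitary_currents_pa": [list(p) for p in points],
                }
                inputs = files
            elif kind == "ecs":
                params = _build_ecs_params(synth, stage.get("params", {}), child_seed)
                trace = synth.simulate_ecs_trace(params)
                fname = out_dir / f"{name}.tsv"
                write_trace(trace, fname)
                part = ecs_pmf.partition_pmf(trace)
                part.ecs_st = ecs_pmf.measure_ecs_st(trace)
                result = {
                    "ecs_t": part.ecs_t_raw,
                    "ecs_st": part.ecs_st,
                    "f_dpsi": part.f_dpsi,
                    "f_dph": part.f_dph,
                    "tau_ms": part.tau_ms,
                    "g_h_per_s": part.g_h,
                }
                inputs = [str(fname)]
            elif kind == "pam":
                params = synth.PamSimParams(seed=child_seed, **stage.get("params", {}))
                trace = synth.simulate_pam_trace(params)
                fname = out_dir / f"{name}.tsv"
                write_trace(trace, fname)
                series = spectroscopy.analyze_pam(trace)
                result = {
                    "npq": series.npq.tolist(),
                    "phi_ii": series.phi_ii.tolist(),
                    "pulse_times_s": series.pulse_times.tolist(),
                }
                inputs = [str(fname)]
            elif kind == "sans":
                params = synth.SansSimParams(seed=child_seed, **stage.get("params", {}))
                curve = synth.simulate_sans_curve(params)
                fname = out_dir / f"{name}.tsv"
                write_trace(curve, fname)
                window = tuple(stage.get("q_window", sans.LEAF_Q_WINDOW))
                fit = sans.fit_bragg_model(curve, window)
                result = {
                    "q_star_inv_a": fit.q_star,
                    "repeat_distance_a": fit.repeat_distance_a,
                    "p_exp": fit.p_exp,
                    "truth_q_star_inv_a": params.q_star,
                }
                inputs = [str(fname)]
            elif kind == "cd":
                params = synth.CdSimParams(seed=child_seed, **stage.get("params", {}))
                spectrum = synth.simulate_cd_spectrum(params)
                fname = out_dir / f"{name}.tsv"
                write_trace(spectrum, fname)
                result = {"psi_band_amplitudes":
                          spectroscopy.psi_band_amplitudes(spectrum)}
                inputs = [str(fname)]
            else:  # selectivity
                ionic = (
                    IonicCondition.from_dict(stage["ionic"])
                    if "ionic" in stage
                    else None
                )
                if ionic is None:
                    from .datatypes import kcl_gradient
                    ionic = kcl_gradient()
                p_true = float(stage.get("p_ratio", 0.17))
                voltages = np.asarray(
                    stage.get("voltages_mv", np.linspace(-60, 60, 11).tolist())
                )
                ideal = ephys.ghk_current(
                    voltages, ionic, {"K": p_true, "Cl": 1.0}
                )
                rng = np.random.default_rng(child_seed)
                noise_rel = float(stage.get("noise_rel", 0.05))
                n_rep = int(stage.get("n_replicates", 3))
                noise_sd = noise_rel * np.max(np.abs(ideal))
                current = np.mean(
                    [ideal + rng.normal(0.0, noise_sd, voltages.size)
                     for _ in range(n_rep)],
                    axis=0,
                )
                v_rev = ephys.estimate_reversal_potential(
                    voltages, current, ionic
                )
                sel = ephys.fit_permeability_ratio(v_rev, ionic)
                result = {
                    "v_rev_mv": sel.v_rev_mv,
                    "p_ratio": sel.p_ratio,
                    "truth_p_ratio": p_true,
                }
                inputs = []
        except Exception as exc:
            raise type(exc)(f"stage {name} ({kind}): {exc}") from exc
        summary["stages"].append(
            {
                "name": name,
                "kind": kind,
                "seed": child_seed,
                "inputs": inputs,
                "elapsed_s": round(_time.perf_counter() - t0, 6),
                "result": result,
                "provenance": {
                    k: v for k, v in stage.items() if k not in ("kind", "name")
                },
            }
        )
    summary["elapsed_s"] = round(_time.perf_counter() - t_start, 6)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline summary written to %s", summary_path)
    return summary


def _build_ecs_params(synth, kw: dict, seed: int):
    kw = dict(kw)
    proto = kw.pop("protocol", None)
    if proto is not None:
        kw["protocol"] = EcsProtocol.from_dict(proto)
    return synth.EcsSimParams(seed=seed, **kw)
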