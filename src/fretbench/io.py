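"""File formats: model/simulation configs, trace files and dataset manifests.

Everything is plain text.  Trace files are one-molecule CSV tables with
a '#'-prefixed header (trace id, sampling rate) and fixed columns
``time_s, donor, acceptor, acceptor_direct, fret``; a JSON manifest
lists the files of a dataset together with provenance (seed, config
hash).  The FRET column is recomputed from the intensity columns on
load so the intensities remain the single source of truth.

Model/simulation configuration files are a flat, versioned ``key:
value`` dialect; arrays are comma-separated in row-major order.  Floats
are written with 12 significant digits so write(read(x)) is
byte-identical for canonical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import KineticModel, validate_model
from .simulate import CHANNELS, Dataset, SimulationConfig, Trace, compute_fret

FORMAT_VERSION = 1
_TRACE_COLUMNS = ["time_s", "donor", "acceptor", "acceptor_direct", "fret"]


class ParseError(ValueError):
    pass


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def _fmt_array(a: np.ndarray) -> str:
    return ", ".join(_fmt(v) for v in np.asarray(a, dtype=float).ravel())


# ---------------------------------------------------------------------------
# model + simulation config


def write_model_config(
    path, model: KineticModel, config: SimulationConfig | None = None
) -> None:
    """Write a kinetic model (and optionally simulator settings) to disk."""
    lines = [
        "# fretbench model config",
        f"format_version: {FORMAT_VERSION}",
        f"n_states: {model.n_states}",
        f"state_labels: {', '.join(model.state_labels)}",
        f"rate_matrix: {_fmt_array(model.rates)}",
        f"fret: {_fmt_array(model.fret)}",
    ]
    if config is not None:
        lines += [
            f"sampling_rate: {_fmt(config.sampling_rate)}",
            f"bleach_rate: {_fmt(config.bleach_rate)}",
            f"min_length: {_fmt(config.min_length)}",
            f"max_length: {_fmt(config.max_length)}",
            f"n_traces: {config.n_traces}",
            f"mean_jitter_scale: {_fmt(config.mean_jitter_scale)}",
            f"brightness_base: {_fmt(config.brightness_base)}",
            f"enable_mean_jitter: {str(config.enable_mean_jitter).lower()}",
            f"enable_brightness: {str(config.enable_brightness).lower()}",
            f"enable_blinking: {str(config.enable_blinking).lower()}",
            f"blink_rates_donor: {_fmt_array(config.blink_rates['donor'])}",
            f"blink_rates_acceptor: {_fmt_array(config.blink_rates['acceptor'])}",
            f"seed: {config.seed}",
        ]
        if config.emission_means is not None:
            lines.append(f"emission_means: {_fmt_array(config.emission_means)}")
        if config.emission_cov is not None:
            lines.append(f"emission_cov: {_fmt_array(config.emission_cov)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_kv(path) -> dict:
    kv = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, value = line.split(":", 1)
        kv[key.strip()] = value.strip()
    return kv


def read_model_config(path) -> tuple[KineticModel, SimulationConfig | None]:
    """Read a model (+ simulation config, if present) from a config file.

    Unknown keys are preserved on the returned config under
    ``extra_keys`` with a warning; mandatory model keys must be present.
    """
    import warnings

    kv = _parse_kv(path)
    for key in ("format_version", "n_states", "rate_matrix", "fret"):
        if key not in kv:
            raise ParseError(f"{path}: missing mandatory key '{key}'")
    n = int(kv["n_states"])
    rates = np.fromstring(kv["rate_matrix"], sep=",")
    if rates.size != n * n:
        raise ParseError(f"{path}: rate_matrix has {rates.size} entries, expected {n * n}")
    fret = np.fromstring(kv["fret"], sep=",")
    if fret.size != n:
        raise ParseError(f"{path}: fret has {fret.size} entries, expected {n}")
    labels = tuple(s.strip() for s in kv.get("state_labels", "").split(",")) if kv.get(
        "state_labels"
    ) else ()
    model = validate_model(KineticModel(rates=rates.reshape(n, n), fret=fret, state_labels=labels))

    known = {
        "format_version", "n_states", "state_labels", "rate_matrix", "fret",
        "sampling_rate", "bleach_rate", "min_length", "max_length", "n_traces",
        "mean_jitter_scale", "brightness_base", "enable_mean_jitter",
        "enable_brightness", "enable_blinking", "blink_rates_donor",
        "blink_rates_acceptor", "seed", "emission_means", "emission_cov",
    }
    extra = {k: v for k, v in kv.items() if k not in known}
    if extra:
        warnings.warn(f"{path}: preserving unknown keys {sorted(extra)}", stacklevel=2)

    config = None
    if "sampling_rate" in kv:
        min_length = float(kv.get("min_length", 1.0))
        max_length = float(kv.get("max_length", min_length))
        if max_length < min_length:
            raise ParseError(f"{path}: max_length < min_length")
        means = cov = None
        if "emission_means" in kv:
            means = np.fromstring(kv["emission_means"], sep=",").reshape(n, 3)
        if "emission_cov" in kv:
            cov = np.fromstring(kv["emission_cov"], sep=",").reshape(n, 3, 3)
        config = SimulationConfig(
            sampling_rate=float(kv["sampling_rate"]),
            bleach_rate=float(kv.get("bleach_rate", 0.01)),
            min_length=min_length,
            max_length=max_length,
            n_traces=int(kv.get("n_traces", 1)),
            emission_means=means,
            emission_cov=cov,
            mean_jitter_scale=float(kv.get("mean_jitter_scale", 5.0)),
            brightness_base=float(kv.get("brightness_base", 1.20)),
            enable_mean_jitter=kv.get("enable_mean_jitter", "false") == "true",
            enable_brightness=kv.get("enable_brightness", "false") == "true",
            enable_blinking=kv.get("enable_blinking", "false") == "true",
            blink_rates={
                "donor": tuple(np.fromstring(kv.get("blink_rates_donor", "0.01, 0.1"), sep=",")),
                "acceptor": tuple(
                    np.fromstring(kv.get("blink_rates_acceptor", "0.01, 0.1"), sep=",")
                ),
            },
            seed=int(kv.get("seed", 0)),
        )
        config.extra_keys = extra
    return model, config


# ---------------------------------------------------------------------------
# traces + manifest


def write_traces(dataset: Dataset, directory) -> Path:
    """Write one CSV file per trace plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, trace in enumerate(dataset.traces):
        name = f"{trace.trace_id or f'trace{i:04d}'}.csv"
        lines = [
            f"# fretbench trace v{FORMAT_VERSION}",
            f"# trace_id: {trace.trace_id or f'trace{i:04d}'}",
            f"# sampling_rate_hz: {_fmt(dataset.sampling_rate)}",
            ",".join(_TRACE_COLUMNS),
        ]
        for k in range(trace.n_frames):
            fret = trace.fret[k]
            lines.append(
                ",".join(
                    [
                        _fmt(trace.times[k]),
                        _fmt(trace.donor[k]),
                        _fmt(trace.acceptor[k]),
                        _fmt(trace.acceptor_direct[k]),
                        "nan" if not np.isfinite(fret) else _fmt(fret),
                    ]
                )
            )
        (directory / name).write_text("\n".join(lines) + "\n")
        files.append(name)
    manifest = {
        "format_version": FORMAT_VERSION,
        "sampling_rate_hz": dataset.sampling_rate,
        "channels": list(CHANNELS),
        "traces": files,
        "provenance": {"seed": dataset.seed, "config_hash": None},
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def read_trace_file(path, sampling_rate: float | None = None) -> Trace:
    """Parse a single trace CSV; FRET is recomputed from the intensities."""
    path = Path(path)
    header = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse table ({exc})") from exc
    missing = [c for c in _TRACE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["time_s"].isna().any():
        line = int(df.index[df["time_s"].isna()][0]) + skip + 2
        raise ParseError(f"{path}:{line}: NaN in time column")
    if (df["time_s"] < 0).any():
        line = int(df.index[df["time_s"] < 0][0]) + skip + 2
        raise ParseError(f"{path}:{line}: negative time value")
    rate = sampling_rate or float(header.get("sampling_rate_hz", 0)) or None
    if rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        rate = 1.0 / float(np.median(dt)) if len(dt) else 1.0
    donor = df["donor"].to_numpy(dtype=float)
    acceptor = df["acceptor"].to_numpy(dtype=float)
    return Trace(
        times=df["time_s"].to_numpy(dtype=float),
        donor=donor,
        acceptor=acceptor,
        acceptor_direct=df["acceptor_direct"].to_numpy(dtype=float),
        fret=compute_fret(donor, acceptor),
        trace_id=header.get("trace_id", path.stem),
        sampling_rate=rate,
    )


def read_traces(manifest_path) -> Dataset:
    """Load a dataset from its manifest; all listed files must exist."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    meta = json.loads(manifest_path.read_text())
    rate = float(meta["sampling_rate_hz"])
    traces = []
    for name in meta["traces"]:
        fpath = manifest_path.parent / name
        if not fpath.exists():
            raise ParseError(f"manifest {manifest_path} references missing file {name}")
        trace = read_trace_file(fpath, sampling_rate=rate)
        if trace.sampling_rate != rate:
            raise ParseError(f"{fpath}: sampling rate differs from manifest")
        traces.append(trace)
    prov = meta.get("provenance", {})
    return Dataset(traces=traces, sampling_rate=rate, seed=prov.get("seed"))


# ---------------------------------------------------------------------------
# inferred models / reports as JSON


def write_inferred_model(path, inferred) -> None:
    """Serialise an inference result (or plain kinetic model) as JSON."""
    if isinstance(inferred, KineticModel):
        doc = {
            "n_states": inferred.n_states,
            "rates_per_s": inferred.rates.tolist(),
            "fret_means": inferred.fret.tolist(),
        }
    else:
        doc = {
            "n_states": inferred.n_states,
            "fret_means": inferred.fret_means.tolist(),
            "fret_sds": inferred.fret_sds.tolist(),
            "transition_matrix": inferred.transmat.tolist(),
            "rates_per_s": inferred.rates.tolist(),
            "rate_method": inferred.rate_method,
            "log_likelihood": inferred.log_likelihood,
            "bic": inferred.bic,
            "n_frames": inferred.n_frames,
            "frame_period_s": inferred.frame_period,
            "converged": inferred.converged,
            "n_iterations": inferred.n_iter,
        }
        if inferred.ci95:
            doc["ci95"] = {
                f"{key[0] + 1}->{key[1] + 1}": list(val)
                for key, val in inferred.ci95.items()
                if isinstance(key, tuple)
            }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_inferred_model(path) -> KineticModel:
    """Read a stored model document back as a kinetic model."""
    doc = json.loads(Path(path).read_text())
    return validate_model(
        KineticModel(
            rates=np.array(doc["rates_per_s"], dtype=float),
            fret=np.array(doc["fret_means"], dtype=float),
        )
    )


def config_hash(path) -> str:
    """Stable content hash of a config file, for run provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
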