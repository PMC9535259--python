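"""Reading and writing signals and analysis results.

On-disk signal format: a two-column UTF-8 CSV ``time_s,value`` with a
mandatory header row, accompanied by a JSON sidecar ``<name>.meta.json``
carrying ``sampling_rate_hz``, ``units`` and ``channel_label``.  When the
sidecar is absent the sampling rate is inferred from a strictly uniform
time column (relative jitter <= 1e-6); anything less regular is rejected.

Axon Binary Format (ABF) import is optional and read-only: it is attempted
through ``pyabf`` or ``neo`` if either is importable, and degrades to a
:class:`~cardiophys.errors.CapabilityError` otherwise.

Results are written as a tidy CSV (one row per animal / cell / AP) plus a
JSON summary document into which the run configuration and seed are
embedded verbatim, so every downstream number is traceable to its
configuration snapshot.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import CapabilityError, FormatError, ValidationError
from .signal import SampledSignal

__all__ = ["read_signal", "write_signal", "write_results", "read_results_summary"]

#: maximum tolerated relative jitter of a CSV time column
_MAX_REL_JITTER = 1e-6


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def _read_abf(path: Path) -> SampledSignal:
    try:  # pragma: no cover - exercised only where a backend is installed
        import pyabf  # type: ignore

        abf = pyabf.ABF(str(path))
        abf.setSweep(0)
        return SampledSignal(
            samples=np.asarray(abf.sweepY, dtype=float),
            sampling_rate=float(abf.dataRate),
            start_time=0.0,
            channel_label=str(abf.sweepLabelY),
            units=str(abf.sweepUnitsY),
        )
    except ImportError:
        pass
    try:  # pragma: no cover
        from neo.io import AxonIO  # type: ignore

        block = AxonIO(filename=str(path)).read_block(lazy=False)
        sig = block.segments[0].analogsignals[0]
        return SampledSignal(
            samples=np.asarray(sig.magnitude[:, 0], dtype=float),
            sampling_rate=float(sig.sampling_rate.rescale("Hz").magnitude),
            start_time=float(sig.t_start.rescale("s").magnitude),
            channel_label=str(sig.name or ""),
            units=str(sig.units.dimensionality),
        )
    except ImportError:
        pass
    raise CapabilityError(
        "ABF import requires an optional backend (pyabf or neo); neither is installed"
    )


def read_signal(path: str | Path, format: str | None = None) -> SampledSignal:
    """Read a :class:`SampledSignal` from ``path``.

    ``format`` is ``"csv"`` or ``"abf"``; when omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format == "abf":
        return _read_abf(path)
    if format != "csv":
        raise FormatError(f"unknown signal format: {format!r}")

    table = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in table.columns:
            raise FormatError(f"signal CSV must have a '{col}' column")
    t = table["time_s"].to_numpy(dtype=float)
    v = table["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("signal CSV must contain at least two samples")

    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0 or np.any(np.abs(dt - dt_med) > _MAX_REL_JITTER * abs(dt_med)):
        raise FormatError(
            "time column is not strictly uniform (relative jitter exceeds 1e-6)"
        )

    meta_path = _sidecar_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        try:
            rate = float(meta["sampling_rate_hz"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"sidecar {meta_path.name} lacks a valid sampling_rate_hz") from exc
        if abs(rate * dt_med - 1.0) > 1e-6:
            raise FormatError(
                f"sidecar sampling rate {rate} Hz disagrees with the time column "
                f"spacing {dt_med} s"
            )
        units = str(meta.get("units", ""))
        label = str(meta.get("channel_label", ""))
    else:
        # rate inferred from the (verified uniform) time column
        rate = 1.0 / dt_med
        units = ""
        label = ""
    return SampledSignal(samples=v, sampling_rate=rate, start_time=float(t[0]),
                         channel_label=label, units=units)


def write_signal(signal: SampledSignal, path: str | Path) -> None:
    """Write ``signal`` as CSV + JSON sidecar, re-readable by :func:`read_signal`."""
    if not isinstance(signal, SampledSignal):
        raise ValidationError("write_signal expects a SampledSignal")
    path = Path(path)
    t = signal.times()
    frame = pd.DataFrame({"time_s": t, "value": signal.samples})
    # repr-precision floats so a round-trip is exact to representation precision
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": signal.sampling_rate,
        "units": signal.units,
        "channel_label": signal.channel_label,
        "start_time_s": signal.start_time,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_results(result: Any, path: str | Path, *, rows: pd.DataFrame | None = None,
                  config: Any = None, seed: int | None = None) -> None:
    """Write an analysis result as a tidy CSV table plus a JSON summary.

    ``result`` is any mapping / dataclass summarizing the run; ``rows`` is
    the tidy per-animal (or per-cell, per-AP) table.  The configuration and
    seed are embedded in the JSON document so results stay traceable.
    Missing optional values are written as empty cells, never as zero.
    """
    if result is None and rows is None:
        raise ValidationError("write_results needs a populated result or rows table")
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".json" else path
    if rows is not None:
        rows.to_csv(base.with_suffix(".csv"), index=False, float_format="%.12g",
                    na_rep="")
    doc = {
        "summary": _jsonable(result),
        "config": _jsonable(config),
        "seed": seed,
        "n_rows": None if rows is None else int(len(rows)),
    }
    base.with_suffix(".json").write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n"
    )


def read_results_summary(path: str | Path) -> dict:
    """Read back the JSON summary document written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
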