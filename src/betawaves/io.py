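"""Array-movie I/O: lossless HDF5 / NPZ round-trips for [nx, ny, nt] movies
with frame-rate and electrode-pitch metadata."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

__all__ = ["write_array", "read_array", "write_record"]

_REQUIRED_ATTRS = ("frame_rate_hz", "pitch_um")


def write_array(path, movie, *, frame_rate_hz, pitch_um=400.0, name="IE",
                extra_datasets=None, **attrs):
    """Write a movie plus metadata to ``.h5``/``.hdf5`` or ``.npz``.

    The primary dataset is stored under ``name`` (default ``IE``, the
    proxy-LFP); additional movies may be passed in ``extra_datasets``.
    """
    path = Path(path)
    movie = np.asarray(movie)
    meta = {"frame_rate_hz": float(frame_rate_hz), "pitch_um": float(pitch_um)}
    meta.update({k: v for k, v in attrs.items() if v is not None})
    extra = extra_datasets or {}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset(name, data=movie)
            for k, v in extra.items():
                f.create_dataset(k, data=np.asarray(v))
            for k, v in meta.items():
                f.attrs[k] = v
    elif path.suffix == ".npz":
        np.savez(path, **{name: movie}, **extra,
                 _meta=np.array([list(meta.keys()),
                                 [str(v) for v in meta.values()]], dtype=object))
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")
    return path


def read_array(path, name="IE") -> dict:
    """Read a movie written by :func:`write_array`.

    Returns a dict with the primary movie under ``"movie"``, every other
    dataset by name, and the metadata attributes.  Raises with a remediation
    hint if the frame-rate or pitch metadata is missing.
    """
    path = Path(path)
    out = {}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if name not in f:
                raise KeyError(f"dataset {name!r} not found in {path}")
            out["movie"] = f[name][()]
            for k in f:
                if k != name:
                    out[k] = f[k][()]
            meta = dict(f.attrs)
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=True) as z:
            if name not in z:
                raise KeyError(f"dataset {name!r} not found in {path}")
            out["movie"] = z[name]
            raw = z["_meta"] if "_meta" in z else np.array([[], []])
            meta = {}
            for k, v in zip(raw[0], raw[1]):
                try:
                    meta[k] = float(v)
                except ValueError:
                    meta[k] = v
            for k in z.files:
                if k not in (name, "_meta"):
                    out[k] = z[k]
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")
    for k in _REQUIRED_ATTRS:
        if k not in meta:
            raise KeyError(
                f"file {path} lacks required attribute {k!r}; rewrite it with "
                f"write_array(..., {k}=<value>)")
    out.update(meta)
    return out


def write_record(path, record, *, include_eta=True):
    """Write a SimulationRecord's measurement-window movies (IE, II and the
    realized shared input) with full provenance attributes."""
    p = record.params
    s = record.measurement_slice()
    extra = {"II": np.moveaxis(record.ii[:, s, s], 0, -1),
             "eta_mean": record.eta_mean, "stim": record.stim,
             "t_ms": record.t_ms}
    if include_eta and record.eta is not None:
        extra["eta"] = np.moveaxis(record.eta[:, s, s], 0, -1)
    return write_array(
        path, record.measurement_movie("ie"),
        frame_rate_hz=record.frame_rate_hz, name="IE", extra_datasets=extra,
        dt_ms=record.dt_ms, preset=p.preset_name, seed=record.seed,
        grid_size=p.grid_size, boundary_depth=p.boundary_depth,
        measure_size=p.measure_size, boundary=p.boundary,
    )
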