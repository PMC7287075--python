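"""Session-bundle persistence.

A session bundle is a directory holding everything one simulated (or
recorded) session needs: a YAML manifest (subject, seeds, generator
parameters, schema version), the trial table as CSV, one plain-text
spike-time file per unit, and an optional eye trace stored as a NumPy
``.npz`` (float arrays with a small header).  Times are seconds on the
session clock as 64-bit floats; reading a written bundle reproduces it
bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .neurons import NeuronParams, SpikeTrainSet

__all__ = [
    "SCHEMA_VERSION",
    "SessionBundle",
    "BundleError",
    "SchemaVersionError",
    "BundleIntegrityError",
    "write_bundle",
    "read_bundle",
]

SCHEMA_VERSION = 1


class BundleError(Exception):
    """Base class for bundle persistence errors."""


class SchemaVersionError(BundleError):
    """Manifest schema version does not match this package."""


class BundleIntegrityError(BundleError):
    """A bundle file is missing or violates an invariant."""


@dataclass
class SessionBundle:
    """One session: manifest + trial table + units + optional eye trace."""

    manifest: dict
    trials: pd.DataFrame
    units: list[SpikeTrainSet]
    eye: dict | None = None  # {'t': ..., 'h': ..., 'v': ...}

    def validate(self) -> None:
        idx = self.trials["trial_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise BundleIntegrityError("trial indices must be contiguous from 0")
        t_end = float(self.trials["t_trial_end"].max())
        for u in self.units:
            st = u.spike_times
            if st.size and (np.any(np.diff(st) < 0)):
                raise BundleIntegrityError(f"unit {u.params.unit_id}: non-monotone spike times")
            if st.size and (st[0] < -1.0 or st[-1] > t_end + 1.0):
                raise BundleIntegrityError(f"unit {u.params.unit_id}: spikes outside session span")


def _to_plain(obj):
    """Recursively convert numpy scalars and tuples to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_bundle(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a bundle directory; returns the path."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "units").mkdir(exist_ok=True)

    manifest = dict(bundle.manifest)
    manifest["schema_version"] = SCHEMA_VERSION
    manifest["n_units"] = len(bundle.units)
    manifest["has_eye"] = bundle.eye is not None
    manifest["unit_params"] = [
        _to_plain(dataclasses.asdict(u.params)) for u in bundle.units
    ]
    manifest = _to_plain(manifest)
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    # %.17g round-trips 64-bit floats exactly through text
    bundle.trials.to_csv(path / "trials.csv", index=False, float_format="%.17g")
    for i, u in enumerate(bundle.units):
        np.savetxt(path / "units" / f"unit_{i:03d}.txt", u.spike_times, fmt="%.17g")
    if bundle.eye is not None:
        np.savez(path / "eye.npz", **bundle.eye)
    return path


def read_bundle(path: str | Path) -> SessionBundle:
    """Read a bundle directory, validating schema and integrity."""
    path = Path(path)
    mpath = path / "manifest.yaml"
    if not mpath.exists():
        raise BundleIntegrityError(f"missing manifest: {mpath}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(f"schema version {version} != {SCHEMA_VERSION}")

    tpath = path / "trials.csv"
    if not tpath.exists():
        raise BundleIntegrityError(f"missing trial table: {tpath}")
    trials = pd.read_csv(tpath, float_precision="round_trip")

    units: list[SpikeTrainSet] = []
    for i, pdict in enumerate(manifest.get("unit_params", [])):
        upath = path / "units" / f"unit_{i:03d}.txt"
        if not upath.exists():
            raise BundleIntegrityError(f"missing spike file: {upath}")
        times = np.loadtxt(upath, ndmin=1)
        if times.size and np.any(np.diff(times) < 0):
            raise BundleIntegrityError(f"unit {i}: non-monotone spike times")
        pdict = {k: (tuple(v) if isinstance(v, list) else v) for k, v in pdict.items()}
        units.append(SpikeTrainSet(times, NeuronParams(**pdict)))

    eye = None
    if manifest.get("has_eye"):
        epath = path / "eye.npz"
        if not epath.exists():
            raise BundleIntegrityError(f"missing eye trace: {epath}")
        with np.load(epath) as data:
            eye = {k: data[k] for k in data.files}

    meta = {k: v for k, v in manifest.items() if k != "unit_params"}
    bundle = SessionBundle(meta, trials, units, eye)
    bundle.validate()
    return bundle
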