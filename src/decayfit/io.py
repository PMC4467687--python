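"""Delimited-text file formats and run manifests.

Everything is diffable TSV/YAML: histogram files carry a ``#`` header with
the bin width and bin count followed by ``bin<TAB>count`` rows; photon-time
files hold one delay time (ps) per line; study configurations are YAML
mappings mirroring :class:`~decayfit.simulate.StudyConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError
from .models import BinSpec, Histogram
from .simulate import StudyConfig

__all__ = [
    "read_histogram",
    "write_histogram",
    "read_photon_times",
    "write_photon_times",
    "read_study_config",
    "write_study_config",
    "run_manifest",
    "write_records",
]


def read_histogram(path) -> Histogram:
    """Read a TSV histogram file (``# delta = ...``, ``# m = ...`` header)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[int, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"expected 'bin<TAB>count', got {line!r}", line=lineno
                )
            try:
                rows.append((int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise FormatError(str(exc), line=lineno) from exc
    for key in ("delta", "m"):
        if key not in meta:
            raise FormatError(f"missing '# {key} = ...' header line")
    try:
        b = BinSpec(delta=float(meta["delta"]), m=int(meta["m"]))
    except ValueError as exc:
        raise FormatError(f"bad header values: {exc}") from exc
    if [r[0] for r in rows] != list(range(1, b.m + 1)):
        raise FormatError(f"bin indices must run contiguously 1..{b.m}")
    counts = np.array([r[1] for r in rows], dtype=np.int64)
    if np.any(counts < 0):
        raise FormatError("counts must be non-negative")
    return Histogram(counts=counts, binspec=b)


def write_histogram(h: Histogram, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# decayfit histogram v1\n")
        fh.write(f"# delta = {h.binspec.delta!r}\n")
        fh.write(f"# m = {h.binspec.m}\n")
        for j, y in enumerate(h.counts, start=1):
            fh.write(f"{j}\t{int(y)}\n")


def read_photon_times(path) -> np.ndarray:
    """Read one delay time (ps) per line; '#' comment lines allowed."""
    path = Path(path)
    values = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError as exc:
                raise FormatError(f"not a number: {line!r}", line=lineno) from exc
            if not np.isfinite(v) or v < 0:
                raise FormatError(
                    f"delay times must be finite and >= 0, got {v}", line=lineno
                )
            values.append(v)
    return np.asarray(values, dtype=float)


def write_photon_times(times, path) -> None:
    path = Path(path)
    arr = np.asarray(times, dtype=float)
    with path.open("w") as fh:
        fh.write("# decayfit photon delay times (ps), one per line\n")
        for v in arr:
            fh.write(f"{float(v)!r}\n")


_CONFIG_KEYS = {
    "tau1", "c_values", "k_values", "delta", "m", "n_photons",
    "n_reps", "seed", "tau1_known", "hellinger_n", "cap_ps",
}


def read_study_config(path) -> StudyConfig:
    """Load a YAML study configuration; keys mirror StudyConfig fields."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("study config must be a YAML mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    for key in ("c_values", "k_values"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return StudyConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"bad config values: {exc}") from exc


def write_study_config(cfg: StudyConfig, path) -> None:
    path = Path(path)
    payload = {k: v for k, v in asdict(cfg).items() if k in _CONFIG_KEYS}
    for key in ("c_values", "k_values"):
        payload[key] = list(payload[key])
    with path.open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def run_manifest(cfg: StudyConfig, package_version: str) -> dict:
    """Config + seed + version fingerprint making a run traceable."""
    payload = {k: v for k, v in asdict(cfg).items() if k in _CONFIG_KEYS}
    payload["package_version"] = package_version
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=list).encode()
    ).hexdigest()[:16]
    return {**payload, "manifest_hash": digest}


def write_records(df: pd.DataFrame, path, manifest: dict | None = None) -> None:
    """Write a records/summary table as TSV with a '#'-prefixed manifest header."""
    path = Path(path)
    with path.open("w") as fh:
        if manifest:
            fh.write(f"# manifest_hash = {manifest['manifest_hash']}\n")
            fh.write(f"# manifest = {json.dumps(manifest, sort_keys=True, default=list)}\n")
        df.to_csv(fh, sep="\t", index=True)
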