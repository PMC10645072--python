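"""Reading and writing excitation-emission scan data.

A fluorescence scan for red edge excitation shift (REES) analysis is a
stack of emission spectra, one per excitation wavelength (default
292-310 nm excitation, 325-500 nm emission, 1 nm steps).  Two text
dialects are supported, matching the common spectrometer export shapes:

``wide``
    Rectangular matrix: first column is the emission wavelength, one
    further column per excitation wavelength (header row carries the
    excitation grid).

``long``
    Three columns ``excitation,emission,intensity``.

Sample metadata (id, group, replicate, tryptophan count) travels in a
JSON manifest with one record per scan file rather than being encoded in
filenames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "SampleScan",
    "ScanFormatError",
    "ScanValidationError",
    "read_scan",
    "write_scan",
    "read_manifest",
    "write_manifest",
    "ingest_dataset",
]

DIALECTS = ("wide", "long")


class ScanValidationError(ValueError):
    """A scan violates a structural invariant (grids, signs, metadata)."""


class ScanFormatError(ValueError):
    """A scan file cannot be parsed in the declared dialect."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ScanValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ScanValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission spectrum recorded at a single excitation wavelength.

    Intensities are arbitrary fluorescence units and must be
    non-negative; construct with ``clip_negative=True`` (see
    :func:`read_scan`) to zero out small negative baseline artefacts
    instead of rejecting them.
    """

    excitation_wavelength: float
    emission_wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        em = _as_float_array(self.emission_wavelengths, "emission_wavelengths")
        f = _as_float_array(self.intensities, "intensities")
        if em.size < 2:
            raise ScanValidationError("spectrum needs at least two emission points")
        if em.size != f.size:
            raise ScanValidationError(
                f"length mismatch: {em.size} wavelengths vs {f.size} intensities"
            )
        steps = np.diff(em)
        if np.any(steps <= 0):
            bad = em[1:][steps <= 0][0]
            raise ScanValidationError(
                f"emission wavelengths not strictly increasing near {bad:g} nm"
            )
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ScanValidationError("emission grid step is not uniform")
        if np.any(f < 0):
            raise ScanValidationError(
                "negative intensities; pass clip_negative=True to clip to zero"
            )
        object.__setattr__(self, "emission_wavelengths", em)
        object.__setattr__(self, "intensities", f)

    @property
    def step(self) -> float:
        return float(self.emission_wavelengths[1] - self.emission_wavelengths[0])


@dataclass(frozen=True)
class SampleScan:
    """A full excitation-emission matrix for one sample replicate."""

    sample_id: str
    group_label: str
    replicate_index: int
    spectra: tuple[EmissionSpectrum, ...]
    n_trp: int | None = None

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ScanValidationError("scan has no spectra")
        spectra = tuple(self.spectra)
        ex = np.array([s.excitation_wavelength for s in spectra])
        if np.any(np.diff(ex) <= 0):
            raise ScanValidationError("excitation wavelengths not strictly increasing")
        grid = spectra[0].emission_wavelengths
        for s in spectra[1:]:
            if not np.array_equal(s.emission_wavelengths, grid):
                raise ScanValidationError(
                    f"spectrum at excitation {s.excitation_wavelength:g} nm has a "
                    "different emission grid"
                )
        if self.replicate_index < 1:
            raise ScanValidationError("replicate_index must be >= 1")
        object.__setattr__(self, "spectra", spectra)

    @property
    def excitation_wavelengths(self) -> np.ndarray:
        return np.array([s.excitation_wavelength for s in self.spectra])

    @property
    def emission_wavelengths(self) -> np.ndarray:
        return self.spectra[0].emission_wavelengths

    def intensity_matrix(self) -> np.ndarray:
        """Emission rows x excitation columns."""
        return np.column_stack([s.intensities for s in self.spectra])

    def __eq__(self, other) -> bool:  # dataclass eq fails on arrays
        if not isinstance(other, SampleScan):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.group_label == other.group_label
            and self.replicate_index == other.replicate_index
            and self.n_trp == other.n_trp
            and len(self.spectra) == len(other.spectra)
            and all(
                a.excitation_wavelength == b.excitation_wavelength
                and np.array_equal(a.emission_wavelengths, b.emission_wavelengths)
                and np.array_equal(a.intensities, b.intensities)
                for a, b in zip(self.spectra, other.spectra)
            )
        )


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _parse_wide(df: pd.DataFrame, path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        excitation = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ScanFormatError(f"{path}: non-numeric excitation header: {exc}") from None
    emission = df.iloc[:, 0].to_numpy(dtype=float)
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    return excitation, emission, matrix


def _parse_long(df: pd.DataFrame, path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    required = {"excitation", "emission", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ScanFormatError(f"{path}: long dialect missing columns {sorted(missing)}")
    pivot = df.pivot_table(
        index="emission", columns="excitation", values="intensity", aggfunc="first"
    )
    if pivot.isna().any().any():
        raise ScanFormatError(f"{path}: incomplete excitation-emission grid")
    n_expected = pivot.shape[0] * pivot.shape[1]
    if len(df) != n_expected:
        raise ScanFormatError(
            f"{path}: {len(df)} rows for a {pivot.shape[0]}x{pivot.shape[1]} grid "
            "(duplicate or missing points)"
        )
    return (
        pivot.columns.to_numpy(dtype=float),
        pivot.index.to_numpy(dtype=float),
        pivot.to_numpy(dtype=float),
    )


def read_scan(
    path,
    dialect: str = "wide",
    *,
    sample_id: str,
    group_label: str,
    replicate_index: int = 1,
    n_trp: int | None = None,
    clip_negative: bool = False,
    sep: str = ",",
) -> SampleScan:
    """Read one scan file into a validated :class:`SampleScan`.

    Metadata is passed explicitly (normally sourced from a manifest, see
    :func:`ingest_dataset`).  Negative intensities are rejected unless
    ``clip_negative`` is set, in which case they are clipped to zero.
    """
    _check_dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ScanFormatError(f"{path}: {exc}") from None
    if dialect == "wide":
        excitation, emission, matrix = _parse_wide(df, path)
    else:
        excitation, emission, matrix = _parse_long(df, path)
    if np.any(np.diff(emission) <= 0):
        dup = emission[1:][np.diff(emission) <= 0]
        raise ScanValidationError(
            f"{path}: emission wavelengths not strictly increasing "
            f"(offending value {dup[0]:g} nm)"
        )
    if clip_negative:
        matrix = np.clip(matrix, 0.0, None)
    spectra = tuple(
        EmissionSpectrum(float(ex), emission, matrix[:, j])
        for j, ex in enumerate(excitation)
    )
    return SampleScan(
        sample_id=sample_id,
        group_label=group_label,
        replicate_index=int(replicate_index),
        spectra=spectra,
        n_trp=n_trp,
    )


def write_scan(scan: SampleScan, path, dialect: str = "wide", *, sep: str = ",") -> None:
    """Write a scan so that :func:`read_scan` reproduces it exactly.

    Full float precision (repr) is used so round-trips are bit-identical.
    """
    _check_dialect(dialect)
    if not isinstance(scan, SampleScan):
        raise ScanValidationError("write_scan expects a SampleScan")
    path = Path(path)
    if dialect == "wide":
        df = pd.DataFrame(
            scan.intensity_matrix(),
            columns=[repr(float(x)) for x in scan.excitation_wavelengths],
        )
        df.insert(0, "emission", scan.emission_wavelengths)
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    else:
        ex = scan.excitation_wavelengths
        em = scan.emission_wavelengths
        rows = pd.DataFrame(
            {
                "excitation": np.repeat(ex, em.size),
                "emission": np.tile(em, ex.size),
                "intensity": scan.intensity_matrix().T.ravel(),
            }
        )
        rows.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass(frozen=True)
class ManifestEntry:
    file: str
    sample_id: str
    group: str
    replicate: int
    n_trp: int | None = None
    dialect: str = "wide"


_MANIFEST_KEYS = ("file", "sample_id", "group", "replicate")


def read_manifest(path) -> list[ManifestEntry]:
    path = Path(path)
    records = json.loads(path.read_text())
    if not isinstance(records, list):
        raise ScanFormatError(f"{path}: manifest must be a JSON array")
    entries = []
    for i, rec in enumerate(records):
        missing = [k for k in _MANIFEST_KEYS if k not in rec]
        if missing:
            raise ScanValidationError(
                f"{path}: manifest record {i} missing required keys {missing}"
            )
        entries.append(
            ManifestEntry(
                file=rec["file"],
                sample_id=rec["sample_id"],
                group=rec["group"],
                replicate=int(rec["replicate"]),
                n_trp=rec.get("n_trp"),
                dialect=rec.get("dialect", "wide"),
            )
        )
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path) -> None:
    records = [
        {
            "file": e.file,
            "sample_id": e.sample_id,
            "group": e.group,
            "replicate": e.replicate,
            "n_trp": e.n_trp,
            "dialect": e.dialect,
        }
        for e in entries
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def ingest_dataset(
    manifest_path,
    *,
    base_dir=None,
    clip_negative: bool = False,
    blank: SampleScan | None = None,
) -> list[SampleScan]:
    """Load every scan listed in a manifest.

    ``blank`` optionally subtracts a buffer-blank scan (same grids) from
    each sample before validation; off by default.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    scans = []
    for entry in read_manifest(manifest_path):
        scan = read_scan(
            base / entry.file,
            entry.dialect,
            sample_id=entry.sample_id,
            group_label=entry.group,
            replicate_index=entry.replicate,
            n_trp=entry.n_trp,
            clip_negative=clip_negative,
        )
        if blank is not None:
            scan = subtract_blank(scan, blank)
        scans.append(scan)
    return scans


def subtract_blank(scan: SampleScan, blank: SampleScan) -> SampleScan:
    """Subtract a buffer-blank scan point-wise, clipping at zero."""
    if not np.array_equal(scan.excitation_wavelengths, blank.excitation_wavelengths):
        raise ScanValidationError("blank excitation grid differs from sample")
    if not np.array_equal(scan.emission_wavelengths, blank.emission_wavelengths):
        raise ScanValidationError("blank emission grid differs from sample")
    spectra = tuple(
        EmissionSpectrum(
            s.excitation_wavelength,
            s.emission_wavelengths,
            np.clip(s.intensities - b.intensities, 0.0, None),
        )
        for s, b in zip(scan.spectra, blank.spectra)
    )
    return replace(scan, spectra=spectra)
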