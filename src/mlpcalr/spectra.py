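"""Replicate NIR spectra: data model, CSV I/O, and preprocessing operators.

A spectral data set couples a wavelength grid with a flat list of replicate
scans, each carrying the metadata needed downstream: which specimen and bone
it came from, which instrument and session recorded it, and its class label
(historical = 1, the positive class; modern = 0; or unknown).

The preprocessing operators (SNV, MSC, Savitzky-Golay smoothing/derivatives,
mean centering) are the standard scatter-correction toolbox used by the
PLS-DA arm; the MLPCA arm works on raw absorbances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "WavelengthGrid",
    "SpectrumRecord",
    "SpectraSet",
    "read_spectra_csv",
    "write_spectra_csv",
    "average_replicates",
    "snv",
    "msc",
    "savgol",
    "mean_center",
]

METADATA_COLUMNS = (
    "specimen_id",
    "bone_type",
    "class_label",
    "instrument_id",
    "session",
    "replicate_index",
)

BONE_TYPES = ("skull", "mandible")

#: text <-> integer coding of the class label; historical is the positive class
CLASS_TO_INT = {"historical": 1, "modern": 0, "unknown": None}
INT_TO_CLASS = {1: "historical", 0: "modern", None: "unknown"}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis of one instrument, in nanometers."""

    instrument_id: str
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("wavelength grid must be a 1-D vector of length >= 2")
        if np.any(w <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths_nm.size


@dataclass(frozen=True)
class SpectrumRecord:
    """One scan: absorbance vector plus acquisition metadata.

    ``replicate_index`` starts at 1 for raw scans; the value 0 is reserved for
    replicate-mean spectra produced by :func:`average_replicates`.
    """

    specimen_id: str
    bone_type: str
    class_label: int | None  # 1 = historical (positive), 0 = modern, None = unknown
    instrument_id: str
    session: str
    replicate_index: int
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", a)
        if a.ndim != 1:
            raise ValueError("absorbance must be a 1-D vector")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance values must be finite")
        if self.bone_type not in BONE_TYPES:
            raise ValueError(f"bone_type must be one of {BONE_TYPES}, got {self.bone_type!r}")
        if self.class_label not in (0, 1, None):
            raise ValueError("class_label must be 0, 1 or None")

    @property
    def group_key(self) -> tuple[str, str, str]:
        """Replicate-group key: (specimen_id, bone_type, instrument_id)."""
        return (self.specimen_id, self.bone_type, self.instrument_id)


@dataclass
class SpectraSet:
    """A wavelength grid plus the replicate scans recorded on it."""

    grid: WavelengthGrid
    records: list[SpectrumRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.grid)
        for rec in self.records:
            if rec.absorbance.size != m:
                raise ValueError(
                    f"record {rec.specimen_id!r} has {rec.absorbance.size} channels, "
                    f"grid has {m}"
                )
        seen: set[tuple[str, str, str, int]] = set()
        for rec in self.records:
            key = (*rec.group_key, rec.replicate_index)
            if key in seen:
                raise ValueError(f"duplicate replicate_index {rec.replicate_index} in group {rec.group_key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def to_matrix(self) -> np.ndarray:
        """Stack all records into an (n_records, n_channels) matrix."""
        if not self.records:
            return np.empty((0, len(self.grid)))
        return np.vstack([r.absorbance for r in self.records])

    def labels(self) -> np.ndarray:
        """Class labels of the records in order (NaN where unknown)."""
        return np.array(
            [np.nan if r.class_label is None else float(r.class_label) for r in self.records]
        )

    def groups(self) -> dict[tuple[str, str, str], list[SpectrumRecord]]:
        """Records keyed by replicate group, preserving record order."""
        out: dict[tuple[str, str, str], list[SpectrumRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.group_key, []).append(rec)
        return out

    def subset(self, predicate) -> "SpectraSet":
        """New SpectraSet with the records for which ``predicate(record)`` holds."""
        return SpectraSet(self.grid, [r for r in self.records if predicate(r)])

    def select_stratum(self, instrument_id: str, bone_type: str) -> "SpectraSet":
        return self.subset(
            lambda r: r.instrument_id == instrument_id and r.bone_type == bone_type
        )

    def specimen_ids(self) -> list[str]:
        """Unique specimen ids in first-appearance order."""
        seen: list[str] = []
        for r in self.records:
            if r.specimen_id not in seen:
                seen.append(r.specimen_id)
        return seen


def read_spectra_csv(path) -> SpectraSet:
    """Read a replicate spectra table.

    Expected layout: one header row; the metadata columns
    ``specimen_id, bone_type, class_label, instrument_id, session,
    replicate_index`` followed by one numeric column per wavelength (nm).
    Wavelength columns may appear in any order; they are sorted ascending.
    Class labels may be given as text (historical/modern/unknown) or as 0/1.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "session": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing metadata column(s): {missing}")

    wl_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column header: {exc}") from None
    if np.unique(wavelengths).size != wavelengths.size:
        raise ValueError("duplicate wavelength columns")
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    wl_cols = [wl_cols[i] for i in order]

    instruments = df["instrument_id"].unique()
    if len(instruments) != 1:
        raise ValueError(
            "one CSV file holds one instrument's grid; "
            f"found instruments {sorted(map(str, instruments))}"
        )
    grid = WavelengthGrid(str(instruments[0]), wavelengths)

    absorbance = df[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(absorbance)):
        raise ValueError("non-finite or missing absorbance values")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, "class_label")
        if isinstance(raw, str):
            if raw not in CLASS_TO_INT:
                raise ValueError(f"unknown class label {raw!r}")
            label = CLASS_TO_INT[raw]
        elif pd.isna(raw):
            label = None
        else:
            label = int(raw)
        records.append(
            SpectrumRecord(
                specimen_id=str(getattr(row, "specimen_id")),
                bone_type=str(getattr(row, "bone_type")),
                class_label=label,
                instrument_id=str(getattr(row, "instrument_id")),
                session=str(getattr(row, "session")),
                replicate_index=int(getattr(row, "replicate_index")),
                absorbance=absorbance[i],
            )
        )
    return SpectraSet(grid, records)


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet in the layout :func:`read_spectra_csv` reads.

    Column order is deterministic: metadata first, wavelengths ascending.
    """
    meta = {
        "specimen_id": [r.specimen_id for r in spectra.records],
        "bone_type": [r.bone_type for r in spectra.records],
        "class_label": [INT_TO_CLASS[r.class_label] for r in spectra.records],
        "instrument_id": [r.instrument_id for r in spectra.records],
        "session": [r.session for r in spectra.records],
        "replicate_index": [r.replicate_index for r in spectra.records],
    }
    mat = spectra.to_matrix()
    wl_cols = {
        format(wl, ".6g"): mat[:, j] for j, wl in enumerate(spectra.grid.wavelengths_nm)
    }
    df = pd.concat([pd.DataFrame(meta), pd.DataFrame(wl_cols)], axis=1)
    df.to_csv(path, index=False)


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Collapse each replicate group to its channel-wise mean spectrum.

    The mean record keeps the group's metadata (session of the first
    replicate) and gets ``replicate_index = 0``.
    """
    records = []
    for group in spectra.groups().values():
        mean = np.mean([r.absorbance for r in group], axis=0)
        records.append(replace(group[0], replicate_index=0, absorbance=mean))
    return SpectraSet(spectra.grid, records)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale one spectrum to sd 1.

    Uses the sample standard deviation (ddof=1). Raises on a flat spectrum.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a zero-variance spectrum")
    return (x - x.mean()) / sd


def msc(
    matrix: np.ndarray, reference: np.ndarray | str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as x = a*ref + b (simple least squares) and
    replaced by (x - b)/a. ``reference="mean"`` fits the column-mean spectrum
    of ``matrix``; pass the stored reference back in to transform new data
    with frozen training statistics.

    Returns (corrected matrix, reference used).
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be a vector or 'mean'")
        ref = x.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.size != x.shape[1]:
        raise ValueError("reference length does not match number of channels")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("MSC reference has zero variance; slope undefined")
    xc = x - x.mean(axis=1, keepdims=True)
    a = xc @ rc / denom  # per-row slope
    b = x.mean(axis=1) - a * ref.mean()  # per-row intercept
    if np.any(a == 0):
        raise ValueError("zero MSC slope; cannot rescale")
    corrected = (x - b[:, None]) / a[:, None]
    return corrected, ref


def savgol(
    spectrum: np.ndarray, window: int, polyorder: int, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay smoothing or derivative of one spectrum.

    ``window`` must be odd and in 7..21 (the searched range); derivatives are
    per channel index, not per nm. Edges are handled by fitting the local
    polynomial on the one-sided frame, so length is preserved.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not 7 <= window <= 21:
        raise ValueError("window must be in 7..21")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    if x.size < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(x, window_length=window, polyorder=polyorder, deriv=deriv, mode="interp")


def mean_center(
    matrix: np.ndarray, fitted_mean: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix; reuse a training mean on new data.

    Returns (centered matrix, mean used). With ``fitted_mean`` given, only a
    subtraction is performed — no re-estimation on the new rows.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if fitted_mean is None:
        mean = x.mean(axis=0)
    else:
        mean = np.asarray(fitted_mean, dtype=float)
        if mean.size != x.shape[1]:
            raise ValueError("fitted_mean length does not match matrix columns")
    return x - mean, mean
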