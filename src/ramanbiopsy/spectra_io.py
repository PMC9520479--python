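"""Reading, validation and writing of Raman spectra and associated tables.

Spectra travel in plain CSV in one of two dialects:

* ``wide``  — first column ``wavenumber``, one column per spectrum; per-spectrum
  metadata in a JSON sidecar keyed by spectrum id.
* ``long``  — columns ``spectrum_id, wavenumber, intensity`` plus the same
  sidecar.

Band libraries are CSV with header ``component,lo,hi``.  Classification
reports are JSON.  Vendor binary formats are deliberately out of scope.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUE_CLASSES = ("normal", "edge", "center")

#: Instrument axis used throughout: 2050 points spanning 127-2830 cm^-1.
AXIS_N_POINTS = 2050
AXIS_LO = 127.0
AXIS_HI = 2830.0


class SpectraIOError(ValueError):
    """Raised on malformed spectral files or invalid domain objects."""


@dataclass(frozen=True)
class SpectralAxis:
    """Shared Raman-shift axis (cm^-1), strictly increasing and finite."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise SpectraIOError("axis must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(wn)):
            raise SpectraIOError("axis contains non-finite wavenumbers")
        if not np.all(np.diff(wn) > 0):
            raise SpectraIOError("axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return np.array_equal(self.wavenumbers, other.wavenumbers)

    def __hash__(self) -> int:
        return hash(self.wavenumbers.tobytes())


def default_axis(n_points: int = AXIS_N_POINTS,
                 lo: float = AXIS_LO, hi: float = AXIS_HI) -> SpectralAxis:
    """Evenly spaced axis emulating the spectrometer grid."""
    return SpectralAxis(np.linspace(lo, hi, n_points))


@dataclass(frozen=True)
class SpectrumMeta:
    spectrum_id: str
    patient_id: str = ""
    sample_id: str = ""
    replicate: int = 1
    tissue_class: str | None = None
    frame_kind: str = "measurement"

    def __post_init__(self) -> None:
        if self.tissue_class is not None and self.tissue_class not in TISSUE_CLASSES:
            raise SpectraIOError(
                f"unknown tissue_class {self.tissue_class!r}; "
                f"expected one of {TISSUE_CLASSES}")
        if self.frame_kind not in ("measurement", "background"):
            raise SpectraIOError(f"unknown frame_kind {self.frame_kind!r}")
        if self.replicate < 1:
            raise SpectraIOError("replicate index must be >= 1")


@dataclass(frozen=True)
class Spectrum:
    """One intensity trace on a shared wavenumber axis plus metadata."""

    axis: SpectralAxis
    intensities: np.ndarray
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.axis),):
            raise SpectraIOError(
                f"spectrum {self.meta.spectrum_id!r}: intensity length "
                f"{y.size} != axis length {len(self.axis)}")
        if not np.all(np.isfinite(y)):
            raise SpectraIOError(
                f"spectrum {self.meta.spectrum_id!r}: non-finite intensities")
        object.__setattr__(self, "intensities", y)

    def with_intensities(self, y: np.ndarray,
                         axis: SpectralAxis | None = None) -> "Spectrum":
        return Spectrum(axis or self.axis, y, self.meta)


@dataclass
class SpectrumSet:
    """A collection of spectra sharing one axis, with an append-only log."""

    spectra: list[Spectrum]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            ax = self.spectra[0].axis
            for s in self.spectra[1:]:
                if s.axis != ax:
                    raise SpectraIOError(
                        f"spectrum {s.meta.spectrum_id!r} has a mismatched axis")

    @property
    def axis(self) -> SpectralAxis:
        if not self.spectra:
            raise SpectraIOError("empty SpectrumSet has no axis")
        return self.spectra[0].axis

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_points) matrix."""
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self) -> list[str | None]:
        return [s.meta.tissue_class for s in self.spectra]

    def derive(self, spectra: Iterable[Spectrum], step: str) -> "SpectrumSet":
        out = SpectrumSet(list(spectra), provenance=list(self.provenance))
        out.log(step)
        return out


@dataclass(frozen=True)
class Band:
    """A Raman-shift interval attributed to a biochemical component."""

    component: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (AXIS_LO <= self.lo < self.hi <= AXIS_HI):
            raise SpectraIOError(
                f"band {self.component} [{self.lo}, {self.hi}] must satisfy "
                f"{AXIS_LO} <= lo < hi <= {AXIS_HI}")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


# Default band table assembled from shifts with reported tissue contrasts:
# cholesterol (926, 960, 1228 cm^-1), protein C-N (1097), carotenoids
# (1157, 1521), protein/cholesterol overlap (1178), hemoglobin (1546-1558),
# water (OH bending near 1635), amide I/III regions.  User-overridable.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("cholesterol", 920.0, 932.0),
    Band("cholesterol", 954.0, 966.0),
    Band("protein", 1090.0, 1104.0),
    Band("carotenoid", 1150.0, 1165.0),
    Band("protein", 1172.0, 1184.0),
    Band("cholesterol", 1222.0, 1234.0),
    Band("amide_iii", 1240.0, 1300.0),
    Band("carotenoid", 1515.0, 1528.0),
    Band("hemoglobin", 1546.0, 1558.0),
    Band("water", 1615.0, 1655.0),
    Band("amide_i", 1650.0, 1680.0),
)


def read_band_library(path: str | Path) -> list[Band]:
    """Read a band library CSV with columns ``component, lo, hi``."""
    df = pd.read_csv(path)
    required = {"component", "lo", "hi"}
    if df.empty and not required.issubset(df.columns):
        warnings.warn(f"band library {path} is empty", stacklevel=2)
        return []
    if not required.issubset(df.columns):
        raise SpectraIOError(f"band library must have columns {sorted(required)}")
    if df.empty:
        warnings.warn(f"band library {path} contains no bands", stacklevel=2)
        return []
    bands = []
    for _, row in df.iterrows():
        bands.append(Band(str(row["component"]), float(row["lo"]), float(row["hi"])))
    return bands


def write_band_library(bands: Sequence[Band], path: str | Path) -> None:
    pd.DataFrame(
        [{"component": b.component, "lo": b.lo, "hi": b.hi} for b in bands]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spectra readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _meta_from_dict(spectrum_id: str, d: dict) -> SpectrumMeta:
    return SpectrumMeta(
        spectrum_id=spectrum_id,
        patient_id=str(d.get("patient_id", "")),
        sample_id=str(d.get("sample_id", "")),
        replicate=int(d.get("replicate", 1)),
        tissue_class=d.get("tissue_class"),
        frame_kind=str(d.get("frame_kind", "measurement")),
    )


def _load_sidecar(path: Path, meta_path: str | Path | None) -> dict:
    p = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    if p.exists():
        return json.loads(p.read_text())
    return {}


def read_spectra(path: str | Path, dialect: str = "wide",
                 meta_path: str | Path | None = None) -> SpectrumSet:
    """Read spectra from CSV, returning a validated :class:`SpectrumSet`.

    Unsorted wavenumbers are sorted ascending with intensities co-permuted.
    Missing tissue_class is permitted (prediction-only use).
    """
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    side = _load_sidecar(path, meta_path)

    try:
        # round_trip parsing keeps %.17g-written float64 values bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas reports details
        raise SpectraIOError(f"cannot parse {path}: {exc}") from exc

    if dialect == "wide":
        return _read_wide(df, side)
    if dialect == "long":
        return _read_long(df, side)
    raise SpectraIOError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _coerce_numeric(series: pd.Series, what: str) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SpectraIOError(f"non-numeric value in {what} at data row {row}")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise SpectraIOError(f"missing value in {what} at data row {row}")
    return vals.to_numpy(dtype=float)


def _read_wide(df: pd.DataFrame, side: dict) -> SpectrumSet:
    if df.shape[1] < 2:
        raise SpectraIOError("wide file needs a wavenumber column plus >= 1 spectrum")
    wn = _coerce_numeric(df.iloc[:, 0], df.columns[0])
    order = np.argsort(wn)
    axis = SpectralAxis(wn[order])
    spectra = []
    for col in df.columns[1:]:
        y = _coerce_numeric(df[col], f"column {col!r}")[order]
        meta = _meta_from_dict(str(col), side.get(str(col), {}))
        spectra.append(Spectrum(axis, y, meta))
    out = SpectrumSet(spectra)
    out.log(f"read {len(spectra)} spectra (wide dialect)")
    return out


def _read_long(df: pd.DataFrame, side: dict) -> SpectrumSet:
    required = {"spectrum_id", "wavenumber", "intensity"}
    if not required.issubset(df.columns):
        raise SpectraIOError(f"long file must have columns {sorted(required)}")
    spectra = []
    axis: SpectralAxis | None = None
    for sid, grp in df.groupby("spectrum_id", sort=True):
        wn = _coerce_numeric(grp["wavenumber"], f"wavenumber of {sid!r}")
        y = _coerce_numeric(grp["intensity"], f"intensity of {sid!r}")
        order = np.argsort(wn)
        this_axis = SpectralAxis(wn[order])
        if axis is None:
            axis = this_axis
        elif this_axis != axis:
            raise SpectraIOError(f"spectrum {sid!r} has a mismatched axis")
        meta = _meta_from_dict(str(sid), side.get(str(sid), {}))
        spectra.append(Spectrum(axis, y[order], meta))
    out = SpectrumSet(spectra)
    out.log(f"read {len(spectra)} spectra (long dialect)")
    return out


def write_spectra(sset: SpectrumSet, path: str | Path, dialect: str = "wide",
                  meta_path: str | Path | None = None) -> None:
    """Write a SpectrumSet as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    if dialect == "wide":
        data = {"wavenumber": sset.axis.wavenumbers}
        for s in sset:
            data[s.meta.spectrum_id] = s.intensities
        # %.17g guarantees float64 round-trips bit-exactly through text
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    elif dialect == "long":
        frames = []
        for s in sset:
            frames.append(pd.DataFrame({
                "spectrum_id": s.meta.spectrum_id,
                "wavenumber": s.axis.wavenumbers,
                "intensity": s.intensities,
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                    float_format="%.17g")
    else:
        raise SpectraIOError(f"unknown dialect {dialect!r}")

    side = {
        s.meta.spectrum_id: {
            "patient_id": s.meta.patient_id,
            "sample_id": s.meta.sample_id,
            "replicate": s.meta.replicate,
            "tissue_class": s.meta.tissue_class,
            "frame_kind": s.meta.frame_kind,
        }
        for s in sset
    }
    p = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    p.write_text(json.dumps(side, indent=1))


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def write_report(report: dict, path: str | Path) -> None:
    """Serialize a classification/comparison report dict to JSON.

    Metric fractions get a companion ``*_pct`` string rendered to one
    decimal, so reports are directly readable.
    """
    def enrich(d: dict) -> dict:
        out = {}
        for k, v in d.items():
            if isinstance(v, dict):
                out[k] = enrich(v)
            else:
                out[k] = v
                if k in ("accuracy", "sensitivity", "specificity") and v is not None:
                    out[k + "_pct"] = f"{100.0 * float(v):.1f}"
        return out

    Path(path).write_text(json.dumps(enrich(report), indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
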