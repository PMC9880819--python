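"""Core records (peaks, spectra, LC-MS features, MS2T entries) and file I/O.

Supported formats: MGF and NIST-style MSP for MS2 spectra, TSV for aligned
feature tables and MS2T library exports. m/z values are written with 5
decimal places and intensities with 2; peaks always emerge sorted by m/z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .chem import PROTON_MASS

POSITIVE = "positive"
NEGATIVE = "negative"

INJECTION_CLASSES = ("sample", "blank", "reference")


class ParseError(ValueError):
    """A record in a spectral or tabular file could not be parsed."""


class SchemaError(ValueError):
    """A tabular file is missing required columns or violates invariants."""


class Peak(NamedTuple):
    """One centroided fragment peak: m/z (Th) and intensity (a.u.)."""

    mz: float
    intensity: float


def _clean_peaks(peaks: Iterable[tuple[float, float]]) -> tuple[Peak, ...]:
    """Validate, sort by m/z and collapse exact duplicate m/z (max intensity)."""
    seen: dict[float, float] = {}
    for mz, inten in peaks:
        mz = float(mz)
        inten = float(inten)
        if not (mz > 0) or math.isnan(mz):
            raise ValueError(f"peak m/z must be positive, got {mz}")
        if inten < 0 or math.isnan(inten):
            raise ValueError(f"peak intensity must be non-negative, got {inten}")
        if mz in seen:
            seen[mz] = max(seen[mz], inten)
        else:
            seen[mz] = inten
    return tuple(Peak(mz, seen[mz]) for mz in sorted(seen))


@dataclass(frozen=True)
class Spectrum:
    """An MS2 record: ion mode, optional precursor m/z and RT, sorted peaks."""

    id: str
    ion_mode: str
    peaks: tuple[Peak, ...]
    precursor_mz: Optional[float] = None
    retention_time: Optional[float] = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.ion_mode not in (POSITIVE, NEGATIVE):
            raise ValueError(f"ion_mode must be positive|negative, got {self.ion_mode!r}")
        object.__setattr__(self, "peaks", _clean_peaks(self.peaks))
        if self.precursor_mz is not None and not self.precursor_mz > 0:
            raise ValueError("precursor_mz must be positive when present")

    @property
    def mz(self):
        return tuple(p.mz for p in self.peaks)

    @property
    def intensity(self):
        return tuple(p.intensity for p in self.peaks)

    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)


@dataclass(frozen=True)
class FeatureRecord:
    """One aligned LC-MS feature with per-injection peak areas.

    ``areas`` maps injection label -> area; ``classes`` maps the same labels
    to one of sample | blank | reference. Ids following the RSM#####p/n
    convention are checked for mode/suffix consistency.
    """

    id: str
    ion_mode: str
    mz: float
    rt: float
    areas: Mapping[str, float] = field(default_factory=dict)
    classes: Mapping[str, str] = field(default_factory=dict)
    ms2: Optional[Spectrum] = None

    def __post_init__(self):
        if self.ion_mode not in (POSITIVE, NEGATIVE):
            raise ValueError(f"ion_mode must be positive|negative, got {self.ion_mode!r}")
        if not self.mz > 0:
            raise ValueError("feature m/z must be positive")
        if self.rt < 0:
            raise ValueError("feature retention time must be non-negative")
        suffix = self.id[-1:] if self.id else ""
        if suffix in ("p", "n") and self.id[:-1].isalnum() and self.id[:3].upper() == "RSM":
            expected = POSITIVE if suffix == "p" else NEGATIVE
            if self.ion_mode != expected:
                raise ValueError(
                    f"feature id {self.id!r} suffix conflicts with ion mode {self.ion_mode}"
                )
        for label, cls in self.classes.items():
            if cls not in INJECTION_CLASSES:
                raise ValueError(f"injection {label!r} has unknown class {cls!r}")
        for label, area in self.areas.items():
            if area < 0:
                raise ValueError(f"injection {label!r} has negative area")

    def class_areas(self, cls: str) -> list[float]:
        """Areas of all injections belonging to one class."""
        return [a for label, a in self.areas.items() if self.classes.get(label) == cls]

    def max_area(self) -> float:
        return max(self.areas.values(), default=0.0)


def neutral_mass(mz: float, ion_mode: str, proton_mass: float = PROTON_MASS) -> float:
    """Neutral monoisotopic mass from the m/z of [M+H]+ or [M-H]-."""
    if ion_mode == POSITIVE:
        return mz - proton_mass
    if ion_mode == NEGATIVE:
        return mz + proton_mass
    raise ValueError(f"unknown ion mode {ion_mode!r}")


@dataclass(frozen=True)
class MS2TEntry:
    """A feature in the MS2T library, with its (optional) annotation."""

    feature: FeatureRecord
    neutral_mass: float
    annotation_name: str = ""
    annotation_source: str = "none"
    annotation_score: Optional[float] = None
    partner_id: str = ""  # id of the opposite-mode twin after merging

    def __post_init__(self):
        if self.annotation_source not in ("experimental", "insilico", "motif", "none"):
            raise ValueError(f"unknown annotation source {self.annotation_source!r}")
        has_score = self.annotation_score is not None
        if has_score != (self.annotation_source != "none"):
            raise ValueError("annotation_score must be present iff the entry is annotated")

    @classmethod
    def from_feature(cls, feature: FeatureRecord, proton_mass: float = PROTON_MASS,
                     **kw) -> "MS2TEntry":
        return cls(feature=feature,
                   neutral_mass=neutral_mass(feature.mz, feature.ion_mode, proton_mass),
                   **kw)


# ---------------------------------------------------------------------------
# Spectral file I/O


def _mode_from_charge(charge) -> str:
    try:
        c = int(str(charge[0] if isinstance(charge, (list, tuple)) else charge)
                .replace("+", "").replace("-", "") or 1)
    except ValueError:
        c = 1
    text = str(charge)
    return NEGATIVE if "-" in text else POSITIVE


def _read_mgf(path: Path) -> list[Spectrum]:
    out = []
    with _mgf.MGF(str(path), convert_arrays=0) as reader:
        for i, rec in enumerate(reader):
            try:
                params = rec["params"]
                pep = params.get("pepmass")
                prec = float(pep[0]) if pep else None
                rt = params.get("rtinseconds")
                rt_min = float(rt) / 60.0 if rt is not None else None
                mode = _mode_from_charge(params.get("charge", "1+"))
                peaks = list(zip(rec["m/z array"], rec["intensity array"]))
                meta = {k: str(v) for k, v in params.items()
                        if k not in ("pepmass", "rtinseconds", "charge", "title")}
                out.append(Spectrum(id=str(params.get("title", f"spectrum_{i}")),
                                    ion_mode=mode, peaks=peaks, precursor_mz=prec,
                                    retention_time=rt_min, metadata=meta))
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(f"malformed MGF record at index {i}: {exc}") from exc
    return out


def _write_mgf(spectra: Sequence[Spectrum], path: Path) -> None:
    records = []
    for s in spectra:
        params = {"title": s.id, "charge": "1+" if s.ion_mode == POSITIVE else "1-"}
        if s.precursor_mz is not None:
            params["pepmass"] = round(s.precursor_mz, 5)
        if s.retention_time is not None:
            params["rtinseconds"] = round(s.retention_time * 60.0, 4)
        params.update(s.metadata)
        records.append({
            "params": params,
            "m/z array": [round(p.mz, 5) for p in s.peaks],
            "intensity array": [round(p.intensity, 2) for p in s.peaks],
        })
    with open(path, "w") as fh:
        _mgf.write(records, fh)


_MSP_FIELDS = ("NAME", "PRECURSORMZ", "IONMODE", "RETENTIONTIME", "FORMULA")


def _read_msp(path: Path) -> list[Spectrum]:
    out = []
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_expected: Optional[int] = None

    def flush(index: int):
        if not fields and not peaks:
            return
        try:
            if n_expected is not None and len(peaks) != n_expected:
                raise ValueError(f"expected {n_expected} peaks, found {len(peaks)}")
            prec = fields.get("PRECURSORMZ")
            rt = fields.get("RETENTIONTIME")
            meta = {k: v for k, v in fields.items()
                    if k not in ("NAME", "PRECURSORMZ", "IONMODE", "RETENTIONTIME")}
            out.append(Spectrum(
                id=fields.get("NAME", f"spectrum_{index}"),
                ion_mode=fields.get("IONMODE", POSITIVE).lower(),
                peaks=peaks,
                precursor_mz=float(prec) if prec else None,
                retention_time=float(rt) if rt else None,
                metadata=meta,
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"malformed MSP record at index {index}: {exc}") from exc

    with open(path) as fh:
        idx = 0
        for raw in fh:
            line = raw.strip()
            if not line:
                if fields or peaks:
                    flush(idx)
                    idx += 1
                    fields, peaks, n_expected = {}, [], None
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().upper()
                value = value.strip()
                if key == "NUM PEAKS":
                    try:
                        n_expected = int(value)
                    except ValueError as exc:
                        raise ParseError(f"malformed MSP record at index {idx}: {exc}") from exc
                else:
                    fields[key] = value
            else:
                parts = line.replace(",", " ").split()
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"malformed MSP record at index {idx}: {exc}") from exc
        if fields or peaks:
            flush(idx)
    return out


def _write_msp(spectra: Sequence[Spectrum], path: Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write(f"NAME: {s.id}\n")
            if s.precursor_mz is not None:
                fh.write(f"PRECURSORMZ: {s.precursor_mz:.5f}\n")
            fh.write(f"IONMODE: {s.ion_mode}\n")
            if s.retention_time is not None:
                fh.write(f"RETENTIONTIME: {s.retention_time:.4f}\n")
            for key in sorted(s.metadata):
                fh.write(f"{key.upper()}: {s.metadata[key]}\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.2f}\n")
            fh.write("\n")


def read_spectra(path, format: Optional[str] = None) -> list[Spectrum]:
    """Read MS2 spectra from an MGF or MSP file.

    ``format`` defaults to the file extension. Peaks are re-sorted by m/z
    when the file stores them unsorted.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "msp":
        return _read_msp(path)
    raise ValueError(f"unsupported spectral format {fmt!r}")


def write_spectra(spectra: Sequence[Spectrum], path, format: Optional[str] = None) -> None:
    """Write spectra to MGF or MSP (format inferred from the extension)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        _write_mgf(spectra, path)
    elif fmt == "msp":
        _write_msp(spectra, path)
    else:
        raise ValueError(f"unsupported spectral format {fmt!r}")


# ---------------------------------------------------------------------------
# Feature table and MS2T table I/O
#
# Feature tables are TSV with columns id, ion_mode, mz, rt and one area
# column per injection, headed "<label>|<class>" with class one of
# sample | blank | reference.

_FEATURE_BASE_COLS = ("id", "ion_mode", "mz", "rt")


def read_feature_table(path) -> list[FeatureRecord]:
    """Read an aligned LC-MS feature table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in _FEATURE_BASE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    inj_cols = [c for c in df.columns if "|" in c]
    classes = {}
    for col in inj_cols:
        label, _, cls = col.partition("|")
        if cls not in INJECTION_CLASSES:
            raise SchemaError(f"injection column {col!r} has unknown class {cls!r}")
        classes[label] = cls
    records = []
    for i, row in df.iterrows():
        areas = {}
        for col in inj_cols:
            label = col.partition("|")[0]
            val = row[col]
            if pd.isna(val):
                continue
            if val < 0:
                raise SchemaError(f"row {i}: negative area in injection {label!r}")
            areas[label] = float(val)
        try:
            records.append(FeatureRecord(
                id=str(row["id"]), ion_mode=str(row["ion_mode"]),
                mz=float(row["mz"]), rt=float(row["rt"]),
                areas=areas, classes={k: classes[k] for k in areas},
            ))
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return records


def write_feature_table(features: Sequence[FeatureRecord], path) -> None:
    """Write features to TSV with <label>|<class> area columns."""
    classes: dict[str, str] = {}
    for f in features:
        for label, cls in f.classes.items():
            classes.setdefault(label, cls)
    inj_labels = sorted(classes)
    cols = list(_FEATURE_BASE_COLS) + [f"{l}|{classes[l]}" for l in inj_labels]
    rows = []
    for f in features:
        row = {"id": f.id, "ion_mode": f.ion_mode,
               "mz": round(f.mz, 5), "rt": round(f.rt, 4)}
        for label in inj_labels:
            if label in f.areas:
                row[f"{label}|{classes[label]}"] = round(f.areas[label], 2)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


MS2T_COLUMNS = ("id", "ion_mode", "mz", "rt", "neutral_mass",
                "annotation_name", "annotation_source", "annotation_score")


def write_ms2t(entries: Sequence[MS2TEntry], path) -> None:
    """Export an MS2T library: a TSV table plus a companion MSP of spectra.

    The MSP sits next to the TSV with the same stem; its records are keyed
    by feature id.
    """
    path = Path(path)
    rows = []
    tagged = []
    for e in entries:
        f = e.feature
        rows.append({
            "id": f.id, "ion_mode": f.ion_mode,
            "mz": round(f.mz, 5), "rt": round(f.rt, 4),
            "neutral_mass": round(e.neutral_mass, 5),
            "annotation_name": e.annotation_name or "",
            "annotation_source": e.annotation_source if e.annotation_source != "none" else "",
            "annotation_score": "" if e.annotation_score is None else round(e.annotation_score, 4),
        })
        if f.ms2 is not None:
            s = f.ms2
            tagged.append(Spectrum(id=f.id, ion_mode=s.ion_mode, peaks=s.peaks,
                                   precursor_mz=s.precursor_mz,
                                   retention_time=s.retention_time,
                                   metadata=s.metadata))
    pd.DataFrame(rows, columns=MS2T_COLUMNS).to_csv(path, sep="\t", index=False)
    _write_msp(tagged, path.with_suffix(".msp"))
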