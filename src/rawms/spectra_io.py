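"""Reading, validating and writing raw SWATH runs (mzML / mzXML).

A run is one sample's acquisition: a single MS1 scan series over the
precursor mass range plus one MS2 scan series per precursor isolation
window. Files are read with pyteomics; writing emits a minimal mzML 1.1
(centroided spectra, 64-bit little-endian float arrays) or mzXML dialect
that the readers parse back losslessly.

Retention times are normalized to seconds on read regardless of the unit
stored in the file, so every downstream stage sees one convention.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from pyteomics import mzxml as _mzxml

from .errors import FormatError, SchemeMismatchError, ValidationError

__all__ = [
    "Scan",
    "MsRun",
    "WindowScheme",
    "read_run",
    "write_run",
    "validate_window_scheme",
]


@dataclass
class Scan:
    """One recorded spectrum: centroided (m/z, intensity) pairs at one RT.

    ``precursor_window`` holds the isolation-window bounds (lower, upper in
    Th) and is present exactly for MS2 scans.
    """

    ms_level: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    precursor_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ms_level not in (1, 2):
            raise ValidationError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValidationError("mz values must be strictly increasing")
        if self.intensity.size and float(self.intensity.min()) < 0:
            raise ValidationError("intensities must be nonnegative")
        if self.ms_level == 2:
            if self.precursor_window is None:
                raise ValidationError("MS2 scan lacks precursor isolation window")
            lo, hi = self.precursor_window
            if not lo < hi:
                raise ValidationError(
                    f"isolation window must have lower < upper, got ({lo}, {hi})"
                )
        elif self.precursor_window is not None:
            raise ValidationError("MS1 scan must not carry a precursor window")


@dataclass
class WindowScheme:
    """Ordered precursor isolation windows, ascending by lower bound."""

    windows: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for lo, hi in self.windows:
            if not lo < hi:
                raise ValidationError(f"window bounds must satisfy lower < upper: ({lo}, {hi})")
        lowers = [w[0] for w in self.windows]
        if lowers != sorted(lowers):
            raise ValidationError("windows must be ordered by ascending lower bound")

    def __len__(self) -> int:
        return len(self.windows)

    def index_of(self, window: tuple[float, float], tol: float = 0.01) -> int:
        for i, (lo, hi) in enumerate(self.windows):
            if abs(lo - window[0]) <= tol and abs(hi - window[1]) <= tol:
                return i
        raise ValidationError(f"window {window} not in scheme")


@dataclass
class MsRun:
    """One sample's raw acquisition: MS1 series + per-window MS2 series."""

    run_id: str
    ms1_scans: list[Scan]
    ms2_series: dict[int, list[Scan]]
    window_scheme: WindowScheme = field(default_factory=lambda: WindowScheme([]))

    def __post_init__(self) -> None:
        if not self.ms1_scans:
            raise ValidationError(f"run {self.run_id!r}: MS1 scan series is empty")
        if sorted(self.ms2_series) != list(range(len(self.window_scheme))):
            raise ValidationError(
                f"run {self.run_id!r}: MS2 series keys must be 0..K-1 matching the scheme"
            )
        for series in [self.ms1_scans, *self.ms2_series.values()]:
            if not series:
                raise ValidationError(f"run {self.run_id!r}: empty scan series")
            rts = [s.rt for s in series]
            if any(b < a for a, b in zip(rts, rts[1:])):
                raise ValidationError(f"run {self.run_id!r}: RT not nondecreasing in a series")
        for idx, series in self.ms2_series.items():
            lo, hi = self.window_scheme.windows[idx]
            for scan in series:
                slo, shi = scan.precursor_window  # type: ignore[misc]
                if abs(slo - lo) > 0.01 or abs(shi - hi) > 0.01:
                    raise ValidationError(
                        f"run {self.run_id!r}: scan window ({slo}, {shi}) does not match "
                        f"scheme window {idx} ({lo}, {hi})"
                    )

    @property
    def n_windows(self) -> int:
        return len(self.window_scheme)


# ---------------------------------------------------------------------------
# reading


def _rt_seconds(value) -> float:
    """Convert a pyteomics time value to seconds (files may store minutes)."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit and "minute" in str(unit):
        return v * 60.0
    return v


# mzML is parsed directly with lxml: the controlled-vocabulary params the
# run model needs (ms level, scan start time, isolation window, binary data
# encoding) are looked up by accession.
_MZML_FLOAT64 = "MS:1000523"
_MZML_FLOAT32 = "MS:1000521"
_MZML_ZLIB = "MS:1000574"
_MZML_MZ_ARRAY = "MS:1000514"
_MZML_INT_ARRAY = "MS:1000515"


def _cv_index(elem) -> dict[str, str]:
    """Map cvParam accession -> value for an element's direct children."""
    out = {}
    for child in elem:
        if etree.QName(child.tag).localname == "cvParam":
            out[child.get("accession")] = child.get("value", "")
    return out


def _decode_binary_array(arr_elem, spectrum_id: str) -> tuple[str | None, np.ndarray]:
    params = _cv_index(arr_elem)
    binary = None
    for child in arr_elem:
        if etree.QName(child.tag).localname == "binary":
            binary = child.text or ""
    if binary is None:
        raise FormatError(f"spectrum {spectrum_id!r}: binaryDataArray without <binary>")
    raw = base64.b64decode(binary)
    if _MZML_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _MZML_FLOAT32 in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = "mz" if _MZML_MZ_ARRAY in params else ("intensity" if _MZML_INT_ARRAY in params else None)
    return kind, values


def _scan_from_mzml_elem(elem) -> Scan:
    spectrum_id = elem.get("id", "?")
    params = _cv_index(elem)
    if "MS:1000511" not in params:
        raise FormatError(f"spectrum {spectrum_id!r} lacks an ms level cvParam")
    level = int(params["MS:1000511"])

    rt = None
    window = None
    arrays: dict[str, np.ndarray] = {}
    for sub in elem.iter():
        tag = etree.QName(sub.tag).localname
        if tag == "scan":
            p = _cv_index(sub)
            if "MS:1000016" in p:
                value = float(p["MS:1000016"])
                unit = next(
                    (
                        c.get("unitName", "")
                        for c in sub
                        if etree.QName(c.tag).localname == "cvParam"
                        and c.get("accession") == "MS:1000016"
                    ),
                    "",
                )
                rt = value * 60.0 if "minute" in unit else value
        elif tag == "isolationWindow":
            p = _cv_index(sub)
            try:
                target = float(p["MS:1000827"])
                window = (target - float(p["MS:1000828"]), target + float(p["MS:1000829"]))
            except KeyError as exc:
                raise ValidationError(
                    f"MS2 spectrum {spectrum_id!r} has an incomplete isolation window"
                ) from exc
        elif tag == "binaryDataArray":
            kind, values = _decode_binary_array(sub, spectrum_id)
            if kind:
                arrays[kind] = values

    if rt is None:
        raise FormatError(f"spectrum {spectrum_id!r} lacks a scan start time")
    if "mz" not in arrays or "intensity" not in arrays:
        raise FormatError(f"spectrum {spectrum_id!r} lacks m/z or intensity arrays")
    if level == 2 and window is None:
        raise ValidationError(
            f"MS2 spectrum {spectrum_id!r} lacks precursor isolation-window metadata"
        )
    return Scan(level, rt, arrays["mz"], arrays["intensity"], window)


def _read_mzml(path: Path) -> tuple[str | None, list[Scan]]:
    run_id = None
    scans: list[Scan] = []
    try:
        for _, elem in etree.iterparse(str(path), events=("end",)):
            tag = etree.QName(elem.tag).localname
            if tag == "run":
                run_id = elem.get("id") or run_id
            elif tag == "spectrum":
                scans.append(_scan_from_mzml_elem(elem))
                elem.clear()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path.name}: not well-formed mzML: {exc}") from exc
    return run_id, scans


def _scan_from_mzxml(spec: dict) -> Scan:
    level = int(spec.get("msLevel", 0))
    rt = _rt_seconds(spec["retentionTime"])
    window = None
    if level == 2:
        prec = spec.get("precursorMz")
        if not prec:
            raise ValidationError(
                f"MS2 scan num={spec.get('num')!r} lacks precursorMz metadata"
            )
        center = float(prec[0]["precursorMz"])
        width = float(prec[0].get("windowWideness", 0.0))
        if width <= 0:
            raise ValidationError(
                f"MS2 scan num={spec.get('num')!r} lacks a usable windowWideness"
            )
        window = (center - width / 2.0, center + width / 2.0)
    return Scan(level, rt, spec["m/z array"], spec["intensity array"], window)


def _group_runs(
    run_id: str, scans: Iterable[Scan], window_tol: float = 0.01
) -> MsRun:
    ms1: list[Scan] = []
    groups: list[tuple[tuple[float, float], list[Scan]]] = []
    for scan in scans:
        if scan.ms_level == 1:
            ms1.append(scan)
            continue
        win = scan.precursor_window
        assert win is not None
        for gwin, gscans in groups:
            if abs(gwin[0] - win[0]) <= window_tol and abs(gwin[1] - win[1]) <= window_tol:
                gscans.append(scan)
                break
        else:
            groups.append((win, [scan]))
    if not ms1 and not groups:
        raise ValidationError(f"run {run_id!r}: file contains no spectra")
    groups.sort(key=lambda g: g[0][0])
    scheme = WindowScheme([g[0] for g in groups])
    ms1.sort(key=lambda s: s.rt)
    series = {}
    for idx, (_, gscans) in enumerate(groups):
        gscans.sort(key=lambda s: s.rt)
        series[idx] = gscans
    return MsRun(run_id, ms1, series, scheme)


def read_run(path, format: str = "auto") -> MsRun:
    """Read one raw run from an mzML or mzXML file.

    MS2 scans are grouped by their precursor isolation window (bounds
    compared with a 0.01 Th tolerance) and windows are indexed ascending by
    lower bound. RTs are converted to seconds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = "mzXML" if suffix == ".mzxml" else "mzML"
    if format not in ("mzML", "mzXML"):
        raise ValueError(f"unknown format {format!r}")

    run_id = None
    if format == "mzML":
        run_id, scans = _read_mzml(path)
    else:
        scans = []
        try:
            with _mzxml.read(str(path)) as spectra:
                for spec in spectra:
                    scans.append(_scan_from_mzxml(spec))
        except etree.XMLSyntaxError as exc:
            raise FormatError(f"{path.name}: not well-formed mzXML: {exc}") from exc

    if not run_id:
        run_id = path.stem
    return _group_runs(run_id, scans)


def validate_window_scheme(runs: Sequence[MsRun], tol: float = 0.01) -> WindowScheme:
    """Check all runs share one isolation-window scheme; return it.

    Window bounds may differ by up to ``tol`` Th across files (storage
    precision); any count or bound mismatch raises naming the offending run.
    """
    if not runs:
        raise ValidationError("need at least one run")
    ref = runs[0].window_scheme
    for run in runs[1:]:
        sch = run.window_scheme
        if len(sch) != len(ref):
            raise SchemeMismatchError(
                f"run {run.run_id!r} has {len(sch)} windows, expected {len(ref)}"
            )
        for (lo, hi), (rlo, rhi) in zip(sch.windows, ref.windows):
            if abs(lo - rlo) > tol or abs(hi - rhi) > tol:
                raise SchemeMismatchError(
                    f"run {run.run_id!r}: window ({lo}, {hi}) differs from "
                    f"({rlo}, {rhi}) by more than {tol} Th"
                )
    return WindowScheme(list(ref.windows))


# ---------------------------------------------------------------------------
# writing

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64_doubles(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


def _cv(parent, accession: str, name: str, value: str | None = None, **unit) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = value
    attrs.update(unit)
    etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", attrs)


def _write_mzml(run: MsRun, path: Path) -> None:
    E = lambda parent, tag, **attrs: etree.SubElement(  # noqa: E731
        parent, f"{{{_MZML_NS}}}{tag}", {k: str(v) for k, v in attrs.items()}
    )
    root = etree.Element(f"{{{_MZML_NS}}}mzML", {"version": "1.1.0"})
    cvlist = E(root, "cvList", count=1)
    E(
        cvlist,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = E(root, "fileDescription")
    fcontent = E(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")

    scans: list[Scan] = list(run.ms1_scans)
    for idx in sorted(run.ms2_series):
        scans.extend(run.ms2_series[idx])

    runel = E(root, "run", id=run.run_id)
    speclist = E(runel, "spectrumList", count=len(scans))
    for i, scan in enumerate(scans):
        spec = E(
            speclist, "spectrum", index=i, id=f"scan={i + 1}", defaultArrayLength=scan.mz.size
        )
        _cv(spec, "MS:1000511", "ms level", str(scan.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        scanlist = E(spec, "scanList", count=1)
        _cv(scanlist, "MS:1000795", "no combination")
        scanel = E(scanlist, "scan")
        _cv(
            scanel,
            "MS:1000016",
            "scan start time",
            repr(scan.rt),
            unitCvRef="UO",
            unitAccession="UO:0000010",
            unitName="second",
        )
        if scan.ms_level == 2:
            lo, hi = scan.precursor_window  # type: ignore[misc]
            target = (lo + hi) / 2.0
            preclist = E(spec, "precursorList", count=1)
            prec = E(preclist, "precursor")
            iso = E(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", repr(target))
            _cv(iso, "MS:1000828", "isolation window lower offset", repr(target - lo))
            _cv(iso, "MS:1000829", "isolation window upper offset", repr(hi - target))
        arrlist = E(spec, "binaryDataArrayList", count=2)
        for accession, name, values in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            payload = _b64_doubles(values)
            arr = E(arrlist, "binaryDataArray", encodedLength=len(payload))
            _cv(arr, "MS:1000523", "64-bit float")
            _cv(arr, "MS:1000576", "no compression")
            _cv(arr, accession, name)
            binel = E(arr, "binary")
            binel.text = payload

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def _write_mzxml(run: MsRun, path: Path) -> None:
    ns = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"
    root = etree.Element(f"{{{ns}}}mzXML")

    scans: list[Scan] = list(run.ms1_scans)
    for idx in sorted(run.ms2_series):
        scans.extend(run.ms2_series[idx])

    msrun = etree.SubElement(root, f"{{{ns}}}msRun", {"scanCount": str(len(scans))})
    for i, scan in enumerate(scans):
        el = etree.SubElement(
            msrun,
            f"{{{ns}}}scan",
            {
                "num": str(i + 1),
                "msLevel": str(scan.ms_level),
                "peaksCount": str(scan.mz.size),
                "retentionTime": f"PT{scan.rt!r}S",
            },
        )
        if scan.ms_level == 2:
            lo, hi = scan.precursor_window  # type: ignore[misc]
            prec = etree.SubElement(
                el, f"{{{ns}}}precursorMz", {"windowWideness": repr(hi - lo)}
            )
            prec.text = repr((lo + hi) / 2.0)
        # network (big-endian) byte order, m/z and intensity interleaved
        interleaved = np.empty(2 * scan.mz.size, dtype=">f8")
        interleaved[0::2] = scan.mz
        interleaved[1::2] = scan.intensity
        peaks = etree.SubElement(
            el,
            f"{{{ns}}}peaks",
            {
                "precision": "64",
                "byteOrder": "network",
                "contentType": "m/z-int",
                "compressionType": "none",
                "compressedLen": "0",
            },
        )
        peaks.text = base64.b64encode(interleaved.tobytes()).decode("ascii")

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def write_run(run: MsRun, path, format: str = "mzML") -> None:
    """Write a run so that :func:`read_run` parses it back equivalently."""
    path = Path(path)
    if format == "mzML":
        _write_mzml(run, path)
    elif format == "mzXML":
        _write_mzxml(run, path)
    else:
        raise ValueError(f"unknown format {format!r}")
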