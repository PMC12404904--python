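"""mzML reading and writing with a normalized in-memory run model.

Retention time is canonically MINUTES everywhere inside the package;
unit conversion happens only at this I/O boundary. Spectra are assumed
centroided — a run advertising profile spectra is loaded anyway with a
warning, its profile points treated as centroid peaks.

Both directions are implemented directly on lxml: a streaming reader for
mzML 1.1.x (plain, indexed, or gzipped; 32/64-bit float arrays, zlib or
uncompressed) and a minimal schema-valid writer (64-bit float,
uncompressed, base64 binary arrays) sufficient for round-tripping runs.
"""

from __future__ import annotations

import base64
import gzip
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from lxml import etree

__all__ = ["SpectrumRecord", "RunData", "read_run", "write_run"]

_MZML_NS = "http://psi.hupo.org/ms/mzml"

# controlled-vocabulary activation terms -> internal labels
_ACTIVATION_TERMS = {
    "beam-type collision-induced dissociation": "HCD",
    "collision-induced dissociation": "CID",
}


@dataclass
class SpectrumRecord:
    """One scan: level, retention time (minutes), centroid peaks, MS2 metadata."""

    scan_id: str
    ms_level: int
    rt_minutes: float
    mz_array: np.ndarray
    intensity_array: np.ndarray
    precursor_mz: Optional[float] = None
    isolation_width_mz: Optional[float] = None
    activation: str = "unknown"  # HCD | CID | other | unknown
    collision_energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz_array = np.asarray(self.mz_array, dtype=np.float64)
        self.intensity_array = np.asarray(self.intensity_array, dtype=np.float64)
        if self.mz_array.shape != self.intensity_array.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz_array.size > 1 and not np.all(np.diff(self.mz_array) > 0):
            raise ValueError("m/z array must be strictly ascending")
        if np.any(self.intensity_array < 0):
            raise ValueError("negative intensity")
        if self.ms_level >= 2 and self.precursor_mz is None:
            raise ValueError(f"MS{self.ms_level} scan {self.scan_id!r} lacks precursor m/z")

    @property
    def tic(self) -> float:
        """Total ion current, recomputed from the peak list (never trusted from file)."""
        return float(self.intensity_array.sum())


@dataclass
class RunData:
    """A whole LC-MS run: ordered scans plus file-level metadata."""

    run_id: str
    scans: Sequence[SpectrumRecord] = field(default_factory=list)
    acquisition_date: Optional[str] = None  # ISO 8601 from <run startTimeStamp>

    def validate(self) -> None:
        rts = [s.rt_minutes for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError(f"run {self.run_id!r}: retention times not non-decreasing")

    def ms1_scans(self) -> list[SpectrumRecord]:
        return [s for s in self.scans if s.ms_level == 1]


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _cv_params(elem) -> dict[str, dict]:
    """Direct-child cvParams of *elem*: name -> {value, unit}."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("name")] = {
                "value": child.get("value", ""),
                "unit": child.get("unitName"),
            }
    return out


def _child(elem, name):
    for child in elem:
        if _local(child.tag) == name:
            return child
    return None


def _rt_to_minutes(value: float, unit: Optional[str]) -> float:
    if unit in ("second", "seconds", "s"):
        return value / 60.0
    if unit in ("millisecond", "milliseconds", "ms"):
        return value / 60000.0
    # 'minute' or unannotated: minutes assumed
    return value


def _decode_binary_array(bda) -> tuple[Optional[str], np.ndarray]:
    params = _cv_params(bda)
    binary = _child(bda, "binary")
    raw = base64.b64decode(binary.text or "") if binary is not None else b""
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    elif "no compression" not in params and raw:
        unknown = [p for p in params if "compression" in p]
        if unknown:
            raise ValueError(f"unsupported binary compression: {unknown}")
    dtype = "<f8" if "64-bit float" in params else "<f4" if "32-bit float" in params else None
    if dtype is None:
        raise ValueError("binary array without a recognized float encoding")
    data = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    kind = None
    if "m/z array" in params:
        kind = "mz"
    elif "intensity array" in params:
        kind = "intensity"
    return kind, data


def _spectrum_to_record(spec) -> tuple[SpectrumRecord, bool]:
    params = _cv_params(spec)
    ms_level = int(params.get("ms level", {"value": "1"})["value"] or 1)
    is_profile = "profile spectrum" in params

    rt = 0.0
    scan_list = _child(spec, "scanList")
    if scan_list is not None:
        scan = _child(scan_list, "scan")
        if scan is not None:
            sp = _cv_params(scan)
            if "scan start time" in sp:
                rt = _rt_to_minutes(
                    float(sp["scan start time"]["value"]), sp["scan start time"]["unit"]
                )

    mz = np.array([])
    inten = np.array([])
    arr_list = _child(spec, "binaryDataArrayList")
    if arr_list is not None:
        for bda in arr_list:
            if _local(bda.tag) != "binaryDataArray":
                continue
            kind, data = _decode_binary_array(bda)
            if kind == "mz":
                mz = data
            elif kind == "intensity":
                inten = data

    precursor_mz = None
    isolation_width = None
    activation = "unknown"
    nce = None
    plist = _child(spec, "precursorList")
    if plist is not None and ms_level >= 2:
        prec = _child(plist, "precursor")
        iso = _child(prec, "isolationWindow")
        if iso is not None:
            ip = _cv_params(iso)
            lo = ip.get("isolation window lower offset")
            hi = ip.get("isolation window upper offset")
            if lo and hi:
                isolation_width = float(lo["value"]) + float(hi["value"])
        silist = _child(prec, "selectedIonList")
        if silist is not None:
            sion = _child(silist, "selectedIon")
            sp = _cv_params(sion)
            if "selected ion m/z" in sp:
                precursor_mz = float(sp["selected ion m/z"]["value"])
        act_el = _child(prec, "activation")
        if act_el is not None:
            act = _cv_params(act_el)
            for term, label in _ACTIVATION_TERMS.items():
                if term in act:
                    activation = label
                    break
            else:
                # any other dissociation CV term is a known-but-other method
                if any("dissociation" in k or "decay" in k for k in act):
                    activation = "other"
            for key in ("normalized collision energy", "collision energy"):
                if key in act:
                    nce = float(act[key]["value"])
                    break
    rec = SpectrumRecord(
        scan_id=str(spec.get("id") or spec.get("index") or ""),
        ms_level=ms_level,
        rt_minutes=rt,
        mz_array=mz,
        intensity_array=inten,
        precursor_mz=precursor_mz,
        isolation_width_mz=isolation_width,
        activation=activation,
        collision_energy=nce,
    )
    return rec, is_profile


#: schema versions this reader has been written against
_SUPPORTED_VERSIONS = ("1.1.",)


def read_run(path: str | Path) -> RunData:
    """Load an mzML file (plain, indexed, or gzipped) into a :class:`RunData`.

    Scan order is preserved exactly as stored; an RT-monotonicity
    violation in the source is reported as a warning, never silently
    reordered. Profile-mode spectra are loaded with a warning, their
    points treated as centroid peaks. An unsupported schema version is
    an error, never a silent skip.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    run_id = path.name
    for suffix in (".gz", ".mzML", ".mzml"):
        if run_id.endswith(suffix):
            run_id = run_id[: -len(suffix)]

    opener = gzip.open if path.suffix == ".gz" else open
    scans: list[SpectrumRecord] = []
    acquisition_date = None
    profile_seen = False
    saw_mzml = False
    with opener(path, "rb") as fh:
        for event, elem in etree.iterparse(fh, events=("start", "end")):
            name = _local(elem.tag)
            if event == "start":
                if name == "mzML":
                    saw_mzml = True
                    version = elem.get("version")
                    if version and not version.startswith(_SUPPORTED_VERSIONS):
                        raise ValueError(
                            f"{path.name}: unsupported mzML schema version {version!r}"
                        )
                elif name == "run":
                    acquisition_date = elem.get("startTimeStamp")
                continue
            if name == "spectrum":
                rec, is_profile = _spectrum_to_record(elem)
                profile_seen = profile_seen or is_profile
                scans.append(rec)
                elem.clear()
    if not saw_mzml:
        raise ValueError(f"{path.name}: not an mzML document")
    if profile_seen:
        warnings.warn(
            f"{path.name}: profile-mode spectra encountered; points treated "
            "as centroid peaks",
            stacklevel=2,
        )
    rts = [s.rt_minutes for s in scans]
    if any(b < a for a, b in zip(rts, rts[1:])):
        warnings.warn(
            f"{path.name}: retention times are not monotonic; scan order kept as stored",
            stacklevel=2,
        )
    return RunData(run_id=run_id, scans=scans, acquisition_date=acquisition_date)


# ---------------------------------------------------------------------------
# writer

def _cv(parent, accession: str, name: str, value: str = "", **unit) -> None:
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrib.update(unit)
    etree.SubElement(parent, "cvParam", attrib)


def _binary_array(parent, data: np.ndarray, array_acc: str, array_name: str) -> None:
    raw = struct.pack(f"<{data.size}d", *map(float, data))
    b64 = base64.b64encode(raw).decode("ascii")
    bda = etree.SubElement(parent, "binaryDataArray", encodedLength=str(len(b64)))
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    _cv(bda, array_acc, array_name)
    etree.SubElement(bda, "binary").text = b64


_ACTIVATION_CV = {
    "HCD": ("MS:1000422", "beam-type collision-induced dissociation"),
    "CID": ("MS:1000133", "collision-induced dissociation"),
}


def write_run(run: RunData, path: str | Path) -> Path:
    """Serialize *run* as plain mzML 1.1.0 (centroid spectra, minute RTs).

    The run is validated first; ``read_run(write_run(r))`` round-trips scan
    count, MS levels, RTs, peak arrays and precursor metadata to float
    precision.
    """
    run.validate()
    for s in run.scans:
        _ = s.tic  # triggers array checks in __post_init__ for mutated records
    path = Path(path)

    nsmap = {None: _MZML_NS}
    root = etree.Element("mzML", nsmap=nsmap, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")

    sw_list = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(sw_list, "software", id="sstlab", version="0.1.0")

    ic_list = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    dp_list = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dp_list, "dataProcessing", id="sstlab_synthesis")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="sstlab")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_attrib = {"id": run.run_id, "defaultInstrumentConfigurationRef": "IC1"}
    if run.acquisition_date:
        run_attrib["startTimeStamp"] = run.acquisition_date
    run_el = etree.SubElement(root, "run", run_attrib)
    spec_list = etree.SubElement(
        run_el, "spectrumList", count=str(len(run.scans)),
        defaultDataProcessingRef="sstlab_synthesis",
    )

    for i, s in enumerate(run.scans):
        spec_el = etree.SubElement(
            spec_list, "spectrum", index=str(i), id=s.scan_id,
            defaultArrayLength=str(s.mz_array.size),
        )
        if s.ms_level == 1:
            _cv(spec_el, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec_el, "MS:1000580", "MSn spectrum")
        _cv(spec_el, "MS:1000511", "ms level", str(s.ms_level))
        _cv(spec_el, "MS:1000127", "centroid spectrum")
        _cv(spec_el, "MS:1000285", "total ion current", repr(s.tic))
        scan_list = etree.SubElement(spec_el, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = etree.SubElement(scan_list, "scan")
        _cv(
            scan_el, "MS:1000016", "scan start time", repr(s.rt_minutes),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        if s.ms_level >= 2:
            plist = etree.SubElement(spec_el, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            if s.isolation_width_mz is not None:
                iso = etree.SubElement(prec, "isolationWindow")
                _cv(iso, "MS:1000827", "isolation window target m/z", repr(s.precursor_mz))
                half = s.isolation_width_mz / 2.0
                _cv(iso, "MS:1000828", "isolation window lower offset", repr(half))
                _cv(iso, "MS:1000829", "isolation window upper offset", repr(half))
            silist = etree.SubElement(prec, "selectedIonList", count="1")
            sion = etree.SubElement(silist, "selectedIon")
            _cv(sion, "MS:1000744", "selected ion m/z", repr(s.precursor_mz))
            act = etree.SubElement(prec, "activation")
            if s.activation in _ACTIVATION_CV:
                acc, name = _ACTIVATION_CV[s.activation]
                _cv(act, acc, name)
            if s.collision_energy is not None:
                _cv(act, "MS:1000045", "collision energy", repr(s.collision_energy))
        arr_list = etree.SubElement(spec_el, "binaryDataArrayList", count="2")
        _binary_array(arr_list, s.mz_array, "MS:1000514", "m/z array")
        _binary_array(arr_list, s.intensity_array, "MS:1000515", "intensity array")

    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )
    return path
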