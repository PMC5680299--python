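"""Reading DDA runs from mzML, and a minimal mzML writer for synthetic runs.

The reader walks the mzML 1.1 vocabulary directly (controlled-vocabulary
accessions for ms level, scan start time, selected ion, binary array
encodings with optional zlib compression) and splits a run into MS1
survey scans and MS2 events; each MS2 is linked to the nearest preceding
survey scan and annotated with its DDA rank (position within the cycle).
The writer emits the same vocabulary (64-bit uncompressed base64 arrays)
so synthetic runs can be materialised without vendor tooling; reader and
writer are developed against each other and the reader additionally
understands 32-bit and zlib-compressed arrays as produced by common
converters.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Ms1Scan:
    scan_number: int
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class ObservedSpectrum:
    """One DDA MS/MS event."""

    scan_number: int
    rt_min: float
    precursor_mz: float
    precursor_intensity: float
    dda_rank: int
    mz: np.ndarray
    intensity: np.ndarray
    survey_scan: int  # scan number of the linked preceding MS1
    peaks: list[tuple[float, float]] = field(init=False)

    def __post_init__(self):
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self.peaks = list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class DdaRun:
    path: str
    ms1_scans: list[Ms1Scan]
    ms2_scans: list[ObservedSpectrum]
    skipped: int = 0

    def survey_for(self, spectrum: ObservedSpectrum) -> Ms1Scan | None:
        for scan in self.ms1_scans:
            if scan.scan_number == spectrum.survey_scan:
                return scan
        return None


def _scan_number(native_id: str, fallback: int) -> int:
    for token in str(native_id).split():
        if token.startswith("scan="):
            return int(token.split("=", 1)[1])
    return fallback


_NS = "{http://psi.hupo.org/ms/mzml}"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, str]:
    """accession -> value for the element's direct cvParam children."""
    return {
        ch.get("accession"): ch.get("value", "")
        for ch in elem
        if _local(ch.tag) == "cvParam"
    }


def _decode_array(bda) -> np.ndarray:
    accs = set()
    text = ""
    for ch in bda.iter():
        if _local(ch.tag) == "cvParam":
            accs.add(ch.get("accession"))
        elif _local(ch.tag) == "binary":
            text = ch.text or ""
    data = base64.b64decode(text)
    if "MS:1000574" in accs:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(data, dtype=dtype).astype(float)


def _parse_spectrum_element(elem) -> dict:
    """Flatten one <spectrum> element into the fields the pipeline needs."""
    out: dict = {
        "id": elem.get("id", ""),
        "ms_level": None,
        "rt_min": 0.0,
        "mz": np.array([]),
        "intensity": np.array([]),
        "precursor_mz": None,
        "precursor_intensity": 0.0,
    }
    params = _cv_params(elem)
    if "MS:1000511" in params:
        out["ms_level"] = int(params["MS:1000511"])
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "scan":
            for cp in child:
                if _local(cp.tag) == "cvParam" and cp.get("accession") == "MS:1000016":
                    rt = float(cp.get("value", "0"))
                    unit = cp.get("unitName", "minute")
                    out["rt_min"] = rt / 60.0 if unit.startswith("second") else rt
        elif tag == "selectedIon":
            p = _cv_params(child)
            if "MS:1000744" in p:
                out["precursor_mz"] = float(p["MS:1000744"])
            if "MS:1000042" in p:
                out["precursor_intensity"] = float(p["MS:1000042"])
        elif tag == "binaryDataArray":
            accs = {
                cp.get("accession") for cp in child if _local(cp.tag) == "cvParam"
            }
            arr = _decode_array(child)
            if "MS:1000514" in accs:
                out["mz"] = arr
            elif "MS:1000515" in accs:
                out["intensity"] = arr
    return out


def read_dda_run(path: str | Path) -> DdaRun:
    """Read an mzML file into MS1 scans and precursor-linked MS2 events.

    MS2 scans without a recorded precursor m/z are skipped and counted.
    Retention times are reported in minutes to four decimals.
    """
    ms1: list[Ms1Scan] = []
    ms2: list[ObservedSpectrum] = []
    skipped = 0
    last_ms1 = -1
    rank = 0
    index = 0
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        index += 1
        spec = _parse_spectrum_element(elem)
        elem.clear()
        scan_no = _scan_number(spec["id"], index)
        rt_min = round(spec["rt_min"], 4)
        if spec["ms_level"] == 1:
            ms1.append(Ms1Scan(scan_no, rt_min, spec["mz"], spec["intensity"]))
            last_ms1 = scan_no
            rank = 0
            continue
        if spec["ms_level"] is None or spec["precursor_mz"] is None:
            skipped += 1
            continue
        rank += 1
        ms2.append(
            ObservedSpectrum(
                scan_number=scan_no,
                rt_min=rt_min,
                precursor_mz=spec["precursor_mz"],
                precursor_intensity=spec["precursor_intensity"],
                dda_rank=rank,
                mz=spec["mz"],
                intensity=spec["intensity"],
                survey_scan=last_ms1,
            )
        )
    return DdaRun(str(path), ms1, ms2, skipped)


# ---------------------------------------------------------------------------
# writer

_CV = "MS"


def _cv(parent, accession: str, name: str, value: str = "", unit=None):
    attrib = {"cvRef": _CV, "accession": accession, "name": name, "value": value}
    if unit is not None:
        attrib.update(
            {"unitCvRef": unit[0], "unitAccession": unit[1], "unitName": unit[2]}
        )
    ET.SubElement(parent, "cvParam", attrib)


def _binary_array(parent, values: np.ndarray, kind: str):
    data = struct.pack(f"<{len(values)}d", *map(float, values))
    b64 = base64.b64encode(data).decode()
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(b64))})
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(bda, "MS:1000514", "m/z array", unit=("MS", "MS:1000040", "m/z"))
    else:
        _cv(
            bda,
            "MS:1000515",
            "intensity array",
            unit=("MS", "MS:1000131", "number of detector counts"),
        )
    ET.SubElement(bda, "binary").text = b64


@dataclass
class SpectrumRecord:
    """Input record for the writer; precursor fields used when ms_level==2."""

    ms_level: int
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_intensity: float = 0.0


def write_mzml(records: list[SpectrumRecord], path: str | Path) -> None:
    root = ET.Element(
        "mzML",
        {
            "xmlns": "http://psi.hupo.org/ms/mzml",
            "version": "1.1.0",
        },
    )
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(
        cvlist,
        "cv",
        {
            "id": "MS",
            "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
            "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
        },
    )
    ET.SubElement(
        cvlist,
        "cv",
        {
            "id": "UO",
            "fullName": "Unit Ontology",
            "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
        },
    )
    run = ET.SubElement(root, "run", {"id": "synthetic_run"})
    slist = ET.SubElement(run, "spectrumList", {"count": str(len(records))})
    for i, rec in enumerate(records):
        spec = ET.SubElement(
            slist,
            "spectrum",
            {
                "index": str(i),
                "id": f"scan={i + 1}",
                "defaultArrayLength": str(len(rec.mz)),
            },
        )
        _cv(spec, "MS:1000511", "ms level", str(rec.ms_level))
        if rec.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        _cv(spec, "MS:1000129", "negative scan")
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            f"{rec.rt_min:.4f}",
            unit=("UO", "UO:0000031", "minute"),
        )
        if rec.ms_level == 2:
            if rec.precursor_mz is None:
                raise ValueError("MS2 record requires a precursor m/z")
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            silist = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            si = ET.SubElement(silist, "selectedIon")
            _cv(
                si,
                "MS:1000744",
                "selected ion m/z",
                f"{rec.precursor_mz:.6f}",
                unit=("MS", "MS:1000040", "m/z"),
            )
            _cv(si, "MS:1000042", "peak intensity", f"{rec.precursor_intensity:.2f}")
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000133", "collision-induced dissociation")
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, rec.mz, "mz")
        _binary_array(arrays, rec.intensity, "intensity")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="unicode")
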