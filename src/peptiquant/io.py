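"""Spectrum I/O: two-column tab-separated text and a minimal mzML 1.1 subset.

The text dialect is: tab-separated ``m/z<TAB>intensity`` lines, ``#`` comment
lines; metadata round-trips through ``# key: value`` header comments. The mzML
writer emits uncompressed 64-bit float binary arrays (base64) with the usual
cvParam accessions; the reader additionally accepts zlib-compressed and 32-bit
arrays.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np

from .errors import InputError
from .spectrum import Spectrum

_MZML_NS = "http://psi.hupo.org/ms/mzml"

# cvParam accessions (PSI-MS controlled vocabulary)
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_PROFILE = "MS:1000128"
_ACC_CENTROID = "MS:1000127"


# ---------------------------------------------------------------------------
# two-column text
# ---------------------------------------------------------------------------


def write_tsv(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in spectrum.metadata.items():
            if value is not None and not isinstance(value, (dict, list)):
                fh.write(f"# {key}: {value}\n")
        for mz, intensity in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f}\t{intensity:.6f}\n")


def _parse_meta_value(text: str) -> Any:
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text in ("True", "False"):
        return text == "True"
    return text


def read_tsv(path: str | Path) -> Spectrum:
    path = Path(path)
    mzs, intensities = [], []
    metadata: Dict[str, Any] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = _parse_meta_value(value.strip())
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mzs.append(float(fields[0]))
                intensities.append(float(fields[1]))
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric value in {line!r}") from None
    try:
        return Spectrum(np.array(mzs), np.array(intensities), metadata)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# minimal mzML
# ---------------------------------------------------------------------------


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "") -> None:
    ET.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value
    )


def write_mzml(spectrum: Spectrum, path: str | Path, centroid: bool = False) -> None:
    """Write one spectrum as a minimal standalone mzML document."""
    path = Path(path)
    root = ET.Element(
        "mzML", xmlns=_MZML_NS, version="1.1.0", id=str(spectrum.metadata.get("sample_id", "spectrum"))
    )
    run = ET.SubElement(root, "run", id="run0")
    spec_list = ET.SubElement(run, "spectrumList", count="1")
    spec = ET.SubElement(
        spec_list,
        "spectrum",
        index="0",
        id=f"scan={spectrum.metadata.get('sample_id', '0')}",
        defaultArrayLength=str(len(spectrum)),
    )
    if centroid:
        _cv(spec, _ACC_CENTROID, "centroid spectrum")
    else:
        _cv(spec, _ACC_PROFILE, "profile spectrum")
    for key, value in spectrum.metadata.items():
        if value is not None and not isinstance(value, (dict, list)):
            ET.SubElement(spec, "userParam", name=str(key), value=str(value))
    arrays = ET.SubElement(spec, "binaryDataArrayList", count="2")
    for accession, name, values in (
        (_ACC_MZ_ARRAY, "m/z array", spectrum.mz),
        (_ACC_INT_ARRAY, "intensity array", spectrum.intensity),
    ):
        encoded = _encode_array(values)
        arr = ET.SubElement(arrays, "binaryDataArray", encodedLength=str(len(encoded)))
        _cv(arr, _ACC_64BIT, "64-bit float")
        _cv(arr, _ACC_NO_COMPRESSION, "no compression")
        _cv(arr, accession, name)
        ET.SubElement(arr, "binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(arr: ET.Element, path: Path) -> tuple[str, np.ndarray]:
    kind = None
    dtype = "d"
    compressed = False
    for cv in arr.iter():
        if _local(cv.tag) != "cvParam":
            continue
        acc = cv.get("accession", "")
        if acc == _ACC_MZ_ARRAY:
            kind = "mz"
        elif acc == _ACC_INT_ARRAY:
            kind = "intensity"
        elif acc == _ACC_32BIT:
            dtype = "f"
        elif acc == _ACC_ZLIB:
            compressed = True
    binary = None
    for child in arr.iter():
        if _local(child.tag) == "binary":
            binary = child.text or ""
            break
    if kind is None or binary is None:
        raise InputError(f"{path}: binaryDataArray missing array-type cvParam or <binary>")
    raw = base64.b64decode(binary)
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    if len(raw) % width:
        raise InputError(f"{path}: binary array length not a multiple of {width}")
    values = np.array(struct.unpack(f"<{len(raw) // width}{dtype}", raw), dtype=float)
    return kind, values


def read_mzml(path: str | Path) -> Spectrum:
    """Read the first spectrum of an mzML file (profile/centroid flag preserved)."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise InputError(f"{path}: malformed mzML ({exc})") from None
    spec = None
    for el in tree.iter():
        if _local(el.tag) == "spectrum":
            spec = el
            break
    if spec is None:
        raise InputError(f"{path}: no <spectrum> element found")
    metadata: Dict[str, Any] = {}
    for el in spec.iter():
        tag = _local(el.tag)
        if tag == "userParam":
            metadata[el.get("name", "")] = _parse_meta_value(el.get("value", ""))
        elif tag == "cvParam":
            if el.get("accession") == _ACC_PROFILE:
                metadata["mode"] = "profile"
            elif el.get("accession") == _ACC_CENTROID:
                metadata["mode"] = "centroid"
    arrays: Dict[str, np.ndarray] = {}
    for el in spec.iter():
        if _local(el.tag) == "binaryDataArray":
            kind, values = _decode_binary_array(el, path)
            arrays[kind] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise InputError(f"{path}: m/z or intensity array missing")
    try:
        return Spectrum(arrays["mz"], arrays["intensity"], metadata)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def read_spectrum(path: str | Path, fmt: Optional[str] = None) -> Spectrum:
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    fmt = fmt.lower()
    if fmt == "mzml":
        return read_mzml(path)
    if fmt in ("tsv", "txt"):
        return read_tsv(path)
    raise InputError(f"unknown spectrum format {fmt!r}")


def write_spectrum(spectrum: Spectrum, path: str | Path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    fmt = fmt.lower()
    if fmt == "mzml":
        write_mzml(spectrum, path)
    elif fmt in ("tsv", "txt"):
        write_tsv(spectrum, path)
    else:
        raise InputError(f"unknown spectrum format {fmt!r}")
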