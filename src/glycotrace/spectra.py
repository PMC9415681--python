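"""Spectrum container and file I/O (two-column CSV and mzML).

A :class:`Spectrum` is an ordered (axis, intensity) pair; the axis is m/z for
FTMS spectra and ppm for NMR spectra. CSV is the interchange format for both
modalities; mzML 1.1 is supported for mass spectra through a small
self-contained reader/writer (base64-encoded 32/64-bit float arrays,
optionally zlib-compressed, plain or index-wrapped documents).
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "read_peak_csv",
    "read_mzml",
    "write_mzml",
    "average_spectra",
]


@dataclass
class Spectrum:
    """Ordered (axis, intensity) pairs with an axis kind of 'mz' or 'ppm'."""

    axis: np.ndarray
    intensity: np.ndarray
    kind: str = "mz"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if self.kind not in ("mz", "ppm"):
            raise ValueError(f"unknown axis kind {self.kind!r}")
        if self.axis.size > 1 and np.any(np.diff(self.axis) <= 0):
            order = np.argsort(self.axis)
            self.axis = self.axis[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.axis.size)

    def to_csv(self, path: str | Path) -> None:
        label = "mz" if self.kind == "mz" else "ppm"
        pd.DataFrame({label: self.axis, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, kind: str | None = None) -> "Spectrum":
        return read_peak_csv(path, kind=kind)


def read_peak_csv(path: str | Path, kind: str | None = None) -> Spectrum:
    """Read a two-column (m/z or ppm, intensity) CSV, with or without header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    first = path.open().readline().lower()
    has_header = any(tok in first for tok in ("mz", "m/z", "ppm", "intensity"))
    df = pd.read_csv(path, header=0 if has_header else None)
    if kind is None:
        kind = "ppm" if (has_header and "ppm" in first) else "mz"
    axis = df.iloc[:, 0].to_numpy(float)
    inten = df.iloc[:, 1].to_numpy(float)
    return Spectrum(axis, inten, kind=kind, metadata={"source": str(path)})


def _local_name(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one ``binaryDataArray`` element: returns (array kind, values)
    where kind is 'mz', 'intensity' or None for other array types."""
    kind = None
    dtype = "<d"  # 64-bit little-endian float is the mzML default here
    compressed = False
    text = ""
    for child in bda.iter():
        name = _local_name(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
            elif acc == "MS:1000521":
                dtype = "<f"
            elif acc == "MS:1000523":
                dtype = "<d"
            elif acc == "MS:1000574":
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    n = len(raw) // width
    values = np.array(struct.unpack(f"{dtype[0]}{n}{dtype[1]}", raw))
    return kind, values


def _iter_mzml_spectra(path: Path):
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local_name(elem.tag) != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter():
            if _local_name(bda.tag) == "binaryDataArray":
                kind, values = _decode_binary_array(bda)
                if kind is not None:
                    arrays[kind] = values
        if "mz" in arrays and "intensity" in arrays:
            yield elem.get("id", ""), arrays["mz"], arrays["intensity"]
        elem.clear()


def read_mzml(path: str | Path, scan_index: int = 0) -> Spectrum:
    """Read one spectrum from an mzML 1.1 file (plain or index-wrapped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mzML file not found: {path}")
    for i, (scan_id, mz, inten) in enumerate(_iter_mzml_spectra(path)):
        if i == scan_index:
            return Spectrum(
                mz,
                inten,
                kind="mz",
                metadata={"source": str(path), "scan_id": scan_id},
            )
    raise IndexError(f"scan index {scan_index} not present in {path}")


def read_all_mzml(path: str | Path) -> list[Spectrum]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mzML file not found: {path}")
    return [
        Spectrum(mz, inten, kind="mz", metadata={"source": str(path), "scan_id": sid})
        for sid, mz, inten in _iter_mzml_spectra(path)
    ]


def _encode_array(values: np.ndarray, compress: bool) -> tuple[str, int]:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    if compress:
        raw = zlib.compress(raw)
    enc = base64.b64encode(raw).decode("ascii")
    return enc, len(enc)


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="glycotrace" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="glycotrace"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="glycotrace">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="{comp_acc}" name="{comp_name}" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="{comp_acc}" name="{comp_name}" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(
    spectra: Spectrum | list[Spectrum],
    path: str | Path,
    centroid: bool = False,
    compress: bool = False,
) -> None:
    """Write spectra to a minimal mzML 1.1.0 file.

    Produces profile or centroid MS1 spectra with 64-bit float m/z and
    intensity arrays (optionally zlib-compressed), readable by standard mzML
    parsers; write -> read round trips are covered by tests.
    """
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    for sp in spectra:
        if sp.kind != "mz":
            raise ValueError("mzML output requires m/z-axis spectra")
    mode_acc, mode_name = (
        ("MS:1000127", "centroid spectrum")
        if centroid
        else ("MS:1000128", "profile spectrum")
    )
    comp_acc, comp_name = (
        ("MS:1000574", "zlib compression")
        if compress
        else ("MS:1000576", "no compression")
    )
    parts = [_MZML_HEADER.format(count=len(spectra))]
    for i, sp in enumerate(spectra):
        mz_b64, mz_len = _encode_array(sp.axis, compress)
        int_b64, int_len = _encode_array(sp.intensity, compress)
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                scan=i + 1,
                n=len(sp),
                mode_acc=mode_acc,
                mode_name=mode_name,
                comp_acc=comp_acc,
                comp_name=comp_name,
                mz_len=mz_len,
                mz_b64=mz_b64,
                int_len=int_len,
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Average multiple scans on a common axis (composite spectrum).

    Scans sharing an identical axis are averaged directly; otherwise each is
    linearly interpolated onto the first scan's axis before averaging.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    acc = np.zeros_like(ref.intensity)
    for sp in spectra:
        if sp.kind != ref.kind:
            raise ValueError("cannot average spectra of mixed axis kinds")
        if sp.axis.shape == ref.axis.shape and np.allclose(sp.axis, ref.axis):
            acc += sp.intensity
        else:
            acc += np.interp(ref.axis, sp.axis, sp.intensity, left=0.0, right=0.0)
    return Spectrum(
        ref.axis.copy(),
        acc / len(spectra),
        kind=ref.kind,
        metadata={"n_averaged": len(spectra)},
    )
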