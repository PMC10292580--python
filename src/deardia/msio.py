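"""Reading DIA runs (mzML/mzXML) and writing pseudo-tandem spectra (MGF).

The internal spectrum model is deliberately small: a run is an RT-ordered
list of MS1/MS2 scans plus the isolation-window scheme inferred from the
first duty cycle. Retention times are normalized to seconds on read
regardless of the source file's unit. Profile and centroid inputs are both
accepted; no centroiding happens here (the preprocessing binning absorbs
profile shapes).

The mzML/mzXML writers cover exactly what the synthetic-run generator needs
for round-trip testing: MS levels, scan times, isolation windows and
uncompressed 64-bit peak arrays.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree
from pyteomics import mzxml as _pyt_mzxml

__all__ = [
    "Spectrum", "Run", "PseudoSpectrum", "FormatError",
    "read_run", "write_mgf", "write_mzml", "write_mzxml",
]

PROTON_MASS = 1.007276466


class FormatError(ValueError):
    """Raised when a file violates the expected mass-spectrometry format."""


@dataclass
class Spectrum:
    """One MS scan.

    `window` is the isolation window (lower_mz, upper_mz); it is required
    for MS2 scans and absent for MS1 scans. `mz` is strictly increasing and
    matches `intensity` in length.
    """
    scan_id: int
    ms_level: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    window: Optional[tuple] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity lengths differ")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"scan {self.scan_id}: m/z not strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_id}: negative intensity")
        if self.ms_level == 2 and self.window is None:
            raise FormatError(f"MS2 scan {self.scan_id} lacks an isolation window")


@dataclass
class Run:
    """An RT-ordered list of scans plus the isolation-window scheme."""
    spectra: list
    window_scheme: list = field(default_factory=list)

    def ms1(self):
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_for_window(self, idx: int):
        lo, hi = self.window_scheme[idx]
        return [s for s in self.spectra
                if s.ms_level == 2
                and abs(s.window[0] - lo) < 1e-6 and abs(s.window[1] - hi) < 1e-6]


@dataclass
class PseudoSpectrum:
    """A deconvolved precursor with its accepted fragment peaks (one MGF entry)."""
    precursor_mz: float
    charge: int
    rt: float
    fragments: list  # list of (mz, intensity)
    title: str

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not self.fragments:
            raise ValueError("pseudo-spectrum needs at least one fragment")
        if any(i <= 0 for _, i in self.fragments):
            raise ValueError("fragment intensities must be positive")


# ---------------------------------------------------------------------------
# reading


def _window_scheme_from_first_cycle(spectra) -> list:
    """Distinct MS2 isolation windows observed before the second MS1 scan."""
    scheme, seen_ms1 = [], 0
    for s in spectra:
        if s.ms_level == 1:
            seen_ms1 += 1
            if seen_ms1 > 1:
                break
        elif seen_ms1 >= 1:
            w = (round(s.window[0], 6), round(s.window[1], 6))
            if w not in scheme:
                scheme.append(w)
    return scheme


def read_run(path, fmt: Optional[str] = None) -> Run:
    """Read an mzML or mzXML file into a :class:`Run`.

    `fmt` is "mzML" or "mzXML"; inferred from the file suffix when omitted.
    RT is normalized to seconds. The window scheme is the ordered list of
    distinct MS2 isolation windows of the first duty cycle.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mzXML" if path.suffix.lower() == ".mzxml" else "mzML"
    reader = _read_mzxml if fmt.lower() == "mzxml" else _read_mzml
    spectra = reader(path)
    spectra.sort(key=lambda s: s.rt)
    return Run(spectra=spectra,
               window_scheme=_window_scheme_from_first_cycle(spectra))


def _rt_seconds(value) -> float:
    unit = getattr(value, "unit_info", None)
    if unit and "min" in str(unit):
        return float(value) * 60.0
    return float(value)


def _cv_params(elem) -> dict:
    out = {}
    for cv in elem.iter("{*}cvParam"):
        out[cv.get("name")] = cv
    return out


def _decode_binary_array(bda) -> Optional[tuple]:
    cvs = _cv_params(bda)
    kind = ("mz" if "m/z array" in cvs
            else "intensity" if "intensity array" in cvs else None)
    if kind is None:
        return None
    dtype = "<f4" if "32-bit float" in cvs else "<f8"
    node = bda.find("{*}binary")
    raw = base64.b64decode(node.text or "")
    if "zlib compression" in cvs:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path) -> list:
    """Minimal namespace-agnostic mzML reader (profile or centroid)."""
    spectra = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise FormatError(f"failed to parse {path.name}: {e}") from e
    for i, sp in enumerate(tree.iter("{*}spectrum")):
        sid = sp.get("id", f"index={i}")
        cvs = _cv_params(sp)
        try:
            level = int(cvs["ms level"].get("value"))
        except KeyError as e:
            raise FormatError(f"spectrum {sid}: no ms level") from e
        scan = sp.find(".//{*}scanList/{*}scan")
        rt = 0.0
        if scan is not None:
            scvs = _cv_params(scan)
            if "scan start time" in scvs:
                node = scvs["scan start time"]
                rt = float(node.get("value"))
                if "min" in (node.get("unitName") or ""):
                    rt *= 60.0
        window = None
        if level >= 2:
            iso = sp.find(".//{*}precursorList/{*}precursor/{*}isolationWindow")
            if iso is None:
                raise FormatError(f"MS2 scan {sid} lacks an isolation window")
            icvs = _cv_params(iso)
            try:
                tgt = float(icvs["isolation window target m/z"].get("value"))
                lo = float(icvs["isolation window lower offset"].get("value"))
                hi = float(icvs["isolation window upper offset"].get("value"))
            except KeyError as e:
                raise FormatError(
                    f"MS2 scan {sid} has an incomplete isolation window") from e
            window = (tgt - lo, tgt + hi)
        mz = inten = None
        for bda in sp.iter("{*}binaryDataArray"):
            decoded = _decode_binary_array(bda)
            if decoded is None:
                continue
            kind, arr = decoded
            if kind == "mz":
                mz = arr
            else:
                inten = arr
        if mz is None or inten is None:
            raise FormatError(f"spectrum {sid}: missing peak arrays")
        spectra.append(Spectrum(scan_id=i + 1, ms_level=level, rt=rt,
                                mz=mz, intensity=inten, window=window))
    return spectra


def _read_mzxml(path) -> list:
    spectra = []
    try:
        with _pyt_mzxml.read(str(path)) as reader:
            for rec in reader:
                num = int(rec["num"])
                level = int(rec["msLevel"])
                rt = _rt_seconds(rec["retentionTime"])
                window = None
                if level >= 2:
                    prec = rec.get("precursorMz")
                    if not prec:
                        raise FormatError(
                            f"MS2 scan {num} lacks precursor window information")
                    center = float(prec[0]["precursorMz"])
                    wide = float(prec[0].get("windowWideness", 0.0))
                    if wide <= 0:
                        raise FormatError(
                            f"MS2 scan {num} lacks isolation window width")
                    window = (center - wide / 2.0, center + wide / 2.0)
                spectra.append(Spectrum(
                    scan_id=num, ms_level=level, rt=rt,
                    mz=rec["m/z array"], intensity=rec["intensity array"],
                    window=window))
    except FormatError:
        raise
    except Exception as e:
        raise FormatError(f"failed to parse {path.name}: {e}") from e
    return spectra


# ---------------------------------------------------------------------------
# MGF output


def write_mgf(spectra: Sequence[PseudoSpectrum], path) -> int:
    """Write pseudo-tandem spectra as MGF; returns the number of blocks.

    Dialect: TITLE, PEPMASS (precursor m/z), CHARGE with trailing sign,
    RTINSECONDS, then one "mz intensity" line per fragment.
    """
    if not spectra:
        raise ValueError("refusing to write an empty MGF")
    lines = []
    for ps in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={ps.title}")
        lines.append(f"PEPMASS={ps.precursor_mz:.6f}")
        lines.append(f"CHARGE={ps.charge}+")
        lines.append(f"RTINSECONDS={ps.rt:.4f}")
        for mz, inten in ps.fragments:
            lines.append(f"{mz:.5f} {inten:.4f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))
    return len(spectra)


# ---------------------------------------------------------------------------
# mzML / mzXML output (what the synthetic generator needs)


def _b64_doubles(values) -> str:
    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""


def write_mzml(run: Run, path, run_id: str = "synthetic") -> None:
    """Serialize a Run as minimal uncompressed 64-bit mzML."""
    parts = [_MZML_HEADER.format(run_id=escape(run_id), count=len(run.spectra))]
    for i, s in enumerate(run.spectra):
        level_cv = ('<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
                    if s.ms_level == 1 else
                    '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum"/>')
        prec = ""
        if s.ms_level == 2:
            lo, hi = s.window
            tgt = 0.5 * (lo + hi)
            prec = f"""
        <precursorList count="1"><precursor><isolationWindow>
          <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{tgt:.6f}"/>
          <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{tgt - lo:.6f}"/>
          <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{hi - tgt:.6f}"/>
        </isolationWindow><selectedIonList count="1"><selectedIon>
          <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{tgt:.6f}"/>
        </selectedIon></selectedIonList><activation/></precursor></precursorList>"""
        mz_b64 = _b64_doubles(s.mz)
        it_b64 = _b64_doubles(s.intensity)
        parts.append(f"""      <spectrum index="{i}" id="scan={s.scan_id}" defaultArrayLength="{s.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>
        {level_cv}
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt / 60.0:.8f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
        </scan></scanList>{prec}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(it_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
            <binary>{it_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(parts))


def write_mzxml(run: Run, path) -> None:
    """Serialize a Run as minimal mzXML (network-order 64-bit peak pairs)."""
    parts = ['<?xml version="1.0" encoding="ISO-8859-1"?>\n'
             '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
             f'<msRun scanCount="{len(run.spectra)}">\n']
    for s in run.spectra:
        pairs = np.empty(2 * s.mz.size, dtype=">f8")
        pairs[0::2] = s.mz
        pairs[1::2] = s.intensity
        b64 = base64.b64encode(pairs.tobytes()).decode("ascii")
        parts.append(f'<scan num="{s.scan_id}" msLevel="{s.ms_level}" '
                     f'peaksCount="{s.mz.size}" retentionTime="PT{s.rt:.4f}S">\n')
        if s.ms_level == 2:
            lo, hi = s.window
            parts.append(f'<precursorMz precursorIntensity="0" windowWideness='
                         f'"{hi - lo:.6f}">{0.5 * (lo + hi):.6f}</precursorMz>\n')
        parts.append('<peaks compressionType="none" compressedLen="0" precision="64" '
                     f'byteOrder="network" contentType="m/z-int">{b64}</peaks>\n</scan>\n')
    parts.append("</msRun>\n</mzXML>\n")
    Path(path).write_text("".join(parts))
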