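"""Minimal mzML reading and writing.

Writing emits plain (non-indexed) mzML 1.1 with uncompressed 64-bit
float binary arrays -- the smallest document standard readers accept.
Reading streams <spectrum> elements with lxml and understands the
subset of the PSI-MS vocabulary that instrument converters emit for
centroided runs: ms level, scan start time (any time unit), selected
ion m/z, and 32/64-bit float binary arrays with optional zlib
compression. Both indexed and plain mzML parse (the index wrapper is
simply ignored).
"""

from __future__ import annotations

import base64
import zlib
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="biospot" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="biospot"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="biospot">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_f64(values) -> tuple[str, int]:
    arr = np.asarray(values, dtype="<f8")
    return base64.b64encode(arr.tobytes()).decode("ascii"), arr.size


def _binary_array(values, array_accession: str, array_name: str, unit: str) -> str:
    b64, _ = _encode_f64(values)
    return f"""            <binaryDataArray encodedLength="{len(b64)}">
              <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
              <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
              <cvParam cvRef="MS" accession="{array_accession}" name="{array_name}" value=""{unit}/>
              <binary>{b64}</binary>
            </binaryDataArray>
"""


def _spectrum_xml(index: int, scan) -> str:
    """One <spectrum> element. ``scan`` is a biospot.lcms.Scan."""
    mz = np.asarray(scan.mz, dtype=float)
    inten = np.asarray(scan.intensity, dtype=float)
    n = mz.size
    level_params = (
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        if scan.ms_level == 1 else
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
    )
    precursor = ""
    if scan.ms_level >= 2 and scan.precursor_mz is not None:
        precursor = f"""        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan.precursor_mz:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              </selectedIon>
            </selectedIonList>
            <activation>
              <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>
            </activation>
          </precursor>
        </precursorList>
"""
    mz_block = _binary_array(
        mz, "MS:1000514", "m/z array",
        ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"')
    int_block = _binary_array(
        inten, "MS:1000515", "intensity array",
        ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"')
    sid = escape(scan.scan_id or f"scan={index + 1}")
    return f"""      <spectrum index="{index}" id="{sid}" defaultArrayLength="{n}">
        {level_params}
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan.ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt_min:.8f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
{precursor}        <binaryDataArrayList count="2">
{mz_block}{int_block}          </binaryDataArrayList>
      </spectrum>
"""


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_CENTROID = "MS:1000127"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"

_TIME_TO_MIN = {
    "UO:0000031": 1.0,           # minute
    "UO:0000010": 1.0 / 60.0,    # second
    "UO:0000028": 1.0 / 60000.0,  # millisecond
    "minute": 1.0,
    "second": 1.0 / 60.0,
    "millisecond": 1.0 / 60000.0,
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_array(bda_elem) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    data = b""
    for child in bda_elem:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif name == "binary" and child.text:
            data = base64.b64decode(child.text)
    if compressed:
        data = zlib.decompress(data)
    return np.frombuffer(data, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> dict:
    """Extract rt (min), ms level, precursor, m/z and intensity arrays."""
    out = {
        "ms_level": 1, "rt_min": 0.0, "precursor_mz": None,
        "centroided": False, "mz": np.empty(0), "intensity": np.empty(0),
        "id": elem.get("id", ""),
    }
    for cv in elem.iter():
        name = _local(cv.tag)
        if name == "cvParam":
            acc = cv.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                out["ms_level"] = int(cv.get("value"))
            elif acc == _ACC_SCAN_START:
                unit = (cv.get("unitAccession")
                        or cv.get("unitName") or "minute")
                out["rt_min"] = float(cv.get("value")) * _TIME_TO_MIN.get(unit, 1.0)
            elif acc == _ACC_CENTROID:
                out["centroided"] = True
            elif acc == _ACC_SELECTED_MZ:
                out["precursor_mz"] = float(cv.get("value"))
        elif name == "binaryDataArray":
            arr = _decode_array(cv)
            accs = {c.get("accession") for c in cv if _local(c.tag) == "cvParam"}
            if _ACC_MZ_ARRAY in accs:
                out["mz"] = arr
            elif _ACC_INT_ARRAY in accs:
                out["intensity"] = arr
    return out


def iter_spectra(path):
    """Yield parsed spectrum dicts from an mzML file (streaming)."""
    try:
        context = etree.iterparse(str(path), events=("end",),
                                  remove_blank_text=True)
        for _, elem in context:
            if _local(elem.tag) == "spectrum":
                yield _parse_spectrum(elem)
                elem.clear()
                parent = elem.getparent()
                if parent is not None:
                    while elem.getprevious() is not None:
                        del parent[0]
    except etree.XMLSyntaxError as exc:
        raise IOError(f"malformed mzML {path}: {exc}") from exc
    except OSError as exc:
        raise IOError(f"cannot read mzML {path}: {exc}") from exc


def write_mzml(scans, path, run_id: str = "biospot_run") -> None:
    """Write an ordered list of scans as plain mzML.

    An empty scan list yields a structurally valid document with a
    zero-count spectrumList.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(run_id=escape(run_id), count=len(scans)))
        for i, scan in enumerate(scans):
            fh.write(_spectrum_xml(i, scan))
        fh.write(_FOOTER)
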