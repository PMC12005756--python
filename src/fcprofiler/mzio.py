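"""mzML and table input/output.

Runs are written as plain (non-indexed) mzML 1.1 with MS1 profile
spectra and uncompressed 64/32-bit binary arrays, and read back with a
small namespace-aware ElementTree parser that understands the subset
this pipeline needs (MS1 spectra, scan start time, m/z and intensity
arrays, optional zlib compression).  Scans whose m/z axis differs from
the first scan's are resampled onto it so the in-memory
:class:`~fcprofiler.signal.SpectrumRun` keeps a shared grid.

Tables (manifest, ground truth, quant, traits) are tidy TSV.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from typing import Dict, List, Optional, Union
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .signal import SpectrumRun

__all__ = ["write_mzml", "read_mzml", "write_table", "read_table"]

_PathLike = Union[str, Path]
_NS = "{http://psi.hupo.org/ms/mzml}"

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="fcprofiler" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="fcprofiler">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
"""


def _encode(array: np.ndarray, dtype: str) -> str:
    return base64.b64encode(np.asarray(array, dtype=dtype).tobytes()).decode("ascii")


def write_mzml(run: SpectrumRun, path: _PathLike, run_id: str = "run1") -> Path:
    """Write the run as MS1-only profile mzML (m/z float64, intensity float32)."""
    path = Path(path)
    n = run.n_scans
    mz_b64 = _encode(run.mz, "<f8")
    mz_len = len(run.mz)
    parts: List[str] = [_HEADER]
    parts.append(
        f'  <run id="{escape(run_id)}" defaultInstrumentConfigurationRef="IC1">\n'
        f'    <spectrumList count="{n}" defaultDataProcessingRef="DP1">\n'
    )
    for i in range(n):
        rt, _, intensity = run.scan(i)
        int_b64 = _encode(intensity, "<f4")
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mz_len}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>\n'
            '        <scanList count="1">\n'
            '          <scan>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            '          </scan>\n'
            '        </scanList>\n'
            '        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            f'            <binary>{mz_b64}</binary>\n'
            '          </binaryDataArray>\n'
            f'          <binaryDataArray encodedLength="{len(int_b64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            f'            <binary>{int_b64}</binary>\n'
            '          </binaryDataArray>\n'
            '        </binaryDataArrayList>\n'
            '      </spectrum>\n'
        )
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts))
    return path


def _cv_params(element) -> Dict[str, Dict[str, str]]:
    """All cvParams of an element (non-recursive), keyed by accession."""
    return {
        cv.get("accession"): cv.attrib
        for cv in element.findall(f"{_NS}cvParam")
    }


def _decode_binary_array(bda) -> Optional[np.ndarray]:
    params = _cv_params(bda)
    binary = bda.find(f"{_NS}binary")
    if binary is None or binary.text is None:
        return None
    raw = base64.b64decode(binary.text.strip())
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), params


def read_mzml(path: _PathLike, metadata: Optional[Dict] = None) -> SpectrumRun:
    """Read MS1 spectra from an mzML file onto a shared m/z grid."""
    rts: List[float] = []
    rows: List[np.ndarray] = []
    grid: Optional[np.ndarray] = None
    for _, spectrum in ElementTree.iterparse(str(path)):
        if spectrum.tag != f"{_NS}spectrum":
            continue
        params = _cv_params(spectrum)
        ms_level = params.get("MS:1000511", {}).get("value", "1")
        if int(ms_level) != 1:
            spectrum.clear()
            continue
        rt = None
        for scan in spectrum.iter(f"{_NS}scan"):
            sp = _cv_params(scan)
            if "MS:1000016" in sp:
                attrs = sp["MS:1000016"]
                rt = float(attrs["value"])
                if "min" in attrs.get("unitName", "second"):
                    rt *= 60.0
            break
        mz = intensity = None
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            decoded = _decode_binary_array(bda)
            if decoded is None:
                continue
            values, params = decoded
            if "MS:1000514" in params:
                mz = values
            elif "MS:1000515" in params:
                intensity = values
        spectrum.clear()
        if rt is None or mz is None or intensity is None:
            continue
        if grid is None:
            grid = mz
            rows.append(intensity)
        elif mz.size == grid.size and np.allclose(mz, grid):
            rows.append(intensity)
        else:
            rows.append(np.interp(grid, mz, intensity, left=0.0, right=0.0))
        rts.append(rt)
    if grid is None:
        raise ValueError(f"no MS1 spectra found in {path}")
    order = np.argsort(rts)
    return SpectrumRun(
        np.asarray(rts)[order],
        grid,
        np.vstack(rows)[order],
        dict(metadata or {}),
    )


def write_table(df: pd.DataFrame, path: _PathLike) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: _PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
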