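"""File formats: mzML, peak-list TSV, and the pipeline's CSV schemas.

Spectra are exchanged as centroided MS1-only mzML (reading via
pyteomics; writing via a minimal standard-conformant serializer —
uncompressed 64-bit arrays, little-endian, base64). Retention times are
minutes everywhere inside the package; unit conversion from mzML
seconds happens here at the reader boundary. A simple one-peak-per-line
TSV dialect (columns ``rt_min, mz, intensity``) is additionally accepted
for tests and quick inspection.

CSV schemas are validated on read and errors name the offending column.
Matrices travel with a JSON sidecar recording their level.
"""

from __future__ import annotations

import base64
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .xic import ID_COLUMNS, QuantMatrix, RunSpectra

logger = logging.getLogger(__name__)

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    etree.SubElement(
        parent,
        "cvParam",
        cvRef="MS",
        accession=accession,
        name=name,
        value=value,
        **attrs,
    )


def write_mzml(run: RunSpectra, path: str | Path) -> Path:
    """Write one run as centroided MS1-only mzML.

    Scan start times are written in minutes with the explicit minute
    unit; m/z and intensity arrays as uncompressed 64-bit floats.
    """
    path = Path(path)
    root = etree.Element("mzML", xmlns=_MZML_NS, version="1.1.0", id=run.run_id)
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cv_list,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdl = etree.SubElement(root, "fileDescription")
    fc = etree.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000127", "centroid spectrum")

    sw_list = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(sw_list, "software", id="phospholfq", version="0.1.0")
    ic_list = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    dp_list = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dp_list, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="phospholfq")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = etree.SubElement(
        root, "run", id=run.run_id, defaultInstrumentConfigurationRef="IC1"
    )
    spec_list = etree.SubElement(
        run_el,
        "spectrumList",
        count=str(run.n_scans),
        defaultDataProcessingRef="DP1",
    )
    for i in range(run.n_scans):
        mz, inten = run.scans[i]
        spectrum = etree.SubElement(
            spec_list,
            "spectrum",
            index=str(i),
            id=f"scan={i + 1}",
            defaultArrayLength=str(int(mz.size)),
        )
        _cv(spectrum, "MS:1000579", "MS1 spectrum")
        _cv(spectrum, "MS:1000511", "ms level", "1")
        _cv(spectrum, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(spectrum, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            f"{run.scan_rts[i]:.10g}",
            unitCvRef="UO",
            unitAccession="UO:0000031",
            unitName="minute",
        )
        bda_list = etree.SubElement(spectrum, "binaryDataArrayList", count="2")
        for accession, name, values in (
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ):
            encoded = _encode_array(values)
            bda = etree.SubElement(
                bda_list, "binaryDataArray", encodedLength=str(len(encoded))
            )
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, accession, name)
            etree.SubElement(bda, "binary").text = encoded

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return path


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit float, plain or zlib."""
    accessions = {
        cv.get("accession") for cv in bda.iterfind(f"{{{_MZML_NS}}}cvParam")
    }
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    text = binary.text or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _spectrum_arrays(spectrum) -> tuple[np.ndarray, np.ndarray]:
    mz = inten = np.empty(0)
    for bda in spectrum.iterfind(
        f"{{{_MZML_NS}}}binaryDataArrayList/{{{_MZML_NS}}}binaryDataArray"
    ):
        accessions = {
            cv.get("accession") for cv in bda.iterfind(f"{{{_MZML_NS}}}cvParam")
        }
        if "MS:1000514" in accessions:
            mz = _decode_binary_array(bda)
        elif "MS:1000515" in accessions:
            inten = _decode_binary_array(bda)
    return mz, inten


def read_mzml(
    path: str | Path,
    run_id: str | None = None,
    sample_id: str = "",
    tech_rep: int = 0,
) -> RunSpectra:
    """Read centroided MS1 scans from an mzML file into a RunSpectra.

    Retention times are converted to minutes if the file stores seconds.
    Non-MS1 spectra are skipped. An empty file yields a valid empty run
    with a logged warning.
    """
    path = Path(path)
    rts: list[float] = []
    scans: list[tuple[np.ndarray, np.ndarray]] = []
    spectrum_tag = f"{{{_MZML_NS}}}spectrum"
    index = -1
    for _, spectrum in etree.iterparse(str(path), tag=spectrum_tag):
        index += 1
        params = {
            cv.get("accession"): cv
            for cv in spectrum.iterfind(f"{{{_MZML_NS}}}cvParam")
        }
        ms_level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1
        if ms_level != 1:
            spectrum.clear()
            continue
        rt_cv = spectrum.find(
            f"{{{_MZML_NS}}}scanList/{{{_MZML_NS}}}scan/"
            f"{{{_MZML_NS}}}cvParam[@accession='MS:1000016']"
        )
        if rt_cv is None:
            raise ValueError(
                f"mzML '{path}': spectrum index {index} lacks a scan start time"
            )
        rt = float(rt_cv.get("value"))
        unit = (rt_cv.get("unitName") or "minute").lower()
        rts.append(rt / 60.0 if unit.startswith("second") else rt)
        scans.append(_spectrum_arrays(spectrum))
        spectrum.clear()
    if not rts:
        logger.warning("mzML file '%s' contains no MS1 spectra", path)
    order = np.argsort(rts, kind="stable")
    rts_arr = np.asarray(rts, dtype=float)[order]
    scans = [scans[i] for i in order]
    return RunSpectra(
        run_id=run_id or path.stem,
        sample_id=sample_id,
        tech_rep=tech_rep,
        scan_rts=rts_arr,
        scans=scans,
    )


def write_peaklist_tsv(run: RunSpectra, path: str | Path) -> Path:
    """Write a run as one-centroid-per-line TSV (rt_min, mz, intensity).

    Empty scans are preserved with a sentinel row carrying no peak.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rt_min\tmz\tintensity\n")
        for i in range(run.n_scans):
            mz, inten = run.scans[i]
            if mz.size == 0:
                fh.write(f"{run.scan_rts[i]:.10g}\t\t\n")
            for m, x in zip(mz, inten):
                fh.write(f"{run.scan_rts[i]:.10g}\t{m:.10g}\t{x:.10g}\n")
    return path


def read_peaklist_tsv(
    path: str | Path,
    run_id: str | None = None,
    sample_id: str = "",
    tech_rep: int = 0,
) -> RunSpectra:
    """Read the TSV peak-list dialect back into a RunSpectra."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    for col in ("rt_min", "mz", "intensity"):
        if col not in frame.columns:
            raise ValueError(f"peak-list TSV missing column '{col}'")
    rts: list[float] = []
    scans: list[tuple[np.ndarray, np.ndarray]] = []
    for rt, grp in frame.groupby("rt_min", sort=True):
        peaks = grp.dropna(subset=["mz"])
        rts.append(float(rt))
        scans.append(
            (peaks["mz"].to_numpy(dtype=float), peaks["intensity"].to_numpy(dtype=float))
        )
    return RunSpectra(
        run_id=run_id or path.stem,
        sample_id=sample_id,
        tech_rep=tech_rep,
        scan_rts=np.asarray(rts),
        scans=scans,
    )


def write_id_table(ids: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ids.to_csv(path, index=False)
    return path


def read_id_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an identification CSV.

    Required columns: peptide_key, sequence, phospho_positions, charge,
    mz, rt, score, fdr. Extra columns (run_id, isoform_scores, ...) pass
    through.
    """
    path = Path(path)
    ids = pd.read_csv(path, dtype={"phospho_positions": str, "isoform_scores": str})
    missing = [c for c in ID_COLUMNS if c not in ids.columns]
    if missing:
        raise ValueError(
            f"identification table '{path}' missing required column(s): {missing}"
        )
    return ids


def write_matrix(m: QuantMatrix, path: str | Path) -> Path:
    """Write a quantification matrix CSV plus a JSON level sidecar."""
    path = Path(path)
    m.values.to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"schema": "phospholfq.matrix/1", "level": m.level}) + "\n"
    )
    return path


def read_matrix(path: str | Path, level: str | None = None) -> QuantMatrix:
    """Read a matrix CSV; the level comes from the sidecar or the caller."""
    path = Path(path)
    frame = pd.read_csv(path, index_col="peptide_key")
    if level is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if not sidecar.exists():
            raise ValueError(
                f"matrix '{path}' has no .meta.json sidecar; pass level= explicitly"
            )
        meta = json.loads(sidecar.read_text())
        level = meta["level"]
    return QuantMatrix(frame, level=level)


def write_run_table(runs: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    runs.to_csv(path, index=False)
    return path


def read_run_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("run_id", "sample_id"):
        if col not in frame.columns:
            raise ValueError(f"run table '{path}' missing column '{col}'")
    return frame


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    path: str | Path,
    config: dict,
    inputs: dict[str, str | Path],
    outputs: list[str | Path],
) -> Path:
    """Record config and input/output hashes for reproducibility."""
    record = {
        "schema": "phospholfq.provenance/1",
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in inputs.items()
            if Path(p).exists()
        },
        "outputs": [str(p) for p in outputs],
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
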