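"""Reading and writing mass-spectrometry runs and pipeline tables.

Input: centroided mzXML (the workflow's native interchange format, as
produced by ProteoWizard) or mzML, parsed with pyteomics. Only MS1 centroid
scans are used; retention times are normalised to minutes internally.

Output: a minimal single-msRun mzXML dialect (so the synthetic-data module
can emit standard-format fixtures), TSV component tables and NIST-style MSP
text for derived spectra.
"""
from __future__ import annotations

import base64
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .models import ComponentTable, DerivedSpectrum, Run, Scan


class MSFileError(Exception):
    """Unreadable, truncated or empty-of-MS1 input file."""


def _rt_to_minutes(rt_value, unit_hint: str | None) -> float:
    """Normalise a retention-time value to minutes.

    mzXML carries ISO-8601 durations like ``PT123.4S`` (seconds); mzML
    attaches an explicit unit name. Bare numbers default to the stated unit
    hint, or seconds (the ProteoWizard convention) when there is none.
    """
    if isinstance(rt_value, str):
        s = rt_value.strip()
        if s.startswith("PT") and s.endswith("S"):
            return float(s[2:-1]) / 60.0
        if s.startswith("PT") and s.endswith("M"):
            return float(s[2:-1])
        rt_value = float(s)
    rt_value = float(rt_value)
    if unit_hint == "minute":
        return rt_value
    return rt_value / 60.0


def _sniff_root(path: str | Path) -> str:
    for _, elem in etree.iterparse(str(path), events=("start",)):
        return etree.QName(elem).localname
    raise MSFileError(f"{path}: empty or unparsable XML")


def read_run(path: str | Path, sample_id: str | None = None, group_label: str = "") -> Run:
    """Read an mzXML or mzML file into a :class:`Run` of MS1 centroid scans.

    MS2+ scans are skipped. Raises :class:`MSFileError` on unreadable files
    or files containing no MS1 scans.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        root = _sniff_root(path)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MSFileError(f"cannot parse {path}: {exc}") from exc

    scans: list[Scan] = []
    try:
        if root == "mzXML":
            from pyteomics import mzxml

            with mzxml.read(str(path)) as reader:
                for sc in reader:
                    if int(sc.get("msLevel", 1)) != 1:
                        continue
                    # pyteomics.mzxml yields retentionTime already in minutes
                    rt = _rt_to_minutes(sc["retentionTime"], "minute")
                    scans.append(Scan(rt=rt, mz_values=sc["m/z array"], intensities=sc["intensity array"]))
        elif root in ("mzML", "indexedmzML"):
            from pyteomics import mzml

            with mzml.read(str(path)) as reader:
                for sc in reader:
                    if sc.get("ms level", 1) != 1:
                        continue
                    scan_info = sc["scanList"]["scan"][0]
                    if "scan start time" in scan_info:
                        rt_val = scan_info["scan start time"]
                        unit = getattr(rt_val, "unit_info", None) or "minute"
                        rt = _rt_to_minutes(float(rt_val), unit)
                    else:
                        rt = 0.0
                    scans.append(Scan(rt=rt, mz_values=sc["m/z array"], intensities=sc["intensity array"]))
        else:
            raise MSFileError(f"{path}: unsupported root element <{root}>")
    except MSFileError:
        raise
    except Exception as exc:  # pyteomics raises assorted parse errors
        raise MSFileError(f"cannot parse {path}: {exc}") from exc

    if not scans:
        raise MSFileError(f"{path}: no MS1 scans found")
    run = Run(sample_id=sample_id, scans=scans, group_label=group_label)
    return run


def _encode_peaks(mz: np.ndarray, inten: np.ndarray) -> str:
    """network-order 64-bit float m/z-intensity pairs, base64 (mzXML 'peaks')."""
    interleaved = np.empty(2 * mz.size, dtype=">f8")
    interleaved[0::2] = mz
    interleaved[1::2] = inten
    return base64.b64encode(interleaved.tobytes()).decode("ascii")


def write_run(run: Run, path: str | Path) -> Path:
    """Write a Run as minimal valid mzXML readable by :func:`read_run`.

    Round-trips scan rts, m/z and intensities at full float64 precision.
    """
    if not run.scans:
        raise MSFileError(f"run {run.sample_id!r} has no scans to write")
    path = Path(path)
    nsmap = {None: "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"}
    root = etree.Element("mzXML", nsmap=nsmap)
    msrun = etree.SubElement(root, "msRun", scanCount=str(len(run.scans)))
    for i, sc in enumerate(run.scans, start=1):
        scan_el = etree.SubElement(
            msrun,
            "scan",
            num=str(i),
            msLevel="1",
            peaksCount=str(sc.mz_values.size),
            retentionTime=f"PT{sc.rt * 60.0:.8f}S",
        )
        peaks = etree.SubElement(
            scan_el,
            "peaks",
            precision="64",
            byteOrder="network",
            contentType="m/z-int",
            compressionType="none",
            compressedLen="0",
        )
        peaks.text = _encode_peaks(sc.mz_values, sc.intensities)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="ISO-8859-1", pretty_print=True)
    return path


def write_component_table(table: ComponentTable, path: str | Path,
                          extra_columns: pd.DataFrame | None = None) -> Path:
    """Write the registered component table as TSV.

    One row per component: id, mean rt, mean m/z, per-sample heights and
    areas. Missing peaks are written as empty cells, never 0, so downstream
    statistics can distinguish "not detected" from a true zero. Optional
    ``extra_columns`` (indexed by component_id) appends e.g. screening or
    annotation results.
    """
    path = Path(path)
    rows = []
    for comp in table.components:
        row: dict[str, object] = {
            "component_id": comp.component_id,
            "mean_rt": round(comp.mean_rt, 4),
            "mean_mz": round(comp.mean_mz, 5),
        }
        for s in table.samples:
            p = comp.members.get(s)
            row[f"height_{s}"] = p.height if p is not None else np.nan
            row[f"area_{s}"] = p.area if p is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if extra_columns is not None:
        df = df.merge(extra_columns, left_on="component_id", right_index=True, how="left")
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def write_msp(spectra: list[DerivedSpectrum], path: str | Path) -> Path:
    """Write derived mass spectra as NIST MSP text, one entry per metabolite."""
    path = Path(path)
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write(f"Name: metabolite_{sp.metabolite_id}\n")
            if sp.source_sample:
                fh.write(f"Comment: source_sample={sp.source_sample}\n")
            fh.write(f"Num Peaks: {len(sp.entries)}\n")
            for mz, inten, role in sp.entries:
                fh.write(f"{mz:.5f} {inten:.1f} \"{role}\"\n")
            fh.write("\n")
    return path


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a sample->group TSV/CSV with columns sample, group."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    return dict(zip(df[cols["sample"]].astype(str), df[cols["group"]].astype(str)))
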