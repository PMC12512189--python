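"""File formats and run configuration.

All tabular interchange is tidy CSV with fixed header schemas; mzML is
the only standard binary format read (MS1 profile arrays via
pyteomics). Floating-point columns are written with a fixed format so
runs under the same seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ThTTrace
from .mobility import ArrivalTimeDistribution
from .spectra import MassSpectrum

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _read_mzml_ms1(path):
    """First MS1 spectrum's profile arrays from an mzML document.

    Supports 64/32-bit float binary arrays with optional zlib
    compression — the encodings written by the common converters.
    """
    import base64
    import struct
    import zlib

    from lxml import etree

    ns = {"m": "http://psi.hupo.org/ms/mzml"}
    tree = etree.parse(str(path))
    root = tree.getroot()
    spectra = root.findall(".//m:spectrum", ns)
    if not spectra:  # indexed or namespace-less documents
        spectra = [el for el in root.iter() if
                   etree.QName(el).localname == "spectrum"]

    def params(el):
        return {c.get("accession"): c.get("name") for c in el.iter()
                if etree.QName(c).localname == "cvParam"}

    for spec_el in spectra:
        level = next((c.get("value") for c in spec_el.iter()
                      if etree.QName(c).localname == "cvParam"
                      and c.get("accession") == "MS:1000511"), "1")
        if level not in ("1", "", None):
            continue
        arrays = {}
        for arr_el in (el for el in spec_el.iter()
                       if etree.QName(el).localname == "binaryDataArray"):
            p = params(arr_el)
            binary = next((el for el in arr_el.iter()
                           if etree.QName(el).localname == "binary"), None)
            if binary is None or binary.text is None:
                continue
            raw = base64.b64decode(binary.text.strip())
            if "MS:1000574" in p:  # zlib compression
                raw = zlib.decompress(raw)
            fmt = "d" if "MS:1000523" in p else "f"
            vals = np.asarray(struct.unpack(
                f"<{len(raw) // struct.calcsize(fmt)}{fmt}", raw))
            if "MS:1000514" in p:
                arrays["mz"] = vals
            elif "MS:1000515" in p:
                arrays["intensity"] = vals
        if "mz" in arrays and "intensity" in arrays:
            return arrays["mz"], arrays["intensity"]
    raise ValueError(f"{path}: no MS1 spectrum with m/z and intensity "
                     "arrays found")

def read_spectrum(path, format: str | None = None,
                  label: str = "") -> MassSpectrum:
    """Read a profile spectrum from mzML or two-column CSV.

    ``format`` is inferred from the suffix when omitted. CSV needs
    columns mz,intensity; unsorted m/z values are sorted on load with a
    warning. mzML reading takes the first MS1 spectrum's profile arrays.
    """
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "csv"
    if format == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as err:
            raise ValueError(f"cannot parse spectrum CSV {path}: {err}") from err
        if not {"mz", "intensity"} <= set(df.columns):
            raise ValueError(f"{path}: spectrum CSV needs mz,intensity columns")
        mz = df["mz"].to_numpy(dtype=float)
        inten = df["intensity"].to_numpy(dtype=float)
    elif format == "mzml":
        mz, inten = _read_mzml_ms1(path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    if np.any(np.diff(mz) <= 0):
        warnings.warn(f"{path}: m/z values not sorted; sorting on load")
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        keep = np.concatenate([[True], np.diff(mz) > 0])
        mz, inten = mz[keep], inten[keep]
    return MassSpectrum(mz=mz, intensity=inten, label=label)


def write_spectrum(spectrum: MassSpectrum, path):
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# peak areas / ATDs / ThT plates / peak lists
# ---------------------------------------------------------------------------

def write_peak_areas(table: pd.DataFrame, path):
    cols = ["titration_point", "charge", "n_bound", "replicate", "area"]
    table[cols].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_peak_areas(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_atds(atds: list[ArrivalTimeDistribution], path):
    frames = []
    for a in atds:
        frames.append(pd.DataFrame({
            "time_ms": a.time, "intensity": a.intensity,
            "charge": a.charge,
            "n_bound": -1 if a.n_bound is None else a.n_bound,
            "titration_point": a.label}))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_atds(path) -> list[ArrivalTimeDistribution]:
    df = pd.read_csv(path)
    out = []
    for (point, charge, n_bound), g in df.groupby(
            ["titration_point", "charge", "n_bound"], sort=False):
        out.append(ArrivalTimeDistribution(
            time=g["time_ms"].to_numpy(), intensity=g["intensity"].to_numpy(),
            charge=int(charge),
            n_bound=None if n_bound == -1 else int(n_bound),
            label=str(point)))
    return out


def write_tht_plate(traces: list[ThTTrace], path):
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "time_h": tr.time, "fluorescence": tr.fluorescence,
            "condition_equivalents": tr.condition,
            "replicate": tr.replicate, "is_blank": int(tr.is_blank)}))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_tht_plate(path) -> list[ThTTrace]:
    df = pd.read_csv(path)
    out = []
    for (cond, rep, blank), g in df.groupby(
            ["condition_equivalents", "replicate", "is_blank"], sort=False):
        out.append(ThTTrace(
            time=g["time_h"].to_numpy(),
            fluorescence=g["fluorescence"].to_numpy(),
            condition=float(cond), replicate=int(rep),
            is_blank=bool(blank)))
    return out


def write_shift_tables(tables: list[pd.DataFrame], path):
    pd.concat(tables, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_shift_tables(path) -> list[pd.DataFrame]:
    df = pd.read_csv(path)
    return [g.reset_index(drop=True)
            for _, g in df.groupby("titration_point", sort=True)]


def read_calibrants(path) -> pd.DataFrame:
    """Calibrant CSV: species,mass_da,charge,ccs_a2,arrival_ms."""
    df = pd.read_csv(path)
    need = {"species", "mass_da", "charge", "ccs_a2", "arrival_ms"}
    if not need <= set(df.columns):
        raise ValueError(f"calibrant CSV needs columns {sorted(need)}")
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Fully resolved configuration of an end-to-end synthetic run."""

    seed: int = 20
    output_dir: str = "znbind_run"
    charges: tuple = (7, 8, 10, 12)
    n_sites: int = 5
    extraction_method: str = "integrate"
    compaction_charge: int = 8
    edc_coefficient: float = 1.35
    plateau_fraction: float = 0.95
    csp_threshold_method: str = "mean"
    run_nmr: bool = True
    run_kinetics: bool = True
    run_mobility: bool = True
    smooth_t50: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            import json
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "charges" in raw:
            raw["charges"] = tuple(raw["charges"])
        return cls(**raw)

    def to_json(self, path=None) -> str:
        import json
        d = dataclasses.asdict(self)
        d["charges"] = list(d["charges"])
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text
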