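"""Readers and writers for the formats the pipeline touches.

MS/MS spectra travel as MGF (one file per ionization mode), feature
quantification tables as CSV (either a plain dialect or the MZmine export
dialect, whose sample columns carry ``"<file> Peak area"`` headers), and
sample metadata as TSV.  Retention times are held in minutes internally;
``RTINSECONDS`` fields are converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger("chemophylo")

POSITIVE = "positive"
NEGATIVE = "negative"
MODES = (POSITIVE, NEGATIVE)

#: default regex stripped from MZmine sample-column headers; MZmine versions
#: differ in whether the filename extension is kept, so it is configurable.
MZMINE_SUFFIX_RE = r"(?:\.(?:mzX?ML|raw|d|cdf))?\s*Peak area\s*$"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One MS/MS scan: precursor, retention time, mode and peak list.

    Peaks are stored as an ``(n, 2)`` float array ``[m/z, intensity]`` and
    kept sorted ascending by m/z.
    """

    feature_id: str
    precursor_mz: float
    rt: float = 0.0
    charge: int = 0
    mode: str = POSITIVE
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    annotation: dict | None = None

    def __post_init__(self) -> None:
        self.feature_id = str(self.feature_id)
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and not np.all(np.isfinite(peaks)):
            raise ValueError(f"spectrum {self.feature_id}: non-finite peak values")
        if peaks.size and (np.any(peaks[:, 0] <= 0) or np.any(peaks[:, 1] < 0)):
            raise ValueError(f"spectrum {self.feature_id}: invalid m/z or intensity")
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.feature_id}: precursor m/z must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"spectrum {self.feature_id}: unknown mode {self.mode!r}")
        if self.charge == 0:
            # unknown charge: assume singly charged with mode-appropriate sign
            self.charge = 1 if self.mode == POSITIVE else -1

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    def replace_peaks(self, peaks: np.ndarray) -> "Spectrum":
        return Spectrum(self.feature_id, self.precursor_mz, self.rt, self.charge,
                        self.mode, peaks, self.annotation)


@dataclass
class FeatureTable:
    """Features x samples matrix of chromatographic peak areas.

    ``areas`` is a DataFrame indexed by feature id with one column per
    sample; ``feature_meta`` carries per-feature precursor m/z and retention
    time (minutes).
    """

    areas: pd.DataFrame
    feature_meta: pd.DataFrame
    has_ms2: pd.Series | None = None

    def __post_init__(self) -> None:
        self.areas.index = self.areas.index.map(str)
        self.feature_meta.index = self.feature_meta.index.map(str)
        if self.areas.index.has_duplicates:
            dups = self.areas.index[self.areas.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.areas.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.feature_meta.index.equals(self.areas.index):
            self.feature_meta = self.feature_meta.reindex(self.areas.index)
        vals = self.areas.to_numpy()
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("peak areas must be finite and non-negative")
        if self.has_ms2 is None:
            self.has_ms2 = pd.Series(True, index=self.areas.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.areas.shape

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        ids = [str(i) for i in ids if str(i) in self.areas.index]
        return FeatureTable(self.areas.loc[ids].copy(),
                            self.feature_meta.loc[ids].copy(),
                            self.has_ms2.loc[ids].copy())

    def subset_samples(self, samples: Sequence[str]) -> "FeatureTable":
        cols = [s for s in samples if s in self.areas.columns]
        return FeatureTable(self.areas[cols].copy(), self.feature_meta.copy(),
                            self.has_ms2.copy())


REQUIRED_META_COLS = ("species", "genus", "clade", "solvent", "mode")


def validate_metadata(meta: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Check the sample-metadata contract: required columns, non-empty genus,
    and (optionally) coverage of every sample in a feature table."""
    missing = [c for c in REQUIRED_META_COLS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if (meta["genus"].astype(str).str.len() == 0).any():
        raise ValueError("metadata contains empty genus entries")
    if table is not None:
        absent = [s for s in table.sample_ids if s not in meta.index]
        if absent:
            raise ValueError(f"samples without metadata rows: {absent}")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path, mode: str | None = None) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Accepts ``FEATURE_ID`` or ``SCANS`` as the feature key and
    ``RTINSECONDS`` or ``RTINMINUTES`` for retention time.  Blocks without a
    precursor (``PEPMASS``) are skipped with a warning; a structurally
    malformed block raises an error naming its index.
    """
    spectra: list[Spectrum] = []
    seen: set[str] = set()
    with _mgf.MGF(str(path), convert_arrays=1, read_charges=True) as reader:
        for i, entry in enumerate(reader):
            try:
                params = entry["params"]
                if "pepmass" not in params or params["pepmass"][0] is None:
                    logger.warning("MGF block %d: missing PEPMASS, skipped", i)
                    continue
                precursor = float(params["pepmass"][0])
                fid = params.get("feature_id") or params.get("scans")
                if fid is None:
                    fid = str(i)
                rt = 0.0
                if "rtinseconds" in params:
                    rt = float(params["rtinseconds"]) / 60.0
                elif "rtinminutes" in params:
                    rt = float(params["rtinminutes"])
                charge = 0
                if params.get("charge"):
                    charge = int(params["charge"][0])
                smode = mode or params.get("ionmode", POSITIVE)
                peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
                spec = Spectrum(str(fid), precursor, rt, charge, str(smode).lower(), peaks)
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed MGF block {i} in {path}: {exc}") from exc
            if spec.feature_id in seen:
                raise ValueError(f"duplicate feature id {spec.feature_id!r} in {path}")
            seen.add(spec.feature_id)
            spectra.append(spec)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; :func:`read_mgf` of the result reproduces the
    input up to float formatting (m/z within 1e-6)."""
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "feature_id": s.feature_id,
                "pepmass": (s.precursor_mz,),
                "rtinseconds": s.rt * 60.0,
                "charge": s.charge,
                "ionmode": s.mode,
            },
        })
    with open(path, "w") as fh:
        _mgf.write(entries, fh, key_order=["feature_id", "pepmass", "rtinseconds",
                                           "charge", "ionmode"])


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _find_column(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    return None


def read_feature_table(path: str | Path, dialect: str = "plain",
                       suffix_re: str = MZMINE_SUFFIX_RE) -> FeatureTable:
    """Read a feature quantification table (CSV).

    ``dialect='mzmine'`` expects ``row ID`` / ``row m/z`` / ``row retention
    time`` id columns and strips ``suffix_re`` (filename + ``" Peak area"``)
    from the sample column headers.  ``dialect='plain'`` expects
    ``feature_id,mz,rt,<sample>...``.
    """
    if dialect not in ("mzmine", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    df = df.loc[:, [c for c in df.columns if not str(c).startswith("Unnamed")]]
    cols = list(df.columns)
    id_col = _find_column(cols, ["row id", "feature_id", "id"])
    mz_col = _find_column(cols, ["row m/z", "mz", "m/z"])
    rt_col = _find_column(cols, ["row retention time", "rt", "retention time"])
    if id_col is None or mz_col is None or rt_col is None:
        raise ValueError(f"{path}: could not locate feature id / m/z / RT columns")
    sample_cols = [c for c in cols if c not in (id_col, mz_col, rt_col)]
    if dialect == "mzmine":
        renames = {c: re.sub(suffix_re, "", str(c)).strip() for c in sample_cols}
    else:
        renames = {c: str(c).strip() for c in sample_cols}

    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate feature ids "
                         f"{ids[ids.duplicated()].unique().tolist()}")
    areas = df[sample_cols].rename(columns=renames)
    areas.index = ids
    for col in areas.columns:
        numeric = pd.to_numeric(areas[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            fid = areas.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric or missing area at "
                             f"feature {fid!r}, sample column {col!r}")
        areas[col] = numeric
    meta = pd.DataFrame({"mz": pd.to_numeric(df[mz_col]).to_numpy(),
                         "rt": pd.to_numeric(df[rt_col]).to_numpy()}, index=ids)
    return FeatureTable(areas, meta)


def write_feature_table(table: FeatureTable, path: str | Path,
                        dialect: str = "plain") -> None:
    out = table.feature_meta.copy()
    if dialect == "mzmine":
        out.columns = ["row m/z", "row retention time"]
        out.insert(0, "row ID", table.areas.index)
        body = table.areas.copy()
        body.columns = [f"{c}.mzXML Peak area" for c in body.columns]
        pd.concat([out.set_index(table.areas.index), body], axis=1).to_csv(
            path, index=False)
    else:
        out.insert(0, "feature_id", table.areas.index)
        pd.concat([out.set_index(table.areas.index), table.areas], axis=1).to_csv(
            path, index=False)


def filter_features_with_ms2(table: FeatureTable,
                             spectra: Iterable[Spectrum]) -> FeatureTable:
    """Keep only table rows whose feature id has an MS/MS spectrum.

    Mirrors the pre-processing rule of exporting only MS2-paired features;
    idempotent, and the sample columns are untouched.
    """
    with_ms2 = {s.feature_id for s in spectra}
    keep = [fid for fid in table.feature_ids if fid in with_ms2]
    if not keep:
        logger.warning("filter_features_with_ms2: no features retained")
    out = table.subset_features(keep)
    out.has_ms2 = pd.Series(True, index=out.areas.index)
    return out


def spectra_by_id(spectra: Iterable[Spectrum]) -> dict[str, Spectrum]:
    out: dict[str, Spectrum] = {}
    for s in spectra:
        if s.feature_id in out:
            raise ValueError(f"duplicate feature id {s.feature_id!r}")
        out[s.feature_id] = s
    return out
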