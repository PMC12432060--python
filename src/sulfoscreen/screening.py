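"""Feature ingestion and the suspect-screening filter cascade.

The screening pipeline mirrors a vendor-software preprocessing chain with
simple, explicit rules: per-run feature tables are aligned into consensus
features (single linkage within ppm/RT tolerances), background features are
removed by a fold-change test against process blanks, features without a
linked MS2 spectrum are discarded, and the survivors are matched against the
suspect mass list as [M-H]- ions within a ppm tolerance.  Every stage is
contractive and logged in a :class:`FilteringReport`.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as pymgf

from .chem import IonConvention, mz_deprotonated, ppm_error
from .database import CompoundEntry, SuspectDatabase

__all__ = [
    "Feature",
    "MS2Spectrum",
    "MatchResult",
    "FilteringReport",
    "read_features",
    "read_spectra",
    "align_replicates",
    "subtract_background",
    "require_ms2",
    "match_mass_list",
]

#: Defaults mirror the acceptance envelope of the workflow: 5 ppm mass
#: tolerance (the widest printed mass error in the curated reference set is
#: 4.7 ppm) and 0.1 min RT tolerance for alignment.
DEFAULT_PPM_TOL = 5.0
DEFAULT_RT_TOL = 0.1
DEFAULT_BLANK_RATIO = 5.0


@dataclass
class Feature:
    """An aligned MS1 feature with per-sample areas and MS2 links."""

    feature_id: str
    mz: float
    rt: float
    areas: dict[str, float] = field(default_factory=dict)
    ms2_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: mz must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        if any(a < 0 for a in self.areas.values()):
            raise ValueError(f"feature {self.feature_id}: negative peak area")

    @property
    def max_area(self) -> float:
        return max(self.areas.values(), default=0.0)


@dataclass
class MS2Spectrum:
    """A centroided MS2 spectrum (peaks kept sorted by m/z)."""

    spectrum_id: str
    precursor_mz: float
    rt: float
    peaks: list[tuple[float, float]] = field(default_factory=list)
    nce_steps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(intensity < 0 for _, intensity in self.peaks):
            raise ValueError(f"spectrum {self.spectrum_id}: negative intensity")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def base_peak_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)


@dataclass
class MatchResult:
    """A feature with its mass-list candidates sorted by |ppm error|."""

    feature: Feature
    candidates: list[tuple[CompoundEntry, float]]

    @property
    def best(self) -> tuple[CompoundEntry, float]:
        return self.candidates[0]


@dataclass
class FilteringReport:
    """In/out feature counts per pipeline stage."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage!r} is not contractive: {n_in} -> {n_out}")
        removed = n_in - n_out
        self.stages.append(
            {
                "stage": stage,
                "n_in": n_in,
                "n_out": n_out,
                "n_removed": removed,
                "percent_removed": (100.0 * removed / n_in) if n_in else 0.0,
            }
        )

    def to_json(self, destination: str | Path | None = None) -> str:
        text = json.dumps({"stages": self.stages}, indent=2)
        if destination is not None:
            Path(destination).write_text(text + "\n", encoding="utf-8")
        return text


def read_features(source: str | Path | pd.DataFrame, run_id: str | None = None) -> list[Feature]:
    """Read a feature table (CSV or DataFrame) into :class:`Feature` objects.

    Required columns: ``feature_id``, ``mz``, ``rt``; every remaining column
    is treated as a per-sample peak-area column.  NaN areas become 0.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, comment="#")
    missing = {"feature_id", "mz", "rt"} - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing required columns: {sorted(missing)}")
    sample_cols = [c for c in table.columns if c not in ("feature_id", "mz", "rt")]
    features = []
    for row in table.itertuples(index=False):
        areas = {
            col: float(getattr(row, col)) if not pd.isna(getattr(row, col)) else 0.0
            for col in sample_cols
        }
        fid = str(row.feature_id)
        if run_id:
            fid = f"{run_id}:{fid}"
        features.append(Feature(feature_id=fid, mz=float(row.mz), rt=float(row.rt), areas=areas))
    return features


def read_spectra(source: str | Path) -> list[MS2Spectrum]:
    """Read centroided MS2 spectra from an MGF or mzML file."""
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix == ".mgf":
        return _read_mgf(path)
    if suffix == ".mzml":
        return _read_mzml(path)
    raise ValueError(f"unsupported spectrum container: {path.name!r} (use .mgf or .mzML)")


def _read_mgf(path: Path) -> list[MS2Spectrum]:
    spectra = []
    with pymgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            rt_s = params.get("rtinseconds", 0.0)
            spectra.append(
                MS2Spectrum(
                    spectrum_id=str(params.get("title", f"scan_{i}")),
                    precursor_mz=float(params["pepmass"][0]),
                    rt=float(rt_s) / 60.0,
                    peaks=list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())),
                )
            )
    return spectra


def _decode_binary_array(array_elem) -> tuple[np.ndarray, str] | None:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float.

    Returns (values, kind) with kind "mz" or "intensity", or None for array
    types this reader does not handle.
    """
    accessions = {
        child.get("accession") for child in array_elem if child.tag.endswith("cvParam")
    }
    binary = array_elem.find(f"{_MZML_NS}binary")
    if binary is None or binary.text is None:
        return None
    raw = base64.b64decode(binary.text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = np.float32 if "MS:1000521" in accessions else np.float64
    values = np.frombuffer(raw, dtype=dtype)
    if "MS:1000514" in accessions:
        return values.astype(float), "mz"
    if "MS:1000515" in accessions:
        return values.astype(float), "intensity"
    return None


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
_RT_ACCESSIONS = ("MS:1000016",)  # scan start time


def _read_mzml(path: Path) -> list[MS2Spectrum]:
    """Minimal mzML reader for centroided MS2 spectra.

    Handles base64-encoded 32/64-bit float peak arrays (optionally
    zlib-compressed), selected-ion precursor m/z and scan start time with
    minute/second units; anything fancier (ion mobility, profile data,
    chromatograms) is out of scope.
    """
    spectra = []
    for _, spectrum in etree.iterparse(str(path), tag=f"{_MZML_NS}spectrum"):
        params = {
            cv.get("accession"): cv
            for cv in spectrum.iterfind(f"{_MZML_NS}cvParam")
        }
        level = params.get("MS:1000511")
        if level is None or level.get("value") != "2":
            spectrum.clear()
            continue
        rt_min = 0.0
        for cv in spectrum.iter(f"{_MZML_NS}cvParam"):
            if cv.get("accession") in _RT_ACCESSIONS:
                rt_min = float(cv.get("value", 0.0))
                if cv.get("unitAccession") == "UO:0000010" or cv.get("unitName") == "second":
                    rt_min /= 60.0
                break
        ion = spectrum.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        if ion is None:
            spectrum.clear()
            continue
        precursor_mz = None
        for cv in ion.iterfind(f"{_MZML_NS}cvParam"):
            if cv.get("accession") == "MS:1000744":
                precursor_mz = float(cv.get("value"))
        if precursor_mz is None:
            spectrum.clear()
            continue
        arrays: dict[str, np.ndarray] = {}
        for array_elem in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
            decoded = _decode_binary_array(array_elem)
            if decoded is not None:
                values, kind = decoded
                arrays[kind] = values
        mzs = arrays.get("mz", np.array([]))
        intensities = arrays.get("intensity", np.ones_like(mzs))
        spectra.append(
            MS2Spectrum(
                spectrum_id=str(spectrum.get("id", spectrum.get("index", ""))),
                precursor_mz=precursor_mz,
                rt=rt_min,
                peaks=list(zip(mzs.tolist(), intensities.tolist())),
            )
        )
        spectrum.clear()
    return spectra


def _within(mz_a: float, mz_b: float, ppm: float) -> bool:
    return abs(mz_a - mz_b) <= ppm * 1e-6 * max(mz_a, mz_b)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def align_replicates(
    runs: Sequence[Sequence[Feature]],
    mz_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[Feature]:
    """Single-linkage alignment of per-run features into consensus features.

    Two features link when both their m/z (ppm) and RT (minutes) agree within
    tolerance; connected components become one consensus feature whose m/z
    and RT are intensity-weighted means and whose per-sample areas are merged
    (same sample id in two runs: areas summed).
    """
    pool: list[Feature] = [f for run in runs for f in run]
    if not pool:
        return []
    order = sorted(range(len(pool)), key=lambda i: pool[i].mz)
    uf = _UnionFind(len(pool))
    for idx, i in enumerate(order):
        fi = pool[i]
        for j in order[idx + 1 :]:
            fj = pool[j]
            if not _within(fi.mz, fj.mz, mz_tol):
                break  # sorted by mz: no later feature can be closer
            if abs(fi.rt - fj.rt) <= rt_tol:
                uf.union(i, j)

    groups: dict[int, list[Feature]] = {}
    for i in range(len(pool)):
        groups.setdefault(uf.find(i), []).append(i)

    consensus: list[Feature] = []
    for k, (root, members) in enumerate(sorted(groups.items())):
        feats = [pool[i] for i in members]
        weights = np.array([max(f.max_area, 1.0) for f in feats])
        mzs = np.array([f.mz for f in feats])
        rts = np.array([f.rt for f in feats])
        areas: dict[str, float] = {}
        for f in feats:
            for sample, area in f.areas.items():
                areas[sample] = areas.get(sample, 0.0) + area
        consensus.append(
            Feature(
                feature_id=f"consensus_{k:05d}",
                mz=float(np.average(mzs, weights=weights)),
                rt=float(np.average(rts, weights=weights)),
                areas=areas,
            )
        )
    consensus.sort(key=lambda f: (f.mz, f.rt))
    return consensus


def subtract_background(
    features: Sequence[Feature],
    blank_features: Sequence[Feature],
    ratio_threshold: float = DEFAULT_BLANK_RATIO,
    mz_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[Feature]:
    """Drop features not sufficiently above the process blank.

    A feature matched to a blank feature (within both tolerances) is kept
    only when its maximum sample area is at least ``ratio_threshold`` times
    the blank area; unmatched features are always kept.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must exceed 1")
    blanks = sorted(blank_features, key=lambda f: f.mz)
    blank_mzs = np.array([b.mz for b in blanks])
    kept = []
    for feature in features:
        lo = np.searchsorted(blank_mzs, feature.mz * (1 - mz_tol * 1e-6 * 2))
        hi = np.searchsorted(blank_mzs, feature.mz * (1 + mz_tol * 1e-6 * 2))
        blank_area = 0.0
        for b in blanks[lo:hi]:
            if _within(feature.mz, b.mz, mz_tol) and abs(feature.rt - b.rt) <= rt_tol:
                blank_area = max(blank_area, b.max_area)
        if blank_area == 0.0 or feature.max_area >= ratio_threshold * blank_area:
            kept.append(feature)
    return kept


def require_ms2(
    features: Sequence[Feature],
    spectra: Sequence[MS2Spectrum],
    precursor_tol: float = DEFAULT_PPM_TOL,
    rt_window: float = 0.2,
) -> list[Feature]:
    """Keep only features with at least one linked MS2 spectrum.

    A spectrum links to a feature when its precursor m/z agrees within
    ``precursor_tol`` ppm and its RT within ``rt_window`` minutes; matching
    spectrum ids are recorded on the surviving features.
    """
    if precursor_tol <= 0 or rt_window <= 0:
        raise ValueError("tolerances must be positive")
    by_mz = sorted(spectra, key=lambda s: s.precursor_mz)
    mzs = np.array([s.precursor_mz for s in by_mz])
    kept = []
    for feature in features:
        lo = np.searchsorted(mzs, feature.mz * (1 - precursor_tol * 1e-6 * 2))
        hi = np.searchsorted(mzs, feature.mz * (1 + precursor_tol * 1e-6 * 2))
        links = [
            s.spectrum_id
            for s in by_mz[lo:hi]
            if _within(feature.mz, s.precursor_mz, precursor_tol)
            and abs(feature.rt - s.rt) <= rt_window
        ]
        if links:
            kept.append(replace(feature, ms2_ids=sorted(links)))
    return kept


def match_mass_list(
    features: Sequence[Feature],
    db: SuspectDatabase,
    ppm_tol: float = DEFAULT_PPM_TOL,
    conv: IonConvention | None = None,
    report: FilteringReport | None = None,
) -> list[MatchResult]:
    """Match feature m/z against the suspect database as [M-H]- ions.

    Candidates within ``ppm_tol`` are sorted by |ppm error|; features without
    any candidate are excluded from the results (and show up in the report's
    removal count).
    """
    if not db.entries:
        raise ValueError("suspect database is empty")
    conv = conv or IonConvention()
    theo = np.array([mz_deprotonated(e.neutral_mass, conv) for e in db.entries])
    order = np.argsort(theo)
    theo_sorted = theo[order]

    results = []
    for feature in features:
        lo = np.searchsorted(theo_sorted, feature.mz * (1 - ppm_tol * 1e-6 * 2))
        hi = np.searchsorted(theo_sorted, feature.mz * (1 + ppm_tol * 1e-6 * 2))
        candidates = []
        for idx in order[lo:hi]:
            err = ppm_error(feature.mz, theo[idx])
            if abs(err) <= ppm_tol:
                candidates.append((db.entries[idx], err))
        if candidates:
            candidates.sort(key=lambda c: (abs(c[1]), c[0].id))
            results.append(MatchResult(feature=feature, candidates=candidates))
    if report is not None:
        report.record("mass_list_match", len(features), len(results))
    return results
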