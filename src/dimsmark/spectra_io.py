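"""Readers and writers for peak lists, compound libraries, manifests and reports.

The canonical peak-list dialect is two-column delimited text (m/z, intensity),
one file per sample x technical replicate -- the unit of analysis in
direct-infusion work, where no chromatographic dimension exists. mzML is
supported read-only for centroided spectra (via pyteomics). All loaders are
total on their documented dialects: malformed input raises a diagnostic
error naming the offending row, never a silent partial load.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mass_calc import MolecularFormula, monoisotopic_mass, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "PeakList",
    "CohortManifest",
    "SpectraIOError",
    "read_peaklist",
    "write_peaklist",
    "read_compound_library",
    "write_compound_library",
    "read_manifest",
    "write_manifest",
    "write_frequency_report",
    "read_frequency_report",
    "TABLE_LIBRARY_COLUMNS",
]


class SpectraIOError(ValueError):
    """Raised for malformed input files, with row/line context."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One library metabolite (HMDB-style record).

    At least one of ``formula`` / ``neutral_mass`` must be present. When both
    are given they must agree to 0.01 Da, otherwise the record is flagged
    ``inconsistent`` (kept, so the caller can decide).
    """

    compound_id: str
    name: str = ""
    compound_class: str = ""
    formula: Optional[MolecularFormula] = None
    neutral_mass: Optional[float] = None
    kegg_id: str = ""
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.formula is None and self.neutral_mass is None:
            raise SpectraIOError(
                f"compound {self.compound_id!r} has neither formula nor neutral mass"
            )
        if self.formula is not None:
            computed = monoisotopic_mass(self.formula)
            if self.neutral_mass is None:
                object.__setattr__(self, "neutral_mass", computed)
            elif abs(computed - self.neutral_mass) > 0.01:
                object.__setattr__(self, "inconsistent", True)


@dataclass
class PeakList:
    """Centroided ions (m/z, intensity) for one sample x one technical replicate.

    m/z is sorted ascending on construction; intensities must be >= 0.
    """

    sample_id: str
    replicate_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectraIOError(
                f"m/z and intensity must be 1-D arrays of equal length "
                f"(got {self.mz.shape} and {self.intensity.shape})"
            )
        neg = np.flatnonzero(self.intensity < 0)
        if neg.size:
            raise SpectraIOError(
                f"negative intensity at peak row {neg[0] + 1} "
                f"(sample {self.sample_id!r}, replicate {self.replicate_id!r})"
            )
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_arrays(self, mz: np.ndarray, intensity: np.ndarray) -> "PeakList":
        return PeakList(self.sample_id, self.replicate_id, mz, intensity)


@dataclass
class CohortManifest:
    """sample_id -> (group label, replicate file paths or ids)."""

    samples: Dict[str, Tuple[str, List[str]]]
    min_replicates: int = 2

    def __post_init__(self) -> None:
        for sample_id, (group, replicates) in self.samples.items():
            if len(replicates) < self.min_replicates:
                raise SpectraIOError(
                    f"sample {sample_id!r} has {len(replicates)} replicates; "
                    f"at least {self.min_replicates} required"
                )

    @property
    def groups(self) -> List[str]:
        seen: List[str] = []
        for group, _ in self.samples.values():
            if group not in seen:
                seen.append(group)
        return seen

    def group_of(self, sample_id: str) -> str:
        return self.samples[sample_id][0]

    def samples_in_group(self, group: str) -> List[str]:
        return [s for s, (g, _) in self.samples.items() if g == group]

    def group_sizes(self) -> Dict[str, int]:
        sizes: Dict[str, int] = {}
        for group, _ in self.samples.values():
            sizes[group] = sizes.get(group, 0) + 1
        return sizes


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------


def _sniff_delimiter(sample: str) -> str:
    if "\t" in sample:
        return "\t"
    if ";" in sample and "," not in sample:
        return ";"
    return ","


def read_peaklist(
    path: str | Path,
    dialect: str = "delimited-text",
    sample_id: Optional[str] = None,
    replicate_id: Optional[str] = None,
) -> PeakList:
    """Load one peak list; returns a sorted, validated :class:`PeakList`.

    ``dialect`` is ``"delimited-text"`` (two columns m/z, intensity; CSV/TSV
    auto-detected; an optional non-numeric header line is skipped) or
    ``"mzML-centroid"`` (centroid arrays from the first spectrum).
    """
    path = Path(path)
    if sample_id is None or replicate_id is None:
        stem_parts = path.stem.rsplit("_", 1)
        sample_id = sample_id or stem_parts[0]
        replicate_id = replicate_id or (stem_parts[1] if len(stem_parts) > 1 else "1")

    if dialect == "mzML-centroid":
        from pyteomics import mzml

        with mzml.read(str(path)) as reader:
            try:
                spectrum = next(iter(reader))
            except StopIteration:
                logger.warning("mzML file %s contains no spectra", path)
                return PeakList(sample_id, replicate_id, np.array([]), np.array([]))
        return PeakList(
            sample_id,
            replicate_id,
            np.asarray(spectrum["m/z array"], dtype=float),
            np.asarray(spectrum["intensity array"], dtype=float),
        )

    if dialect != "delimited-text":
        raise SpectraIOError(f"unknown peak-list dialect {dialect!r}")

    text = path.read_text()
    if not text.strip():
        logger.warning("peak-list file %s is empty", path)
        return PeakList(sample_id, replicate_id, np.array([]), np.array([]))

    delimiter = _sniff_delimiter(text.splitlines()[0])
    mzs: List[float] = []
    intensities: List[float] = []
    for lineno, row in enumerate(csv.reader(io.StringIO(text), delimiter=delimiter), 1):
        if not row or not "".join(row).strip():
            continue
        try:
            mz, inten = float(row[0]), float(row[1])
        except (ValueError, IndexError):
            if lineno == 1:  # tolerated header line
                continue
            raise SpectraIOError(
                f"{path}: unparseable peak row at line {lineno}: {row!r}"
            ) from None
        mzs.append(mz)
        intensities.append(inten)
    try:
        return PeakList(sample_id, replicate_id, np.array(mzs), np.array(intensities))
    except SpectraIOError as exc:
        raise SpectraIOError(f"{path}: {exc}") from None


def write_peaklist(peaks: PeakList, path: str | Path, delimiter: str = ",") -> Path:
    """Write a peak list as two-column delimited text (m/z to 6 dp)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"{mz:.6f}{delimiter}{inten:.6g}"
        for mz, inten in zip(peaks.mz, peaks.intensity)
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


# ---------------------------------------------------------------------------
# Compound libraries
# ---------------------------------------------------------------------------

TABLE_LIBRARY_COLUMNS = [
    "compound_id",
    "name",
    "compound_class",
    "kegg_id",
    "formula",
    "neutral_mass",
]


def read_compound_library(path: str | Path) -> List[CompoundRecord]:
    """Load a delimited compound table into validated :class:`CompoundRecord` s.

    Required column: ``compound_id``; at least one of ``formula`` /
    ``neutral_mass`` per row. ``neutral_mass`` is backfilled from the formula
    when absent. Duplicate ids are an error.
    """
    path = Path(path)
    sep = _sniff_delimiter(path.read_text().splitlines()[0])
    table = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "compound_id" not in table.columns:
        raise SpectraIOError(f"{path}: missing required column 'compound_id'")

    duplicates = table["compound_id"][table["compound_id"].duplicated()].tolist()
    if duplicates:
        raise SpectraIOError(f"{path}: duplicate compound_id values: {duplicates}")

    records: List[CompoundRecord] = []
    for _, row in table.iterrows():
        formula_text = str(row.get("formula", "")).strip()
        mass_text = str(row.get("neutral_mass", "")).strip()
        if not formula_text and not mass_text:
            raise SpectraIOError(
                f"{path}: compound {row['compound_id']!r} has neither "
                "formula nor neutral_mass"
            )
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                name=str(row.get("name", "")),
                compound_class=str(row.get("compound_class", "")),
                kegg_id=str(row.get("kegg_id", "")),
                formula=parse_formula(formula_text) if formula_text else None,
                neutral_mass=float(mass_text) if mass_text else None,
            )
        )
    return records


def write_compound_library(
    records: Iterable[CompoundRecord], path: str | Path, sep: str = "\t"
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rows.append(
            {
                "compound_id": rec.compound_id,
                "name": rec.name,
                "compound_class": rec.compound_class,
                "kegg_id": rec.kegg_id,
                "formula": str(rec.formula) if rec.formula is not None else "",
                "neutral_mass": f"{rec.neutral_mass:.6f}",
            }
        )
    pd.DataFrame(rows, columns=TABLE_LIBRARY_COLUMNS).to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path, min_replicates: int = 2) -> CohortManifest:
    """Read a manifest table: columns sample_id, group, replicate_path.

    One row per replicate file; rows for the same sample are aggregated.
    """
    path = Path(path)
    sep = _sniff_delimiter(path.read_text().splitlines()[0])
    table = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "group", "replicate_path"}
    missing = required - set(table.columns)
    if missing:
        raise SpectraIOError(f"{path}: manifest missing columns {sorted(missing)}")
    samples: Dict[str, Tuple[str, List[str]]] = {}
    for _, row in table.iterrows():
        sid, group, rep = row["sample_id"], row["group"], row["replicate_path"]
        if sid in samples:
            if samples[sid][0] != group:
                raise SpectraIOError(
                    f"{path}: sample {sid!r} assigned to two groups "
                    f"({samples[sid][0]!r}, {group!r})"
                )
            samples[sid][1].append(rep)
        else:
            samples[sid] = (group, [rep])
    return CohortManifest(samples, min_replicates=min_replicates)


def write_manifest(manifest: CohortManifest, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"sample_id": sid, "group": group, "replicate_path": rep}
        for sid, (group, reps) in manifest.samples.items()
        for rep in reps
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# Frequency reports
# ---------------------------------------------------------------------------


def write_frequency_report(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    """Write a per-metabolite frequency/count report, one row per metabolite.

    ``table`` is the long-form frequency table produced by
    :func:`dimsmark.cohort_analysis.group_frequency` (columns compound_id,
    group, detected_count, group_size, frequency). The report is wide:
    ``frequency_<group>`` printed to 2 dp and ``n_samples_<group>`` per group,
    mirroring how such panels are tabulated. Full-precision frequencies are
    kept internally; rounding here is presentation only.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    groups = list(dict.fromkeys(table["group"])) if len(table) else []
    columns = ["compound_id"]
    for group in groups:
        columns += [f"frequency_{group}", f"n_samples_{group}"]
    rows = []
    for compound_id, sub in table.groupby("compound_id", sort=True):
        row: Dict[str, object] = {"compound_id": compound_id}
        for _, rec in sub.iterrows():
            row[f"frequency_{rec['group']}"] = f"{rec['frequency']:.2f}"
            row[f"n_samples_{rec['group']}"] = int(rec["detected_count"])
        rows.append(row)
    report = pd.DataFrame(rows, columns=columns)
    report.to_csv(path, sep=sep, index=False)
    return path


def read_frequency_report(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back a written frequency report (counts exact, frequencies 2 dp)."""
    return pd.read_csv(Path(path), sep=sep)
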