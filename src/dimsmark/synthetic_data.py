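"""Synthetic direct-infusion MS cohorts with known ground truth.

Emulates the statistical structure the downstream analysis assumes: four
patient groups of unequal size, two technical replicates per sample, ions in
m/z 50-1000 with ~1 ppm mass error, H+/Na+/K+ adduct formation, group-
specific metabolite prevalence, uniform noise peaks, and a spiked internal
standard (losartan) present in every replicate.

Presence is drawn once per sample from the group prevalence; replicate
dropout is layered on top, which is what gives the both-replicates consensus
rule something to do. An optional linear ppm calibration drift per spectrum
gives the recalibration stage something real to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mass_calc import BUILTIN_ADDUCTS, adduct_mz, parse_formula
from .peak_processing import ProfileTrace
from .spectra_io import CohortManifest, CompoundRecord, PeakList, write_manifest, write_peaklist

__all__ = [
    "ConfigurationError",
    "PanelMetabolite",
    "CohortDesign",
    "SyntheticTruth",
    "LOSARTAN",
    "PE_MARKER_PANEL",
    "study_design",
    "generate_cohort",
    "generate_profile_spectrum",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Raised when a cohort design violates its invariants."""


#: The spiked internal standard: losartan, C22H23ClN6O, detected as [M+H]+.
LOSARTAN = CompoundRecord(
    compound_id="IS_LOSARTAN",
    name="Losartan",
    compound_class="internal standard",
    formula=parse_formula("C22H23ClN6O"),
)


@dataclass(frozen=True)
class PanelMetabolite:
    """One planted metabolite: a compound, its per-group detection
    probability, the adduct it forms, and a log-normal intensity model."""

    compound: CompoundRecord
    group_probs: Mapping[str, float]
    adduct: str = "[M+H]+"
    intensity_median: float = 1e4
    intensity_sigma: float = 1.0

    def prob(self, group: str) -> float:
        return float(self.group_probs.get(group, 0.0))


# Nine plasma metabolites (HMDB accessions) with per-group detection
# probabilities matching the published panel's frequencies in the four-group
# design (first-trimester control / first-trimester pre-PE / third-trimester
# control / third-trimester PE). The adduct is the cation nearest to the
# reported detected-vs-nominal mass difference; rows whose mass difference
# fits no cation default to [M+H]+.
_PANEL_ROWS: List[Tuple[str, str, str, str, float, Tuple[float, float, float, float], str]] = [
    ("HMDB0002282", "2-(acetylamino)-1,5-anhydro-2-deoxy-4-O-b-D-galactopyranosyl-D-arabino-Hex-1-enitol",
     "O-glycosyl compounds", "", 365.13, (0.04, 0.67, 0.0, 0.06), "[M+H]+"),
    ("HMDB0003689", "Neuroprotectin D1", "Very long-chain fatty acids", "",
     360.23, (0.12, 1.0, 0.0, 0.03), "[M+K]+"),
    ("HMDB0013327", "Dodecanedioylcarnitine", "Tricarboxylic acids", "",
     373.25, (0.08, 0.67, 0.0, 0.0), "[M+K]+"),
    ("HMDB0006766", "Estriol-16-Glucuronide", "Steroids and steroid derivatives",
     "C05504", 464.20, (0.04, 0.67, 0.0, 0.0), "[M+K]+"),
    ("HMDB0004220", "Biotinyl-5'-AMP", "Carboxylic acids and derivatives",
     "C05921", 573.14, (0.0, 0.67, 0.0, 0.0), "[M+H]+"),
    ("HMDB0001445", "N-Acetyl-D-glucosaminyldiphosphodolichol", "Prenol lipids",
     "C04500", 587.23, (0.04, 0.67, 0.05, 0.10), "[M+Na]+"),
    ("HMDB0006557", "ADP-glucose", "Purine nucleotide sugars", "C00498",
     589.08, (0.0, 0.67, 0.0, 0.0), "[M+Na]+"),
    ("HMDB0011764", "Cer(d18:0/20:0)", "Ceramides", "", 595.59,
     (0.04, 1.0, 0.05, 0.06), "[M+Na]+"),
    ("HMDB0000381", "Allolithocholic acid", "Bile acids", "", 376.30,
     (0.12, 0.67, 0.05, 0.10), "[M+H]+"),
]

_STUDY_GROUPS: Tuple[Tuple[str, int], ...] = (
    ("group1", 25), ("group2", 3), ("group3", 20), ("group4", 31),
)

PE_MARKER_PANEL: List[PanelMetabolite] = [
    PanelMetabolite(
        compound=CompoundRecord(cid, name, cls, neutral_mass=mass, kegg_id=kegg),
        group_probs=dict(zip([g for g, _ in _STUDY_GROUPS], probs)),
        adduct=adduct,
    )
    for cid, name, cls, kegg, mass, probs, adduct in _PANEL_ROWS
]


@dataclass(frozen=True)
class CohortDesign:
    """Everything :func:`generate_cohort` needs, with study-shaped defaults.

    Defaults: four groups of 25/3/20/31 samples, two technical replicates,
    1 ppm Gaussian mass-error SD (inside the instrument's 3 ppm accuracy),
    10% per-replicate dropout of truly present ions, 150 uniform noise peaks
    per spectrum, losartan spiked into every replicate, m/z range 50-1000,
    and no calibration drift.
    """

    groups: Tuple[Tuple[str, int], ...] = _STUDY_GROUPS
    metabolite_panel: Tuple[PanelMetabolite, ...] = tuple(PE_MARKER_PANEL)
    replicates_per_sample: int = 2
    mass_error_ppm_sd: float = 1.0
    replicate_dropout_prob: float = 0.1
    noise_peaks_per_spectrum: int = 150
    noise_intensity_median: float = 500.0
    noise_intensity_sigma: float = 1.0
    internal_standard: Optional[CompoundRecord] = LOSARTAN
    internal_standard_adduct: str = "[M+H]+"
    internal_standard_intensity: float = 1e5
    mz_range: Tuple[float, float] = (50.0, 1000.0)
    # linear ppm drift across the m/z range: (ppm at low edge, ppm at high edge)
    calibration_drift_ppm: Tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ConfigurationError("every group needs n_samples >= 1")
        if self.replicates_per_sample < 2:
            raise ConfigurationError("replicates_per_sample must be >= 2")
        if not 0 <= self.replicate_dropout_prob <= 1:
            raise ConfigurationError("replicate_dropout_prob must be in [0, 1]")
        if self.mass_error_ppm_sd < 0 or self.noise_peaks_per_spectrum < 0:
            raise ConfigurationError("mass_error_ppm_sd and noise count must be >= 0")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ConfigurationError("mz_range must be (low, high) with low < high")
        group_labels = [g for g, _ in self.groups]
        for entry in self.metabolite_panel:
            for group, p in entry.group_probs.items():
                if group not in group_labels:
                    raise ConfigurationError(
                        f"panel metabolite {entry.compound.compound_id!r} references "
                        f"unknown group {group!r}"
                    )
                if not 0 <= p <= 1:
                    raise ConfigurationError(
                        f"detection probability {p} out of [0, 1] for "
                        f"{entry.compound.compound_id!r}"
                    )
            mz = adduct_mz(entry.compound.neutral_mass, entry.adduct)
            if not lo <= mz <= hi:
                raise ConfigurationError(
                    f"{entry.compound.compound_id!r} {entry.adduct} m/z {mz:.3f} "
                    f"outside instrument range {self.mz_range}"
                )

    @property
    def internal_standard_mz(self) -> float:
        if self.internal_standard is None:
            raise ConfigurationError("design has no internal standard")
        return adduct_mz(self.internal_standard.neutral_mass, self.internal_standard_adduct)

    def library(self, include_internal_standard: bool = True) -> List[CompoundRecord]:
        """Compound library covering the panel (and optionally the IS)."""
        records = [entry.compound for entry in self.metabolite_panel]
        if include_internal_standard and self.internal_standard is not None:
            records.append(self.internal_standard)
        return records


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort.

    ``presence``: compound x sample booleans drawn at the sample level.
    ``consensus_presence``: presence AND emitted in every replicate (what a
    perfect consensus + annotation stage should recover).
    ``peak_origins``: (sample_id, replicate_id) -> per-peak labels, aligned
    with the sorted peak list; a label is a compound id or ``"noise"`` /
    ``"internal_standard"``.
    """

    presence: pd.DataFrame
    consensus_presence: pd.DataFrame
    adduct_assignment: Dict[Tuple[str, str], str]
    peak_origins: Dict[Tuple[str, str], List[str]]
    sample_groups: Dict[str, str]
    drift_ppm: Dict[Tuple[str, str], Tuple[float, float]]

    def manifest(self, replicate_ids: Optional[Sequence[str]] = None) -> CohortManifest:
        reps = list(replicate_ids) if replicate_ids else None
        samples = {}
        for sample_id, group in self.sample_groups.items():
            r = reps or sorted({rid for (s, rid) in self.peak_origins if s == sample_id})
            samples[sample_id] = (group, [f"{sample_id}_{rid}.csv" for rid in r])
        return CohortManifest(samples)


def study_design(seed: int = 0, **overrides) -> CohortDesign:
    """The default four-group, two-replicate design with the marker panel."""
    return replace(CohortDesign(seed=seed), **overrides)


def generate_cohort(design: CohortDesign) -> Tuple[List[PeakList], SyntheticTruth]:
    """Draw one cohort: a peak list per sample x replicate, plus ground truth.

    Sample-level presence of each panel metabolite is Bernoulli in its group
    probability; a present metabolite emits one adduct peak per replicate,
    each independently dropped with ``replicate_dropout_prob``, at the
    theoretical adduct m/z perturbed by Gaussian ppm error (and by the
    configured calibration drift). Noise peaks are uniform in the m/z range
    with low-tail log-normal intensities. The internal standard appears in
    every replicate. Identical designs (including seed) give identical output.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    lo, hi = design.mz_range
    drift_lo, drift_hi = design.calibration_drift_ppm
    drift_slope = (drift_hi - drift_lo) / (hi - lo)

    def apply_drift(mz: np.ndarray) -> np.ndarray:
        ppm = drift_lo + drift_slope * (mz - lo)
        return mz * (1.0 + ppm * 1e-6)

    compound_ids = [e.compound.compound_id for e in design.metabolite_panel]
    sample_ids: List[str] = []
    sample_groups: Dict[str, str] = {}
    for group, n in design.groups:
        for i in range(1, n + 1):
            sid = f"{group}_s{i:02d}"
            sample_ids.append(sid)
            sample_groups[sid] = group

    presence = pd.DataFrame(False, index=compound_ids, columns=sample_ids)
    consensus = pd.DataFrame(False, index=compound_ids, columns=sample_ids)
    adduct_assignment: Dict[Tuple[str, str], str] = {}
    peak_origins: Dict[Tuple[str, str], List[str]] = {}
    drift_record: Dict[Tuple[str, str], Tuple[float, float]] = {}
    replicate_ids = [f"r{j + 1}" for j in range(design.replicates_per_sample)]

    peaklists: List[PeakList] = []
    for sid in sample_ids:
        group = sample_groups[sid]
        present_entries: List[PanelMetabolite] = []
        for entry in design.metabolite_panel:
            if rng.random() < entry.prob(group):
                presence.at[entry.compound.compound_id, sid] = True
                adduct_assignment[(sid, entry.compound.compound_id)] = entry.adduct
                present_entries.append(entry)

        emitted_in_all = {e.compound.compound_id: True for e in present_entries}
        for rid in replicate_ids:
            mzs: List[float] = []
            intensities: List[float] = []
            labels: List[str] = []
            for entry in present_entries:
                if rng.random() < design.replicate_dropout_prob:
                    emitted_in_all[entry.compound.compound_id] = False
                    continue
                theo = adduct_mz(entry.compound.neutral_mass, entry.adduct)
                eps = rng.normal(0.0, design.mass_error_ppm_sd)
                mzs.append(theo * (1.0 + eps * 1e-6))
                intensities.append(
                    entry.intensity_median
                    * np.exp(rng.normal(0.0, entry.intensity_sigma))
                )
                labels.append(entry.compound.compound_id)
            # internal standard: every replicate, tight intensity spread
            if design.internal_standard is not None:
                is_theo = design.internal_standard_mz
                eps = rng.normal(0.0, design.mass_error_ppm_sd)
                mzs.append(is_theo * (1.0 + eps * 1e-6))
                intensities.append(
                    design.internal_standard_intensity * np.exp(rng.normal(0.0, 0.1))
                )
                labels.append("internal_standard")
            # uniform noise
            n_noise = design.noise_peaks_per_spectrum
            if n_noise:
                noise_mz = rng.uniform(lo, hi, size=n_noise)
                noise_int = design.noise_intensity_median * np.exp(
                    -np.abs(rng.normal(0.0, design.noise_intensity_sigma, size=n_noise))
                )
                mzs.extend(noise_mz.tolist())
                intensities.extend(noise_int.tolist())
                labels.extend(["noise"] * n_noise)

            mz_arr = apply_drift(np.asarray(mzs, dtype=float))
            mz_arr = np.clip(mz_arr, lo, hi)
            order = np.argsort(mz_arr, kind="stable")
            peaklists.append(
                PeakList(sid, rid, mz_arr[order], np.asarray(intensities)[order])
            )
            peak_origins[(sid, rid)] = [labels[k] for k in order]
            drift_record[(sid, rid)] = (drift_lo, drift_hi)

        for entry in present_entries:
            cid = entry.compound.compound_id
            consensus.at[cid, sid] = emitted_in_all[cid]

    truth = SyntheticTruth(
        presence=presence,
        consensus_presence=consensus,
        adduct_assignment=adduct_assignment,
        peak_origins=peak_origins,
        sample_groups=sample_groups,
        drift_ppm=drift_record,
    )
    return peaklists, truth


def generate_profile_spectrum(
    peaks: PeakList,
    peak_width: float = 0.01,
    baseline_noise_sd: float = 0.0,
    grid_step: float = 0.002,
    seed: int = 0,
    mz_margin: float = 1.0,
    mz_range: Optional[Tuple[float, float]] = None,
) -> ProfileTrace:
    """Render a centroid list as a profile trace (Gaussian shapes + white noise).

    ``peak_width`` is the Gaussian sigma in Da. Deterministic under a fixed
    seed; the grid spans the peaks plus a margin (or an explicit range).
    """
    if peak_width <= 0 or grid_step <= 0:
        raise ConfigurationError("peak_width and grid_step must be > 0")
    if grid_step >= peak_width:
        raise ConfigurationError("grid_step must be smaller than peak_width")
    if mz_range is not None:
        lo, hi = mz_range
    elif len(peaks):
        lo, hi = float(peaks.mz.min()) - mz_margin, float(peaks.mz.max()) + mz_margin
    else:
        lo, hi = 0.0, 1.0
    grid = np.arange(lo, hi + grid_step, grid_step)
    trace = np.zeros_like(grid)
    for mz, inten in zip(peaks.mz, peaks.intensity):
        trace += inten * np.exp(-0.5 * ((grid - mz) / peak_width) ** 2)
    if baseline_noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, baseline_noise_sd, size=grid.size)
    return ProfileTrace(grid, trace)


def write_cohort(
    peaklists: Sequence[PeakList],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> Path:
    """Write per-replicate peak-list files plus a manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples: Dict[str, Tuple[str, List[str]]] = {}
    for peaks in peaklists:
        fname = f"{peaks.sample_id}_{peaks.replicate_id}.csv"
        write_peaklist(peaks, outdir / fname)
        group = truth.sample_groups[peaks.sample_id]
        samples.setdefault(peaks.sample_id, (group, []))[1].append(fname)
    manifest_path = outdir / "manifest.tsv"
    write_manifest(CohortManifest(samples), manifest_path)
    return manifest_path
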