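"""Spectrum-to-ion-list stages for direct-infusion spectra.

Order of operations, mirroring standard DIMS practice: detect centroids in
the profile trace, recalibrate m/z against characteristic high-intensity
reference ions, normalize intensities (internal standard or total ion
current), then keep only ions registered in every technical replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .spectra_io import PeakList

logger = logging.getLogger(__name__)

__all__ = [
    "PeakDetectionParams",
    "ProfileTrace",
    "ConsensusIonTable",
    "detect_peaks",
    "recalibrate",
    "normalize",
    "replicate_consensus",
    "multi_replicate_consensus",
]

#: Replicate m/z matching tolerance, ppm. Not dictated by the acquisition
#: itself; chosen above the instrument accuracy (3 ppm) but well below
#: typical peak spacing. Configurable everywhere it is used.
DEFAULT_MATCH_TOL_PPM = 5.0


@dataclass(frozen=True)
class PeakDetectionParams:
    """Centroiding thresholds.

    Defaults follow common vendor-software settings for high-resolution
    infusion spectra: >= 2 points per peak, SNR >= 1, and intensity cutoffs
    of 0.01% of the base peak (relative) and 100 counts (absolute).
    """

    min_points_per_peak: int = 2
    min_snr: float = 1.0
    relative_intensity_cutoff: float = 0.0001
    absolute_intensity_cutoff: float = 100.0
    noise_window_points: int = 501

    def __post_init__(self) -> None:
        if self.min_points_per_peak < 1:
            raise ValueError("min_points_per_peak must be >= 1")
        if min(self.min_snr, self.relative_intensity_cutoff,
               self.absolute_intensity_cutoff) < 0:
            raise ValueError("detection thresholds must be >= 0")
        if self.relative_intensity_cutoff > 1:
            raise ValueError("relative_intensity_cutoff is a fraction <= 1")


@dataclass
class ProfileTrace:
    """A profile-mode spectrum: intensity sampled on a monotone m/z grid."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("trace m/z and intensity must be 1-D and equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("trace m/z grid must be strictly increasing")


@dataclass
class ConsensusIonTable:
    """Per-sample ions surviving the all-replicates rule.

    ``consensus_mz`` is the intensity-weighted mean of the contributing
    replicate m/z values; ``intensities`` has one column per replicate.
    """

    sample_id: str
    consensus_mz: np.ndarray
    intensities: np.ndarray  # shape (n_ions, n_replicates)
    source_indices: List[Tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.consensus_mz = np.asarray(self.consensus_mz, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.consensus_mz.size == 0:
            self.intensities = self.intensities.reshape(0, max(self.intensities.shape[-1], 0))

    def __len__(self) -> int:
        return int(self.consensus_mz.size)

    @property
    def mean_intensity(self) -> np.ndarray:
        if len(self) == 0:
            return np.array([])
        return self.intensities.mean(axis=1)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------


def _local_noise(intensity: np.ndarray, window: int) -> np.ndarray:
    """Scaled sliding-window MAD noise estimate, floored at machine epsilon.

    Computed blockwise and interpolated; robust to sparse peaks because the
    median ignores the (rare) signal points.
    """
    n = intensity.size
    window = max(3, min(window, n))
    n_blocks = max(1, n // window)
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mads = np.empty(n_blocks)
    for i in range(n_blocks):
        block = intensity[edges[i]:edges[i + 1]]
        mads[i] = np.median(np.abs(block - np.median(block)))
    noise = 1.4826 * mads
    floor = max(1.4826 * np.median(np.abs(intensity - np.median(intensity))), 1e-12)
    noise = np.maximum(noise, 1e-12)
    if n_blocks == 1:
        return np.full(n, max(noise[0], 1e-12))
    return np.interp(np.arange(n), centers, noise, left=noise[0], right=noise[-1])


def _parabolic_apex(mz: np.ndarray, intensity: np.ndarray, idx: int) -> float:
    """3-point parabolic interpolation of the apex m/z around grid index idx."""
    if idx <= 0 or idx >= mz.size - 1:
        return float(mz[idx])
    y0, y1, y2 = intensity[idx - 1], intensity[idx], intensity[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a concave triple
        return float(mz[idx])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    step = 0.5 * (mz[idx + 1] - mz[idx - 1])
    return float(mz[idx] + shift * step)


def detect_peaks(
    trace: ProfileTrace,
    params: PeakDetectionParams = PeakDetectionParams(),
    sample_id: str = "",
    replicate_id: str = "",
) -> PeakList:
    """Centroid a profile trace into a :class:`PeakList`.

    A peak is a local maximum with at least ``min_points_per_peak``
    contiguous points above the local noise level, apex SNR >=
    ``min_snr``, and apex intensity above both the absolute cutoff and
    ``relative_intensity_cutoff`` x base-peak intensity. Apex m/z is refined
    by 3-point parabolic interpolation.
    """
    mz, inten = trace.mz, trace.intensity
    if mz.size < params.min_points_per_peak:
        logger.warning("trace shorter than min_points_per_peak; no peaks")
        return PeakList(sample_id, replicate_id, np.array([]), np.array([]))
    if not np.any(inten > 0):
        return PeakList(sample_id, replicate_id, np.array([]), np.array([]))

    noise = _local_noise(inten, params.noise_window_points)
    base_peak = float(inten.max())
    min_intensity = max(
        params.absolute_intensity_cutoff,
        params.relative_intensity_cutoff * base_peak,
    )

    candidates, _ = signal.find_peaks(inten)
    above = inten > noise
    out_mz: List[float] = []
    out_int: List[float] = []
    for idx in candidates:
        apex = float(inten[idx])
        if apex < min_intensity or apex < params.min_snr * noise[idx]:
            continue
        # count contiguous above-noise points spanning the apex
        lo = idx
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = idx
        while hi < inten.size - 1 and above[hi + 1]:
            hi += 1
        if (hi - lo + 1) < params.min_points_per_peak or not above[idx]:
            continue
        out_mz.append(_parabolic_apex(mz, inten, idx))
        out_int.append(apex)
    return PeakList(sample_id, replicate_id, np.array(out_mz), np.array(out_int))


# ---------------------------------------------------------------------------
# Internal recalibration
# ---------------------------------------------------------------------------


def _match_references(
    peaks: PeakList, reference_mzs: Sequence[float], tol_ppm: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest observed peak within tol for each reference; (observed, reference)."""
    obs: List[float] = []
    ref: List[float] = []
    for r in np.sort(np.asarray(reference_mzs, dtype=float)):
        if peaks.mz.size == 0:
            break
        i = int(np.clip(np.searchsorted(peaks.mz, r), 1, peaks.mz.size - 1))
        candidates = peaks.mz[i - 1:i + 1]
        nearest = float(candidates[np.argmin(np.abs(candidates - r))])
        if abs(nearest - r) / r * 1e6 <= tol_ppm:
            obs.append(nearest)
            ref.append(float(r))
    return np.asarray(obs), np.asarray(ref)


def recalibrate(
    peaks: PeakList,
    reference_mzs: Sequence[float],
    match_tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
) -> PeakList:
    """Internal calibration against characteristic reference ions.

    Fits a linear ppm-vs-m/z drift model on the matched (observed, reference)
    pairs and divides it out of every peak; with a single matched reference a
    constant ppm shift is applied. Never makes things worse: if the mean
    absolute reference error would increase, the input is returned unchanged.
    With zero matched references the input is returned with a warning.
    """
    obs, ref = _match_references(peaks, reference_mzs, match_tol_ppm)
    if obs.size == 0:
        logger.warning(
            "recalibrate: no reference matched within %.1f ppm; peaks unchanged",
            match_tol_ppm,
        )
        return peaks
    errs_ppm = (obs - ref) / ref * 1e6
    if obs.size == 1:
        slope, intercept = 0.0, float(errs_ppm[0])
    else:
        slope, intercept = np.polyfit(obs, errs_ppm, 1)

    def correct(mz: np.ndarray) -> np.ndarray:
        return mz / (1.0 + (slope * mz + intercept) * 1e-6)

    before = float(np.mean(np.abs(errs_ppm)))
    after = float(np.mean(np.abs((correct(obs) - ref) / ref * 1e6)))
    if after > before:
        logger.warning("recalibrate: correction rejected (residual %.3f > %.3f ppm)",
                       after, before)
        return peaks
    return peaks.with_arrays(correct(peaks.mz), peaks.intensity.copy())


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------


def normalize(
    peaks: PeakList,
    method: str = "internal_standard",
    is_mz: Optional[float] = None,
    is_tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
    fallback_to_tic: bool = False,
) -> PeakList:
    """Divide every intensity by a per-spectrum reference quantity.

    ``internal_standard``: the intensity of the ion matching ``is_mz`` within
    ``is_tol_ppm`` (most intense match if several). ``total_ion_current``:
    the summed intensity. m/z values are untouched.
    """
    if method == "total_ion_current":
        total = float(peaks.intensity.sum())
        if total <= 0:
            raise ValueError("cannot TIC-normalize a spectrum with zero total intensity")
        return peaks.with_arrays(peaks.mz.copy(), peaks.intensity / total)
    if method != "internal_standard":
        raise ValueError(f"unknown normalization method {method!r}")
    if is_mz is None:
        raise ValueError("internal_standard normalization requires is_mz")
    window = is_mz * is_tol_ppm * 1e-6
    mask = np.abs(peaks.mz - is_mz) <= window
    if not mask.any():
        if fallback_to_tic:
            logger.warning(
                "internal standard m/z %.4f not found within %.1f ppm; "
                "falling back to TIC normalization", is_mz, is_tol_ppm,
            )
            return normalize(peaks, "total_ion_current")
        raise ValueError(
            f"internal standard m/z {is_mz:.4f} not found within {is_tol_ppm} ppm"
        )
    reference = float(peaks.intensity[mask].max())
    if reference <= 0:
        raise ValueError("internal standard has zero intensity")
    return peaks.with_arrays(peaks.mz.copy(), peaks.intensity / reference)


# ---------------------------------------------------------------------------
# Technical-replicate consensus
# ---------------------------------------------------------------------------


def _pair_ions(
    mz_a: np.ndarray, mz_b: np.ndarray, tol_ppm: float
) -> List[Tuple[int, int]]:
    """Greedy best-first pairing of ions agreeing within tol_ppm.

    Candidate pairs are ranked by relative m/z deviation (ppm of the pair
    mean, a symmetric quantity), then accepted greedily with each ion pairing
    at most once. Symmetric in its arguments by construction.
    """
    pairs: List[Tuple[float, float, int, int]] = []
    for i, a in enumerate(mz_a):
        lo = np.searchsorted(mz_b, a * (1 - tol_ppm * 1e-6), side="left")
        hi = np.searchsorted(mz_b, a * (1 + tol_ppm * 1e-6), side="right")
        for j in range(int(lo), int(hi)):
            mean = 0.5 * (a + mz_b[j])
            dev_ppm = abs(a - mz_b[j]) / mean * 1e6
            if dev_ppm <= tol_ppm:
                pairs.append((dev_ppm, mean, i, j))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    matched: List[Tuple[int, int]] = []
    for _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    matched.sort()
    return matched


def replicate_consensus(
    rep_a: PeakList,
    rep_b: PeakList,
    match_tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
) -> ConsensusIonTable:
    """Keep only ions registered in both technical replicates.

    Ions are paired greedily by closest relative m/z within ``match_tol_ppm``;
    unpaired ions are discarded. The consensus m/z is the intensity-weighted
    mean of the paired values, so it always lies between them.
    """
    matched = _pair_ions(rep_a.mz, rep_b.mz, match_tol_ppm)
    if not matched:
        return ConsensusIonTable(rep_a.sample_id, np.array([]), np.zeros((0, 2)))
    idx_a = np.array([i for i, _ in matched])
    idx_b = np.array([j for _, j in matched])
    int_a, int_b = rep_a.intensity[idx_a], rep_b.intensity[idx_b]
    weights = int_a + int_b
    safe = np.where(weights > 0, weights, 1.0)
    consensus_mz = np.where(
        weights > 0,
        (rep_a.mz[idx_a] * int_a + rep_b.mz[idx_b] * int_b) / safe,
        0.5 * (rep_a.mz[idx_a] + rep_b.mz[idx_b]),
    )
    order = np.argsort(consensus_mz, kind="stable")
    return ConsensusIonTable(
        rep_a.sample_id,
        consensus_mz[order],
        np.column_stack([int_a, int_b])[order],
        [(int(idx_a[k]), int(idx_b[k])) for k in order],
    )


def multi_replicate_consensus(
    replicates: Sequence[PeakList],
    match_tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
) -> ConsensusIonTable:
    """Generalize the both-replicates rule to R replicates: present in all R.

    Folds pairwise: the running consensus is matched against each further
    replicate, and ions missing from any replicate are dropped.
    """
    if len(replicates) < 2:
        raise ValueError("consensus requires at least 2 technical replicates")
    table = replicate_consensus(replicates[0], replicates[1], match_tol_ppm)
    for rep in replicates[2:]:
        pseudo = PeakList(
            table.sample_id, "consensus", table.consensus_mz, table.mean_intensity
        )
        matched = _pair_ions(pseudo.mz, rep.mz, match_tol_ppm)
        if not matched:
            return ConsensusIonTable(
                table.sample_id, np.array([]),
                np.zeros((0, table.intensities.shape[1] + 1)),
            )
        idx_c = [i for i, _ in matched]
        idx_r = [j for _, j in matched]
        int_r = rep.intensity[idx_r]
        prev_int = table.intensities[idx_c]
        w = prev_int.sum(axis=1) + int_r
        safe = np.where(w > 0, w, 1.0)
        new_mz = (
            table.consensus_mz[idx_c] * prev_int.sum(axis=1) + rep.mz[idx_r] * int_r
        ) / safe
        table = ConsensusIonTable(
            table.sample_id,
            new_mz,
            np.column_stack([prev_int, int_r]),
            [tuple(table.source_indices[i]) + (int(j),) for i, j in matched],
        )
    return table
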