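"""Adduct-aware putative identification of consensus ions by accurate mass.

Replaces an external accurate-mass library-search service with a local
interval query: every (compound, adduct) whose theoretical m/z falls within
the ppm tolerance of an observed ion is emitted. Identification by accurate
mass alone is putative — ambiguity is preserved, not collapsed to a best
hit, and a compound counts as detected in a sample if any candidate
annotation exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .mass_calc import AdductSpec, BUILTIN_ADDUCTS, adduct_mz, ppm_error
from .peak_processing import ConsensusIonTable
from .spectra_io import CohortManifest, CompoundRecord

__all__ = [
    "DEFAULT_TOL_PPM",
    "AnnotationResult",
    "annotate_ions",
    "annotate_cohort",
    "build_detection_matrix",
]

#: Identification mass-accuracy window, ppm.
DEFAULT_TOL_PPM = 2.0


@dataclass(frozen=True)
class AnnotationResult:
    """One candidate (ion, compound, adduct) match within tolerance."""

    sample_id: str
    consensus_mz: float
    compound_id: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


def _theoretical_index(
    library: Sequence[CompoundRecord], adducts: Sequence[AdductSpec]
) -> tuple[np.ndarray, List[tuple[str, str]]]:
    """Sorted theoretical m/z array over all (compound, adduct) pairs."""
    mzs: List[float] = []
    labels: List[tuple[str, str]] = []
    for rec in library:
        if rec.neutral_mass is None:
            continue
        for adduct in adducts:
            mzs.append(adduct_mz(rec.neutral_mass, adduct))
            labels.append((rec.compound_id, adduct.name))
    order = np.argsort(mzs, kind="stable")
    return np.asarray(mzs)[order], [labels[i] for i in order]


def annotate_ions(
    ions: ConsensusIonTable,
    library: Sequence[CompoundRecord],
    adducts: Optional[Sequence[AdductSpec]] = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> List[AnnotationResult]:
    """Annotate every consensus ion against the compound library.

    For each ion, all (compound, adduct) pairs whose theoretical m/z lies
    within ``tol_ppm`` are emitted, sorted per ion by \\|ppm error\\|
    ascending. Ions matching nothing are silently left unannotated. The
    candidate search is an interval query over the precomputed, sorted
    theoretical m/z index — equivalent to an exhaustive all-pairs scan.
    """
    if not library:
        raise ValueError("compound library is empty")
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be > 0, got {tol_ppm}")
    if adducts is None:
        adducts = list(BUILTIN_ADDUCTS.values())
    theo_mz, labels = _theoretical_index(library, adducts)
    results: List[AnnotationResult] = []
    for observed in ions.consensus_mz:
        lo = int(np.searchsorted(theo_mz, observed / (1 + tol_ppm * 1e-6), "left"))
        hi = int(np.searchsorted(theo_mz, observed / (1 - tol_ppm * 1e-6), "right"))
        candidates = []
        for k in range(lo, hi):
            err = ppm_error(float(observed), float(theo_mz[k]))
            if abs(err) <= tol_ppm:
                compound_id, adduct_name = labels[k]
                candidates.append(
                    AnnotationResult(
                        sample_id=ions.sample_id,
                        consensus_mz=float(observed),
                        compound_id=compound_id,
                        adduct=adduct_name,
                        theoretical_mz=float(theo_mz[k]),
                        ppm_error=err,
                    )
                )
        candidates.sort(key=lambda r: (abs(r.ppm_error), r.compound_id, r.adduct))
        results.extend(candidates)
    return results


def annotate_cohort(
    tables: Iterable[ConsensusIonTable],
    library: Sequence[CompoundRecord],
    adducts: Optional[Sequence[AdductSpec]] = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> List[AnnotationResult]:
    """Annotate consensus tables for every sample of a cohort."""
    out: List[AnnotationResult] = []
    for table in tables:
        out.extend(annotate_ions(table, library, adducts, tol_ppm))
    return out


def build_detection_matrix(
    annotations: Sequence[AnnotationResult], manifest: CohortManifest
) -> pd.DataFrame:
    """Compound x sample boolean detection matrix.

    A cell is True iff at least one annotation links that compound to that
    sample; samples with no annotations still appear as all-False columns.
    """
    sample_ids = list(manifest.samples)
    unknown = {a.sample_id for a in annotations} - set(sample_ids)
    if unknown:
        raise ValueError(f"annotations reference samples not in manifest: {sorted(unknown)}")
    compound_ids = sorted({a.compound_id for a in annotations})
    matrix = pd.DataFrame(False, index=compound_ids, columns=sample_ids, dtype=bool)
    for ann in annotations:
        matrix.at[ann.compound_id, ann.sample_id] = True
    matrix.index.name = "compound_id"
    matrix.columns.name = "sample_id"
    return matrix
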