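"""Per-group detection frequencies and presence/absence marker selection.

The headline computation: for each putatively identified metabolite, the
fraction of each group's samples in which it was detected, and the selection
of metabolites rare-or-absent in control groups but frequent in case groups.
An exact test (Fisher, two-sided) on the 2x2 detection table is available as
an optional filter; no multiple-testing correction is applied by default,
with Benjamini-Hochberg available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationResult
from .spectra_io import CohortManifest

__all__ = [
    "MarkerSelectionRule",
    "group_frequency",
    "select_markers",
    "frequency_difference_test",
    "replicate_level_frequency",
]

FREQUENCY_COLUMNS = ["compound_id", "group", "detected_count", "group_size", "frequency"]


@dataclass(frozen=True)
class MarkerSelectionRule:
    """Thresholded presence/absence rule.

    A compound is selected iff its frequency is <= ``max_control_frequency``
    in every control group and >= ``min_case_frequency`` in every case group.
    The strict literal rule "absent from controls, present in cases" is
    ``max_control_frequency=0`` with any positive ``min_case_frequency``.
    ``alpha`` additionally requires a two-sided Fisher exact p-value (pooled
    controls vs pooled cases) <= alpha; ``correct_fdr`` applies
    Benjamini-Hochberg across the tested compounds first.
    """

    control_groups: Tuple[str, ...]
    case_groups: Tuple[str, ...]
    max_control_frequency: float = 0.0
    min_case_frequency: float = 0.5
    alpha: Optional[float] = None
    correct_fdr: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_groups", tuple(self.control_groups))
        object.__setattr__(self, "case_groups", tuple(self.case_groups))
        if set(self.control_groups) & set(self.case_groups):
            raise ValueError("control and case group sets must be disjoint")
        for name in ("max_control_frequency", "min_case_frequency"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def group_frequency(matrix: pd.DataFrame, manifest: CohortManifest) -> pd.DataFrame:
    """Per-(compound, group) detection counts and frequencies.

    ``matrix`` is the boolean compound x sample detection matrix. Returns a
    long-form table with columns compound_id, group, detected_count,
    group_size, frequency (full precision; any 2-dp rounding is left to the
    report writer).
    """
    unknown = set(matrix.columns) - set(manifest.samples)
    if unknown:
        raise ValueError(f"detection matrix has samples not in manifest: {sorted(unknown)}")
    rows: List[Dict[str, object]] = []
    for group in manifest.groups:
        members = manifest.samples_in_group(group)
        if not members:
            raise ValueError(f"group {group!r} has no samples")
        present = [s for s in members if s in matrix.columns]
        for compound_id in matrix.index:
            count = int(matrix.loc[compound_id, present].sum()) if present else 0
            rows.append(
                {
                    "compound_id": compound_id,
                    "group": group,
                    "detected_count": count,
                    "group_size": len(members),
                    "frequency": count / len(members),
                }
            )
    return pd.DataFrame(rows, columns=FREQUENCY_COLUMNS)


def _pivot(freqs: pd.DataFrame, column: str) -> pd.DataFrame:
    return freqs.pivot(index="compound_id", columns="group", values=column)


def select_markers(freqs: pd.DataFrame, rule: MarkerSelectionRule) -> pd.DataFrame:
    """Apply a :class:`MarkerSelectionRule` to a frequency table.

    Returns the marker panel: one row per selected compound with its
    per-group frequencies (columns ``frequency_<group>``) and, when the rule
    carries an ``alpha``, the exact-test p-value (``p_value``; BH-adjusted in
    ``p_adjusted`` if requested). Deterministic and order-independent:
    output is sorted by compound_id.
    """
    freq_wide = _pivot(freqs, "frequency")
    missing = (set(rule.control_groups) | set(rule.case_groups)) - set(freq_wide.columns)
    if missing:
        raise ValueError(f"rule references groups absent from table: {sorted(missing)}")

    ctrl_ok = (freq_wide[list(rule.control_groups)] <= rule.max_control_frequency).all(axis=1)
    case_ok = (freq_wide[list(rule.case_groups)] >= rule.min_case_frequency).all(axis=1)
    selected = ctrl_ok & case_ok

    panel = freq_wide.copy()
    panel.columns = [f"frequency_{g}" for g in panel.columns]

    if rule.alpha is not None:
        counts = _pivot(freqs, "detected_count")
        sizes = _pivot(freqs, "group_size")
        pvals = {}
        for compound_id in freq_wide.index:
            pvals[compound_id] = frequency_difference_test(
                int(counts.loc[compound_id, list(rule.control_groups)].sum()),
                int(sizes.loc[compound_id, list(rule.control_groups)].sum()),
                int(counts.loc[compound_id, list(rule.case_groups)].sum()),
                int(sizes.loc[compound_id, list(rule.case_groups)].sum()),
            )
        panel["p_value"] = pd.Series(pvals)
        if rule.correct_fdr:
            from statsmodels.stats.multitest import multipletests

            _, adjusted, _, _ = multipletests(panel["p_value"].to_numpy(), method="fdr_bh")
            panel["p_adjusted"] = adjusted
            selected &= panel["p_adjusted"] <= rule.alpha
        else:
            selected &= panel["p_value"] <= rule.alpha

    out = panel[selected].sort_index()
    out.index.name = "compound_id"
    return out.reset_index()


def frequency_difference_test(
    count_a: int, n_a: int, count_b: int, n_b: int
) -> float:
    """Two-sided Fisher exact p-value for a 2x2 detection table.

    Rows are the two groups; columns detected / not detected. Computed by
    exact hypergeometric enumeration over all tables with the observed
    margins, in integer arithmetic: the p-value is the total conditional
    probability of tables no more probable than the observed one.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValueError("counts must lie within group sizes")
    s = count_a + count_b  # detected-column margin
    k_lo, k_hi = max(0, s - n_b), min(n_a, s)
    weights = [comb(n_a, k) * comb(n_b, s - k) for k in range(k_lo, k_hi + 1)]
    observed = weights[count_a - k_lo]
    return float(sum(w for w in weights if w <= observed) / comb(n_a + n_b, s))


def replicate_level_frequency(
    annotations: Sequence[AnnotationResult],
    manifest: CohortManifest,
    replicates_per_sample: int = 2,
) -> pd.DataFrame:
    """Detection frequencies with technical replicates as independent units.

    Annotations must carry replicate-level sample ids of the form
    ``"<sample_id>::<replicate_id>"`` (produced by annotating each replicate
    peak list separately, bypassing the consensus stage). The denominator is
    group_size x replicates_per_sample; with zero replicate dropout this
    equals the sample-level frequency.
    """
    units: Dict[str, set] = {}
    for ann in annotations:
        sample_id, _, replicate_id = ann.sample_id.partition("::")
        if not replicate_id:
            raise ValueError(
                f"annotation sample id {ann.sample_id!r} lacks a '::replicate' suffix"
            )
        if sample_id not in manifest.samples:
            raise ValueError(f"annotation references unknown sample {sample_id!r}")
        units.setdefault(ann.compound_id, set()).add((sample_id, replicate_id))

    rows: List[Dict[str, object]] = []
    for group in manifest.groups:
        members = set(manifest.samples_in_group(group))
        denominator = len(members) * replicates_per_sample
        for compound_id in sorted(units):
            count = sum(1 for s, _ in units[compound_id] if s in members)
            rows.append(
                {
                    "compound_id": compound_id,
                    "group": group,
                    "detected_count": count,
                    "group_size": denominator,
                    "frequency": count / denominator,
                }
            )
    return pd.DataFrame(rows, columns=FREQUENCY_COLUMNS)
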