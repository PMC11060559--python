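"""VTU detection-validation cascade.

Four stages, applied in a fixed order, turn a raw VTU x library count
matrix into a validated one:

1. per-library detection floor — cells with fewer than 10 reads are set to
   zero (the VTU counts as undetected in that library);
2. dataset-total floor — VTUs with fewer than 100 reads summed over all
   libraries (after stage 1) are dropped;
3. cross-contamination guard — for abundant VTUs (row total strictly above
   the third quartile of row totals) any cell strictly below 5% of that
   VTU's largest per-library count is zeroed, on the logic that reads from
   a very abundant taxon can bleed into other libraries at low level;
4. host filter — VTUs whose best hit comes from a non-arthropod host are
   removed, since they are unlikely to be genuine mosquito viruses.

Thresholds are strict exactly as stated: a 10-read cell survives stage 1,
a 100-read row survives stage 2, a cell exactly at the 5% threshold
survives stage 3, and a row exactly at the third quartile is not subject
to stage 3 at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, HostGroup
from .vtu import VTU

logger = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "StageReport",
    "FilterReport",
    "min_reads_per_library",
    "min_total_reads",
    "cross_contamination_filter",
    "host_taxon_filter",
    "run_cascade",
]


@dataclass(frozen=True)
class FilterParams:
    """All numeric thresholds of the cascade (defaults as used in the study)."""

    min_reads_per_library: int = 10
    min_total_reads: int = 100
    abundance_quantile: float = 0.75
    contamination_fraction: float = 0.05
    required_host_group: HostGroup = HostGroup.ARTHROPODA
    strict_host: bool = False  # drop Unknown hosts too
    quantile_method: str = "linear"  # numpy quantile estimator

    def __post_init__(self) -> None:
        if self.min_reads_per_library < 1 or self.min_total_reads < 1:
            raise ValueError("read thresholds must be positive")
        if not 0 < self.abundance_quantile < 1:
            raise ValueError("abundance_quantile must be in (0, 1)")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")


@dataclass
class StageReport:
    stage: str
    vtus_in: int
    vtus_out: int
    cells_zeroed: int
    reads_removed: int

    @property
    def vtus_dropped(self) -> int:
        return self.vtus_in - self.vtus_out


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    @property
    def reads_removed(self) -> int:
        return sum(s.reads_removed for s in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "stage": s.stage, "vtus_in": s.vtus_in, "vtus_out": s.vtus_out,
            "vtus_dropped": s.vtus_dropped, "cells_zeroed": s.cells_zeroed,
            "reads_removed": s.reads_removed,
        } for s in self.stages])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def min_reads_per_library(counts: CountMatrix, t: int = 10) -> CountMatrix:
    """Zero every cell with fewer than ``t`` reads; cells >= t unchanged."""
    if t < 1:
        raise ValueError("t must be >= 1")
    arr = counts.counts.copy()
    arr[arr < t] = 0
    return CountMatrix(pd.DataFrame(arr, index=counts.taxa, columns=counts.libraries))


def min_total_reads(counts: CountMatrix, t: int = 100) -> CountMatrix:
    """Drop VTU rows whose total over all libraries is below ``t``."""
    if t < 1:
        raise ValueError("t must be >= 1")
    totals = counts.data.sum(axis=1)
    return CountMatrix(counts.data.loc[totals >= t])


def cross_contamination_filter(
    counts: CountMatrix,
    q: float = 0.75,
    f: float = 0.05,
    quantile_method: str = "linear",
) -> CountMatrix:
    """Zero sub-threshold cells of abundant VTUs.

    For each VTU whose row total is strictly greater than the ``q``-quantile
    of all row totals, the detection threshold is ``f`` times that VTU's
    maximum per-library count; cells strictly below it are zeroed.  Rows at
    or below the quantile are untouched, and no rows are removed.
    """
    if counts.data.empty:
        return counts.copy()
    totals = counts.data.sum(axis=1).to_numpy()
    if len(totals) < 4:
        logger.warning(
            "cross-contamination filter: only %d VTUs; quantile estimate is crude",
            len(totals))
    q3 = float(np.quantile(totals, q, method=quantile_method))
    arr = counts.counts.copy()
    for i in np.flatnonzero(totals > q3):
        tau = f * arr[i].max()
        row = arr[i]
        row[row < tau] = 0
    return CountMatrix(pd.DataFrame(arr, index=counts.taxa, columns=counts.libraries))


def host_taxon_filter(
    vtus: Sequence[VTU],
    counts: CountMatrix,
    required: HostGroup = HostGroup.ARTHROPODA,
    strict: bool = False,
) -> tuple[list[VTU], CountMatrix]:
    """Remove VTUs whose best hit belongs to a non-matching host taxon.

    VTUs with an unknown host are kept with a warning by default; with
    ``strict`` they are dropped along with the mismatches.
    """
    by_name = {v.vtu_name: v for v in vtus}
    kept_names = []
    unknown = []
    for name in counts.taxa:
        v = by_name.get(name)
        group = v.host_group if v else HostGroup.UNKNOWN
        if group == required:
            kept_names.append(name)
        elif group == HostGroup.UNKNOWN:
            unknown.append(name)
            if not strict:
                kept_names.append(name)
    if unknown:
        action = "dropped (strict mode)" if strict else "kept"
        logger.warning("%d VTUs with unknown host group %s: %s",
                       len(unknown), action, unknown[:5])
    kept_vtus = [by_name[n] for n in kept_names if n in by_name]
    return kept_vtus, CountMatrix(counts.data.loc[kept_names])


def run_cascade(
    vtus: Sequence[VTU],
    counts: CountMatrix,
    params: FilterParams = FilterParams(),
) -> tuple[list[VTU], CountMatrix, FilterReport]:
    """Apply the four validation stages once, in order, with accounting.

    The report records, per stage, the VTUs entering and leaving, cells
    zeroed, and reads removed; the stage removals sum to the overall
    read delta.
    """
    report = FilterReport()

    def _record(stage: str, before: CountMatrix, after: CountMatrix) -> None:
        zeroed = 0
        common = [t for t in after.taxa]
        if common:
            b = before.data.loc[common].to_numpy()
            a = after.data.to_numpy()
            zeroed = int(np.sum((b > 0) & (a == 0)))
        dropped_rows = len(before.taxa) - len(after.taxa)
        zeroed += int(before.data.drop(index=common, errors="ignore").to_numpy().astype(bool).sum()) if dropped_rows else 0
        report.stages.append(StageReport(
            stage=stage, vtus_in=len(before.taxa), vtus_out=len(after.taxa),
            cells_zeroed=zeroed, reads_removed=before.total() - after.total(),
        ))

    current = counts
    step = min_reads_per_library(current, params.min_reads_per_library)
    _record("min_reads_per_library", current, step)
    current = step

    step = min_total_reads(current, params.min_total_reads)
    _record("min_total_reads", current, step)
    current = step

    step = cross_contamination_filter(
        current, params.abundance_quantile, params.contamination_fraction,
        params.quantile_method)
    _record("cross_contamination", current, step)
    current = step

    kept_vtus, step = host_taxon_filter(
        vtus, current, params.required_host_group, params.strict_host)
    _record("host_taxon", current, step)
    current = step

    return kept_vtus, current, report
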