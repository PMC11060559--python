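"""Contig-to-taxon clustering: EVE screening, VTU assignment, family-like
clusters, and collapsing contig counts to taxon counts.

A viral taxonomic unit (VTU) is a species-like taxon grouping every contig
whose lowest-e-value protein hit is the same known virus species.  Its name
appends the alignment-length-weighted mean amino-acid identity after a
double underscore, e.g. ``Alphamesonivirus 1__96.5``, so the name itself
signals whether the VTU likely contains a new virus species: identities at
or below 90% (the usual species-demarcation cutoff) flag a novel taxon.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ContigRecord, CountMatrix, HostGroup, TaxonomyMap, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "VTU",
    "UNASSIGNED_CLUSTER",
    "NOVELTY_PID_CUTOFF",
    "EVE_COVERAGE_CUTOFF",
    "screen_eves",
    "assign_vtus",
    "assign_clusters",
    "collapse_counts",
    "parse_vtu_name",
    "write_vtu_table",
]

UNASSIGNED_CLUSTER = "Unassigned"
#: contigs are "known" virus species only above this amino-acid identity
NOVELTY_PID_CUTOFF = 90.0
#: contigs whose best non-viral nucleotide hit covers more than this are
#: treated as potential endogenous viral elements and removed
EVE_COVERAGE_CUTOFF = 25.0

_NAME_RE = re.compile(r"^(?P<species>.*)__(?P<pid>\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class VTU:
    vtu_name: str
    best_hit_species: str
    member_contig_ids: frozenset[str]
    weighted_mean_pid_aa: float
    mean_pid_aa: float
    is_novel: bool
    cluster: str = UNASSIGNED_CLUSTER
    order: str = ""
    phylum: str = ""
    host_group: HostGroup = HostGroup.UNKNOWN
    n_contigs: int = 0
    sum_reads: int = 0
    mean_contig_length: float = 0.0

    def __post_init__(self) -> None:
        if not self.member_contig_ids:
            raise ValidationError(f"VTU {self.vtu_name}: empty member set")


def parse_vtu_name(name: str) -> tuple[str, float]:
    """Invert the naming scheme: ``species__96.5`` -> (``species``, 96.5)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a VTU name: {name!r}")
    return m.group("species"), float(m.group("pid"))


def screen_eves(
    contigs: Sequence[ContigRecord],
    coverage_cutoff: float = EVE_COVERAGE_CUTOFF,
) -> tuple[list[ContigRecord], list[ContigRecord]]:
    """Split contigs into (kept, removed-as-potential-EVE).

    A contig is a potential endogenous viral element when its best
    non-viral nucleotide hit covers strictly more than ``coverage_cutoff``
    percent of it.  Contigs with no non-viral hit are kept.  Input order is
    preserved in both outputs.
    """
    if not 0 < coverage_cutoff < 100:
        raise ValueError("coverage_cutoff must be in (0, 100)")
    kept, removed = [], []
    for c in contigs:
        if c.nonviral_cov_pct is not None and c.nonviral_cov_pct > coverage_cutoff:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def _majority_host(members: Sequence[ContigRecord]) -> HostGroup:
    counts = Counter(c.host_group for c in members)
    best = counts.most_common()
    if len(best) > 1 and best[0][1] == best[1][1]:
        return HostGroup.UNKNOWN
    return best[0][0]


def assign_vtus(contigs: Sequence[ContigRecord]) -> list[VTU]:
    """Group contigs by best-hit species into VTUs.

    The VTU's headline identity is the mean amino-acid identity of its
    members weighted by alignment length; the unweighted mean is kept as
    well.  The name formats the weighted value to one decimal place, while
    novelty (<= 90%) is decided on the unrounded value.  Output is sorted
    by species name so the result is independent of input order.
    """
    groups: dict[str, list[ContigRecord]] = {}
    for c in contigs:
        groups.setdefault(c.best_hit_species.strip(), []).append(c)
    vtus = []
    for species in sorted(groups):
        # fixed member order so float sums are permutation-invariant
        members = sorted(groups[species], key=lambda c: c.contig_id)
        lens = np.array([c.aln_len_aa for c in members], dtype=float)
        pids = np.array([c.pid_aa for c in members], dtype=float)
        weighted = float(np.sum(pids * lens) / np.sum(lens))
        plain = float(np.mean(pids))
        vtus.append(VTU(
            vtu_name=f"{species}__{weighted:.1f}",
            best_hit_species=species,
            member_contig_ids=frozenset(c.contig_id for c in members),
            weighted_mean_pid_aa=weighted,
            mean_pid_aa=plain,
            is_novel=weighted <= NOVELTY_PID_CUTOFF,
            host_group=_majority_host(members),
            n_contigs=len(members),
            mean_contig_length=float(np.mean([c.contig_len_nt for c in members])),
        ))
    return vtus


def assign_clusters(vtus: Sequence[VTU], taxonomy: TaxonomyMap) -> list[VTU]:
    """Attach the family-like cluster (and order/phylum when mapped)."""
    out = []
    unmapped = []
    for v in vtus:
        lineage = taxonomy.lineage_of(v.best_hit_species)
        if lineage is None:
            unmapped.append(v.best_hit_species)
            out.append(replace(v, cluster=UNASSIGNED_CLUSTER, order="", phylum=""))
        else:
            cluster, order, phylum = lineage
            out.append(replace(v, cluster=cluster, order=str(order), phylum=str(phylum)))
    if unmapped:
        logger.warning(
            "%d best-hit species not in taxonomy map (cluster=%s): %s",
            len(unmapped), UNASSIGNED_CLUSTER, ", ".join(sorted(set(unmapped))[:5]),
        )
    return out


def collapse_counts(contig_counts: CountMatrix, vtus: Sequence[VTU]) -> tuple[CountMatrix, list[VTU]]:
    """Sum member-contig counts into VTU rows.

    Returns the VTU x library matrix and the VTUs updated with their
    ``sum_reads``.  The grand total over the output equals the total over
    all contigs assigned to some VTU (conservation).
    """
    available = set(contig_counts.taxa)
    rows = {}
    updated = []
    for v in vtus:
        missing = sorted(set(v.member_contig_ids) - available)
        if missing:
            raise ValidationError(
                f"VTU {v.vtu_name}: member contig(s) missing from count matrix: {missing}"
            )
        block = contig_counts.data.loc[sorted(v.member_contig_ids)]
        row = block.sum(axis=0)
        rows[v.vtu_name] = row
        updated.append(replace(v, sum_reads=int(row.sum())))
    if rows:
        df = pd.DataFrame(rows).T[contig_counts.libraries]
    else:
        df = pd.DataFrame(columns=contig_counts.libraries, dtype=np.int64)
    return CountMatrix(df.astype(np.int64)), updated


def collapse_to_clusters(vtu_counts: CountMatrix, vtus: Sequence[VTU]) -> CountMatrix:
    """Aggregate VTU counts to the family-like cluster level."""
    cluster_of = {v.vtu_name: v.cluster for v in vtus}
    missing = [t for t in vtu_counts.taxa if t not in cluster_of]
    if missing:
        raise ValidationError(f"VTUs without cluster assignment in matrix: {missing[:5]}")
    grouped = vtu_counts.data.groupby(
        [cluster_of[t] for t in vtu_counts.taxa]).sum()
    grouped.index.name = None
    return CountMatrix(grouped.sort_index())


def write_vtu_table(vtus: Iterable[VTU], path: str | Path) -> None:
    """Emit the per-VTU summary table."""
    rows = [{
        "VTU": v.vtu_name,
        "cluster": v.cluster,
        "order": v.order,
        "phylum": v.phylum,
        "host_group": v.host_group.value,
        "sum_reads": v.sum_reads,
        "n_Contigs": v.n_contigs,
        "Avg_contigs_length": f"{v.mean_contig_length:.1f}",
        "avg_contigs_p_id": f"{v.mean_pid_aa:.3f}",
        "weighted_avg_p_id": f"{v.weighted_mean_pid_aa:.3f}",
        "is_novel": v.is_novel,
    } for v in vtus]
    pd.DataFrame(rows, columns=[
        "VTU", "cluster", "order", "phylum", "host_group", "sum_reads",
        "n_Contigs", "Avg_contigs_length", "avg_contigs_p_id",
        "weighted_avg_p_id", "is_novel",
    ]).to_csv(path, sep="\t", index=False)
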