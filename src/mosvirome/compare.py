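"""Cross-species VTU matching, known-virus flagging, diversity partition,
dissimilarity-regime classification and host/geographic-range summaries.

Because contigs are assembled per mosquito genus, the "same" virus detected
in two host species appears as two same-named VTUs.  They are merged into
one cross-host taxon only when there is direct nucleotide evidence: some
contig pair across the two hosts aligns at more than 80% identity.  A VTU
is flagged as a previously known virus when a contig matches its best-hit
species at >80% nucleotide identity over at least 90% alignment coverage.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError
from .vtu import VTU

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseIdentity",
    "MatchParams",
    "Regime",
    "cross_species_match",
    "known_virus_flag",
    "partition_presence",
    "dissimilarity_regime",
    "host_range_summary",
]


@dataclass(frozen=True)
class PairwiseIdentity:
    """A nucleotide alignment between two contigs (order-insensitive)."""

    contig_a: str
    contig_b: str
    percent_identity_nt: float
    alignment_coverage_pct: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity_nt <= 100:
            raise ValidationError(
                f"pair ({self.contig_a}, {self.contig_b}): identity outside [0, 100]")
        if not 0 <= self.alignment_coverage_pct <= 100:
            raise ValidationError(
                f"pair ({self.contig_a}, {self.contig_b}): coverage outside [0, 100]")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.contig_a, self.contig_b))


@dataclass(frozen=True)
class MatchParams:
    cross_species_min_pid_nt: float = 80.0
    known_virus_min_pid_nt: float = 80.0
    known_virus_min_coverage: float = 90.0

    def __post_init__(self) -> None:
        for v in (self.cross_species_min_pid_nt, self.known_virus_min_pid_nt,
                  self.known_virus_min_coverage):
            if not 0 < v <= 100:
                raise ValueError("match thresholds must be in (0, 100]")


class Regime(str, enum.Enum):
    """Which component dominates between-group virome differences."""

    ABUNDANCE_DOMINATED = "abundance_dominated"
    DIVERSITY_DOMINATED = "diversity_dominated"
    MIXED = "mixed"


def _best_pair_identity(
    contigs_a: Iterable[str],
    contigs_b: Iterable[str],
    by_pair: Mapping[frozenset[str], float],
) -> float:
    best = -1.0
    for ca in contigs_a:
        for cb in contigs_b:
            pid = by_pair.get(frozenset((ca, cb)), -1.0)
            if pid > best:
                best = pid
    return best


def cross_species_match(
    vtus_by_host: Mapping[str, Sequence[VTU]],
    identities: Sequence[PairwiseIdentity],
    params: MatchParams = MatchParams(),
) -> pd.DataFrame:
    """Merge same-named VTUs across host species on nucleotide evidence.

    Returns a presence table (rows: merged taxa, columns: host species,
    values 0/1) plus a ``merged`` column.  Two same-named VTUs from
    different hosts count as one taxon iff ANY cross-host contig pair has
    identity strictly above the 80% cutoff; an absent pair is absence of
    evidence and blocks the merge.  Unmerged same-named VTUs are kept
    distinct (suffixed with the host name) and flagged.
    """
    by_pair: dict[frozenset[str], float] = {}
    for rec in identities:
        k = rec.key
        if by_pair.get(k, -1.0) < rec.percent_identity_nt:
            by_pair[k] = rec.percent_identity_nt

    hosts = sorted(vtus_by_host)
    by_name_host: dict[str, dict[str, VTU]] = {}
    for host in hosts:
        for v in vtus_by_host[host]:
            by_name_host.setdefault(v.vtu_name, {})[host] = v

    rows = []
    for name in sorted(by_name_host):
        present_in = by_name_host[name]
        if len(present_in) == 1:
            host = next(iter(present_in))
            rows.append({"taxon": name, "merged": False,
                         **{h: int(h == host) for h in hosts}})
            continue
        # union-find over the hosts carrying this name, linked by >80% pairs
        hs = sorted(present_in)
        parent = {h: h for h in hs}

        def find(h: str) -> str:
            while parent[h] != h:
                parent[h] = parent[parent[h]]
                h = parent[h]
            return h

        for i, ha in enumerate(hs):
            for hb in hs[i + 1:]:
                best = _best_pair_identity(
                    present_in[ha].member_contig_ids,
                    present_in[hb].member_contig_ids, by_pair)
                if best > params.cross_species_min_pid_nt:
                    parent[find(ha)] = find(hb)
        components: dict[str, list[str]] = {}
        for h in hs:
            components.setdefault(find(h), []).append(h)
        merged_any = any(len(c) > 1 for c in components.values())
        if len(components) > 1:
            logger.info("VTU name %s: %d unmergeable same-named groups kept distinct",
                        name, len(components))
        for members in components.values():
            label = name if len(components) == 1 else f"{name}|{'+'.join(sorted(members))}"
            rows.append({"taxon": label, "merged": len(members) > 1,
                         **{h: int(h in members) for h in hosts}})
    return pd.DataFrame(rows, columns=["taxon", "merged", *hosts]).set_index("taxon")


def known_virus_flag(
    vtu: VTU,
    reference_identities: Sequence[PairwiseIdentity],
    params: MatchParams = MatchParams(),
) -> bool:
    """True iff some contig matches the best-hit species' sequences at
    >80% nucleotide identity with >=90% alignment coverage."""
    members = vtu.member_contig_ids
    for rec in reference_identities:
        if rec.contig_a in members or rec.contig_b in members:
            if (rec.percent_identity_nt > params.known_virus_min_pid_nt
                    and rec.alignment_coverage_pct >= params.known_virus_min_coverage):
                return True
    return False


def partition_presence(presence: pd.DataFrame) -> pd.DataFrame:
    """Count taxa in each nonempty membership region of a 2-3 level factor.

    ``presence`` has taxa as rows and factor levels (e.g. host species) as
    0/1 columns.  Returns one row per region (e.g. ``A``, ``A&B``...),
    with counts and percentages of the taxa present in at least one level.
    """
    levels = list(presence.columns)
    if not 2 <= len(levels) <= 3:
        raise ValueError("partition requires 2 or 3 factor levels")
    pres = presence.astype(bool)
    in_any = pres.any(axis=1)
    total = int(in_any.sum())
    rows = []
    for mask in range(1, 2 ** len(levels)):
        members = [levels[i] for i in range(len(levels)) if mask >> i & 1]
        sel = np.ones(len(pres), dtype=bool)
        for i, lv in enumerate(levels):
            want = bool(mask >> i & 1)
            sel &= pres[lv].to_numpy() == want
        count = int(sel.sum())
        rows.append({
            "region": "&".join(members),
            "n_levels": len(members),
            "count": count,
            "pct_of_total": 100.0 * count / total if total else 0.0,
        })
    out = pd.DataFrame(rows)
    assert out["count"].sum() == total, "Venn regions must partition the taxa"
    return out


def dissimilarity_regime(
    mean_sorensen: float,
    mean_bray_curtis: float,
    threshold: float = 0.5,
) -> Regime:
    """Classify between-group virome differences.

    Low presence/absence turnover (Sorensen below threshold) with high
    abundance dissimilarity (Bray-Curtis at or above it) means the groups
    share taxa but at shifted relative abundances: abundance-dominated.
    High Sorensen means taxon turnover itself dominates.  Both low means
    neither component stands out.
    """
    for v in (mean_sorensen, mean_bray_curtis):
        if not 0 <= v <= 1:
            raise ValueError("mean dissimilarities must be in [0, 1]")
    if mean_sorensen >= threshold:
        return Regime.DIVERSITY_DOMINATED
    if mean_bray_curtis >= threshold:
        return Regime.ABUNDANCE_DOMINATED
    return Regime.MIXED


def host_range_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Distinct host/geography counts per virus, plus cross-virus medians.

    ``records`` has columns virus, mosquito_species, mosquito_genus,
    country, continent; one row per detection record.  Medians use the
    midpoint convention for an even number of viruses.
    """
    required = ["virus", "mosquito_species", "mosquito_genus", "country", "continent"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"virus record table missing columns: {missing}")
    if records.empty:
        raise ValueError("virus record table is empty")
    dedup = records[required].drop_duplicates()
    per_virus = dedup.groupby("virus").agg(
        n_species=("mosquito_species", "nunique"),
        n_genera=("mosquito_genus", "nunique"),
        n_countries=("country", "nunique"),
        n_continents=("continent", "nunique"),
    ).sort_values("n_species", ascending=False)
    medians = per_virus.median()
    medians.index = [f"median_{c}" for c in per_virus.columns]
    return per_virus, medians
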