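"""Shared data types and tab-separated readers/writers.

Every table the pipeline consumes or emits is UTF-8, tab-separated, with a
header row.  Counts are kept as exact integers end to end: fractional input
is rejected rather than rounded, so ambiguity surfaces as an error instead
of a silent guess.  Numeric parsing always uses the decimal point,
independent of locale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HostGroup",
    "ContigRecord",
    "LibraryMeta",
    "CountMatrix",
    "TaxonomyMap",
    "FormatError",
    "ValidationError",
    "read_contig_table",
    "write_contig_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_library_metadata",
    "write_library_metadata",
    "read_taxonomy_map",
    "write_taxonomy_map",
]


class FormatError(ValueError):
    """A table is structurally malformed (missing column, duplicate id...)."""


class ValidationError(ValueError):
    """A table parsed but a value violates a domain invariant."""


class HostGroup(str, enum.Enum):
    """Host taxon of a contig's best homology hit, collapsed to three bins.

    Anything recognisably arthropod keeps its label; any other non-empty
    host string maps to ``OTHER``; empty/missing maps to ``UNKNOWN``.
    """

    ARTHROPODA = "Arthropoda"
    OTHER = "Other"
    UNKNOWN = "Unknown"

    @classmethod
    def parse(cls, raw: object) -> "HostGroup":
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return cls.UNKNOWN
        text = str(raw).strip()
        if not text or text.lower() in ("unknown", "na", "nan"):
            return cls.UNKNOWN
        if text.lower() == "arthropoda":
            return cls.ARTHROPODA
        if text.lower() == "other":
            return cls.OTHER
        return cls.OTHER


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig whose best homology hit is a virus.

    Fields mirror the tabular output of a protein-level homology search
    (best hit, amino-acid percent identity, alignment length) plus the
    nucleotide-level screen used to flag endogenous viral elements:
    ``nonviral_cov_pct`` is the query coverage of the best *non-viral*
    nucleotide hit, or ``None`` when no such hit exists.
    """

    contig_id: str
    best_hit_species: str
    best_hit_accession: str
    pid_aa: float
    aln_len_aa: int
    evalue: float
    contig_len_nt: int
    host_group: HostGroup = HostGroup.UNKNOWN
    nonviral_cov_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValidationError("contig_id must be non-empty")
        if not 0.0 <= self.pid_aa <= 100.0:
            raise ValidationError(
                f"contig {self.contig_id}: pid_aa {self.pid_aa} outside [0, 100]"
            )
        if self.aln_len_aa < 1:
            raise ValidationError(
                f"contig {self.contig_id}: aln_len_aa must be >= 1"
            )
        if self.contig_len_nt < 1:
            raise ValidationError(
                f"contig {self.contig_id}: contig_len_nt must be >= 1"
            )
        if self.evalue < 0:
            raise ValidationError(f"contig {self.contig_id}: negative e-value")
        if self.nonviral_cov_pct is not None and not 0.0 <= self.nonviral_cov_pct <= 100.0:
            raise ValidationError(
                f"contig {self.contig_id}: nonviral_cov_pct outside [0, 100]"
            )


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for one sequencing library (a pool of mosquitoes)."""

    library_id: str
    species: str
    site: str
    habitat: str
    year: int
    mosquito_count: int

    def __post_init__(self) -> None:
        if not self.library_id:
            raise ValidationError("library_id must be non-empty")
        if self.mosquito_count < 1:
            raise ValidationError(
                f"library {self.library_id}: mosquito_count must be >= 1"
            )


class CountMatrix:
    """Non-negative integer read counts, taxa (rows) by libraries (columns).

    Thin wrapper over a ``pandas.DataFrame`` that enforces the container
    invariants once at construction: integer dtype, no negative entries,
    duplicate-free taxon and library ids.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate library ids: {dups}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            as_float = arr.astype(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
                raise ValidationError("counts must be integers (no NaN/fractional values)")
            data = data.astype(np.int64)
        else:
            data = data.astype(np.int64) if arr.size else data.astype(np.int64, errors="ignore")
        if data.size and (data.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.data = data

    # -- accessors -------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def total(self) -> int:
        return int(self.data.to_numpy().sum()) if self.data.size else 0

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.data.copy())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CountMatrix({len(self.taxa)} taxa x {len(self.libraries)} libraries)"


@dataclass
class TaxonomyMap:
    """Best-hit species -> family-like cluster (plus optional order/phylum).

    The "cluster" is a family-like rank assigned even when the best-hit
    species lacks a formal family in the reference taxonomy.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["best_hit_species", "cluster", "order", "phylum"]))

    def __post_init__(self) -> None:
        required = {"best_hit_species", "cluster"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"taxonomy map missing columns: {sorted(missing)}")
        for col in ("order", "phylum"):
            if col not in self.table.columns:
                self.table[col] = ""
        # conflicting duplicates are an error; exact duplicates collapse
        dedup = self.table.drop_duplicates()
        counts = dedup["best_hit_species"].value_counts()
        conflicts = counts[counts > 1].index.tolist()
        if conflicts:
            raise FormatError(
                f"conflicting taxonomy rows for species: {conflicts}"
            )
        if (dedup["cluster"].astype(str).str.strip() == "").any():
            raise ValidationError("taxonomy map contains empty cluster labels")
        self.table = dedup.reset_index(drop=True)
        self._lookup = {
            row.best_hit_species: (row.cluster, row.order, row.phylum)
            for row in self.table.itertuples()
        }

    def cluster_of(self, species: str) -> str | None:
        hit = self._lookup.get(species)
        return hit[0] if hit else None

    def lineage_of(self, species: str) -> tuple[str, str, str] | None:
        return self._lookup.get(species)

    def __contains__(self, species: str) -> bool:
        return species in self._lookup


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

CONTIG_COLUMNS = [
    "contig_id", "best_hit_species", "best_hit_accession", "pid_aa",
    "aln_len_aa", "evalue", "contig_len_nt", "host_group",
]
META_COLUMNS = ["library_id", "species", "site", "habitat", "year", "mosquito_count"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing mandatory column(s) {missing}")


def _parse_float(value: str, what: str, row: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"{what}: row {row}: not a number: {value!r}") from exc


def _parse_int(value: str, what: str, row: int) -> int:
    try:
        return int(value)
    except ValueError:
        # reject fractional rather than round
        raise ValidationError(f"{what}: row {row}: not an integer: {value!r}") from None


def read_contig_table(path: str | Path) -> list[ContigRecord]:
    """Read a contig annotation table (one row per viral contig)."""
    df = _read_tsv(path)
    _require_columns(df, CONTIG_COLUMNS, "contig table")
    has_cov = "nonviral_cov_pct" in df.columns
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        cid = d["contig_id"]
        if cid in seen:
            raise FormatError(f"contig table: duplicate contig_id {cid!r} at row {i}")
        seen.add(cid)
        cov_raw = d.get("nonviral_cov_pct", "") if has_cov else ""
        cov = None if cov_raw in ("", "NA") else _parse_float(cov_raw, "contig table", i)
        try:
            records.append(ContigRecord(
                contig_id=cid,
                best_hit_species=d["best_hit_species"].strip(),
                best_hit_accession=d["best_hit_accession"],
                pid_aa=_parse_float(d["pid_aa"], "contig table", i),
                aln_len_aa=_parse_int(d["aln_len_aa"], "contig table", i),
                evalue=_parse_float(d["evalue"], "contig table", i),
                contig_len_nt=_parse_int(d["contig_len_nt"], "contig table", i),
                host_group=HostGroup.parse(d["host_group"]),
                nonviral_cov_pct=cov,
            ))
        except ValidationError as exc:
            raise ValidationError(f"contig table: row {i}: {exc}") from None
    return records


def write_contig_table(records: Iterable[ContigRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "contig_id": r.contig_id,
            "best_hit_species": r.best_hit_species,
            "best_hit_accession": r.best_hit_accession,
            "pid_aa": repr(r.pid_aa),
            "aln_len_aa": r.aln_len_aa,
            "evalue": repr(r.evalue),
            "contig_len_nt": r.contig_len_nt,
            "host_group": r.host_group.value,
            "nonviral_cov_pct": "" if r.nonviral_cov_pct is None else repr(r.nonviral_cov_pct),
        })
    pd.DataFrame(rows, columns=CONTIG_COLUMNS + ["nonviral_cov_pct"]).to_csv(
        path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a taxon x library count matrix (first column ``taxon_id``)."""
    df = _read_tsv(path)
    if df.columns[0] != "taxon_id":
        raise FormatError("count matrix: first column must be 'taxon_id'")
    df = df.set_index("taxon_id")
    df.index.name = None
    for col in df.columns:
        for i, v in enumerate(df[col], start=1):
            if not v.lstrip("-").isdigit():
                raise ValidationError(
                    f"count matrix: row {i}, library {col}: non-integer count {v!r}")
    return CountMatrix(df.astype(np.int64))


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.insert(0, "taxon_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_library_metadata(path: str | Path) -> list[LibraryMeta]:
    df = _read_tsv(path)
    _require_columns(df, META_COLUMNS, "library metadata")
    seen: set[str] = set()
    metas: list[LibraryMeta] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        lid = d["library_id"]
        if lid in seen:
            raise FormatError(f"library metadata: duplicate library_id {lid!r} at row {i}")
        seen.add(lid)
        metas.append(LibraryMeta(
            library_id=lid,
            species=d["species"],
            site=d["site"],
            habitat=d["habitat"],
            year=_parse_int(d["year"], "library metadata", i),
            mosquito_count=_parse_int(d["mosquito_count"], "library metadata", i),
        ))
    return metas


def write_library_metadata(metas: Iterable[LibraryMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{
            "library_id": m.library_id, "species": m.species, "site": m.site,
            "habitat": m.habitat, "year": m.year, "mosquito_count": m.mosquito_count,
        } for m in metas],
        columns=META_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy_map(path: str | Path) -> TaxonomyMap:
    df = _read_tsv(path)
    _require_columns(df, ["best_hit_species", "cluster"], "taxonomy map")
    return TaxonomyMap(df)


def write_taxonomy_map(taxonomy: TaxonomyMap, path: str | Path) -> None:
    taxonomy.table.to_csv(path, sep="\t", index=False)


def metadata_frame(metas: Sequence[LibraryMeta]) -> pd.DataFrame:
    """Library metadata as a DataFrame indexed by library_id."""
    df = pd.DataFrame(
        [{
            "library_id": m.library_id, "species": m.species, "site": m.site,
            "habitat": m.habitat, "year": m.year, "mosquito_count": m.mosquito_count,
        } for m in metas]
    )
    return df.set_index("library_id")
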