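"""End-to-end orchestration: simulate/load -> cluster -> filter ->
diversity -> compare -> report.

``analyze_experiment`` is the in-memory core used by tests and the
acceptance script; ``run_pipeline`` wraps it with file I/O, a manifest
(input hashes, parameters, seed) and a plain-text report so a run is
reproducible byte for byte from its config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    CountMatrix, HostGroup, metadata_frame,
    read_contig_table, read_count_matrix, read_library_metadata,
    read_taxonomy_map, write_count_matrix,
)
from .vtu import (
    assign_clusters, assign_vtus, collapse_counts, collapse_to_clusters,
    screen_eves, write_vtu_table,
)
from .filters import FilterParams, run_cascade
from .diversity import (
    alpha_diversity, beta_dissimilarity, mean_between_group_dissimilarity,
    nmds, permanova, tss_normalize,
)
from .compare import (
    MatchParams, PairwiseIdentity, Regime, cross_species_match,
    dissimilarity_regime, host_range_summary, known_virus_flag,
    partition_presence,
)
from .simulate import SimConfig, SimDataset, generate_experiment, write_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "analyze_experiment",
           "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """One run: either a simulation config or paths to real input tables."""

    sim: SimConfig | None = None
    input_paths: dict[str, str] | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    match_params: MatchParams = field(default_factory=MatchParams)
    n_permutations: int = 999
    nmds_restarts: int = 20
    run_permanova: bool = True
    run_nmds: bool = True
    permanova_terms: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_paths is None):
            raise ValueError("specify exactly one of: simulation config, input paths")


@dataclass
class PipelineResult:
    vtus: list
    filtered_counts: CountMatrix
    filter_report: Any
    alpha: pd.DataFrame
    sorensen: Any
    bray_curtis: Any
    mean_sorensen_between_hosts: float | None
    mean_bray_curtis_between_hosts: float | None
    regime: Regime | None
    permanova_table: pd.DataFrame | None
    nmds_coords: pd.DataFrame | None
    nmds_stress: float | None
    presence: pd.DataFrame | None
    venn: pd.DataFrame | None
    known_flags: dict[str, bool]
    host_ranges: pd.DataFrame | None
    range_medians: pd.Series | None
    n_eves_removed: int


def _load_inputs(paths: dict[str, str]) -> SimDataset:
    """Assemble a SimDataset-shaped bundle from real input tables."""
    required = ["contigs", "contig_counts", "metadata"]
    missing = [k for k in required if k not in paths or not Path(paths[k]).exists()]
    if missing:
        raise FileNotFoundError(f"missing input tables: {missing}")
    contigs = read_contig_table(paths["contigs"])
    counts = read_count_matrix(paths["contig_counts"])
    metadata = read_library_metadata(paths["metadata"])
    taxonomy = (read_taxonomy_map(paths["taxonomy"])
                if paths.get("taxonomy") and Path(paths["taxonomy"]).exists()
                else None)

    def _read_ident(key: str) -> list[PairwiseIdentity]:
        if not paths.get(key) or not Path(paths[key]).exists():
            return []
        df = pd.read_csv(paths[key], sep="\t")
        return [PairwiseIdentity(
            contig_a=str(r.contig_a), contig_b=str(r.contig_b),
            percent_identity_nt=float(r.percent_identity_nt),
            alignment_coverage_pct=float(getattr(r, "alignment_coverage_pct", 100.0)),
        ) for r in df.itertuples()]

    records = (pd.read_csv(paths["virus_records"], sep="\t")
               if paths.get("virus_records") and Path(paths["virus_records"]).exists()
               else pd.DataFrame())
    from .io import TaxonomyMap
    return SimDataset(
        contigs=contigs, contig_counts=counts, metadata=metadata,
        taxonomy=taxonomy or TaxonomyMap(),
        cross_identities=_read_ident("cross_identities"),
        reference_identities=_read_ident("reference_identities"),
        virus_records=records, truth=None, config=None,
    )


def analyze_experiment(
    dataset: SimDataset,
    filter_params: FilterParams = FilterParams(),
    match_params: MatchParams = MatchParams(),
    n_permutations: int = 999,
    nmds_restarts: int = 20,
    run_permanova: bool = True,
    run_nmds: bool = True,
    permanova_terms: list[str] | None = None,
    level: str = "cluster",
    seed: int = 0,
) -> PipelineResult:
    """Run every analysis stage on an in-memory dataset.

    ``level`` selects the taxonomic grain of the diversity statistics:
    ``"cluster"`` (family-like; the default, which is less sensitive to
    taxon-demarcation errors) or ``"vtu"``.  VTU sharing between hosts is
    always assessed at the VTU level.
    """
    # -- cluster -----------------------------------------------------------
    kept_contigs, eves = screen_eves(dataset.contigs)
    vtus = assign_vtus(kept_contigs)
    vtus = assign_clusters(vtus, dataset.taxonomy)
    kept_ids = [c.contig_id for c in kept_contigs]
    vtu_counts, vtus = collapse_counts(
        CountMatrix(dataset.contig_counts.data.loc[kept_ids]), vtus)

    # -- filter ------------------------------------------------------------
    vtus, filtered, report = run_cascade(vtus, vtu_counts, filter_params)

    meta = metadata_frame(dataset.metadata)
    host_of = meta["species"].to_dict()

    empty = filtered.data.empty or filtered.total() == 0
    if empty:
        logger.warning("no VTUs survive filtering; diversity stages skipped")
        return PipelineResult(
            vtus=vtus, filtered_counts=filtered, filter_report=report,
            alpha=pd.DataFrame(), sorensen=None, bray_curtis=None,
            mean_sorensen_between_hosts=None, mean_bray_curtis_between_hosts=None,
            regime=None, permanova_table=None, nmds_coords=None, nmds_stress=None,
            presence=None, venn=None, known_flags={}, host_ranges=None,
            range_medians=None, n_eves_removed=len(eves))

    # -- diversity ---------------------------------------------------------
    if level not in ("cluster", "vtu"):
        raise ValueError("level must be 'cluster' or 'vtu'")
    analysis_counts = filtered
    if level == "cluster":
        cluster_counts = collapse_to_clusters(filtered, vtus)
        if len(cluster_counts.taxa) > 1:
            analysis_counts = cluster_counts
        else:
            logger.warning("single cluster label; diversity computed at VTU level")
    rel = tss_normalize(analysis_counts)
    alpha = alpha_diversity(rel)
    sor = beta_dissimilarity(rel, "sorensen")
    bc = beta_dissimilarity(rel, "bray_curtis")

    hosts_present = sorted(set(host_of.values()))
    mean_sor = mean_bc = None
    regime = None
    if len(hosts_present) >= 2:
        mean_sor = mean_between_group_dissimilarity(sor, host_of)
        mean_bc = mean_between_group_dissimilarity(bc, host_of)
        regime = dissimilarity_regime(mean_sor, mean_bc)

    perm_table = None
    if run_permanova and len(hosts_present) >= 2:
        terms = permanova_terms
        if terms is None:
            terms = ["species"]
            for extra in ("habitat", "year"):
                if meta[extra].astype(str).nunique() > 1:
                    terms.append(extra)
        try:
            perm_table = permanova(
                bc, meta.astype(str), terms, n_perm=n_permutations, seed=seed,
            ).table
        except ValueError as exc:
            logger.warning("PERMANOVA skipped: %s", exc)

    coords = stress = None
    if run_nmds and len(bc.ids) >= 3:
        res = nmds(bc, k=2, n_restarts=nmds_restarts, seed=seed)
        coords, stress = res.coordinates, res.stress

    # -- compare -----------------------------------------------------------
    presence = venn = None
    if len(hosts_present) >= 2:
        by_host = {}
        for host in hosts_present:
            libs = [l for l, h in host_of.items() if h == host]
            host_contigs = [c for c in kept_contigs]
            sub = dataset.contig_counts.data.loc[kept_ids, libs]
            present_contigs = sub.index[sub.sum(axis=1) > 0]
            host_vtus = assign_vtus(
                [c for c in kept_contigs if c.contig_id in set(present_contigs)])
            # restrict to VTUs that survived the global cascade
            surviving_species = {v.best_hit_species for v in vtus}
            by_host[host] = [v for v in host_vtus
                             if v.best_hit_species in surviving_species]
        presence = cross_species_match(by_host, dataset.cross_identities, match_params)
        if 2 <= len(hosts_present) <= 3:
            venn = partition_presence(presence[hosts_present])

    known = {v.vtu_name: known_virus_flag(v, dataset.reference_identities, match_params)
             for v in vtus}

    ranges = medians = None
    if dataset.virus_records is not None and not dataset.virus_records.empty:
        ranges, medians = host_range_summary(dataset.virus_records)

    return PipelineResult(
        vtus=vtus, filtered_counts=filtered, filter_report=report,
        alpha=alpha, sorensen=sor, bray_curtis=bc,
        mean_sorensen_between_hosts=mean_sor,
        mean_bray_curtis_between_hosts=mean_bc, regime=regime,
        permanova_table=perm_table, nmds_coords=coords, nmds_stress=stress,
        presence=presence, venn=venn, known_flags=known,
        host_ranges=ranges, range_medians=medians, n_eves_removed=len(eves))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages, writing tables, a manifest and a report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        dataset = generate_experiment(config.sim)
        input_paths = write_experiment(dataset, outdir / "inputs")
    else:
        dataset = _load_inputs(config.input_paths)
        input_paths = {k: Path(v) for k, v in config.input_paths.items()
                       if v and Path(v).exists()}

    result = analyze_experiment(
        dataset,
        filter_params=config.filter_params,
        match_params=config.match_params,
        n_permutations=config.n_permutations,
        nmds_restarts=config.nmds_restarts,
        run_permanova=config.run_permanova,
        run_nmds=config.run_nmds,
        permanova_terms=config.permanova_terms,
        seed=config.seed,
    )

    # -- write outputs -----------------------------------------------------
    write_vtu_table(result.vtus, outdir / "vtu_table.tsv")
    write_count_matrix(result.filtered_counts, outdir / "filtered_counts.tsv")
    result.filter_report.write(outdir / "filter_report.tsv")
    if not result.alpha.empty:
        result.alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        pd.concat([result.sorensen.to_long(), result.bray_curtis.to_long()]).to_csv(
            outdir / "dissimilarities.tsv", sep="\t", index=False)
    if result.permanova_table is not None:
        result.permanova_table.to_csv(outdir / "permanova.tsv", sep="\t")
    if result.nmds_coords is not None:
        result.nmds_coords.to_csv(outdir / "nmds_coordinates.tsv", sep="\t")
    if result.presence is not None:
        result.presence.astype(int).to_csv(outdir / "presence_by_host.tsv", sep="\t")
    if result.venn is not None:
        result.venn.to_csv(outdir / "venn_regions.tsv", sep="\t", index=False)
    if result.host_ranges is not None:
        result.host_ranges.to_csv(outdir / "host_ranges.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "filter_params": {k: (v.value if isinstance(v, HostGroup) else v)
                          for k, v in vars(config.filter_params).items()},
        "match_params": vars(config.match_params),
        "n_permutations": config.n_permutations,
        "inputs": {k: _sha256(Path(p)) for k, p in input_paths.items()
                   if Path(p).is_file()},
        "simulation": (None if config.sim is None else
                       {k: v for k, v in vars(config.sim).items()}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    make_report(outdir, result)
    return outdir


def make_report(outdir: str | Path, result: PipelineResult | None = None) -> Path:
    """Write (or rewrite) the plain-text run summary from the run tables."""
    outdir = Path(outdir)
    lines = ["# Virome pipeline run summary", ""]
    vtu_path = outdir / "vtu_table.tsv"
    if not vtu_path.exists():
        raise FileNotFoundError("incomplete run: missing vtu_table.tsv")
    vtu_df = pd.read_csv(vtu_path, sep="\t")
    fr = pd.read_csv(outdir / "filter_report.tsv", sep="\t")
    lines += [
        f"Validated VTUs: {len(vtu_df)}",
        f"Family-like clusters: {vtu_df['cluster'].nunique()}",
        f"Novel VTUs (<= 90% aa identity): {int(vtu_df['is_novel'].sum())}",
        f"Reads removed by filters: {int(fr['reads_removed'].sum())}",
        "",
        "## Filter cascade",
        fr.to_string(index=False),
        "",
    ]
    if (outdir / "alpha_diversity.tsv").exists():
        alpha = pd.read_csv(outdir / "alpha_diversity.tsv", sep="\t", index_col=0)
        lines += ["## Alpha diversity (per library)", alpha.to_string(), ""]
        diss = pd.read_csv(outdir / "dissimilarities.tsv", sep="\t")
        means = diss.groupby("metric")["value"].mean()
        lines += ["## Mean pairwise dissimilarities",
                  means.to_string(), ""]
    else:
        lines += ["No VTUs survived filtering; diversity sections skipped.", ""]
    if (outdir / "permanova.tsv").exists():
        perm = pd.read_csv(outdir / "permanova.tsv", sep="\t", index_col=0)
        lines += ["## PERMANOVA (sequential terms, Bray-Curtis)",
                  perm.to_string(), ""]
    if (outdir / "venn_regions.tsv").exists():
        venn = pd.read_csv(outdir / "venn_regions.tsv", sep="\t")
        lines += ["## VTU sharing between host species", venn.to_string(index=False), ""]
    if result is not None and result.regime is not None:
        lines += [f"Between-host difference regime: {result.regime.value}",
                  f"  mean Sorensen     = {result.mean_sorensen_between_hosts:.3f}",
                  f"  mean Bray-Curtis  = {result.mean_bray_curtis_between_hosts:.3f}",
                  ""]
    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
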