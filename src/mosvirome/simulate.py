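"""Synthetic virome experiments with known ground truth.

The generator emulates the statistical structure of a pooled-mosquito
metatranscriptomic study at the contig/count abstraction: a contig
annotation table, a contig x library read-count matrix, library metadata
over a hosts x sites x years design, a best-hit taxonomy map, pairwise
nucleotide-identity tables, and a virus-records table -- plus a truth
object recording what was injected.

Key structural features emulated:

* skewed within-library abundance (log-normal base abundances, so a few
  taxa carry most reads);
* three host scenarios -- ``null`` (no host structure), ``host_abundance_shift``
  (identical taxon membership across hosts, per-host log-normal abundance
  multipliers) and ``diversity_turnover`` (hosts share only a fraction of
  taxa and carry their own otherwise);
* cross-library contamination: for dominant taxa, reads appear in foreign
  libraries just below the 5%-of-maximum detection threshold, so the
  cascade's third stage can be scored against truth;
* low-count noise (per-cell Poisson), endogenous-viral-element contigs
  (non-viral hit coverage above 25%), and non-arthropod-host taxa.

All randomness flows from one seed through ``numpy.random.SeedSequence``
child streams, one per generation concern, so adding draws to one concern
does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ContigRecord, CountMatrix, HostGroup, LibraryMeta, TaxonomyMap,
    write_contig_table, write_count_matrix, write_library_metadata,
    write_taxonomy_map,
)
from .compare import PairwiseIdentity

__all__ = ["SimConfig", "SimTruth", "SimDataset", "generate_experiment",
           "expected_outcomes", "write_experiment"]

SCENARIOS = ("null", "host_abundance_shift", "diversity_turnover")

_SPECIES_NAMES = ["Culex simulans", "Culex fictus", "Aedes fictus",
                  "Anopheles fictus", "Mansonia ficta"]
_HABITATS = ["Ponds", "River", "Lake", "Marsh", "Canal"]
_GENERA = ["Culex", "Aedes", "Anopheles", "Mansonia", "Armigeres"]
_CONTINENTS = ["Africa", "Asia", "Europe", "America", "Oceania"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of one synthetic experiment.

    Defaults mirror the emulated study: two host species sampled in three
    habitats over two years (12 libraries), ~40 detectable taxa per host,
    three quarters of taxa shared within a genus, strongly skewed
    abundances, and around 1e5 virus-like reads per library.
    """

    n_hosts: int = 2
    n_sites: int = 3
    n_years: int = 2
    n_vtus: int = 40
    shared_fraction: float = 0.75
    scenario: str = "host_abundance_shift"
    abundance_lognormal_sigma: float = 1.5
    host_effect_sigma: float = 2.0
    library_jitter_sigma: float = 0.6
    contamination_rate: float = 0.5
    contamination_margin: float = 0.8  # injected cell = margin * (5% of row max)
    noise_count_lambda: float = 0.3
    eve_fraction: float = 0.05
    nonarthropod_fraction: float = 0.05
    same_name_distinct_fraction: float = 0.0  # decoy same-named, non-shared taxa
    library_depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for name in ("shared_fraction", "contamination_rate", "eve_fraction",
                     "nonarthropod_fraction", "same_name_distinct_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_hosts, self.n_sites, self.n_years, self.n_vtus) < 1:
            raise ValueError("design dimensions must be >= 1")
        if self.library_depth < 1:
            raise ValueError("library_depth must be positive")
        if self.scenario == "host_abundance_shift" and self.shared_fraction == 0:
            raise ValueError(
                "host_abundance_shift requires shared taxa (shared_fraction > 0)")

    @classmethod
    def for_scenario(cls, scenario: str, seed: int = 0, **overrides) -> "SimConfig":
        """Scenario presets mirroring the two study comparisons.

        Within-genus comparisons showed ~75% taxon sharing with abundance
        shifts; the between-genus comparison shared only ~16% of taxa.
        """
        defaults = {"scenario": scenario, "seed": seed}
        if scenario == "diversity_turnover":
            defaults["shared_fraction"] = 0.16
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimTruth:
    """Ground truth of one generated experiment (keys are best-hit species)."""

    vtu_contigs: dict[str, list[str]]          # species -> member contig ids
    shared_species: list[str]                  # taxa truly shared by all hosts
    host_species_map: dict[str, list[str]]     # host -> member species
    contamination_cells: list[tuple[str, str]]  # (species, library_id)
    eve_contigs: list[str]
    nonarthropod_species: list[str]
    known_species: list[str]                   # amino-acid identity > 90%
    scenario: str

    def to_json(self) -> str:
        d = asdict(self)
        d["contamination_cells"] = [list(c) for c in self.contamination_cells]
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SimDataset:
    """Everything one synthetic experiment produces."""

    contigs: list[ContigRecord]
    contig_counts: CountMatrix
    metadata: list[LibraryMeta]
    taxonomy: TaxonomyMap
    cross_identities: list[PairwiseIdentity]
    reference_identities: list[PairwiseIdentity]
    virus_records: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    @property
    def host_of_library(self) -> dict[str, str]:
        return {m.library_id: m.species for m in self.metadata}


def _species_name(idx: int) -> str:
    return f"Simulated mosvirus {idx + 1:03d}"


def generate_experiment(config: SimConfig) -> SimDataset:
    """Generate a complete experiment; bit-reproducible for a given config."""
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_taxa, rng_abund, rng_counts, rng_contig, rng_contam, rng_ident, \
        rng_records, rng_meta = (np.random.default_rng(s) for s in streams)

    hosts = _SPECIES_NAMES[:config.n_hosts] + [
        f"Species {i}" for i in range(len(_SPECIES_NAMES), config.n_hosts)]

    # ---- taxon catalogue -------------------------------------------------
    n_shared = round(config.shared_fraction * config.n_vtus)
    if config.scenario in ("null", "host_abundance_shift"):
        n_shared = config.n_vtus  # identical membership across hosts
    n_specific = config.n_vtus - n_shared

    shared_species = [_species_name(i) for i in range(n_shared)]
    host_species: dict[str, list[str]] = {}
    specific_pool: dict[str, list[str]] = {}
    next_idx = n_shared
    for host in hosts:
        own = [_species_name(next_idx + j) for j in range(n_specific)]
        next_idx += n_specific
        specific_pool[host] = own
        host_species[host] = shared_species + own

    # optional decoys: same-named but genuinely distinct taxa across hosts
    n_decoy = round(config.same_name_distinct_fraction * n_specific)
    decoy_species: list[str] = []
    if n_decoy and len(hosts) >= 2:
        for j in range(n_decoy):
            name = specific_pool[hosts[0]][j]
            for other in hosts[1:]:
                host_species[other][host_species[other].index(specific_pool[other][j])] = name
                specific_pool[other][j] = name
            decoy_species.append(name)

    all_species = sorted({s for members in host_species.values() for s in members})
    # amino-acid identity per taxon: uniform(60, 100) -> ~25% "known" (> 90)
    pid_aa = {s: float(rng_taxa.uniform(60, 100)) for s in all_species}
    known_species = sorted(s for s in all_species if pid_aa[s] > 90)
    n_other = round(config.nonarthropod_fraction * len(all_species))
    nonarthropod = sorted(rng_taxa.choice(all_species, size=n_other, replace=False).tolist())

    # ---- taxonomy map ------------------------------------------------------
    # family-like clusters mirror the host structure: taxa shared by hosts
    # sit in a core cluster pool, host-specific taxa in host-specific pools
    # (different virus families dominate different mosquito genera)
    n_core = max(1, n_shared // 4)
    core_clusters = [f"Simviridae core{k + 1:02d}" for k in range(n_core)]
    own_clusters = {
        host: [f"Simviridae h{hi + 1}-{k + 1:02d}"
               for k in range(max(1, n_specific // 4))]
        for hi, host in enumerate(hosts)
    }
    cluster_names = core_clusters + [c for cs in own_clusters.values() for c in cs]
    order_of_cluster = {c: f"Simvirales {k % max(1, len(cluster_names) // 2) + 1:02d}"
                        for k, c in enumerate(cluster_names)}
    phyla = [f"Phylum {chr(65 + i)}" for i in range(5)]
    owner_of: dict[str, str] = {}
    for host in hosts:
        for s in specific_pool[host]:
            owner_of.setdefault(s, host)
    cluster_of: dict[str, str] = {}
    tax_rows = []
    for s in all_species:
        pool = (own_clusters[owner_of[s]] if s in owner_of else core_clusters)
        cluster = str(rng_taxa.choice(pool))
        cluster_of[s] = cluster
        tax_rows.append({
            "best_hit_species": s, "cluster": cluster,
            "order": order_of_cluster[cluster],
            "phylum": phyla[hash(cluster) % len(phyla)],
        })
    taxonomy = TaxonomyMap(pd.DataFrame(tax_rows))

    # ---- library design --------------------------------------------------
    sites = [f"Site{i + 1}" for i in range(config.n_sites)]
    habitats = {s: _HABITATS[i % len(_HABITATS)] for i, s in enumerate(sites)}
    years = [2014 + y for y in range(config.n_years)]
    metadata: list[LibraryMeta] = []
    for hi, host in enumerate(hosts):
        for si, site in enumerate(sites):
            for year in years:
                lib_id = f"H{hi + 1}{site[0]}{si + 1}Y{year % 100}"
                metadata.append(LibraryMeta(
                    library_id=lib_id, species=host, site=site,
                    habitat=habitats[site], year=year,
                    mosquito_count=int(rng_meta.integers(80, 4000)),
                ))
    libraries = [m.library_id for m in metadata]
    host_of = {m.library_id: m.species for m in metadata}

    # ---- abundances and counts at the taxon level ------------------------
    base = {s: rng_abund.lognormal(0.0, config.abundance_lognormal_sigma)
            for s in all_species}
    # host effects act at the family level: each cluster has a host-affinity
    # score and each host a position on that axis, so a family favoured in
    # one host is relatively disfavoured in the other (dominant families
    # differ between host species); smaller taxon-level variation on top
    host_mult: dict[str, dict[str, float]] = {}
    if config.scenario == "host_abundance_shift":
        affinity = {c: rng_abund.normal(0.0, config.host_effect_sigma)
                    for c in cluster_names}
        host_direction = {
            host: (1.0 - 2.0 * (hi % 2) if hi < 2
                   else float(rng_abund.uniform(-1, 1)))
            for hi, host in enumerate(hosts)}
    for host in hosts:
        if config.scenario == "host_abundance_shift":
            d = host_direction[host]
            host_mult[host] = {
                s: float(np.exp(d * affinity[cluster_of[s]]))
                * rng_abund.lognormal(0.0, config.host_effect_sigma / 2.0)
                for s in host_species[host]}
        else:
            host_mult[host] = {s: 1.0 for s in host_species[host]}

    taxon_counts = pd.DataFrame(0, index=all_species, columns=libraries, dtype=np.int64)
    for m in metadata:
        members = host_species[m.species]
        weights = np.array([
            base[s] * host_mult[m.species][s]
            * rng_abund.lognormal(0.0, config.library_jitter_sigma)
            for s in members])
        probs = weights / weights.sum()
        draws = rng_counts.multinomial(config.library_depth, probs)
        taxon_counts.loc[members, m.library_id] = draws

    # per-cell low-count noise
    if config.noise_count_lambda > 0:
        noise = rng_counts.poisson(config.noise_count_lambda, size=taxon_counts.shape)
        taxon_counts = taxon_counts + noise

    # ---- contamination injection ----------------------------------------
    contamination_cells: list[tuple[str, str]] = []
    if config.contamination_rate > 0:
        # judge dominance on counts as the cascade will see them: cells under
        # the 10-read floor zeroed, rows under 100 total dropped
        z = taxon_counts.to_numpy().copy()
        z[z < 10] = 0
        row_tot = z.sum(axis=1)
        survivors = row_tot >= 100
        q3 = float(np.quantile(row_tot[survivors], 0.75)) if survivors.any() else np.inf
        dominant = [s for i, s in enumerate(all_species)
                    if row_tot[i] > q3 and z[i].max() >= 300]
        chosen = [s for s in dominant
                  if rng_contam.random() < config.contamination_rate]
        for s in chosen:
            row = taxon_counts.loc[s]
            tau = 0.05 * float(row.max())
            injected = int(np.floor(config.contamination_margin * tau))
            if injected < 10:
                continue  # would be removed by the per-library floor, not stage 3
            target_libs = [lib for lib in libraries if row[lib] <= 2]
            if not target_libs:
                continue
            n_targets = min(len(target_libs), int(rng_contam.integers(1, 4)))
            picked = rng_contam.choice(target_libs, size=n_targets, replace=False)
            for lib in picked:
                taxon_counts.loc[s, lib] = injected
                contamination_cells.append((s, str(lib)))

    # ---- contigs and contig-level counts ---------------------------------
    contigs: list[ContigRecord] = []
    vtu_contigs: dict[str, list[str]] = {s: [] for s in all_species}
    contig_rows: dict[str, np.ndarray] = {}
    acc_counter = 0
    for host in hosts:
        for s in host_species[host]:
            n_c = int(rng_contig.integers(1, 5))
            lens = rng_contig.integers(500, 10_000, size=n_c)
            for j in range(n_c):
                acc_counter += 1
                cid = f"{host.split()[0][:2].upper()}{hosts.index(host) + 1}_" \
                      f"c{acc_counter:05d}"
                contigs.append(ContigRecord(
                    contig_id=cid,
                    best_hit_species=s,
                    best_hit_accession=f"SIM{acc_counter:06d}",
                    pid_aa=float(np.clip(pid_aa[s] + rng_contig.normal(0, 1.0), 0, 100)),
                    aln_len_aa=int(rng_contig.integers(100, 600)),
                    evalue=float(10 ** rng_contig.uniform(-50, -5)),
                    contig_len_nt=int(lens[j]),
                    host_group=(HostGroup.OTHER if s in nonarthropod
                                else HostGroup.ARTHROPODA),
                    nonviral_cov_pct=(float(rng_contig.uniform(0, 25))
                                      if rng_contig.random() < 0.3 else None),
                ))
                vtu_contigs[s].append(cid)

    # split each taxon x library count over that taxon's contigs by length
    contig_by_id = {c.contig_id: c for c in contigs}
    for s in all_species:
        members = vtu_contigs[s]
        lens = np.array([contig_by_id[c].contig_len_nt for c in members], dtype=float)
        w = lens / lens.sum()
        split = np.zeros((len(members), len(libraries)), dtype=np.int64)
        for li, lib in enumerate(libraries):
            total = int(taxon_counts.loc[s, lib])
            if total:
                split[:, li] = rng_counts.multinomial(total, w)
        for ci, cid in enumerate(members):
            contig_rows[cid] = split[ci]

    # ---- EVE contigs ------------------------------------------------------
    eve_contigs: list[str] = []
    n_eves = round(config.eve_fraction * len(contigs))
    for j in range(n_eves):
        s = str(rng_contig.choice(all_species))
        acc_counter += 1
        cid = f"EVE_c{acc_counter:05d}"
        contigs.append(ContigRecord(
            contig_id=cid, best_hit_species=s,
            best_hit_accession=f"SIM{acc_counter:06d}",
            pid_aa=float(np.clip(pid_aa[s] + rng_contig.normal(0, 1.0), 0, 100)),
            aln_len_aa=int(rng_contig.integers(100, 600)),
            evalue=float(10 ** rng_contig.uniform(-50, -5)),
            contig_len_nt=int(rng_contig.integers(500, 5000)),
            host_group=(HostGroup.OTHER if s in nonarthropod
                        else HostGroup.ARTHROPODA),
            nonviral_cov_pct=float(rng_contig.uniform(26, 95)),
        ))
        row = np.zeros(len(libraries), dtype=np.int64)
        hit_libs = rng_counts.choice(len(libraries),
                                     size=int(rng_counts.integers(1, 4)), replace=False)
        row[hit_libs] = rng_counts.poisson(40, size=len(hit_libs))
        contig_rows[cid] = row
        eve_contigs.append(cid)
        vtu_contigs.setdefault(s, []).append(cid)

    contig_counts = CountMatrix(pd.DataFrame(
        np.vstack([contig_rows[c.contig_id] for c in contigs]),
        index=[c.contig_id for c in contigs], columns=libraries))

    # ---- pairwise nucleotide identities -----------------------------------
    cross_identities: list[PairwiseIdentity] = []
    per_host_contigs: dict[str, dict[str, list[str]]] = {h: {} for h in hosts}
    for c in contigs:
        if c.contig_id in eve_contigs:
            continue
        host_tag = int(c.contig_id[2]) - 1 if c.contig_id[0] != "E" else None
        if host_tag is not None and 0 <= host_tag < len(hosts):
            per_host_contigs[hosts[host_tag]].setdefault(
                c.best_hit_species, []).append(c.contig_id)
    for s in all_species:
        carriers = [h for h in hosts if s in per_host_contigs[h]]
        truly_shared = s in shared_species
        for i, ha in enumerate(carriers):
            for hb in carriers[i + 1:]:
                ca = str(rng_ident.choice(per_host_contigs[ha][s]))
                cb = str(rng_ident.choice(per_host_contigs[hb][s]))
                if truly_shared:
                    pid = float(rng_ident.uniform(85, 100))
                else:  # decoy same-named but distinct taxa
                    pid = float(rng_ident.uniform(50, 75))
                cross_identities.append(PairwiseIdentity(
                    contig_a=ca, contig_b=cb, percent_identity_nt=pid,
                    alignment_coverage_pct=float(rng_ident.uniform(50, 100))))

    reference_identities: list[PairwiseIdentity] = []
    for s in all_species:
        cid = vtu_contigs[s][0]
        if s in known_species:
            pid, cov = rng_ident.uniform(85, 100), rng_ident.uniform(92, 100)
        else:
            pid, cov = rng_ident.uniform(50, 75), rng_ident.uniform(50, 95)
        reference_identities.append(PairwiseIdentity(
            contig_a=cid, contig_b=f"ref|{s}",
            percent_identity_nt=float(pid), alignment_coverage_pct=float(cov)))

    # ---- virus records (host / geographic ranges of known taxa) -----------
    rec_rows = []
    for s in known_species:
        n_sp = 1 + int(rng_records.poisson(5))
        n_ct = 1 + int(rng_records.poisson(5))
        for j in range(n_sp):
            genus = _GENERA[int(rng_records.integers(0, min(3, len(_GENERA))))]
            rec_rows.append({
                "virus": s, "mosquito_species": f"{genus} host{j + 1:02d}",
                "mosquito_genus": genus,
                "country": f"Country{int(rng_records.integers(1, n_ct + 1)):02d}",
                "continent": _CONTINENTS[int(rng_records.integers(0, len(_CONTINENTS)))],
            })
    virus_records = pd.DataFrame(
        rec_rows, columns=["virus", "mosquito_species", "mosquito_genus",
                           "country", "continent"]).drop_duplicates()

    truth = SimTruth(
        vtu_contigs=vtu_contigs,
        shared_species=shared_species,
        host_species_map=host_species,
        contamination_cells=contamination_cells,
        eve_contigs=eve_contigs,
        nonarthropod_species=nonarthropod,
        known_species=known_species,
        scenario=config.scenario,
    )
    return SimDataset(
        contigs=contigs, contig_counts=contig_counts, metadata=metadata,
        taxonomy=taxonomy, cross_identities=cross_identities,
        reference_identities=reference_identities, virus_records=virus_records,
        truth=truth, config=config,
    )


def expected_outcomes(config: SimConfig, truth: SimTruth) -> dict:
    """Qualitative truth summary used by end-to-end recovery tests."""
    regime = {
        "null": "mixed_or_abundance",
        "host_abundance_shift": "abundance_dominated",
        "diversity_turnover": "diversity_dominated",
    }[config.scenario]
    return {
        "expected_regime": regime,
        "expected_shared_count": len(truth.shared_species),
        "host_p_uniform": config.scenario == "null",
    }


def write_experiment(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all artifacts as TSV (plus truth.json); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.tsv",
        "contig_counts": outdir / "contig_counts.tsv",
        "metadata": outdir / "library_metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "cross_identities": outdir / "cross_identities.tsv",
        "reference_identities": outdir / "reference_identities.tsv",
        "virus_records": outdir / "virus_records.tsv",
        "truth": outdir / "truth.json",
    }
    write_contig_table(dataset.contigs, paths["contigs"])
    write_count_matrix(dataset.contig_counts, paths["contig_counts"])
    write_library_metadata(dataset.metadata, paths["metadata"])
    write_taxonomy_map(dataset.taxonomy, paths["taxonomy"])
    for key in ("cross_identities", "reference_identities"):
        pd.DataFrame([{
            "contig_a": r.contig_a, "contig_b": r.contig_b,
            "percent_identity_nt": r.percent_identity_nt,
            "alignment_coverage_pct": r.alignment_coverage_pct,
        } for r in getattr(dataset, key)]).to_csv(paths[key], sep="\t", index=False)
    dataset.virus_records.to_csv(paths["virus_records"], sep="\t", index=False)
    paths["truth"].write_text(dataset.truth.to_json())
    return paths
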