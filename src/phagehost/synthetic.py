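"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover the pipeline's inputs:

* a clade-structured bacterial population with clade-private diagnostic SNPs,
  habitat-dependent mobile-element loads, gene-family and gene-order tables;
* a phage genome family with a planted genus/species partition whose pairwise
  divergences sit on the correct sides of the 70/95 similarity thresholds;
* replicated, LOQ-censored, log-normally noisy ddPCR abundance series over
  unevenly spaced sampling dates, with optional seasonality or lag coupling,
  down to simulated droplet counts.

Every generator emits truth tables sufficient to compute the expected answer
of each downstream stage, and is bit-reproducible under a fixed seed.
The mutation model is site-independent substitution, uniform over the three
alternative bases, with no indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SequenceRecord, ValidationError

BASES = np.array(list("ACGT"))

#: class mix of classified mobile elements (plasmid, prophage, satellite,
#: integrase) roughly matching an MGE census of a coastal Vibrio population
MGE_CLASS_PROBS: dict[str, float] = {
    "plasmid": 0.32, "prophage": 0.44, "satellite": 0.05, "integrase": 0.19,
}


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _to_string(seq: np.ndarray) -> str:
    return "".join(BASES[seq])


# ---------------------------------------------------------------------------
# Bacterial population
# ---------------------------------------------------------------------------

@dataclass
class PopulationSimConfig:
    """Clade-structured population with planted diagnostic SNPs.

    Defaults emulate a small oyster-farm survey: eight clades, the first
    seawater-associated and the rest oyster-associated, with oyster strains
    carrying several-fold more mobile elements.  ``snp_layout='clustered'``
    plants each clade's private SNPs in two nearby windows inside one core
    gene, the SNP-dense geometry that makes a ddPCR amplicon designable.
    """

    n_clades: int = 8
    strains_per_clade: int = 8
    core_genes: int = 20
    gene_length: int = 900
    gene_spacer: int = 50
    clade_private_snps_per_clade: int = 6
    background_snp_rate: float = 1e-4
    habitat_assignment: dict[str, str] | None = None
    mge_rate_oyster: float = 6.0
    mge_rate_seawater: float = 1.0
    snp_layout: str = "clustered"  # or "uniform"
    private_snp_positions: dict[str, list[int]] | None = None
    accessory_gene_length: int = 800
    n_accessory_families: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clades", "strains_per_clade", "core_genes",
                     "gene_length", "clade_private_snps_per_clade"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.mge_rate_oyster < 0 or self.mge_rate_seawater < 0:
            raise ValidationError("MGE rates must be non-negative")
        if self.snp_layout not in ("clustered", "uniform"):
            raise ValidationError("snp_layout must be 'clustered' or 'uniform'")
        if self.snp_layout == "clustered" and self.n_clades > self.core_genes:
            raise ValidationError(
                "clustered layout requires core_genes >= n_clades")
        if self.private_snp_positions is not None:
            seen: set[int] = set()
            for clade, positions in self.private_snp_positions.items():
                overlap = seen & set(positions)
                if overlap or len(set(positions)) != len(positions):
                    raise ValidationError(
                        f"planted SNP positions overlap at {sorted(overlap)}")
                seen |= set(positions)

    @property
    def clades(self) -> list[str]:
        return [f"V{i + 1}" for i in range(self.n_clades)]

    @property
    def core_length(self) -> int:
        return self.core_genes * (self.gene_length + self.gene_spacer)

    def habitats(self) -> dict[str, str]:
        if self.habitat_assignment is not None:
            return dict(self.habitat_assignment)
        # first clade planktonic, the rest host-associated
        return {c: ("seawater" if i == 0 else "oyster")
                for i, c in enumerate(self.clades)}


@dataclass
class SimulatedPopulation:
    records: list[SequenceRecord]
    clade_labels: dict[str, str]
    habitat: dict[str, str]
    snp_truth: pd.DataFrame        # clade, position, ref, alt, gene_id
    allele_matrix: pd.DataFrame    # strains x variable positions (bases)
    site_info: pd.DataFrame        # per column: gene_id, is_core
    gene_families: pd.DataFrame    # strains x families (0/1)
    gene_order: pd.DataFrame       # strain, contig, gene_id, family_id, start, end, strand
    annotations: pd.DataFrame      # per planted MGE: flags + true_class


def _plant_positions(cfg: PopulationSimConfig,
                     rng: np.random.Generator) -> dict[str, list[int]]:
    if cfg.private_snp_positions is not None:
        return {c: sorted(p) for c, p in cfg.private_snp_positions.items()}
    positions: dict[str, list[int]] = {}
    stride = cfg.gene_length + cfg.gene_spacer
    if cfg.snp_layout == "clustered":
        genes = rng.permutation(cfg.core_genes)[:cfg.n_clades]
        for clade, gene in zip(cfg.clades, genes):
            n = cfg.clade_private_snps_per_clade
            first = (n + 1) // 2
            span = 210 + 12 * max(first, n - first)
            if cfg.gene_length <= span:
                raise ValidationError(
                    f"clustered layout needs gene_length > {span} bp")
            anchor = int(gene) * stride + int(rng.integers(0, cfg.gene_length - span))
            window1 = [anchor + 12 * i for i in range(first)]
            window2 = [anchor + 210 + 12 * i for i in range(n - first)]
            positions[clade] = sorted(window1 + window2)
    else:
        total = cfg.n_clades * cfg.clade_private_snps_per_clade
        chosen = rng.choice(cfg.core_length, size=total, replace=False)
        for i, clade in enumerate(cfg.clades):
            block = chosen[i * cfg.clade_private_snps_per_clade:
                           (i + 1) * cfg.clade_private_snps_per_clade]
            positions[clade] = sorted(int(p) for p in block)
    return positions


def _gene_of(position: int, cfg: PopulationSimConfig) -> str:
    return f"core_{position // (cfg.gene_length + cfg.gene_spacer) + 1:03d}"


def simulate_bacterial_population(cfg: PopulationSimConfig) -> SimulatedPopulation:
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_sequence(rng, cfg.core_length)
    planted = _plant_positions(cfg, rng)
    all_planted = sorted(p for ps in planted.values() for p in ps)
    if len(set(all_planted)) != len(all_planted):
        raise ValidationError("planted SNP positions overlap across clades")

    # one alternative allele per planted site, fixed within the clade
    alt_alleles = {p: int((ancestor[p] + rng.integers(1, 4)) % 4)
                   for p in all_planted}
    snp_truth = pd.DataFrame(
        [{"clade": clade, "position": p,
          "ref": str(BASES[ancestor[p]]), "alt": str(BASES[alt_alleles[p]]),
          "gene_id": _gene_of(p, cfg)}
         for clade, ps in planted.items() for p in ps])

    habitats = cfg.habitats()
    records: list[SequenceRecord] = []
    clade_labels: dict[str, str] = {}
    habitat: dict[str, str] = {}
    variable: set[int] = set(all_planted)
    genomes: dict[str, np.ndarray] = {}
    for clade in cfg.clades:
        for k in range(cfg.strains_per_clade):
            strain = f"{clade}_s{k + 1:02d}"
            genome = ancestor.copy()
            for p in planted[clade]:
                genome[p] = alt_alleles[p]
            hits = np.flatnonzero(rng.random(genome.size) < cfg.background_snp_rate)
            hits = hits[~np.isin(hits, all_planted)]
            if hits.size:
                genome[hits] = (genome[hits] + rng.integers(1, 4, size=hits.size)) % 4
                variable |= {int(h) for h in hits}
            genomes[strain] = genome
            clade_labels[strain] = clade
            habitat[strain] = habitats[clade]

    # mobile elements: habitat-dependent Poisson load, class mix fixed
    classes = list(MGE_CLASS_PROBS)
    probs = np.array([MGE_CLASS_PROBS[c] for c in classes])
    stride = cfg.gene_length + cfg.gene_spacer
    acc_stride = cfg.accessory_gene_length + cfg.gene_spacer
    family_pool = [f"acc_{i + 1:03d}" for i in range(cfg.n_accessory_families)]
    gene_rows, ann_rows = [], []
    presence: dict[str, set[str]] = {}
    for strain, genome in genomes.items():
        rate = (cfg.mge_rate_oyster if habitat[strain] == "oyster"
                else cfg.mge_rate_seawater)
        n_mge = int(rng.poisson(rate))
        for g in range(cfg.core_genes):
            gene_rows.append({
                "strain": strain, "contig": "chromosome",
                "gene_id": f"{strain}|core_{g + 1:03d}",
                "family_id": f"core_{g + 1:03d}",
                "start": g * stride, "end": g * stride + cfg.gene_length,
                "strand": "+"})
        presence[strain] = {f"core_{g + 1:03d}" for g in range(cfg.core_genes)}
        cursor = cfg.core_length
        for m in range(n_mge):
            cls = classes[int(rng.choice(len(classes), p=probs))]
            n_genes = int(rng.integers(4, 9))
            families = rng.choice(cfg.n_accessory_families, size=n_genes,
                                  replace=False)
            start = cursor
            for j, fam in enumerate(families):
                gene_rows.append({
                    "strain": strain, "contig": "chromosome",
                    "gene_id": f"{strain}|mge{m + 1}_{j + 1}",
                    "family_id": family_pool[int(fam)],
                    "start": cursor, "end": cursor + cfg.accessory_gene_length,
                    "strand": "+"})
                presence[strain].add(family_pool[int(fam)])
                cursor += acc_stride
            ann_rows.append({
                "strain": strain, "contig": "chromosome",
                "start": start, "end": cursor - cfg.gene_spacer,
                "plasmid_origin": cls == "plasmid",
                "satellite_full_segment": cls == "satellite",
                "viral_call": cls == "prophage",
                "prophage_quality": "high" if cls == "prophage" else "none",
                "viral_gene_count": n_genes if cls == "prophage" else 0,
                "integrase_present": cls == "integrase",
                "true_class": cls})
        records.append(SequenceRecord(
            id=strain, sequence=_to_string(genome),
            metadata={"clade": clade_labels[strain],
                      "habitat": habitat[strain], "replicon_type": "chromosome"}))

    strains = sorted(genomes)
    columns = sorted(variable)
    allele_matrix = pd.DataFrame(
        {f"chromosome:{p}": [str(BASES[genomes[s][p]]) for s in strains]
         for p in columns}, index=strains)
    site_info = pd.DataFrame(
        {"gene_id": [_gene_of(p, cfg) for p in columns],
         "is_core": True},
        index=[f"chromosome:{p}" for p in columns])
    all_families = sorted(set().union(*presence.values()))
    gene_families = pd.DataFrame(
        [[int(f in presence[s]) for f in all_families] for s in strains],
        index=strains, columns=all_families)
    gene_order = pd.DataFrame(gene_rows)
    annotations = pd.DataFrame(
        ann_rows, columns=["strain", "contig", "start", "end", "plasmid_origin",
                           "satellite_full_segment", "viral_call",
                           "prophage_quality", "viral_gene_count",
                           "integrase_present", "true_class"])
    return SimulatedPopulation(
        records=records, clade_labels=clade_labels, habitat=habitat,
        snp_truth=snp_truth, allele_matrix=allele_matrix, site_info=site_info,
        gene_families=gene_families, gene_order=gene_order,
        annotations=annotations)


# ---------------------------------------------------------------------------
# Phage family
# ---------------------------------------------------------------------------

@dataclass
class PhageFamilySimConfig:
    """Planted genus/species partition via a star phylogeny per species
    nested in a star per genus.

    Divergence bands must keep expected pairwise similarities on the correct
    sides of the 95 (species) and 70 (genus) thresholds: same species
    ~ ``within_species_divergence`` (< 0.05), same genus across species
    ~ ``within_genus_divergence`` (in (0.05, 0.30) including the
    within-species contribution), different genera unrelated (similarity
    near zero).
    """

    n_genomes: int = 16
    genome_length: int = 10_000
    planted_partition: dict[str, tuple[int, int]] | None = None
    within_species_divergence: float = 0.02
    within_genus_divergence: float = 0.15
    private_families_per_genus: int = 3
    shared_families: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        ws, wg = self.within_species_divergence, self.within_genus_divergence
        if not (0 <= ws < 0.05):
            raise ValidationError("within_species_divergence must be in [0, 0.05)")
        if not (0.05 < wg < 0.30):
            raise ValidationError("within_genus_divergence must be in (0.05, 0.30)")
        if wg + ws >= 0.30:
            raise ValidationError(
                "combined within-genus divergence crosses the genus threshold")
        if self.n_genomes < 2 or self.genome_length < 1000:
            raise ValidationError("need >= 2 genomes of >= 1 kb")

    def partition(self) -> dict[str, tuple[int, int]]:
        if self.planted_partition is not None:
            return dict(self.planted_partition)
        # default: genera of 4 genomes split into 2 species of 2
        out = {}
        for i in range(self.n_genomes):
            genus = i // 4
            species = genus * 2 + (i % 4) // 2
            out[f"phage_{i + 1:03d}"] = (genus, species)
        return out


@dataclass
class SimulatedPhageFamily:
    records: list[SequenceRecord]
    truth: pd.DataFrame            # genome_id, genus_truth, species_truth
    gene_families: pd.DataFrame    # phage x family presence (0/1)


def simulate_phage_family(cfg: PhageFamilySimConfig) -> SimulatedPhageFamily:
    rng = np.random.default_rng(cfg.seed)
    partition = cfg.partition()
    genera = sorted({g for g, _ in partition.values()})
    species = sorted({s for _, s in partition.values()})
    genus_anc = {g: _random_sequence(rng, cfg.genome_length) for g in genera}
    genus_of_species = {s: next(g for gid, (g, sp) in partition.items() if sp == s)
                        for s in species}
    half_genus = (cfg.within_genus_divergence - cfg.within_species_divergence) / 2.0
    species_anc = {s: _mutate(genus_anc[genus_of_species[s]], half_genus, rng)
                   for s in species}
    records, rows = [], []
    for gid in sorted(partition):
        genus, sp = partition[gid]
        genome = _mutate(species_anc[sp], cfg.within_species_divergence / 2.0, rng)
        records.append(SequenceRecord(
            id=gid, sequence=_to_string(genome),
            metadata={"replicon_type": "phage", "genus_truth": genus,
                      "species_truth": sp}))
        rows.append({"genome_id": gid, "genus_truth": genus, "species_truth": sp})
    truth = pd.DataFrame(rows)

    # gene-family presence: shared families everywhere, private ones per genus
    families = [f"shared_{i + 1:02d}" for i in range(cfg.shared_families)]
    private = {g: [f"genus{g}_private_{i + 1}" for i in
                   range(cfg.private_families_per_genus)] for g in genera}
    columns = families + [f for g in genera for f in private[g]]
    mat = []
    for gid in sorted(partition):
        genus, _ = partition[gid]
        row = {f: 1 for f in families}
        for g in genera:
            for f in private[g]:
                row[f] = int(g == genus)
        mat.append(row)
    gene_families = pd.DataFrame(mat, index=sorted(partition), columns=columns)
    return SimulatedPhageFamily(records=records, truth=truth,
                                gene_families=gene_families)


# ---------------------------------------------------------------------------
# ddPCR abundance series
# ---------------------------------------------------------------------------

@dataclass
class SeriesSimConfig:
    """Log-normally noisy, LOQ-censored abundance series with droplet counts.

    Defaults follow the survey design: 35 uneven sampling dates over an
    ~80-day summer season with 10 replicate oysters per date.  Trends are
    constant, sinusoidal (``seasonal_period`` days) or lag-coupled to an
    internally generated driver series (``coupling_lag`` sampling dates at
    ``coupling_strength``).
    """

    n_dates: int = 35
    dates: Sequence[int] | None = None
    season_span_days: int = 79
    replicates_per_date: int = 10
    log10_mean: float = 3.0
    log10_sd: float = 0.5
    seasonal_period: float | None = None
    seasonal_amplitude: float = 1.0
    coupling_lag: int | None = None
    coupling_strength: float = 0.0
    driver_sd: float = 1.0
    loq_copies_per_ml: float = 200.0
    total_droplets: int = 15_000
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    sample_volume_ml: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dates is not None:
            d = list(self.dates)
            if any(b <= a for a, b in zip(d, d[1:])):
                raise ValidationError("dates must be strictly increasing")
            self.n_dates = len(d)
        if self.replicates_per_date < 2:
            raise ValidationError("need at least 2 replicates per date")
        if self.coupling_lag is not None and self.coupling_lag >= self.n_dates:
            raise ValidationError("coupling_lag must be smaller than n_dates")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValidationError("coupling_strength must lie in [0, 1]")


@dataclass
class SimulatedSeries:
    series: pd.DataFrame   # target_id, date, replicate, copies_per_ml, below_loq
    wells: pd.DataFrame    # sample_id, target_id, date, replicate, total/positive droplets
    trend: pd.DataFrame    # target_id, date, log10_trend


def _sample_dates(cfg: SeriesSimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.dates is not None:
        return np.asarray(list(cfg.dates), dtype=int)
    if cfg.n_dates > cfg.season_span_days + 1:
        raise ValidationError("more dates than days in the season span")
    days = rng.choice(cfg.season_span_days + 1, size=cfg.n_dates, replace=False)
    return np.sort(days)


def simulate_ddpcr_series(cfg: SeriesSimConfig) -> SimulatedSeries:
    rng = np.random.default_rng(cfg.seed)
    dates = _sample_dates(cfg, rng)
    n = dates.size

    trends: dict[str, np.ndarray] = {}
    if cfg.coupling_lag is None:
        base = np.full(n, cfg.log10_mean)
        if cfg.seasonal_period is not None:
            base = base + cfg.seasonal_amplitude * np.sin(
                2.0 * np.pi * dates / cfg.seasonal_period)
        trends["target"] = base
    else:
        driver_dev = rng.normal(0.0, cfg.driver_sd, size=n)
        own_dev = rng.normal(0.0, cfg.driver_sd, size=n)
        response_dev = np.empty(n)
        lag, strength = cfg.coupling_lag, cfg.coupling_strength
        for i in range(n):
            if i >= lag:
                response_dev[i] = (strength * driver_dev[i - lag]
                                   + np.sqrt(1 - strength ** 2) * own_dev[i])
            else:
                response_dev[i] = own_dev[i]
        trends["driver"] = cfg.log10_mean + driver_dev
        trends["response"] = cfg.log10_mean + response_dev

    series_rows, well_rows, trend_rows = [], [], []
    for target, trend in trends.items():
        for i, date in enumerate(dates):
            trend_rows.append({"target_id": target, "date": int(date),
                               "log10_trend": float(trend[i])})
            for rep in range(cfg.replicates_per_date):
                log_v = trend[i] + rng.normal(0.0, cfg.log10_sd)
                copies_per_ml = 10.0 ** log_v
                copies_per_reaction = copies_per_ml * cfg.sample_volume_ml
                lam = (copies_per_reaction / cfg.reaction_volume_ul
                       * cfg.droplet_volume_nl / 1000.0)
                positive = int(rng.binomial(cfg.total_droplets,
                                            1.0 - np.exp(-lam)))
                sample_id = f"{target}_d{int(date):03d}_r{rep + 1:02d}"
                series_rows.append({
                    "target_id": target, "date": int(date), "replicate": rep + 1,
                    "copies_per_ml": copies_per_ml,
                    "below_loq": copies_per_ml < cfg.loq_copies_per_ml})
                well_rows.append({
                    "sample_id": sample_id, "target_id": target,
                    "date": int(date), "replicate": rep + 1,
                    "total_droplets": cfg.total_droplets,
                    "positive_droplets": positive})
    return SimulatedSeries(series=pd.DataFrame(series_rows),
                           wells=pd.DataFrame(well_rows),
                           trend=pd.DataFrame(trend_rows))
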