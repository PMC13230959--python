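"""Pangenome persistence, regions of genomic plasticity (RGPs), MGE
classification, prophage retention filters, cargo screening and per-kbp
coding-density statistics.

An RGP is a maximal run of consecutive non-persistent genes on one contig,
kept when it spans at least ``min_span`` bp and ``min_genes`` genes.  RGPs
are classified into mobile-genetic-element types by a fixed precedence of
annotation flags (plasmid -> satellite -> prophage -> integrase ->
unclassified), so every region receives exactly one class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

PROPHAGE_QUALITIES = frozenset({"complete", "high", "medium", "low"})

#: strict minimum genome sizes (bp) for retaining predicted prophages, per viral class
PROPHAGE_SIZE_FLOORS: dict[str, int] = {
    "Caudoviricetes": 25_000,
    "Tectiliviricetes": 10_000,
    "Faserviricetes": 4_000,
}

MGE_CLASSES = ("plasmid", "satellite", "prophage", "integrase", "unclassified")


@dataclass
class RGP:
    """A contiguous flexible-genome interval with its annotation flags."""

    strain: str
    contig: str
    start: int
    end: int
    gene_ids: list[str] = field(default_factory=list)
    plasmid_origin: bool = False
    satellite_full_segment: bool = False
    viral_call: bool = False
    prophage_quality: str = "none"
    viral_gene_count: int = 0
    integrase_present: bool = False
    assigned_class: str = "unclassified"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProphagePrediction:
    element_id: str
    viral_class: str
    genome_size: int
    extrachromosomal: bool = False

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValidationError("prophage genome_size must be positive")


@dataclass
class CargoScreenSpec:
    """Identity/coverage floors for screening a cargo-gene database."""

    database_name: str
    min_identity: float   # percent
    min_coverage: float   # percent


#: screening conventions per cargo database
CARGO_SCREENS: dict[str, CargoScreenSpec] = {
    "metal": CargoScreenSpec("metal", 70.0, 50.0),
    "amr": CargoScreenSpec("amr", 30.0, 50.0),
    "virulence": CargoScreenSpec("virulence", 70.0, 50.0),
}


@dataclass
class CargoHit:
    query_id: str
    reference_id: str
    identity: float   # percent
    coverage: float   # percent of the reference aligned


def classify_persistent_families(matrix: pd.DataFrame,
                                 persistent_fraction: float = 0.90) -> pd.Series:
    """Persistent flags per gene family (prevalence >= threshold, inclusive).

    ``matrix`` is strains x families with 0/1 presence.
    """
    if matrix.empty:
        raise ValidationError("empty gene-family matrix")
    prevalence = matrix.astype(bool).mean(axis=0)
    return prevalence >= persistent_fraction


def call_rgps(gene_order: pd.DataFrame, persistent: Mapping[str, bool],
              min_span: int = 3000, min_genes: int = 3) -> list[RGP]:
    """Maximal runs of consecutive non-persistent genes per strain/contig.

    ``gene_order`` columns: strain, contig, gene_id, family_id, start, end
    (0-based half-open, sorted by start within each contig).  ``persistent``
    maps family_id to its persistence flag.
    """
    required = {"strain", "contig", "gene_id", "family_id", "start", "end"}
    if not required.issubset(gene_order.columns):
        raise ValidationError(f"gene_order must have columns {sorted(required)}")
    rgps: list[RGP] = []
    for (strain, contig), block in gene_order.groupby(["strain", "contig"],
                                                      sort=True):
        starts = block["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValidationError(
                f"genes unsorted within {strain}/{contig}")
        run: list[pd.Series] = []
        for _, gene in block.iterrows():
            if not persistent.get(gene["family_id"], False):
                run.append(gene)
                continue
            _flush_run(run, strain, contig, min_span, min_genes, rgps)
            run = []
        _flush_run(run, strain, contig, min_span, min_genes, rgps)
    return rgps


def _flush_run(run, strain, contig, min_span, min_genes, out: list[RGP]) -> None:
    if len(run) < min_genes:
        return
    start = int(run[0]["start"])
    end = int(max(g["end"] for g in run))
    if end - start < min_span:
        return
    out.append(RGP(strain=strain, contig=contig, start=start, end=end,
                   gene_ids=[g["gene_id"] for g in run]))


def classify_rgp(rgp: RGP) -> str:
    """Assign exactly one MGE class by fixed flag precedence."""
    if rgp.plasmid_origin:
        cls = "plasmid"
    elif rgp.satellite_full_segment:
        cls = "satellite"
    elif rgp.viral_call or (rgp.prophage_quality in PROPHAGE_QUALITIES
                            and rgp.viral_gene_count >= 1):
        cls = "prophage"
    elif rgp.integrase_present:
        cls = "integrase"
    else:
        cls = "unclassified"
    rgp.assigned_class = cls
    return cls


def filter_prophages(predictions: Sequence[ProphagePrediction],
                     size_floors: Mapping[str, int] | None = None
                     ) -> list[ProphagePrediction]:
    """Retain predictions strictly above their class-specific size floor;
    unknown viral classes are skipped with a warning."""
    import logging
    floors = dict(PROPHAGE_SIZE_FLOORS if size_floors is None else size_floors)
    kept = []
    for p in predictions:
        floor = floors.get(p.viral_class)
        if floor is None:
            logging.getLogger("phagehost").warning(
                "skipping prophage %s with unknown viral class %r",
                p.element_id, p.viral_class)
            continue
        if p.genome_size > floor:
            kept.append(p)
    return kept


def _local_alignment_stats(query: str, reference: str) -> tuple[float, float]:
    """(percent identity, percent reference coverage) of the best local
    protein alignment."""
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    alignments = aligner.align(query, reference)
    if len(reference) == 0:
        raise ValidationError("empty reference protein")
    try:
        best = alignments[0]
    except IndexError:
        return 0.0, 0.0
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0.0
    identity = 100.0 * counts.identities / columns
    rstart, rend = best.aligned[1][0][0], best.aligned[1][-1][1]
    coverage = 100.0 * (rend - rstart) / len(reference)
    return identity, coverage


def screen_cargo(proteins: Sequence[tuple[str, str]],
                 reference_set: Sequence[tuple[str, str]],
                 spec: CargoScreenSpec) -> list[CargoHit]:
    """Best-hit screening of query proteins against a cargo database.

    A query is a hit when its best reference alignment reaches both the
    identity and the (reference-) coverage floors; at most one hit per query.
    """
    if not reference_set:
        raise ValidationError("empty cargo reference set")
    hits: list[CargoHit] = []
    for qid, qseq in proteins:
        best: CargoHit | None = None
        for rid, rseq in sorted(reference_set):
            identity, coverage = _local_alignment_stats(qseq, rseq)
            if best is None or identity > best.identity:
                best = CargoHit(qid, rid, identity, coverage)
        if best is not None and best.identity >= spec.min_identity \
                and best.coverage >= spec.min_coverage:
            hits.append(best)
    return hits


def coding_density(n_hits: int, region_length_bp: int) -> float:
    """Cargo hits per kbp of region."""
    if region_length_bp <= 0:
        raise ValidationError("region length must be positive")
    return n_hits * 1000.0 / region_length_bp


def non_mobile_length(genome_length: int, rgps: Sequence[RGP]) -> int:
    """Length of the genome outside all RGP spans."""
    occupied = sum(r.length for r in rgps)
    if occupied > genome_length:
        raise ValidationError("RGP spans exceed genome length")
    return genome_length - occupied


@dataclass
class DensityComparison:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame      # group_a, group_b, z, p_raw, p_adjusted
    letters: dict[str, str]     # compact letter display per group


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction."""
    labels = sorted(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [groups[g].size for g in labels])
    mean_rank = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                 for i, g in enumerate(labels)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            na, nb = groups[a].size, groups[b].size
            se = math.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                           * (1.0 / na + 1.0 / nb))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def _compact_letter_display(labels: Sequence[str],
                            significant: set[tuple[str, str]],
                            medians: Mapping[str, float]) -> dict[str, str]:
    """Insert-and-absorb letters over the pairwise non-significance graph;
    groups ordered by descending median for deterministic lettering."""
    order = sorted(labels, key=lambda g: (-medians[g], g))
    letter_sets: list[set[str]] = [set(order)]
    for a, b in sorted(significant):
        nxt: list[set[str]] = []
        for ls in letter_sets:
            if a in ls and b in ls:
                nxt.append(ls - {a})
                nxt.append(ls - {b})
            else:
                nxt.append(ls)
        # absorb subsets and duplicates
        nxt.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for ls in nxt:
            if not any(ls <= other for other in kept):
                kept.append(ls)
        letter_sets = kept
    # assign letters in the order groups first appear
    letter_sets.sort(key=lambda ls: min(order.index(g) for g in ls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for i, ls in enumerate(letter_sets):
        for g in order:
            if g in ls:
                out[g] += alphabet[i % len(alphabet)]
    return out


def compare_densities(groups: Mapping[str, Sequence[float]],
                      alpha: float = 0.05) -> DensityComparison:
    """Kruskal-Wallis omnibus + Dunn/Benjamini-Hochberg pairwise comparisons
    with a compact letter display (groups share a letter iff their adjusted
    pairwise comparison is non-significant at ``alpha``)."""
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    for g, v in arrays.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
    values = [arrays[g] for g in sorted(arrays)]
    if np.ptp(np.concatenate(values)) == 0:
        h, p = 0.0, 1.0  # all observations identical: no evidence of difference
    else:
        h, p = stats.kruskal(*values)
    pairwise = _dunn_pairwise(arrays)
    pairwise["p_adjusted"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
    significant = {(r.group_a, r.group_b)
                   for r in pairwise.itertuples() if r.p_adjusted < alpha}
    medians = {g: float(np.median(v)) for g, v in arrays.items()}
    letters = _compact_letter_display(sorted(arrays), significant, medians)
    return DensityComparison(h_statistic=float(h), p_value=float(p),
                             pairwise=pairwise, letters=letters)
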