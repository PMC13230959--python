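"""Clade-diagnostic SNP scoring, SNP-proximity graph and ddPCR primer design.

A SNP is diagnostic for a target clade when the alternative allele is carried
by every called strain of the clade (sensitivity 1) and by no called strain
outside it (specificity 1).  Retained SNPs in core genes become nodes of a
proximity graph whose connected neighbourhoods delimit candidate primer
windows; primer/amplicon geometry follows the assay constraints
(25-40 bp primers, 180-300 bp amplicons, >= 2 diagnostic positions per
primer).  Thermodynamics (Tm, GC clamp, dimers) are deliberately not
modelled; candidates are flagged ``thermodynamics=unchecked``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .core import SequenceRecord, ValidationError

MISSING_CALLS = frozenset({"N", "-", ".", ""})


@dataclass
class SNPSite:
    """A scored reference position with per-clade diagnostic statistics."""

    replicon: str
    position: int  # 0-based on the reference
    ref_allele: str
    alt_allele: str
    gene_id: str = ""
    is_core: bool = True
    sensitivity: float = 0.0
    specificity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValidationError("sensitivity/specificity must lie in [0, 1]")


@dataclass
class PrimerSet:
    """Primer/probe intervals on the reference (0-based, half-open)."""

    forward: tuple[int, int]
    reverse: tuple[int, int]
    probe: tuple[int, int]
    forward_specific: int
    reverse_specific: int
    probe_specific: int

    @property
    def amplicon(self) -> tuple[int, int]:
        # measured from forward-primer start to reverse-primer end, inclusive of primers
        return (self.forward[0], self.reverse[1])

    @property
    def amplicon_length(self) -> int:
        return self.reverse[1] - self.forward[0]

    @property
    def total_specific(self) -> int:
        return self.forward_specific + self.reverse_specific


@dataclass
class PrimerConstraints:
    primer_min: int = 25
    primer_max: int = 40
    amplicon_min: int = 180
    amplicon_max: int = 300
    min_specific_per_primer: int = 2
    probe_min: int = 18
    probe_max: int = 30
    min_specific_in_probe: int = 1


def score_clade_snps(alleles: pd.DataFrame, clades: Mapping[str, str],
                     target_clade: str,
                     site_info: pd.DataFrame | None = None) -> list[SNPSite]:
    """Score every polymorphic column of a strain x position allele matrix.

    ``alleles`` is indexed by strain with one column per reference position
    (column name ``replicon:position`` or an integer position); entries are
    single bases, with ``N``/``-`` treated as missing and excluded from both
    numerator and denominator.  ``site_info``, if given, is indexed like the
    columns with ``gene_id`` and ``is_core`` fields.

    The alternative allele at each site is the modal allele among called
    target-clade strains; the reference allele is the modal allele among
    called non-target strains.
    """
    strains = list(alleles.index)
    labels = {s: clades[s] for s in strains}
    if target_clade not in set(labels.values()):
        raise ValidationError(f"clade {target_clade!r} absent from labels")
    in_target = [s for s in strains if labels[s] == target_clade]
    out_target = [s for s in strains if labels[s] != target_clade]
    if not in_target or not out_target:
        raise ValidationError("need strains both inside and outside the target clade")

    sites: list[SNPSite] = []
    for col in alleles.columns:
        calls = alleles[col].astype(str).str.upper()
        called = calls[~calls.isin(MISSING_CALLS)]
        if called.nunique() < 2:
            continue  # monomorphic or all-missing
        tgt = called.loc[called.index.intersection(in_target)]
        out = called.loc[called.index.intersection(out_target)]
        if tgt.empty or out.empty:
            continue
        alt = sorted(tgt.mode())[0]
        ref = sorted(out.mode())[0]
        sensitivity = float((tgt == alt).mean())
        specificity = float((out != alt).mean())
        if isinstance(col, str) and ":" in col:
            replicon, pos = col.rsplit(":", 1)
            position = int(pos)
        else:
            replicon, position = "chromosome", int(col)
        gene_id, is_core = "", True
        if site_info is not None and col in site_info.index:
            gene_id = str(site_info.loc[col, "gene_id"])
            is_core = bool(site_info.loc[col, "is_core"])
        sites.append(SNPSite(replicon=replicon, position=position,
                             ref_allele=ref, alt_allele=alt, gene_id=gene_id,
                             is_core=is_core, sensitivity=sensitivity,
                             specificity=specificity))
    return sites


def filter_optimal_snps(sites: Sequence[SNPSite], min_sensitivity: float = 1.0,
                        min_specificity: float = 1.0) -> list[SNPSite]:
    """Retain core-gene SNPs with optimal (default: exactly 1.0) statistics."""
    return [s for s in sites
            if s.is_core and s.sensitivity >= min_sensitivity
            and s.specificity >= min_specificity]


def build_snp_graph(sites: Sequence[SNPSite], horizon: int = 300) -> nx.Graph:
    """Proximity graph: edges join same-replicon SNPs <= horizon bp apart,
    weighted by their bp separation."""
    graph = nx.Graph()
    for i, s in enumerate(sites):
        graph.add_node(i, replicon=s.replicon, position=s.position, site=s)
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            if a.replicon != b.replicon:
                continue
            w = abs(a.position - b.position)
            if 1 <= w <= horizon:
                graph.add_edge(i, j, weight=w)
    return graph


def _candidate_windows(positions: list[int], length_range: tuple[int, int],
                       min_specific: int, ref_len: int) -> list[tuple[int, int, int]]:
    """Canonical (start, end, n_specific) windows containing at least
    ``min_specific`` diagnostic positions.

    Only windows anchored at a diagnostic position (starting on one, or
    ending immediately after one) are enumerated: any window can be shifted
    onto such an anchor without losing contained positions, so every
    achievable containment set keeps a representative with both the maximal
    count and the tightest geometry.
    """
    lo, hi = length_range
    pos = sorted(positions)
    out = set()
    for length in range(lo, hi + 1):
        starts = {p for p in pos} | {p - length + 1 for p in pos}
        for s in starts:
            if s < 0 or s + length > ref_len:
                continue
            e = s + length
            n = sum(1 for p in pos if s <= p < e)
            if n >= min_specific:
                out.add((s, e, n))
    return sorted(out)


def design_primers(graph: nx.Graph, reference: SequenceRecord,
                   constraints: PrimerConstraints | None = None,
                   max_candidates: int = 50) -> list[PrimerSet]:
    """Enumerate and rank assay candidates satisfying the positional rules.

    Ranking: total diagnostic positions covered by the two primers
    (descending), then amplicon length (ascending), then leftmost forward
    start.  Infeasible inputs give an empty list.
    """
    c = constraints or PrimerConstraints()
    positions = sorted(nx.get_node_attributes(graph, "position").values())
    if any(p >= reference.length for p in positions):
        raise ValidationError("reference does not cover all SNP positions")
    if len(positions) < 2 * c.min_specific_per_primer:
        return []
    windows = _candidate_windows(positions, (c.primer_min, c.primer_max),
                                 c.min_specific_per_primer, reference.length)
    results: list[PrimerSet] = []
    for fs, fe, fn in windows:
        for rs, re, rn in windows:
            if rs < fe:
                continue  # primers must not overlap
            amp = re - fs
            if amp < c.amplicon_min or amp > c.amplicon_max:
                continue
            probe = _best_probe(positions, fe, rs, c)
            if probe is None:
                continue
            results.append(PrimerSet(forward=(fs, fe), reverse=(rs, re),
                                     probe=probe[:2], forward_specific=fn,
                                     reverse_specific=rn, probe_specific=probe[2]))
    results.sort(key=lambda p: (-p.total_specific, p.amplicon_length,
                                p.forward[0], p.reverse[0]))
    return results[:max_candidates]


def _best_probe(positions: list[int], gap_start: int, gap_end: int,
                c: PrimerConstraints) -> tuple[int, int, int] | None:
    """Best 18-30 bp probe window strictly between the primers, maximising
    contained diagnostic positions (at least one required)."""
    best: tuple[int, int, int] | None = None
    inner = [p for p in positions if gap_start <= p < gap_end]
    if gap_end - gap_start < c.probe_min:
        return None
    if not inner and c.min_specific_in_probe > 0:
        return None
    starts = sorted({s for p in inner
                     for s in (p, p - c.probe_max + 1)} | {gap_start})
    for s in starts:
        if s < gap_start:
            s = gap_start
        for length in range(c.probe_min, c.probe_max + 1):
            e = s + length
            if e > gap_end:
                break
            n = sum(1 for p in inner if s <= p < e)
            if n < c.min_specific_in_probe:
                continue
            if best is None or n > best[2]:
                best = (s, e, n)
    return best


def select_phage_marker_genes(presence: pd.DataFrame,
                              target_set: Sequence[str]) -> list[str]:
    """Gene families present in all phages of ``target_set`` and absent from
    every other phage (presence/absence marker genes)."""
    targets = list(target_set)
    if not targets:
        raise ValidationError("target set is empty")
    missing = set(targets) - set(presence.index)
    if missing:
        raise ValidationError(f"unknown phage ids: {sorted(missing)}")
    others = presence.index.difference(targets)
    if len(others) == 0:
        raise ValidationError("target set covers every phage")
    mat = presence.astype(bool)
    in_all = mat.loc[targets].all(axis=0)
    in_none = ~mat.loc[others].any(axis=0)
    return sorted(mat.columns[in_all & in_none])
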