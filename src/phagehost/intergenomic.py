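"""Pairwise intergenomic similarity, genus/species clustering and SNP distances.

The similarity of two genomes is the fraction of identically aligned
nucleotides normalised by the sum of the genome lengths,

    sim(a, b) = 100 * (I_ab + I_ba) / (L_a + L_b),

where ``I_xy`` counts identical positions over a non-overlapping set of local
alignment fragments of ``x`` against ``y``.  Genomes are clustered into
genera (similarity >= 70) and species (>= 95) by complete linkage on the
distance ``100 - sim``, the two ranks being two cuts of one dendrogram so
that species always nest inside genera.

The alignment engine is a deterministic seed-and-extend over exact k-mer
anchors (k = 11 by default) chained along diagonals, with greedy
non-overlapping fragment selection by descending identical-position count.
It targets substitution-level divergence on co-linear genomes (forward
strand); it is not a general-purpose aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import SequenceRecord, ValidationError

ACGT = frozenset("ACGT")

#: fragments shorter than this never contribute identical positions
DEFAULT_FRAGMENT_FLOOR = 30
DEFAULT_K = 11
#: anchors on one diagonal separated by at most this many bp are chained
DEFAULT_CHAIN_GAP = 100
#: k-mers occurring more often than this in the subject are ignored
MAX_KMER_HITS = 50


@dataclass
class AlignmentFragment:
    """An ungapped local alignment fragment on one diagonal."""

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    identical_positions: int

    def __post_init__(self) -> None:
        qlen = self.query_end - self.query_start
        slen = self.subject_end - self.subject_start
        if self.identical_positions > min(qlen, slen):
            raise ValidationError("identical_positions exceeds fragment length")


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValidationError("similarity matrix diagonal must be 100")
        if v.min() < -1e-9 or v.max() > 100 + 1e-9:
            raise ValidationError("similarities must lie in [0, 100]")
        self.values = np.clip(v, 0.0, 100.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class TaxonAssignment:
    """Genus/species membership per genome, species nested within genera."""

    assignments: pd.DataFrame  # genome_id, genus_id, species_id, genus/species singleton

    def __post_init__(self) -> None:
        df = self.assignments
        # every species must live wholly inside one genus
        n_genera = df.groupby("species_id")["genus_id"].nunique()
        if (n_genera > 1).any():
            raise ValidationError("species partition does not refine genus partition")

    @property
    def n_genera(self) -> int:
        return self.assignments["genus_id"].nunique()

    @property
    def n_species(self) -> int:
        return self.assignments["species_id"].nunique()


def _count_identical(a: str, b: str, a_start: int, a_end: int, offset: int) -> int:
    """Identical A/C/G/T positions of a[a_start:a_end] vs b shifted by offset."""
    n = 0
    for i in range(a_start, a_end):
        ca = a[i]
        cb = b[i - offset]
        if ca == cb and ca in ACGT:
            n += 1
    return n


def _collect_fragments(query: str, subject: str, k: int, chain_gap: int,
                       floor: int) -> list[AlignmentFragment]:
    """Chain exact k-mer anchors per diagonal into candidate fragments."""
    lq, ls = len(query), len(subject)
    if lq < k or ls < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(ls - k + 1):
        kmer = subject[j:j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    diagonals: dict[int, list[int]] = {}
    for i in range(lq - k + 1):
        kmer = query[i:i + k]
        if "N" in kmer:
            continue
        hits = index.get(kmer)
        if hits is None or len(hits) > MAX_KMER_HITS:
            continue
        for j in hits:
            diagonals.setdefault(i - j, []).append(i)
    fragments: list[AlignmentFragment] = []
    for d, starts in diagonals.items():
        starts.sort()
        run_start = starts[0]
        run_end = starts[0] + k
        runs = []
        for s in starts[1:]:
            if s <= run_end + chain_gap:
                run_end = max(run_end, s + k)
            else:
                runs.append((run_start, run_end))
                run_start, run_end = s, s + k
        runs.append((run_start, run_end))
        for qs, qe in runs:
            # extend ends through any exact matches the anchors missed
            while qs > 0 and qs - d > 0 and query[qs - 1] == subject[qs - 1 - d] \
                    and query[qs - 1] in ACGT:
                qs -= 1
            while qe < lq and qe - d < ls and query[qe] == subject[qe - d] \
                    and query[qe] in ACGT:
                qe += 1
            if qe - qs < floor:
                continue
            ident = _count_identical(query, subject, qs, qe, d)
            if ident == 0:
                continue
            fragments.append(AlignmentFragment(qs, qe, qs - d, qe - d, ident))
    return fragments


def _subtract(interval: tuple[int, int], covered: list[tuple[int, int]]):
    """Yield the sub-intervals of `interval` not covered by any in `covered`."""
    start, end = interval
    pieces = [(start, end)]
    for cs, ce in covered:
        nxt = []
        for ps, pe in pieces:
            if ce <= ps or cs >= pe:
                nxt.append((ps, pe))
                continue
            if ps < cs:
                nxt.append((ps, cs))
            if ce < pe:
                nxt.append((ce, pe))
        pieces = nxt
        if not pieces:
            break
    return pieces


def aligned_identity_count(query: str, subject: str, k: int = DEFAULT_K,
                           chain_gap: int = DEFAULT_CHAIN_GAP,
                           floor: int = DEFAULT_FRAGMENT_FLOOR) -> int:
    """Total identical positions of query vs subject over a greedy
    non-overlapping fragment set (descending identical-count order; later
    fragments trimmed to the uncovered remainder and recounted)."""
    fragments = _collect_fragments(query, subject, k, chain_gap, floor)
    fragments.sort(key=lambda f: (-f.identical_positions, f.query_start,
                                  f.subject_start))
    covered_q: list[tuple[int, int]] = []
    covered_s: list[tuple[int, int]] = []
    total = 0
    for frag in fragments:
        d = frag.query_start - frag.subject_start
        pieces = _subtract((frag.query_start, frag.query_end), covered_q)
        remaining: list[tuple[int, int]] = []
        for ps, pe in pieces:
            remaining.extend(
                (ss + d, se + d)
                for ss, se in _subtract((ps - d, pe - d), covered_s))
        if not remaining:
            continue
        qs, qe = max(remaining, key=lambda iv: iv[1] - iv[0])
        if qe - qs < floor:
            continue
        ident = _count_identical(query, subject, qs, qe, d)
        if ident == 0:
            continue
        total += ident
        covered_q.append((qs, qe))
        covered_s.append((qs - d, qe - d))
    return total


def pairwise_intergenomic_similarity(a: SequenceRecord, b: SequenceRecord,
                                     k: int = DEFAULT_K,
                                     chain_gap: int = DEFAULT_CHAIN_GAP,
                                     floor: int = DEFAULT_FRAGMENT_FLOOR) -> float:
    """Percent intergenomic similarity of two genomes in [0, 100]."""
    if a.length == 0 or b.length == 0:
        raise ValidationError("cannot compare empty sequences")
    if a.sequence == b.sequence:
        return 100.0
    i_ab = aligned_identity_count(a.sequence, b.sequence, k, chain_gap, floor)
    i_ba = aligned_identity_count(b.sequence, a.sequence, k, chain_gap, floor)
    sim = 100.0 * (i_ab + i_ba) / (a.length + b.length)
    return float(min(sim, 100.0))


def similarity_matrix(genomes: list[SequenceRecord], **kwargs) -> SimilarityMatrix:
    if len(genomes) < 2:
        raise ValidationError("need at least two genomes")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate genome ids")
    n = len(genomes)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = pairwise_intergenomic_similarity(genomes[i], genomes[j], **kwargs)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids=ids, values=values)


def _label_partition(ids: list[str], flat: np.ndarray, prefix: str) -> dict[str, str]:
    """Deterministic cluster labels ordered by lexicographically smallest member."""
    members: dict[int, list[str]] = {}
    for gid, cl in zip(ids, flat):
        members.setdefault(int(cl), []).append(gid)
    order = sorted(members, key=lambda cl: min(members[cl]))
    label = {cl: f"{prefix}{i + 1}" for i, cl in enumerate(order)}
    return {gid: label[int(cl)] for gid, cl in zip(ids, flat)}


def cluster_taxa(matrix: SimilarityMatrix, genus_threshold: float = 70.0,
                 species_threshold: float = 95.0) -> TaxonAssignment:
    """Complete-linkage genus/species assignment from one dendrogram.

    Membership at a rank requires similarity >= threshold for ALL pairs in
    the cluster (complete linkage on distance 100 - similarity, cut at
    100 - threshold, inclusive).
    """
    if not (0 <= genus_threshold <= species_threshold <= 100):
        raise ValidationError("need 0 <= genus_threshold <= species_threshold <= 100")
    dist = 100.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="complete")
    genus_flat = fcluster(tree, t=100.0 - genus_threshold, criterion="distance")
    species_flat = fcluster(tree, t=100.0 - species_threshold, criterion="distance")
    genus = _label_partition(matrix.ids, genus_flat, "G")
    species = _label_partition(matrix.ids, species_flat, "S")
    df = pd.DataFrame({
        "genome_id": matrix.ids,
        "genus_id": [genus[g] for g in matrix.ids],
        "species_id": [species[g] for g in matrix.ids],
    })
    genus_sizes = df["genus_id"].value_counts()
    species_sizes = df["species_id"].value_counts()
    df["genus_singleton"] = df["genus_id"].map(genus_sizes).eq(1)
    df["species_singleton"] = df["species_id"].map(species_sizes).eq(1)
    return TaxonAssignment(assignments=df)


def snp_distance(aligned_a: str, aligned_b: str) -> int:
    """SNPs between two aligned sequences; gap and N columns are excluded."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned sequences must have equal length")
    a, b = aligned_a.upper(), aligned_b.upper()
    return sum(1 for ca, cb in zip(a, b)
               if ca in ACGT and cb in ACGT and ca != cb)
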