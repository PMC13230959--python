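"""Weighted gene repertoire relatedness (wGRR) and plasmid inference.

wGRR between two gene repertoires A and B is

    wGRR(A, B) = 100 * sum_{(p,q) in BBH} id(p, q) / min(|A|, |B|),

where the sum runs over bidirectional best hits (each protein used at most
once) and ``id`` is the global-alignment protein identity in [0, 1].  A
plasmid family is called present in a strain when its best wGRR against the
family's references is strictly greater than 50; the argmax reference is the
most closely related plasmid.  Element copy number is the mean read depth of
the element normalised by the mean chromosomal depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ValidationError

logger = logging.getLogger("phagehost")

#: candidate hits below this identity are discarded before BBH resolution
DEFAULT_IDENTITY_FLOOR = 0.35


@dataclass
class ProteinRepertoire:
    """The ordered protein complement of one genetic element."""

    element_id: str
    proteins: list[tuple[str, str]]  # (protein_id, amino-acid sequence)

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"duplicate protein ids in repertoire {self.element_id!r}")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class WGRRResult:
    pair: tuple[str, str]
    bbh_pairs: list[tuple[str, str, float]]
    wgrr_percent: float


@dataclass
class PlasmidCall:
    strain: str
    family: str
    present: bool
    closest_reference: str | None
    wgrr_percent: float


def global_identity(a: str, b: str) -> float:
    """Global protein alignment identity: matches / alignment columns."""
    if not a or not b:
        raise ValidationError("cannot align empty protein sequences")
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    best = aligner.align(a, b)[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def bidirectional_best_hits(a: ProteinRepertoire, b: ProteinRepertoire,
                            identity_floor: float = DEFAULT_IDENTITY_FLOOR
                            ) -> list[tuple[str, str, float]]:
    """BBH pairs between two repertoires with their identities.

    A pair (p, q) is kept iff q is p's unique best-identity hit in b and p is
    q's unique best in a, both at or above the identity floor.  Ties are
    broken by lexicographic protein ID so results are deterministic.
    """
    if len(a) == 0 or len(b) == 0:
        logger.warning("empty repertoire in BBH: %s vs %s",
                       a.element_id, b.element_id)
        return []
    ident: dict[tuple[str, str], float] = {}
    for pid, pseq in a.proteins:
        for qid, qseq in b.proteins:
            v = global_identity(pseq, qseq)
            if v >= identity_floor:
                ident[(pid, qid)] = v

    def best_of(source_ids, partner_axis):
        best = {}
        for (pid, qid), v in ident.items():
            key, partner = (pid, qid) if partner_axis == 1 else (qid, pid)
            cur = best.get(key)
            if cur is None or v > cur[1] or (v == cur[1] and partner < cur[0]):
                best[key] = (partner, v)
        return best

    best_a = best_of([pid for pid, _ in a.proteins], partner_axis=1)
    best_b = best_of([qid for qid, _ in b.proteins], partner_axis=0)
    pairs = []
    for pid, (qid, v) in sorted(best_a.items()):
        back = best_b.get(qid)
        if back is not None and back[0] == pid:
            pairs.append((pid, qid, v))
    # partial-matching guarantee: no protein appears twice
    assert len({p for p, _, _ in pairs}) == len(pairs)
    assert len({q for _, q, _ in pairs}) == len(pairs)
    return pairs


def wgrr(a: ProteinRepertoire, b: ProteinRepertoire,
         identity_floor: float = DEFAULT_IDENTITY_FLOOR) -> WGRRResult:
    """Weighted gene repertoire relatedness of two repertoires (percent)."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("wGRR requires non-empty repertoires")
    pairs = bidirectional_best_hits(a, b, identity_floor)
    score = 100.0 * sum(v for _, _, v in pairs) / min(len(a), len(b))
    return WGRRResult(pair=(a.element_id, b.element_id), bbh_pairs=pairs,
                      wgrr_percent=float(min(score, 100.0)))


def plasmid_presence(strain_repertoire: ProteinRepertoire,
                     references: Sequence[ProteinRepertoire],
                     family: str = "", threshold: float = 50.0,
                     identity_floor: float = DEFAULT_IDENTITY_FLOOR) -> PlasmidCall:
    """Presence call: present iff max wGRR over references is strictly above
    the threshold; closest reference is the argmax (lexicographic on ties)."""
    if not references:
        raise ValidationError("at least one reference plasmid required")
    scores = {ref.element_id: wgrr(strain_repertoire, ref, identity_floor).wgrr_percent
              for ref in references}
    best_score = max(scores.values())
    best_ids = sorted(rid for rid, s in scores.items() if s == best_score)
    if len(best_ids) > 1:
        logger.info("wGRR tie among references %s; keeping %s",
                    best_ids, best_ids[0])
    present = best_score > threshold
    return PlasmidCall(strain=strain_repertoire.element_id, family=family,
                       present=present,
                       closest_reference=best_ids[0] if present else None,
                       wgrr_percent=float(best_score))


def copy_number(element_depths: Sequence[float] | float,
                chromosome_mean_depth: float) -> float:
    """Element copy number relative to the chromosome (depth ratio)."""
    if chromosome_mean_depth <= 0:
        raise ValidationError("chromosome mean depth must be positive")
    mean_depth = float(np.mean(np.asarray(element_depths, dtype=float)))
    return mean_depth / chromosome_mean_depth
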