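"""Mendelian trio-consistency scoring of HLA genotypes.

Each child genotype is scored against its parents at a chosen field
resolution with a three-level point system: 1 when the child's alleles
admit a biparental assignment (one allele traceable to each parent), 0.5
when no biparental assignment exists but at least one child allele matches
a parental allele, and 0 when neither child allele matches either parent.
Per-locus percentages are the mean score over evaluable trios, times 100.

Trios with a ``Not typed`` slot in any member at a locus are excluded from
that locus's denominator (dropout makes the trio unevaluable there); a
locus missing from a member's assay is likewise excluded.  Exclusion is
per locus and per family — a family excluded at one locus still counts
everywhere else.

The copy-number-variable DRB3/4/5 loci need a relaxed rule: tools render a
hemizygous paralog as a homozygote, so a child whose single secondary-DRB
allele came from one parent (the other haplotype carrying a different
paralog or none) is Mendelian-consistent even though the strict diploid
rule would award only half a point.  Those loci — and the pooled DRB345
unit — are therefore scored on allele multisets: a child with one distinct
allele scores 1 if it matches either parent's set, and a child with two
distinct alleles needs one traceable to each parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .nomenclature import (
    COPY_NUMBER_VARIABLE,
    REPORT_LOCI,
    AlleleCall,
    Resolution,
    alleles_match,
)
from .typing_io import (
    ConsistencyRow,
    ConsistencyTable,
    GenotypeCall,
    SampleTyping,
    TrioRecord,
    pool_drb345,
)


class ExclusionReason(str, Enum):
    not_typed_member = "not_typed_member"
    locus_not_assayed = "locus_not_assayed"


@dataclass(frozen=True)
class TrioScore:
    family_id: str
    locus: str
    resolution: int
    score: Optional[float]
    included: bool
    exclusion_reason: Optional[ExclusionReason] = None

    def __post_init__(self) -> None:
        if self.included:
            if self.score not in (0.0, 0.5, 1.0):
                raise ValueError(f"invalid trio score {self.score}")
        elif self.score is not None:
            raise ValueError("excluded trio carries no score")


def _match(a: AlleleCall, b: AlleleCall, r: Resolution) -> bool:
    """Resolution-aware match that treats cross-paralog pairs as unequal
    instead of raising (needed when comparing pooled DRB3/4/5 sets)."""
    if a.locus != b.locus:
        return False
    return alleles_match(a, b, r)


def score_trio_locus(child: GenotypeCall, father: GenotypeCall,
                     mother: GenotypeCall, r: Resolution) -> float:
    """Score a regular (diploid) locus: 1 / 0.5 / 0.

    All three genotypes must be fully typed (callers exclude otherwise).
    A homozygous child must trace one copy to each parent: matching only
    one parent scores 0.5, because each parent transmits exactly one
    haplotype.
    """
    for g in (child, father, mother):
        if g.locus != child.locus:
            raise ValueError("trio genotypes must share a locus")
        if g.any_not_typed:
            raise ValueError(
                f"{g.locus.name}: not-typed slot in trio scoring; "
                "the family should have been excluded")
    c1, c2 = child.alleles
    pat = father.alleles
    mat = mother.alleles
    c1_pat = any(_match(c1, p, r) for p in pat)
    c1_mat = any(_match(c1, m, r) for m in mat)
    c2_pat = any(_match(c2, p, r) for p in pat)
    c2_mat = any(_match(c2, m, r) for m in mat)
    if (c1_pat and c2_mat) or (c2_pat and c1_mat):
        return 1.0
    if c1_pat or c1_mat or c2_pat or c2_mat:
        return 0.5
    return 0.0


def _distinct(alleles: Sequence[AlleleCall]) -> List[AlleleCall]:
    out: List[AlleleCall] = []
    for a in alleles:
        if a not in out:
            out.append(a)
    return out


def score_trio_unit(child: Sequence[AlleleCall], father: Sequence[AlleleCall],
                    mother: Sequence[AlleleCall], r: Resolution) -> float:
    """Score copy-number-aware allele multisets (DRB345 unit, or one
    DRB3/4/5 locus).

    Duplicate child alleles are collapsed first (a reported homozygote may
    be a rendered hemizygote).  A child with no alleles is consistent with
    two null haplotypes (score 1); with one distinct allele it scores 1
    when the allele matches either parent's set (the other haplotype may
    carry no secondary-DRB gene); with two or more distinct alleles a
    biparental assignment of two of them is required for 1, any single
    parental match gives 0.5, none gives 0.
    """
    cs = _distinct(child)
    pat = list(father)
    mat = list(mother)
    if not cs:
        return 1.0
    any_hit = any(_match(c, p, r) for c in cs for p in (*pat, *mat))
    if len(cs) == 1:
        return 1.0 if any_hit else 0.0
    for i, ca in enumerate(cs):
        for cb in cs[:i] + cs[i + 1:]:
            if (any(_match(ca, p, r) for p in pat)
                    and any(_match(cb, m, r) for m in mat)):
                return 1.0
    return 0.5 if any_hit else 0.0


def _unit_alleles(g: GenotypeCall) -> Tuple[AlleleCall, ...]:
    return g.typed_alleles


def exclude_family(trio: TrioRecord, typings: Mapping[str, SampleTyping],
                   locus: str) -> Optional[ExclusionReason]:
    """Exclusion rule for one family at one locus.

    ``locus_not_assayed`` when any member lacks the locus entirely (e.g.
    non-targeted genes on a panel); ``not_typed_member`` when any member's
    genotype has a not-typed slot.  The pooled DRB345 unit needs complete
    typing for all members in a weaker sense: a fully not-typed paralog
    next to a typed one is plausible gene absence and is kept, but a
    member with a *partially* typed paralog genotype (one typed, one
    dropped slot), or with no typed secondary-DRB allele at all, makes the
    trio unevaluable there.
    """
    members = [typings[sid] for sid in trio.member_ids()]
    if locus == "DRB345":
        for s in members:
            paralogs = [s.calls[n] for n in COPY_NUMBER_VARIABLE
                        if n in s.calls]
            if not paralogs:
                return ExclusionReason.locus_not_assayed
            if not any(g.typed_alleles for g in paralogs):
                return ExclusionReason.not_typed_member
            for g in paralogs:
                if g.any_not_typed and g.typed_alleles:
                    return ExclusionReason.not_typed_member
        return None
    for s in members:
        g = s.calls.get(locus)
        if g is None:
            return ExclusionReason.locus_not_assayed
        if g.any_not_typed:
            return ExclusionReason.not_typed_member
    return None


def consistency_percentage(scores: Sequence[TrioScore]
                           ) -> Tuple[Optional[float], int]:
    """Weighted percentage over included trios; ``(None, 0)`` when no trio
    is evaluable."""
    if scores:
        loci = {s.locus for s in scores}
        ks = {s.resolution for s in scores}
        if len(loci) > 1 or len(ks) > 1:
            raise ValueError(
                "scores must share one locus and one resolution, got "
                f"loci={sorted(loci)} resolutions={sorted(ks)}")
    included = [s for s in scores if s.included]
    if not included:
        return None, 0
    total = sum(s.score for s in included)
    return 100.0 * total / len(included), len(included)


def score_trio_at_locus(trio: TrioRecord,
                        typings: Mapping[str, SampleTyping],
                        locus: str, r: Resolution) -> TrioScore:
    """Exclusion check plus scoring for one family/locus/resolution."""
    reason = exclude_family(trio, typings, locus)
    if reason is not None:
        return TrioScore(trio.family_id, locus, r.k, None, False, reason)
    child = typings[trio.child_id]
    father = typings[trio.father_id]
    mother = typings[trio.mother_id]
    if locus == "DRB345" or locus in COPY_NUMBER_VARIABLE:
        score = score_trio_unit(
            _unit_alleles(child.calls[locus]),
            _unit_alleles(father.calls[locus]),
            _unit_alleles(mother.calls[locus]), r)
    else:
        score = score_trio_locus(child.calls[locus], father.calls[locus],
                                 mother.calls[locus], r)
    return TrioScore(trio.family_id, locus, r.k, score, True)


def evaluate_trios(typings: Mapping[str, SampleTyping],
                   trios: Sequence[TrioRecord],
                   loci: Optional[Sequence[str]] = None,
                   drb345_unit: bool = True,
                   dataset_label: str = "",
                   ) -> Tuple[ConsistencyTable, List[TrioScore]]:
    """Score every family at every locus and resolution.

    Returns the per-locus consistency table (resolutions 1-3) and the full
    per-trio audit trail, including exclusion records.  With
    ``drb345_unit`` the pooled DRB345 row is appended after the per-locus
    rows.
    """
    if loci is None:
        assayed = {n for s in typings.values() for n in s.calls}
        loci = [n for n in REPORT_LOCI if n in assayed]
    if drb345_unit:
        typings = {sid: pool_drb345(s) for sid, s in typings.items()}
        loci = [*loci, "DRB345"]
    missing = [sid for t in trios for sid in t.member_ids()
               if sid not in typings]
    if missing:
        raise ValueError(f"pedigree references unknown samples: "
                         f"{sorted(set(missing))}")
    rows: List[ConsistencyRow] = []
    audit: List[TrioScore] = []
    for locus in loci:
        pcts: List[Optional[float]] = []
        n_fam = 0
        for k in (1, 2, 3):
            scores = [score_trio_at_locus(t, typings, locus, Resolution(k))
                      for t in trios]
            audit.extend(scores)
            pct, n_fam = consistency_percentage(scores)
            pcts.append(pct)
        rows.append(ConsistencyRow(locus, tuple(pcts), n_fam))
    return ConsistencyTable(rows, dataset_label), audit


def audit_frame(audit: Sequence[TrioScore]):
    """Audit trail as a DataFrame (one row per family/locus/resolution)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "family": [a.family_id for a in audit],
            "locus": [a.locus for a in audit],
            "resolution": [a.resolution for a in audit],
            "score": [a.score for a in audit],
            "included": [a.included for a in audit],
            "exclusion_reason": [
                a.exclusion_reason.value if a.exclusion_reason else ""
                for a in audit],
        }
    )
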