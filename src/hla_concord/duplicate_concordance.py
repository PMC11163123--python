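"""Allele-level concordance between two typings of the same sample.

Duplicate samples (the same DNA typed on two assays, or by two tools) are
scored per locus and resolution as the size of a maximum matching between
the two genotypes' allele slots, divided by the slot count: identical
genotypes score 1, one agreeing slot scores 0.5, none 0.  Slot order in
call files is arbitrary, so matching — not positional comparison — is
used.  ``Not typed`` slots participate and match only ``Not typed`` slots:
concordant absence is agreement, which is why duplicate pairs are never
excluded for dropout (unlike trio families).

Loci absent from one dataset's assay design are skipped entirely rather
than scored 0 (an amplicon panel is only comparable on its targeted loci).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import List, Mapping, Optional, Sequence, Tuple

from .nomenclature import (
    REPORT_LOCI,
    AlleleCall,
    Resolution,
    alleles_match,
)
from .typing_io import (
    ConsistencyRow,
    ConsistencyTable,
    DuplicatePair,
    GenotypeCall,
    SampleTyping,
)


@dataclass(frozen=True)
class PairScore:
    sample_id_a: str
    sample_id_b: str
    locus: str
    resolution: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"pair score {self.score} out of [0, 1]")


def _slot_match(a: AlleleCall, b: AlleleCall, r: Resolution) -> bool:
    if a.locus != b.locus:
        return False
    return alleles_match(a, b, r)


def match_fraction(a_slots: Sequence[AlleleCall],
                   b_slots: Sequence[AlleleCall], r: Resolution) -> float:
    """Maximum-matching agreement between two slot lists, in [0, 1].

    The denominator is the larger slot count, so unmatched extra alleles
    count as disagreement; two empty lists agree perfectly.  Slot lists
    are tiny (2 for regular genotypes, 0-4 for pooled units), so an exact
    permutation search is used.
    """
    n_a, n_b = len(a_slots), len(b_slots)
    if n_a == 0 and n_b == 0:
        return 1.0
    if n_a > n_b:
        a_slots, b_slots = b_slots, a_slots
        n_a, n_b = n_b, n_a
    best = 0
    for perm in permutations(range(n_b), n_a):
        hits = sum(
            1 for i, j in enumerate(perm)
            if _slot_match(a_slots[i], b_slots[j], r))
        best = max(best, hits)
    return best / n_b


def score_pair_locus(a: GenotypeCall, b: GenotypeCall, r: Resolution,
                     sample_id_a: str = "", sample_id_b: str = ""
                     ) -> PairScore:
    """Score one locus of one duplicate pair."""
    if a.locus != b.locus:
        raise ValueError(
            f"cannot score pair across loci ({a.locus.name} vs "
            f"{b.locus.name})")
    frac = match_fraction(a.alleles, b.alleles, r)
    return PairScore(sample_id_a, sample_id_b, a.locus.name, r.k, frac)


def concordance_percentage(scores: Sequence[PairScore]
                           ) -> Tuple[Optional[float], int]:
    """Mean pair score times 100; ``(None, 0)`` with no scored pairs."""
    if not scores:
        return None, 0
    loci = {s.locus for s in scores}
    ks = {s.resolution for s in scores}
    if len(loci) > 1 or len(ks) > 1:
        raise ValueError(
            "scores must share one locus and one resolution, got "
            f"loci={sorted(loci)} resolutions={sorted(ks)}")
    return 100.0 * sum(s.score for s in scores) / len(scores), len(scores)


def evaluate_pairs(typings_a: Mapping[str, SampleTyping],
                   typings_b: Mapping[str, SampleTyping],
                   pairs: Sequence[DuplicatePair],
                   loci: Optional[Sequence[str]] = None,
                   dataset_label: str = "",
                   ) -> Tuple[ConsistencyTable, List[PairScore]]:
    """Score every duplicate pair at every shared locus and resolution.

    A locus enters a pair's scoring only when both typings assay it; a
    locus row is emitted when at least one pair could be scored there (or
    as an NA row if it was requested explicitly via ``loci``).
    """
    missing = [p.sample_id_a for p in pairs if p.sample_id_a not in typings_a]
    missing += [p.sample_id_b for p in pairs if p.sample_id_b not in typings_b]
    if missing:
        raise ValueError(
            f"pairing file references unknown samples: {sorted(set(missing))}")
    if loci is None:
        assayed_a = {n for s in typings_a.values() for n in s.calls}
        assayed_b = {n for s in typings_b.values() for n in s.calls}
        loci = [n for n in REPORT_LOCI if n in assayed_a and n in assayed_b]
    rows: List[ConsistencyRow] = []
    audit: List[PairScore] = []
    for locus in loci:
        pcts: List[Optional[float]] = []
        n_pairs = 0
        for k in (1, 2, 3):
            scores = []
            for p in pairs:
                ga = typings_a[p.sample_id_a].calls.get(locus)
                gb = typings_b[p.sample_id_b].calls.get(locus)
                if ga is None or gb is None:
                    continue  # not assayed in one dataset: skipped, not 0
                scores.append(score_pair_locus(
                    ga, gb, Resolution(k), p.sample_id_a, p.sample_id_b))
            audit.extend(scores)
            pct, n_pairs = concordance_percentage(scores)
            pcts.append(pct)
        rows.append(ConsistencyRow(locus, tuple(pcts), n_pairs))
    return ConsistencyTable(rows, dataset_label), audit


@dataclass(frozen=True)
class Discrepancy:
    """One pair/locus/resolution where the two typings disagree."""

    sample_id_a: str
    sample_id_b: str
    locus: str
    resolution: int
    score: float
    alleles_a: Tuple[str, ...]
    alleles_b: Tuple[str, ...]


def list_discrepancies(typings_a: Mapping[str, SampleTyping],
                       typings_b: Mapping[str, SampleTyping],
                       audit: Sequence[PairScore]) -> List[Discrepancy]:
    """Expand every non-perfect pair score into a discrepancy record."""
    out = []
    for s in audit:
        if s.score >= 1.0:
            continue
        ga = typings_a[s.sample_id_a].calls[s.locus]
        gb = typings_b[s.sample_id_b].calls[s.locus]
        out.append(Discrepancy(
            s.sample_id_a, s.sample_id_b, s.locus, s.resolution, s.score,
            tuple(a.name() for a in ga.alleles),
            tuple(b.name() for b in gb.alleles)))
    return out
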