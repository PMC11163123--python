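"""Shared builders and independent scoring oracles for the test suite.

The oracles here deliberately re-derive scores by exhaustive enumeration
over parental transmissions / slot orderings, independently of the
implementation's shortcut logic.
"""

from itertools import permutations

from hla_concord.nomenclature import (
    AlleleCall,
    Resolution,
    alleles_match,
    get_locus,
    parse_allele,
)
from hla_concord.typing_io import GenotypeCall


def allele(text, locus=None):
    hint = get_locus(locus) if locus else None
    if text in ("NT", "Not typed"):
        return AlleleCall.make_not_typed(hint)
    return parse_allele(text, locus_hint=hint)


def geno(locus_name, s1, s2):
    locus = get_locus(locus_name)
    return GenotypeCall(
        locus, (allele(s1, locus_name), allele(s2, locus_name)))


def _m(a, b, r):
    if a.locus != b.locus:
        return False
    return alleles_match(a, b, r)


def oracle_trio_score(child, father, mother, r):
    """Exhaustive enumeration over parental transmissions.

    A trio is fully consistent iff some ordered pair (paternal allele,
    maternal allele) covers the child's two slots in some order; half
    consistent iff any child allele matches any parental allele.
    """
    c = child.alleles
    for cp, cm in ((c[0], c[1]), (c[1], c[0])):
        for f in father.alleles:
            for m in mother.alleles:
                if _m(cp, f, r) and _m(cm, m, r):
                    return 1.0
    parental = (*father.alleles, *mother.alleles)
    if any(_m(ci, p, r) for ci in c for p in parental):
        return 0.5
    return 0.0


def oracle_pair_score(a, b, r):
    """Best agreement over all slot orderings of both genotypes."""
    n = max(len(a.alleles), len(b.alleles))
    if n == 0:
        return 1.0
    best = 0
    for pa in permutations(a.alleles):
        for pb in permutations(b.alleles):
            hits = sum(1 for x, y in zip(pa, pb) if _m(x, y, r))
            best = max(best, hits)
    return best / n


def random_toy_allele(rng, locus_name="A"):
    """Small allele universe with mixed 2- and 3-field depths so matches
    collide at some resolutions and not others."""
    locus = get_locus(locus_name)
    f1 = f"{int(rng.integers(1, 4)):02d}"
    f2 = f"{int(rng.integers(1, 3)):02d}"
    if int(rng.integers(0, 2)):
        return AlleleCall.make_typed(locus, (f1, f2))
    f3 = f"{int(rng.integers(1, 3)):02d}"
    return AlleleCall.make_typed(locus, (f1, f2, f3))


def random_toy_genotype(rng, locus_name="A"):
    locus = get_locus(locus_name)
    return GenotypeCall(locus, (random_toy_allele(rng, locus_name),
                                random_toy_allele(rng, locus_name)))


def resolutions():
    return [Resolution(k) for k in (1, 2, 3)]
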