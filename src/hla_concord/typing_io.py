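"""File formats and in-memory containers for HLA typing call data.

All formats are tab-separated UTF-8 text; lines starting with ``#`` are
comments.  Two typing dialects are supported:

* the HLA-HD final-result dialect — one locus per line,
  ``locus<TAB>allele1<TAB>allele2``, where ``-`` in the second slot marks
  homozygosity (expanded to a second copy of slot 1 on read);
* a generic long-format TSV — header ``sample locus allele1 allele2``,
  where ``-`` means not typed (the generic dialect has no homozygosity
  shorthand, so it stays unambiguous).

A locus absent from a file is *not assayed* (e.g. non-targeted genes on an
amplicon panel) and is distinct from a locus reported ``Not typed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .nomenclature import (
    DRB345,
    COPY_NUMBER_VARIABLE,
    AlleleCall,
    Locus,
    NomenclatureError,
    get_locus,
    parse_allele,
)


class TypingIOError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclass(frozen=True)
class GenotypeCall:
    """The allele calls of one sample at one locus.

    Regular loci carry exactly two slots.  The DRB345 pooling unit carries
    a variable-length multiset (0-2 alleles for clean data; more only for
    artifactual inputs) of typed calls pooled from DRB3/DRB4/DRB5.
    """

    locus: Locus
    alleles: Tuple[AlleleCall, ...]
    origin_dataset: str = ""

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a.locus != self.locus and not (
                    self.locus == DRB345
                    and a.locus.name in COPY_NUMBER_VARIABLE):
                raise TypingIOError(
                    f"allele at {a.locus.name} in genotype at "
                    f"{self.locus.name}")
        if self.locus != DRB345 and len(self.alleles) != 2:
            raise TypingIOError(
                f"{self.locus.name}: regular genotype needs 2 slots, "
                f"got {len(self.alleles)}")

    @property
    def slot1(self) -> AlleleCall:
        return self.alleles[0]

    @property
    def slot2(self) -> AlleleCall:
        return self.alleles[1]

    @property
    def typed_alleles(self) -> Tuple[AlleleCall, ...]:
        return tuple(a for a in self.alleles if a.is_typed)

    @property
    def fully_typed(self) -> bool:
        return all(a.is_typed for a in self.alleles)

    @property
    def any_not_typed(self) -> bool:
        return any(not a.is_typed for a in self.alleles)


@dataclass
class SampleTyping:
    """All genotype calls of one sample: mapping locus name -> GenotypeCall."""

    sample_id: str
    calls: Dict[str, GenotypeCall] = field(default_factory=dict)
    dataset: str = ""

    def loci(self) -> List[str]:
        return list(self.calls)


@dataclass(frozen=True)
class TrioRecord:
    family_id: str
    child_id: str
    father_id: str
    mother_id: str

    def __post_init__(self) -> None:
        ids = (self.child_id, self.father_id, self.mother_id)
        if len(set(ids)) != 3:
            raise TypingIOError(
                f"family {self.family_id}: child/father/mother IDs "
                f"must be distinct, got {ids}")

    def member_ids(self) -> Tuple[str, str, str]:
        return (self.child_id, self.father_id, self.mother_id)


@dataclass(frozen=True)
class DuplicatePair:
    sample_id_a: str
    dataset_a: str
    sample_id_b: str
    dataset_b: str

    def __post_init__(self) -> None:
        if self.dataset_a == self.dataset_b:
            raise TypingIOError(
                f"duplicate pair {self.sample_id_a}/{self.sample_id_b}: "
                "the two typings must come from different datasets/tools")


# ---------------------------------------------------------------------------
# readers


def _data_lines(path) -> Iterable[Tuple[int, List[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_hlahd_result(path, sample_id: Optional[str] = None,
                      dataset: str = "") -> SampleTyping:
    """Read one sample's HLA-HD final-result file.

    ``-`` in slot 2 with a typed slot 1 is the tool's homozygosity marker
    and is expanded to a second copy of slot 1.  ``Not typed`` yields a
    not-typed slot.  Loci absent from the file are absent from the mapping.
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    typing = SampleTyping(sample_id, dataset=dataset)
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise TypingIOError(
                f"{path}:{lineno}: expected 'locus<TAB>allele<TAB>allele', "
                f"got {len(cols)} column(s)")
        locus_name, s1, s2 = cols[0].strip(), cols[1].strip(), cols[2].strip()
        try:
            locus = get_locus(locus_name)
            a1 = parse_allele(s1, locus_hint=locus)
            if s2 == "-":
                if not a1.is_typed:
                    raise NomenclatureError(
                        "homozygosity marker '-' with a not-typed slot 1")
                a2 = a1
            else:
                a2 = parse_allele(s2, locus_hint=locus)
        except NomenclatureError as exc:
            raise TypingIOError(f"{path}:{lineno}: {exc}") from exc
        if locus_name in typing.calls:
            raise TypingIOError(f"{path}:{lineno}: duplicate locus line "
                                f"{locus_name}")
        typing.calls[locus_name] = GenotypeCall(locus, (a1, a2), dataset)
    return typing


_TYPING_COLUMNS = ("sample", "locus", "allele1", "allele2")


def read_typing_tsv(path, dataset: str = "") -> Dict[str, SampleTyping]:
    """Read a generic long-format typing TSV into sample -> SampleTyping.

    Header ``sample locus allele1 allele2``; ``-`` and ``Not typed`` both
    denote a not-typed slot; the optional ``HLA-`` prefix is accepted.
    """
    rows = list(_data_lines(path))
    if not rows:
        raise TypingIOError(f"{path}: empty typing file")
    header_no, header = rows[0]
    if [c.strip() for c in header[:4]] != list(_TYPING_COLUMNS):
        raise TypingIOError(
            f"{path}:{header_no}: expected header "
            f"{' '.join(_TYPING_COLUMNS)}")
    typings: Dict[str, SampleTyping] = {}
    for lineno, cols in rows[1:]:
        if len(cols) < 4 or any(not c.strip() for c in cols[:4]):
            raise TypingIOError(
                f"{path}:{lineno}: need 4 non-empty columns")
        sid, locus_name, s1, s2 = (c.strip() for c in cols[:4])
        try:
            locus = get_locus(locus_name)
            a1 = parse_allele(s1, locus_hint=locus, dash_is_not_typed=True)
            a2 = parse_allele(s2, locus_hint=locus, dash_is_not_typed=True)
        except NomenclatureError as exc:
            raise TypingIOError(f"{path}:{lineno}: {exc}") from exc
        typing = typings.setdefault(sid, SampleTyping(sid, dataset=dataset))
        if locus_name in typing.calls:
            raise TypingIOError(
                f"{path}:{lineno}: conflicting rows for sample {sid} "
                f"locus {locus_name}")
        typing.calls[locus_name] = GenotypeCall(locus, (a1, a2), dataset)
    return typings


def write_typing_tsv(typings: Mapping[str, SampleTyping], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TYPING_COLUMNS) + "\n")
        for typing in typings.values():
            for locus_name, call in typing.calls.items():
                names = [a.name() if a.is_typed else "Not typed"
                         for a in call.alleles]
                fh.write("\t".join([typing.sample_id, locus_name, *names])
                         + "\n")


_PED_COLUMNS = ("family", "child", "father", "mother")


def read_pedigree(path) -> List[TrioRecord]:
    """Read a PED-like trio file: ``family child father mother`` per row."""
    rows = list(_data_lines(path))
    if not rows:
        return []
    header_no, header = rows[0]
    if [c.strip() for c in header[:4]] != list(_PED_COLUMNS):
        raise TypingIOError(
            f"{path}:{header_no}: expected header {' '.join(_PED_COLUMNS)}")
    trios: List[TrioRecord] = []
    seen = set()
    for lineno, cols in rows[1:]:
        if len(cols) < 4 or any(not c.strip() for c in cols[:4]):
            raise TypingIOError(f"{path}:{lineno}: need 4 non-empty columns")
        fam, child, father, mother = (c.strip() for c in cols[:4])
        if fam in seen:
            raise TypingIOError(f"{path}:{lineno}: duplicate family {fam}")
        seen.add(fam)
        try:
            trios.append(TrioRecord(fam, child, father, mother))
        except TypingIOError as exc:
            raise TypingIOError(f"{path}:{lineno}: {exc}") from exc
    return trios


def resolve_trios(trios: Sequence[TrioRecord],
                  typings: Mapping[str, SampleTyping]) -> List[str]:
    """Return the IDs referenced by ``trios`` missing from ``typings``."""
    missing = []
    for trio in trios:
        for sid in trio.member_ids():
            if sid not in typings:
                missing.append(sid)
    return missing


_PAIR_COLUMNS = ("sample_a", "dataset_a", "sample_b", "dataset_b")


def read_pairs(path) -> List[DuplicatePair]:
    rows = list(_data_lines(path))
    if not rows:
        return []
    header_no, header = rows[0]
    if [c.strip() for c in header[:4]] != list(_PAIR_COLUMNS):
        raise TypingIOError(
            f"{path}:{header_no}: expected header {' '.join(_PAIR_COLUMNS)}")
    pairs = []
    for lineno, cols in rows[1:]:
        if len(cols) < 4 or any(not c.strip() for c in cols[:4]):
            raise TypingIOError(f"{path}:{lineno}: need 4 non-empty columns")
        try:
            pairs.append(DuplicatePair(*(c.strip() for c in cols[:4])))
        except TypingIOError as exc:
            raise TypingIOError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_pairs(pairs: Sequence[DuplicatePair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(f"{p.sample_id_a}\t{p.dataset_a}\t"
                     f"{p.sample_id_b}\t{p.dataset_b}\n")


# ---------------------------------------------------------------------------
# DRB3/4/5 pooling


def pool_drb345(s: SampleTyping) -> SampleTyping:
    """Add the DRB345 pooling unit to a sample's calls.

    The unit is the multiset of typed alleles across DRB3/DRB4/DRB5,
    interpreted as transmitted copies.  Because typing tools render a
    hemizygous paralog as a homozygote, a homozygous pair at one paralog
    collapses to a single copy when any *other* paralog also carries typed
    alleles (the individual has at most two secondary-DRB haplotypes); when
    it is the only typed paralog, both copies are kept.  Not-typed slots
    contribute nothing.  Original per-locus entries are retained.
    """
    per_locus: Dict[str, List[AlleleCall]] = {}
    for name in COPY_NUMBER_VARIABLE:
        call = s.calls.get(name)
        if call is not None:
            per_locus[name] = list(call.typed_alleles)
    n_loci_typed = sum(1 for v in per_locus.values() if v)
    pooled: List[AlleleCall] = []
    for name in COPY_NUMBER_VARIABLE:
        alleles = per_locus.get(name, [])
        if (len(alleles) == 2 and alleles[0] == alleles[1]
                and n_loci_typed > 1):
            alleles = alleles[:1]
        pooled.extend(alleles)
    out = SampleTyping(s.sample_id, dict(s.calls), s.dataset)
    out.calls["DRB345"] = GenotypeCall(DRB345, tuple(pooled), s.dataset)
    return out


# ---------------------------------------------------------------------------
# consistency/concordance report tables


@dataclass(frozen=True)
class ConsistencyRow:
    """Per-locus percentages at field resolutions 1-3 plus the denominator.

    ``pct`` values are unrounded; ``None`` marks a locus with zero
    evaluable families/pairs (printed as ``NA``).
    """

    locus: str
    pct: Tuple[Optional[float], Optional[float], Optional[float]]
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("negative denominator")
        for p in self.pct:
            if p is None:
                if self.n != 0:
                    raise ValueError(
                        f"{self.locus}: NA percentage with n={self.n}")
            elif not (0.0 <= p <= 100.0 + 1e-9):
                raise ValueError(f"{self.locus}: percentage {p} out of range")


@dataclass
class ConsistencyTable:
    """Per-locus x per-resolution percentages (the shape of the published
    trio-consistency tables)."""

    rows: List[ConsistencyRow]
    dataset_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [r.locus for r in self.rows],
                "first_field_pct": [r.pct[0] for r in self.rows],
                "second_field_pct": [r.pct[1] for r in self.rows],
                "third_field_pct": [r.pct[2] for r in self.rows],
                "n": [r.n for r in self.rows],
            }
        )

    def column(self, k: int) -> List[Optional[float]]:
        """All per-locus percentages at field resolution ``k`` (1-3)."""
        return [r.pct[k - 1] for r in self.rows]


_TABLE_COLUMNS = ("locus", "first_field_pct", "second_field_pct",
                  "third_field_pct", "n")


def _fmt_pct(p: Optional[float]) -> str:
    from .aggregation import round2  # local import avoids a cycle

    return "NA" if p is None else f"{round2(p):.2f}"


def write_consistency_table(t: ConsistencyTable, path) -> None:
    """Write a per-locus report TSV, percentages to 2 decimals, ``NA`` for
    loci with zero evaluable families."""
    with open(path, "w", encoding="utf-8") as fh:
        if t.dataset_label:
            fh.write(f"# dataset: {t.dataset_label}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in t.rows:
            fh.write("\t".join([r.locus, *(_fmt_pct(p) for p in r.pct),
                                str(r.n)]) + "\n")


def read_consistency_table(path, dataset_label: str = "") -> ConsistencyTable:
    rows: List[ConsistencyRow] = []
    data = list(_data_lines(path))
    if not data:
        raise TypingIOError(f"{path}: empty table")
    header_no, header = data[0]
    if [c.strip() for c in header[:5]] != list(_TABLE_COLUMNS):
        raise TypingIOError(
            f"{path}:{header_no}: expected header {' '.join(_TABLE_COLUMNS)}")
    for lineno, cols in data[1:]:
        if len(cols) < 5:
            raise TypingIOError(f"{path}:{lineno}: need 5 columns")
        locus = cols[0].strip()
        try:
            pct = tuple(
                None if c.strip() == "NA" else float(c) for c in cols[1:4])
            n = int(cols[4])
            rows.append(ConsistencyRow(locus, pct, n))
        except ValueError as exc:
            raise TypingIOError(f"{path}:{lineno}: {exc}") from exc
    return ConsistencyTable(rows, dataset_label)
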