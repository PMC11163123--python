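"""HLA allele nomenclature: parsing, truncation, and resolution-aware matching.

An HLA allele name is a gene symbol and a colon-separated list of numeric
fields, e.g. ``HLA-DRB3*02:02:01``.  Field 1 is the allele group
(serological), field 2 the specific protein, field 3 synonymous coding
substitutions; an optional expression suffix (N/L/S/C/A/Q) may follow the
last field.  Typing tools emit the sentinel ``Not typed`` when reads are
insufficient to assign an allele, which for copy-number-variable loci can
also reflect true absence of the gene.

Field tokens are kept as zero-padded strings — IPD-IMGT/HLA names are text,
so ``01`` and ``1`` are different tokens and never compared numerically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple


class ClassGroup(str, Enum):
    classical_I = "classical_I"
    classical_II = "classical_II"
    nonclassical = "nonclassical"
    DRB_paralog = "DRB_paralog"
    pseudo = "pseudo"


@dataclass(frozen=True)
class Locus:
    """One locus from the 29-locus registry (plus the DRB345 pooling unit)."""

    name: str
    class_group: ClassGroup

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


def _build_registry() -> dict:
    groups = {
        ClassGroup.classical_I: ["A", "B", "C"],
        ClassGroup.classical_II: ["DRB1", "DQA1", "DQB1", "DPA1", "DPB1"],
        ClassGroup.nonclassical: [
            "DMA", "DMB", "DOA", "DOB", "DRA",
            "E", "F", "G", "H", "J", "K", "L", "V",
        ],
        ClassGroup.DRB_paralog: [
            "DRB2", "DRB3", "DRB4", "DRB5", "DRB6", "DRB7", "DRB8", "DRB9",
        ],
    }
    reg = {}
    for group, names in groups.items():
        for name in names:
            reg[name] = Locus(name, group)
    # Pooling unit for the copy-number-variable secondary DRB loci; never
    # read directly from input files.
    reg["DRB345"] = Locus("DRB345", ClassGroup.pseudo)
    return reg


LOCUS_REGISTRY: dict = _build_registry()

#: The 29 loci a typing tool reports on, in canonical report order.
REPORT_LOCI: Tuple[str, ...] = (
    "A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1",
    "DMA", "DMB", "DOA", "DOB", "DRA",
    "DRB2", "DRB3", "DRB4", "DRB5", "DRB6", "DRB7", "DRB8", "DRB9",
    "E", "F", "G", "H", "J", "K", "L", "V",
)

#: Loci with variable copy number (0-2 gene copies per individual),
#: presence linked to the DRB1 allele group of the haplotype.
COPY_NUMBER_VARIABLE: Tuple[str, ...] = ("DRB3", "DRB4", "DRB5")

DRB345 = LOCUS_REGISTRY["DRB345"]

EXPRESSION_SUFFIXES = "NLSCAQ"

NOT_TYPED_SENTINEL = "Not typed"


class NomenclatureError(ValueError):
    """Raised for malformed allele names or locus mismatches."""


def get_locus(name: str) -> Locus:
    try:
        return LOCUS_REGISTRY[name]
    except KeyError:
        raise NomenclatureError(f"unknown HLA locus: {name!r}") from None


class CallStatus(str, Enum):
    typed = "typed"
    not_typed = "not_typed"


@dataclass(frozen=True)
class Resolution:
    """Comparison depth in fields, 1-3."""

    k: int

    def __post_init__(self) -> None:
        if self.k not in (1, 2, 3):
            raise ValueError(f"resolution must be 1, 2 or 3, got {self.k}")


@dataclass(frozen=True)
class AlleleCall:
    """One parsed allele name, or the not-typed sentinel, at one locus."""

    locus: Locus
    status: CallStatus
    fields: Tuple[str, ...] = ()
    suffix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status is CallStatus.typed:
            if not self.fields:
                raise NomenclatureError("typed allele must have >=1 field")
            for tok in self.fields:
                if not tok.isdigit():
                    raise NomenclatureError(
                        f"field token must be digits, got {tok!r}")
            if self.suffix is not None and self.suffix not in EXPRESSION_SUFFIXES:
                raise NomenclatureError(
                    f"unknown expression suffix {self.suffix!r}")
        else:
            if self.fields or self.suffix is not None:
                raise NomenclatureError(
                    "not_typed call carries no fields or suffix")

    @classmethod
    def make_typed(cls, locus: Locus, fields, suffix: Optional[str] = None
                   ) -> "AlleleCall":
        return cls(locus, CallStatus.typed, tuple(fields), suffix)

    @classmethod
    def make_not_typed(cls, locus: Locus) -> "AlleleCall":
        return cls(locus, CallStatus.not_typed)

    @property
    def is_typed(self) -> bool:
        return self.status is CallStatus.typed

    @property
    def depth(self) -> int:
        """Number of typed fields (0 for not-typed)."""
        return len(self.fields)

    def name(self, prefix: bool = False) -> str:
        """Render back to IPD-IMGT-style text (``Not typed`` for sentinels)."""
        if not self.is_typed:
            return NOT_TYPED_SENTINEL
        base = f"{self.locus.name}*{':'.join(self.fields)}{self.suffix or ''}"
        return f"HLA-{base}" if prefix else base

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name()


_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z][A-Z0-9]*)\*"
    r"(?P<fields>\d+(?::\d+)*)"
    r"(?P<suffix>[A-Z])?$"
)


def parse_allele(text: str, locus_hint: Optional[Locus] = None,
                 dash_is_not_typed: bool = False) -> AlleleCall:
    """Parse one allele string into an :class:`AlleleCall`.

    Recognised sentinels: ``Not typed`` always; ``-`` only when
    ``dash_is_not_typed`` is set (the generic TSV dialect — in HLA-HD
    result files ``-`` marks homozygosity and is expanded by the reader
    before this function sees it).  ``locus_hint`` is required for
    sentinels and must agree with the gene symbol of typed names.
    """
    text = text.strip()
    if not text:
        raise NomenclatureError("empty allele string")
    if text.lower() == NOT_TYPED_SENTINEL.lower() or (
            dash_is_not_typed and text == "-"):
        if locus_hint is None:
            raise NomenclatureError(
                f"sentinel {text!r} needs a locus hint to be interpreted")
        return AlleleCall.make_not_typed(locus_hint)
    m = _ALLELE_RE.match(text)
    if m is None:
        raise NomenclatureError(f"malformed allele name: {text!r}")
    locus = get_locus(m.group("gene"))
    if locus_hint is not None and locus != locus_hint:
        raise NomenclatureError(
            f"allele {text!r} is at locus {locus.name}, "
            f"expected {locus_hint.name}")
    suffix = m.group("suffix")
    if suffix is not None and suffix not in EXPRESSION_SUFFIXES:
        raise NomenclatureError(
            f"unknown expression suffix {suffix!r} in {text!r}")
    fields = tuple(m.group("fields").split(":"))
    if len(fields) > 4:
        raise NomenclatureError(f"more than 4 fields in {text!r}")
    return AlleleCall.make_typed(locus, fields, suffix)


def truncate(a: AlleleCall, r: Resolution) -> AlleleCall:
    """Truncate an allele call to at most ``r.k`` fields.

    Not-typed sentinels pass through; the expression suffix is dropped
    whenever fields are actually removed (it annotates the full name).
    """
    if not a.is_typed or len(a.fields) <= r.k:
        return a
    return AlleleCall.make_typed(a.locus, a.fields[: r.k], None)


def alleles_match(a: AlleleCall, b: AlleleCall, r: Resolution,
                  compare_suffix: bool = False) -> bool:
    """True iff two same-locus calls agree at resolution ``r``.

    Both calls must be typed to at least ``r.k`` fields and agree on the
    first ``r.k`` tokens; a call typed to fewer fields than ``r.k`` never
    matches (no optimistic prefix match — short calls count as
    disagreements at deeper resolutions).  Two not-typed calls match
    (concordant absence); typed vs not-typed never match.  Expression
    suffixes are ignored unless ``compare_suffix`` is set.
    """
    if a.locus != b.locus:
        raise NomenclatureError(
            f"cannot compare alleles across loci "
            f"({a.locus.name} vs {b.locus.name})")
    if not a.is_typed and not b.is_typed:
        return True
    if a.is_typed != b.is_typed:
        return False
    if a.depth < r.k or b.depth < r.k:
        return False
    if a.fields[: r.k] != b.fields[: r.k]:
        return False
    if compare_suffix and a.suffix != b.suffix:
        return False
    return True
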