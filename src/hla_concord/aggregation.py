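"""Success rates and cross-locus averages of consistency percentages.

Per-resolution averages are *unweighted* arithmetic means of the per-locus
percentages (a 2-family DRB5 row counts as much as a 25-family HLA-A row),
excluding NA loci; the overall average is the mean of the three
per-resolution means.  Presentation rounding is half-up to two decimals.

The per-locus consistency tables published for three trio cohorts
(research-grade exome, clinical-grade exome, targeted HLA panel), and the
per-resolution concordance means published for the tool comparison and the
two duplicate-sample analyses, ship as packaged fixtures so the
aggregation stage can be run and checked without any genotype-level data
(which was never released).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .typing_io import (
    ConsistencyTable,
    SampleTyping,
    read_consistency_table,
)


def round2(x: float) -> float:
    """Round half-up to 2 decimals (presentation convention)."""
    return float(Decimal(repr(float(x))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SuccessRateRow:
    locus: str
    dataset_label: str
    pct_samples_typed: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_samples_typed <= 100.0:
            raise ValueError("success rate out of [0, 100]")


def success_rate(samples: Mapping[str, SampleTyping], locus: str,
                 dataset_label: str = "") -> SuccessRateRow:
    """Share of samples with both slots typed at ``locus``.

    The denominator is the samples that assay the locus; a locus assayed
    by no sample is an error, not a 0% row.
    """
    assaying = [s for s in samples.values() if locus in s.calls]
    if not assaying:
        raise ValueError(f"locus {locus} not assayed in dataset "
                         f"{dataset_label!r}")
    n_typed = sum(1 for s in assaying if s.calls[locus].fully_typed)
    return SuccessRateRow(locus, dataset_label,
                          100.0 * n_typed / len(assaying), len(assaying))


def resolution_average(t: ConsistencyTable, k: int,
                       rounded: bool = True) -> float:
    """Unweighted mean of per-locus percentages at field resolution ``k``,
    NA rows excluded; rounded half-up to 2 decimals unless ``rounded`` is
    disabled (useful when comparing against tables whose printed cells
    were truncated rather than rounded)."""
    vals = [p for p in t.column(k) if p is not None]
    if not vals:
        raise ValueError(f"no locus has a value at field resolution {k}")
    mean = sum(vals) / len(vals)
    return round2(mean) if rounded else mean


def overall_average(means: Sequence[float]) -> float:
    """Mean of the three per-resolution means, 2-decimal presentation."""
    if len(means) != 3:
        raise ValueError("expected exactly the field-1..3 means")
    return round2(sum(means) / 3.0)


@dataclass(frozen=True)
class ResolutionSummary:
    dataset_label: str
    mean_field1: float
    mean_field2: float
    mean_field3: float
    overall_mean: float
    n_loci: int

    def means(self) -> Tuple[float, float, float]:
        return (self.mean_field1, self.mean_field2, self.mean_field3)


def summarize(t: ConsistencyTable,
              dataset_label: Optional[str] = None) -> ResolutionSummary:
    """Per-resolution and overall means of one consistency table."""
    means = [resolution_average(t, k) for k in (1, 2, 3)]
    n_loci = sum(1 for p in t.column(1) if p is not None)
    return ResolutionSummary(
        dataset_label if dataset_label is not None else t.dataset_label,
        *means, overall_average(means), n_loci)


# ---------------------------------------------------------------------------
# packaged published fixtures

#: Published per-locus trio-consistency tables (fixture name -> file).
PUBLISHED_TABLES: Dict[str, str] = {
    "research_exome_trios": "consistency_research_exome_trios.tsv",
    "clinical_exome_trios": "consistency_clinical_exome_trios.tsv",
    "panel_trios": "consistency_panel_trios.tsv",
}


def load_published_table(name: str) -> ConsistencyTable:
    """Load one packaged published per-locus consistency table.

    The research-exome fixture reproduces the published rows verbatim,
    including a locus label printed twice in the original (kept so column
    means reproduce exactly).
    """
    try:
        fname = PUBLISHED_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown published table {name!r}; "
            f"choose from {sorted(PUBLISHED_TABLES)}") from None
    ref = resources.files("hla_concord.data") / fname
    with resources.as_file(ref) as path:
        return read_consistency_table(path, dataset_label=name)


def load_published_resolution_means() -> Dict[str, List[float]]:
    """Published per-resolution concordance means (field 1, 2, 3) for the
    analyses whose per-locus tables were not printed: the HLA-HD vs
    HLA-Twin tool comparison, panel-vs-exome duplicates, and
    genome-vs-exome duplicates."""
    ref = resources.files("hla_concord.data") / "published_resolution_means.json"
    return json.loads(ref.read_text(encoding="utf-8"))
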