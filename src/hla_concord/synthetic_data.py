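"""Synthetic HLA typing data with the structure the scoring assumes.

The generator draws founder individuals as two independent haplotypes per
locus from per-locus categorical allele frequencies, transmits one
haplotype per parent to each trio child (the whole haplotype, so the DRB
region is co-transmitted), and renders truth into observed call tables
under three independent per-allele noise channels:

* dropout — the call becomes ``Not typed``;
* truncation — a 3-field call is emitted with only 2 fields (the
  insufficient-coverage failure mode);
* mistyping — the allele is replaced by a different allele from the locus
  pool.

Copy-number structure of the secondary DRB loci is simulated explicitly:
which of DRB3/DRB4/DRB5 (or none) a haplotype carries is determined by the
allele-group (field 1) of its DRB1 allele, mirroring the known linkage.
A haplotype without the gene contributes nothing; an individual carrying
one copy is rendered as a homozygote, and an individual carrying none as
``Not typed`` — the conventions of the typing tools whose output the
scorer consumes.

Sampling is fully deterministic under a fixed seed: all random decisions
are integer draws against integer thresholds (rates and frequencies are
quantized to 1e-6), never floating-point comparisons.

Synthetic allele names use valid IPD-IMGT-like syntax on the real locus
symbols (e.g. ``A*03:15:40``) with every pool allele distinct already at
field 1, so a mistyped allele is detectable at every resolution — the
simplest pool geometry for closed-form expectations.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .nomenclature import (
    COPY_NUMBER_VARIABLE,
    AlleleCall,
    get_locus,
)
from .typing_io import (
    DuplicatePair,
    GenotypeCall,
    SampleTyping,
    TrioRecord,
)

#: Default simulated loci: the classical panel targets plus the secondary
#: DRB loci whose copy-number behaviour the scoring must handle.
DEFAULT_LOCI: Tuple[str, ...] = (
    "A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1",
    "DRB3", "DRB4", "DRB5",
)

#: DRB1 allele groups used for synthetic DRB1 pools, and which secondary
#: DRB locus each group's haplotype carries (None = no secondary gene).
DEFAULT_DRB1_LINKAGE: Dict[str, Optional[str]] = {
    "01": None,
    "08": None,
    "03": "DRB3",
    "11": "DRB3",
    "13": "DRB3",
    "04": "DRB4",
    "07": "DRB4",
    "15": "DRB5",
}

#: Default DRB1 allele-group frequencies (aligned with the linkage map
#: order).  Chosen so every carriage class — no secondary gene, DRB3,
#: DRB4, DRB5 — is well represented, as in real outbred populations where
#: DRB3/DRB4/DRB5 haplotypes each segregate at substantial frequency.
DEFAULT_DRB1_GROUP_FREQS: Tuple[float, ...] = (
    0.10, 0.06, 0.14, 0.16, 0.12, 0.16, 0.12, 0.14,
)

_GRID = 1_000_000  # integer probability grid (rates quantized to 1e-6)


def _int_thresholds(probs: Sequence[float]) -> List[int]:
    """Cumulative integer thresholds on the 1e-6 grid, summing to _GRID."""
    weights = [int(round(p * _GRID)) for p in probs]
    weights[-1] += _GRID - sum(weights)
    if weights[-1] < 0:
        raise ValueError("frequencies do not sum to 1")
    cum, total = [], 0
    for w in weights:
        total += w
        cum.append(total)
    return cum


def _int_rate(rate: float) -> int:
    return int(round(rate * _GRID))


@dataclass(frozen=True)
class NoiseProfile:
    """One dataset's assay design and noise rates."""

    label: str
    loci: Tuple[str, ...]
    dropout_rate: float = 0.0
    truncation_rate: float = 0.0
    mistyping_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.dropout_rate, self.truncation_rate,
                  self.mistyping_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"noise rate {r} out of [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    loci: Tuple[str, ...] = DEFAULT_LOCI
    n_alleles: int = 8
    allele_frequencies: Optional[Mapping[str, Sequence[float]]] = None
    drb1_linkage: Mapping[str, Optional[str]] = field(
        default_factory=lambda: dict(DEFAULT_DRB1_LINKAGE))
    n_families: int = 14
    n_duplicates: int = 0
    dropout_rate: float = 0.0
    truncation_rate: float = 0.0
    mistyping_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise ValueError("allele pool needs >= 2 alleles")
        for r in (self.dropout_rate, self.truncation_rate,
                  self.mistyping_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"noise rate {r} out of [0, 1]")
        if self.allele_frequencies is not None:
            for locus, probs in self.allele_frequencies.items():
                if abs(sum(probs) - 1.0) > 1e-6:
                    raise ValueError(f"{locus}: frequencies must sum to 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "loci" in d:
            d["loci"] = tuple(d["loci"])
        return cls(**d)

    def noise_profile(self, label: str = "simulated") -> NoiseProfile:
        return NoiseProfile(label, self.loci, self.dropout_rate,
                            self.truncation_rate, self.mistyping_rate)


def default_frequencies(n: int) -> List[float]:
    """Geometric-decay frequency spectrum (few common, many rare alleles)."""
    raw = [0.6 ** i for i in range(n)]
    s = sum(raw)
    return [x / s for x in raw]


def build_allele_pools(cfg: SimulationConfig
                       ) -> Dict[str, List[AlleleCall]]:
    """Synthetic 3-field allele pools per locus, distinct at field 1.

    DRB1 field-1 tokens cycle through the linkage groups so every group is
    represented; with the default pool size of 8 there is exactly one
    allele per group.
    """
    groups = list(cfg.drb1_linkage)
    pools: Dict[str, List[AlleleCall]] = {}
    sim_loci = set(cfg.loci) | set(COPY_NUMBER_VARIABLE)
    for locus_name in sorted(sim_loci):
        locus = get_locus(locus_name)
        pool = []
        for i in range(cfg.n_alleles):
            if locus_name == "DRB1":
                f1 = groups[i % len(groups)]
            else:
                f1 = f"{i + 1:02d}"
            fields = (f1, f"{(i * 7) % 90 + 1:02d}", f"{(i * 13) % 90 + 1:02d}")
            pool.append(AlleleCall.make_typed(locus, fields))
        pools[locus_name] = pool
    return pools


Haplotype = Dict[str, AlleleCall]  # locus name -> allele (CNV loci optional)


@dataclass(frozen=True)
class TrueSample:
    sample_id: str
    haplotypes: Tuple[Haplotype, Haplotype]

    def true_unit(self) -> Tuple[AlleleCall, ...]:
        """The truly carried DRB3/4/5 alleles, one per carrying haplotype."""
        out = []
        for h in self.haplotypes:
            for name in COPY_NUMBER_VARIABLE:
                if name in h:
                    out.append(h[name])
        return tuple(out)


@dataclass
class TruthSet:
    """True genotypes plus the structures needed to render and audit them."""

    config: SimulationConfig
    pools: Dict[str, List[AlleleCall]]
    samples: Dict[str, TrueSample]
    trios: List[TrioRecord] = field(default_factory=list)


def _draw_index(thresholds: List[int], rng: np.random.Generator) -> int:
    r = int(rng.integers(0, _GRID))
    return bisect_right(thresholds, r)


def _draw_haplotype(cfg: SimulationConfig,
                    pools: Mapping[str, List[AlleleCall]],
                    thresholds: Mapping[str, List[int]],
                    rng: np.random.Generator) -> Haplotype:
    hap: Haplotype = {}
    for locus_name in cfg.loci:
        if locus_name in COPY_NUMBER_VARIABLE:
            continue  # presence decided by the DRB1 draw below
        hap[locus_name] = pools[locus_name][
            _draw_index(thresholds[locus_name], rng)]
    if "DRB1" in hap:
        group = hap["DRB1"].fields[0]
        paralog = cfg.drb1_linkage.get(group)
        if paralog is not None:
            hap[paralog] = pools[paralog][
                _draw_index(thresholds[paralog], rng)]
    return hap


def _thresholds_for(cfg: SimulationConfig,
                    pools: Mapping[str, List[AlleleCall]]
                    ) -> Dict[str, List[int]]:
    out = {}
    for locus_name, pool in pools.items():
        if cfg.allele_frequencies and locus_name in cfg.allele_frequencies:
            probs = list(cfg.allele_frequencies[locus_name])
            if len(probs) != len(pool):
                raise ValueError(
                    f"{locus_name}: {len(probs)} frequencies for "
                    f"{len(pool)} alleles")
        elif (locus_name == "DRB1"
                and dict(cfg.drb1_linkage) == DEFAULT_DRB1_LINKAGE
                and len(pool) == len(DEFAULT_DRB1_GROUP_FREQS)):
            probs = list(DEFAULT_DRB1_GROUP_FREQS)
        else:
            probs = default_frequencies(len(pool))
        out[locus_name] = _int_thresholds(probs)
    return out


def simulate_population(cfg: SimulationConfig, n: int,
                        rng: Optional[np.random.Generator] = None,
                        id_prefix: str = "S") -> TruthSet:
    """Draw ``n`` unrelated founders (two independent haplotypes each)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pools = build_allele_pools(cfg)
    thresholds = _thresholds_for(cfg, pools)
    samples: Dict[str, TrueSample] = {}
    for i in range(n):
        sid = f"{id_prefix}{i + 1:04d}"
        haps = (_draw_haplotype(cfg, pools, thresholds, rng),
                _draw_haplotype(cfg, pools, thresholds, rng))
        samples[sid] = TrueSample(sid, haps)
    return TruthSet(cfg, pools, samples)


def simulate_trio(father: TrueSample, mother: TrueSample,
                  rng: np.random.Generator,
                  child_id: str = "child") -> TrueSample:
    """Transmit one whole haplotype per parent to the child."""
    hp = father.haplotypes[int(rng.integers(0, 2))]
    hm = mother.haplotypes[int(rng.integers(0, 2))]
    return TrueSample(child_id, (dict(hp), dict(hm)))


def simulate_families(cfg: SimulationConfig,
                      rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Simulate ``cfg.n_families`` trios (founder parents plus one child)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pools = build_allele_pools(cfg)
    thresholds = _thresholds_for(cfg, pools)
    truth = TruthSet(cfg, pools, {})
    for i in range(cfg.n_families):
        fam = f"FAM{i + 1:04d}"
        father = TrueSample(f"{fam}_F", (
            _draw_haplotype(cfg, pools, thresholds, rng),
            _draw_haplotype(cfg, pools, thresholds, rng)))
        mother = TrueSample(f"{fam}_M", (
            _draw_haplotype(cfg, pools, thresholds, rng),
            _draw_haplotype(cfg, pools, thresholds, rng)))
        child = simulate_trio(father, mother, rng, f"{fam}_C")
        for s in (child, father, mother):
            truth.samples[s.sample_id] = s
        truth.trios.append(TrioRecord(fam, child.sample_id,
                                      father.sample_id, mother.sample_id))
    return truth


def render_truth(truth: TruthSet, dataset_label: str = "truth",
                 loci: Optional[Sequence[str]] = None
                 ) -> Dict[str, SampleTyping]:
    """Render true haplotypes into per-sample call tables.

    Secondary DRB loci: two carried copies render as the genotype, one
    copy as a homozygote, none as ``Not typed`` — matching typing-tool
    conventions.  ``loci`` restricts to a dataset's assay design.
    """
    if loci is None:
        loci = truth.config.loci
    out: Dict[str, SampleTyping] = {}
    for sid, ts in truth.samples.items():
        typing = SampleTyping(sid, dataset=dataset_label)
        for locus_name in loci:
            locus = get_locus(locus_name)
            carried = [h[locus_name] for h in ts.haplotypes
                       if locus_name in h]
            if locus_name in COPY_NUMBER_VARIABLE:
                if len(carried) == 2:
                    alleles = tuple(carried)
                elif len(carried) == 1:
                    alleles = (carried[0], carried[0])
                else:
                    nt = AlleleCall.make_not_typed(locus)
                    alleles = (nt, nt)
            else:
                alleles = tuple(carried)
            typing.calls[locus_name] = GenotypeCall(locus, alleles,
                                                    dataset_label)
        out[sid] = typing
    return out


@dataclass(frozen=True)
class NoiseEvent:
    sample_id: str
    locus: str
    slot: int
    kind: str  # dropout | truncation | mistyping
    before: str
    after: str


def apply_noise(typings: Mapping[str, SampleTyping],
                profile: NoiseProfile,
                pools: Mapping[str, List[AlleleCall]],
                rng: np.random.Generator,
                samples: Optional[Sequence[str]] = None,
                ) -> Tuple[Dict[str, SampleTyping], List[NoiseEvent]]:
    """Independently perturb every typed allele slot; log every event.

    Per slot: dropout with probability ``dropout_rate``; otherwise
    truncation (to 2 fields, only for calls deeper than 2 fields) with
    ``truncation_rate``; otherwise mistyping (replacement by a different
    pool allele, uniform) with ``mistyping_rate``.  ``samples`` restricts
    noise to a subset (e.g. children only); others pass through intact.
    """
    p_drop = _int_rate(profile.dropout_rate)
    p_trunc = _int_rate(profile.truncation_rate)
    p_mis = _int_rate(profile.mistyping_rate)
    subset = set(samples) if samples is not None else None
    events: List[NoiseEvent] = []
    out: Dict[str, SampleTyping] = {}
    for sid, typing in typings.items():
        noised = SampleTyping(sid, dataset=profile.label)
        for locus_name, call in typing.calls.items():
            new_alleles = []
            for slot, a in enumerate(call.alleles):
                if (not a.is_typed
                        or (subset is not None and sid not in subset)):
                    new_alleles.append(a)
                    continue
                b = a
                kind = None
                if int(rng.integers(0, _GRID)) < p_drop:
                    b = AlleleCall.make_not_typed(a.locus)
                    kind = "dropout"
                elif (int(rng.integers(0, _GRID)) < p_trunc
                        and a.depth > 2):
                    b = AlleleCall.make_typed(a.locus, a.fields[:2])
                    kind = "truncation"
                elif int(rng.integers(0, _GRID)) < p_mis:
                    pool = pools[locus_name]
                    j = int(rng.integers(0, len(pool) - 1))
                    b = pool[j] if pool[j] != a else pool[-1]
                    kind = "mistyping"
                if kind is not None:
                    events.append(NoiseEvent(sid, locus_name, slot, kind,
                                             a.name(), b.name()))
                new_alleles.append(b)
            noised.calls[locus_name] = GenotypeCall(
                call.locus, tuple(new_alleles), profile.label)
        out[sid] = noised
    return out, events


def replay_events(typings: Mapping[str, SampleTyping],
                  events: Sequence[NoiseEvent],
                  dataset_label: str = "") -> Dict[str, SampleTyping]:
    """Re-apply a noise log to clean typings; must reproduce the observed
    data exactly (the log is a complete account of the corruption)."""
    from .nomenclature import parse_allele

    out = {
        sid: SampleTyping(
            sid,
            {n: GenotypeCall(c.locus, tuple(c.alleles), dataset_label)
             for n, c in t.calls.items()},
            dataset_label)
        for sid, t in typings.items()
    }
    for ev in events:
        call = out[ev.sample_id].calls[ev.locus]
        alleles = list(call.alleles)
        after = parse_allele(ev.after, locus_hint=alleles[ev.slot].locus,
                             dash_is_not_typed=False) \
            if ev.after != "Not typed" \
            else AlleleCall.make_not_typed(alleles[ev.slot].locus)
        alleles[ev.slot] = after
        out[ev.sample_id].calls[ev.locus] = GenotypeCall(
            call.locus, tuple(alleles), call.origin_dataset)
    return out


@dataclass(frozen=True)
class NoiseEstimate:
    dropout: float
    truncation: float
    mistyping: float
    n_slots: int
    n_dropout: int
    n_truncation: int
    n_mistyping: int


def estimate_noise_rates(truth_typings: Mapping[str, SampleTyping],
                         observed: Mapping[str, SampleTyping]
                         ) -> NoiseEstimate:
    """Recover the channel rates by diffing observed calls against truth.

    Estimators follow the sequential channel structure: dropout over all
    truly-typed slots; truncation over surviving slots; mistyping over
    surviving, untruncated slots.
    """
    n = n_drop = n_trunc = n_mis = 0
    n_truncatable = 0
    for sid, truth_t in truth_typings.items():
        obs_t = observed[sid]
        for locus_name, truth_call in truth_t.calls.items():
            obs_call = obs_t.calls[locus_name]
            for a, b in zip(truth_call.alleles, obs_call.alleles):
                if not a.is_typed:
                    continue
                n += 1
                if not b.is_typed:
                    n_drop += 1
                    continue
                if a.depth > 2:
                    n_truncatable += 1
                    if b.depth == 2 and b.fields == a.fields[:2]:
                        n_trunc += 1
                        continue
                if b != a:
                    n_mis += 1
    d = n_drop / n if n else 0.0
    t = n_trunc / n_truncatable if n_truncatable else 0.0
    m_denom = n - n_drop - n_trunc
    m = n_mis / m_denom if m_denom else 0.0
    return NoiseEstimate(d, t, m, n, n_drop, n_trunc, n_mis)


def simulate_duplicates(truth: TruthSet, profile_a: NoiseProfile,
                        profile_b: NoiseProfile,
                        rng: np.random.Generator,
                        ) -> Tuple[Dict[str, SampleTyping],
                                   Dict[str, SampleTyping],
                                   List[DuplicatePair],
                                   List[NoiseEvent]]:
    """Render the same truth twice under independent noise and assay
    designs; every sample becomes one duplicate pair."""
    clean_a = render_truth(truth, profile_a.label, profile_a.loci)
    clean_b = render_truth(truth, profile_b.label, profile_b.loci)
    obs_a, ev_a = apply_noise(clean_a, profile_a, truth.pools, rng)
    obs_b, ev_b = apply_noise(clean_b, profile_b, truth.pools, rng)
    pairs = [DuplicatePair(sid, profile_a.label, sid, profile_b.label)
             for sid in truth.samples]
    return obs_a, obs_b, pairs, [*ev_a, *ev_b]


@dataclass
class StudyBundle:
    """One simulated cohort: truth, observed calls, pedigree, noise log."""

    truth: TruthSet
    typings: Dict[str, SampleTyping]
    trios: List[TrioRecord]
    events: List[NoiseEvent]


def simulate_study(cfg: SimulationConfig,
                   dataset_label: str = "simulated") -> StudyBundle:
    """Families plus rendered, noised calls — the full trio-analysis input."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_families(cfg, rng)
    clean = render_truth(truth, dataset_label)
    observed, events = apply_noise(clean, cfg.noise_profile(dataset_label),
                                   truth.pools, rng)
    return StudyBundle(truth, observed, truth.trios, events)
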