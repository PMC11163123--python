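#!/usr/bin/env python
"""Simulate the three trio cohorts the consistency analysis runs on.

Three study arms with realistic sizes and failure modes:

* ``research_exome`` — 14 trios, all 29 loci; coverage-limited, so calls
  are sometimes truncated to 2 fields and occasionally dropped or wrong;
* ``clinical_exome`` — 25 trios, all 29 loci; deep coverage, low noise;
* ``panel`` — 40 trios, the 11 targeted classical loci only; very clean
  but with occasional dropout at the copy-number-variable DRB paralogs.

Writes generic typing TSVs, pedigrees, and noise-event logs under
``results/sim/`` for the downstream scoring scripts.
"""

import os

from hla_concord.nomenclature import REPORT_LOCI
from hla_concord.synthetic_data import SimulationConfig, simulate_study
from hla_concord.typing_io import write_typing_tsv

OUT = os.path.join("results", "sim")

PANEL_LOCI = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1",
              "DRB3", "DRB4", "DRB5")

COHORTS = {
    "research_exome": SimulationConfig(
        loci=REPORT_LOCI, n_families=14, seed=101,
        dropout_rate=0.02, truncation_rate=0.06, mistyping_rate=0.01),
    "clinical_exome": SimulationConfig(
        loci=REPORT_LOCI, n_families=25, seed=102,
        dropout_rate=0.005, truncation_rate=0.01, mistyping_rate=0.002),
    "panel": SimulationConfig(
        loci=PANEL_LOCI, n_families=40, seed=103,
        dropout_rate=0.01, truncation_rate=0.0, mistyping_rate=0.005),
}


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    for label, cfg in COHORTS.items():
        bundle = simulate_study(cfg, dataset_label=label)
        write_typing_tsv(bundle.typings,
                         os.path.join(OUT, f"{label}.typing.tsv"))
        with open(os.path.join(OUT, f"{label}.pedigree.tsv"), "w") as fh:
            fh.write("family\tchild\tfather\tmother\n")
            for t in bundle.trios:
                fh.write(f"{t.family_id}\t{t.child_id}\t{t.father_id}\t"
                         f"{t.mother_id}\n")
        with open(os.path.join(OUT, f"{label}.noise_events.tsv"), "w") as fh:
            fh.write("sample\tlocus\tslot\tkind\tbefore\tafter\n")
            for ev in bundle.events:
                fh.write(f"{ev.sample_id}\t{ev.locus}\t{ev.slot}\t"
                         f"{ev.kind}\t{ev.before}\t{ev.after}\n")
        print(f"{label}: {cfg.n_families} trios, {len(cfg.loci)} loci, "
              f"{len(bundle.events)} noise events -> {OUT}/{label}.*")


if __name__ == "__main__":
    main()
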