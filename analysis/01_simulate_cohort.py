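#!/usr/bin/env python
"""Simulate the demonstration cohort.

Writes, under results/demo_run/data/: genotypes for 374 half-sib animals
(26 sires) at five designed miRNA loci plus 5,000 unlinked background markers,
the miRBase-dialect annotation and sequence files for those loci, five 3'UTRs
with planted allele-specific target sites, and trait/expression/protein tables
with known planted effects (truth.json records everything planted).
"""

import json

from mirsnp_rewire.pipeline import RunConfig, stage_simulate

CONFIG = RunConfig(workdir="results/demo_run", seed=1)

if __name__ == "__main__":
    truth = stage_simulate(CONFIG)
    print(f"cohort: {truth['n_individuals']} animals, {truth['n_sires']} sires")
    print("planted transcript classes:")
    for t, info in truth["transcript_classes"].items():
        print(f"  {t:10s} {info['class']:14s} layer={info['layer']}")
    print(f"inputs written under {CONFIG.data_dir}")
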