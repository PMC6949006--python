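"""Generate the study-design synthetic dataset.

Writes per-locus FASTA (parents, hybrid clone reads, hybrid direct
reads), the sample map, the truth table and a config echo under
results/dataset/.  Design: 20 + 20 parental individuals, 14 hybrids (all
F1, maternal mix 11 from parent B : 3 from parent A), five nuclear loci
(657/505/529/263/271 bp) and an 815 bp chloroplast spacer.
"""

from _common import DATASET, study_config

from hybdiag.synthetic import write_dataset

cfg = study_config()
out = write_dataset(cfg, DATASET)
n_records = cfg.n_parent_a + cfg.n_parent_b + cfg.n_hybrid
print(f"dataset written to {out} (seed={cfg.seed})")
print(f"  {len(cfg.loci)} nuclear loci + 1 chloroplast locus")
print(f"  {n_records} individuals; hybrids carry "
      f"{cfg.clones_per_individual} clone reads + 1 direct read per nuclear locus")
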