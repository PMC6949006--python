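"""Shared setup for the analysis drivers: the study-design dataset.

Drivers operate on the synthetic study-scale cohort (20 + 20 parents,
14 hybrids, five nuclear loci + chloroplast spacer, seed 2020).  If
``results/dataset`` exists (written by 01_simulate.py) it is read back
through the FASTA reader, exercising the full I/O path; otherwise the
dataset is simulated in memory with the same seed.
"""

from pathlib import Path

from hybdiag.seqio import SampleMap, read_locus_fasta
from hybdiag.synthetic import SimConfig, simulate

SEED = 2020
ROOT = Path(__file__).resolve().parent.parent
DATASET = ROOT / "results" / "dataset"
RESULTS = ROOT / "results"


def study_config() -> SimConfig:
    return SimConfig(seed=SEED)


def load_alignments():
    cfg = study_config()
    names = [l.name for l in cfg.loci] + [cfg.cp_locus.name]
    if DATASET.exists():
        sm = SampleMap.read_tsv(DATASET / "samples.tsv")
        return cfg, {
            name: read_locus_fasta(
                DATASET / f"{name}.fasta",
                name,
                "chloroplast" if name == cfg.cp_locus.name else "nuclear",
                sm,
            )
            for name in names
        }
    alignments, _ = simulate(cfg)
    return cfg, alignments
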