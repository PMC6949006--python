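"""Call hybrid classes and infer hybridization direction.

Composes each hybrid's per-locus haplotype origins, calls its class
(F1 / parental / later-generation-or-backcross / ambiguous), assigns the
maternal parent from the chloroplast spacer, and summarizes direction.
Writes results/hybrid_calls.tsv and results/summary.json.
"""

from _common import RESULTS, load_alignments, study_config

from hybdiag.pipeline import classify_cohort, write_calls_tsv, write_summary_json

cfg, alignments = load_alignments()
cohort = classify_cohort(alignments, cfg.cp_locus.name, t_nuclear=1, t_cp=0)

RESULTS.mkdir(exist_ok=True)
write_calls_tsv(cohort, RESULTS / "hybrid_calls.tsv")
write_summary_json(cohort, RESULTS / "summary.json")

d = cohort.direction
print(f"hybrid classes: {cohort.class_histogram()}")
print(f"maternal parent: A={d.n_maternal_a}  B={d.n_maternal_b}  "
      f"unassigned={d.n_unassigned}")
print(f"direction verdict: {d.verdict} (major maternal parent: {d.major_maternal})")
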