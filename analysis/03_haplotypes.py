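"""Collapse phased sequences into per-locus haplotype tables.

Hybrid clone reads are phased per individual (majority rule over eight
clones, singleton one-step variants folded in as PCR artifacts), joined
with the parental and chloroplast sequences, collapsed into distinct
haplotypes and labelled by sharing class.  Writes results/haplotypes.tsv.
"""

from _common import RESULTS, load_alignments

from hybdiag.pipeline import analyse_locus, write_haplotypes_tsv

cfg, alignments = load_alignments()
results = {name: analyse_locus(aln) for name, aln in alignments.items()}

RESULTS.mkdir(exist_ok=True)
write_haplotypes_tsv(results, RESULTS / "haplotypes.tsv")

print("locus        hapsA hapsB  hybrid: total sharedA sharedB unique")
for name in sorted(results):
    r = results[name]
    s = r.sharing
    print(f"{name:<12} {len(r.table.by_role('parent_a')):>5} "
          f"{len(r.table.by_role('parent_b')):>5}        "
          f"{s['hybrid_total']:>5} {s['shared_with_a']:>7} "
          f"{s['shared_with_b']:>7} {s['hybrid_unique']:>6}")
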