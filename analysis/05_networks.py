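"""Build median-joining haplotype networks per locus.

Constructs the epsilon = 0 MJ network for every locus from the phased
haplotype tables, exports GraphML + TSV edge lists and a static plot per
locus under results/networks/.
"""

from _common import RESULTS, load_alignments

from hybdiag.mj_network import export_network, median_joining_network, plot_network
from hybdiag.pipeline import analyse_locus

cfg, alignments = load_alignments()
outdir = RESULTS / "networks"
outdir.mkdir(parents=True, exist_ok=True)

for name in sorted(alignments):
    table = analyse_locus(alignments[name]).table
    net = median_joining_network(table.haplotypes, epsilon=0)
    export_network(net, str(outdir / name))
    plot_network(net, str(outdir / f"{name}.png"))
    n_obs = len(net.observed_ids())
    n_med = len(net.graph) - n_obs
    print(f"{name:<12} {n_obs:>2} observed haplotypes, {n_med} median nodes, "
          f"{net.graph.number_of_edges()} edges"
          + ("  [truncated]" if net.truncated else ""))
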