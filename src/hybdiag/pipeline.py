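"""End-to-end hybrid-diagnosis pipeline over a set of locus alignments.

Ties the stages together: diagnostic fixed differences per nuclear locus,
additivity of hybrid direct reads, haplotype tables with sharing classes,
per-individual hybrid-class calls, chloroplast maternal assignment, and a
cohort direction summary.  Also writes the TSV/JSON tables the analysis
drivers and the CLI expose.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import diagnostics, haplotypes, hybrid_classify
from .seqio import LocusAlignment, partition_by_role


@dataclass
class LocusResult:
    locus: str
    marker_class: str
    alignment_length: int
    sites: list[diagnostics.DiagnosticSite]
    table: haplotypes.HaplotypeTable
    sharing: dict[str, int]
    segregating_a: int
    segregating_b: int
    additivity: list[diagnostics.AdditivityReport] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return sum(1 for s in self.sites if s.kind == "substitution")

    @property
    def n_indels(self) -> int:
        return sum(1 for s in self.sites if s.kind == "indel")


@dataclass
class CohortResult:
    loci: dict[str, LocusResult]
    cp_locus: str
    calls: list[hybrid_classify.HybridCall]
    direction: hybrid_classify.DirectionSummary
    thresholds: dict[str, int]

    def class_histogram(self) -> dict[str, int]:
        hist: dict[str, int] = {}
        for c in self.calls:
            hist[c.hybrid_class] = hist.get(c.hybrid_class, 0) + 1
        return dict(sorted(hist.items()))


def analyse_locus(aln: LocusAlignment) -> LocusResult:
    """Per-locus analysis: fixed differences, haplotypes, sharing, additivity."""
    a, b, h = partition_by_role(aln)
    sites = diagnostics.find_fixed_differences(a, b)
    phased = haplotypes.phased_records_for_hybrids(aln.records)
    table = haplotypes.classify_sharing(haplotypes.collapse_haplotypes(phased))
    reports = []
    if aln.marker_class == "nuclear":
        for read in h:
            if read.read_type == "direct":
                reports.append(diagnostics.check_additivity(read, sites))
    return LocusResult(
        locus=aln.locus,
        marker_class=aln.marker_class,
        alignment_length=aln.length,
        sites=sites,
        table=table,
        sharing=haplotypes.sharing_summary(table),
        segregating_a=diagnostics.segregating_sites(a),
        segregating_b=diagnostics.segregating_sites(b),
        additivity=reports,
    )


def classify_cohort(
    alignments: dict[str, LocusAlignment],
    cp_locus: str,
    t_nuclear: int = 1,
    t_cp: int = 0,
) -> CohortResult:
    """Run the full pipeline and call every hybrid individual.

    ``alignments`` maps locus name -> alignment; ``cp_locus`` names the
    chloroplast marker used for maternal assignment.
    """
    if cp_locus not in alignments:
        raise hybrid_classify.UsageError(f"chloroplast locus {cp_locus!r} missing")
    results = {name: analyse_locus(aln) for name, aln in alignments.items()}
    nuclear = [n for n in alignments if n != cp_locus]
    if not nuclear:
        raise hybrid_classify.UsageError("no nuclear loci to classify on")

    parental_tables: dict[str, tuple[list, list]] = {}
    for name in nuclear:
        t = results[name].table
        parental_tables[name] = (t.by_role("parent_a"), t.by_role("parent_b"))

    # per-individual phased haplotypes at each nuclear locus
    hybrid_ids: list[str] = []
    per_ind: dict[str, dict[str, tuple]] = {}
    for name in nuclear:
        aln = alignments[name]
        _, _, hyb = partition_by_role(aln)
        by_sample: dict[str, list] = {}
        for r in hyb:
            if r.read_type == "clone":
                by_sample.setdefault(r.sample_id, []).append(r)
        for sid, clones in by_sample.items():
            seqs = haplotypes.phase_individual(clones)
            pair = tuple(
                _match_haplotype(results[name].table, s) for s in seqs
            )
            per_ind.setdefault(sid, {})[name] = pair
            if sid not in hybrid_ids:
                hybrid_ids.append(sid)

    cp_table = results[cp_locus].table
    cp_a = cp_table.by_role("parent_a")
    cp_b = cp_table.by_role("parent_b")
    _, _, cp_hyb = partition_by_role(alignments[cp_locus])
    cp_by_sample = {r.sample_id: r for r in cp_hyb}

    calls: list[hybrid_classify.HybridCall] = []
    for sid in hybrid_ids:
        comp = hybrid_classify.compose_genotype(
            sid, per_ind[sid], parental_tables, t=t_nuclear
        )
        call = hybrid_classify.call_hybrid_class(comp)
        if sid in cp_by_sample:
            call.maternal = hybrid_classify.assign_maternal(
                cp_by_sample[sid], cp_a, cp_b, t=t_cp
            )
        calls.append(call)

    direction = hybrid_classify.summarize_direction(calls)
    return CohortResult(
        loci=results,
        cp_locus=cp_locus,
        calls=calls,
        direction=direction,
        thresholds={"t_nuclear": t_nuclear, "t_cp": t_cp},
    )


def _match_haplotype(table: haplotypes.HaplotypeTable, seq: str):
    for h in table.haplotypes:
        if haplotypes.sequences_match(h.sequence, seq):
            return h
    # phased sequence absent from the joint table (should not happen when the
    # table was built from the same phased records); wrap it unlabelled
    return haplotypes.Haplotype(
        locus=table.locus, hap_id=f"{table.locus}_Hx", sequence=seq
    )


# ---------------------------------------------------------------- writers

def write_sites_tsv(results: dict[str, LocusResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["locus", "kind", "start", "end", "state_a", "state_b"])
        for name in sorted(results):
            for s in results[name].sites:
                w.writerow([s.locus, s.kind, s.start, s.end, s.state_a, s.state_b])


def write_haplotypes_tsv(results: dict[str, LocusResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "locus", "hap_id", "count_parent_a", "count_parent_b",
            "count_hybrid", "sharing", "sequence",
        ])
        for name in sorted(results):
            for h in results[name].table.haplotypes:
                w.writerow([
                    h.locus, h.hap_id, h.count("parent_a"), h.count("parent_b"),
                    h.count("hybrid"), h.sharing, h.sequence,
                ])


def write_calls_tsv(cohort: CohortResult, path: str | Path) -> None:
    loci = sorted(n for n in cohort.loci if n != cohort.cp_locus)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "hybrid_class", "maternal", "n_usable_loci"]
                   + [f"comp_{n}" for n in loci])
        for c in sorted(cohort.calls, key=lambda c: c.sample_id):
            w.writerow([c.sample_id, c.hybrid_class, c.maternal, c.n_usable_loci]
                       + [c.evidence.get(n, "") for n in loci])


def write_summary_json(cohort: CohortResult, path: str | Path) -> None:
    d = cohort.direction
    payload = {
        "class_histogram": cohort.class_histogram(),
        "direction": {
            "n_maternal_a": d.n_maternal_a,
            "n_maternal_b": d.n_maternal_b,
            "n_unassigned": d.n_unassigned,
            "verdict": d.verdict,
            "major_maternal": d.major_maternal,
        },
        "thresholds": cohort.thresholds,
        "assumptions": ["chloroplast inheritance is maternal"],
        "loci": {
            name: {
                "marker_class": r.marker_class,
                "alignment_length": r.alignment_length,
                "n_fixed_substitutions": r.n_substitutions,
                "n_fixed_indels": r.n_indels,
                "segregating_parent_a": r.segregating_a,
                "segregating_parent_b": r.segregating_b,
                "haplotypes_parent_a": len(r.table.by_role("parent_a")),
                "haplotypes_parent_b": len(r.table.by_role("parent_b")),
                "sharing": r.sharing,
                "n_hybrids_all_additive": sum(
                    1 for rep in r.additivity if rep.all_additive
                ),
            }
            for name, r in sorted(cohort.loci.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
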