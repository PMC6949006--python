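"""Haplotype collapsing, sharing classes and mutational distances.

Phased sequences (clone reads, chloroplast reads, or unambiguous direct
reads) are grouped into distinct haplotypes per locus, DnaSP-style, with
one deliberate departure: the gap character is compared as a fifth state,
so haplotypes separated only by a fixed indel remain distinct (site
exclusion would merge them, and the study's loci segregate fixed indels).

Mutational distance between haplotypes = number of differing substitution
columns + number of differing maximal gap-run events; an indel of any
length is one step.  'N' positions are skipped pairwise.

Hybrids are phased by cloning (eight colonies per individual): an
individual contributes its at-most-two majority clone sequences, and
singleton clone variants one step away from a majority sequence are folded
in as PCR/cloning artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import ROLES, SequenceRecord

GAP = "-"


class PhasingError(ValueError):
    pass


class UsageError(ValueError):
    pass


@dataclass
class Haplotype:
    locus: str
    hap_id: str
    sequence: str
    count_by_role: dict[str, int] = field(default_factory=dict)
    sharing: str | None = None

    @property
    def total_count(self) -> int:
        return sum(self.count_by_role.values())

    def count(self, role: str) -> int:
        return self.count_by_role.get(role, 0)


@dataclass
class HaplotypeTable:
    locus: str
    haplotypes: list[Haplotype]
    comparison_policy: str = (
        "all columns; gap is a fifth state; 'N' excluded pairwise and "
        "resolved by joining"
    )

    def by_role(self, role: str) -> list[Haplotype]:
        return [h for h in self.haplotypes if h.count(role) > 0]


_AMBIG = set("RYSWKMBDHV")


def sequences_match(a: str, b: str) -> bool:
    """Identity under the comparison policy: N is a pairwise wildcard."""
    if len(a) != len(b):
        return False
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def _resolve(a: str, b: str) -> str:
    """Merge two matching sequences, preferring known states over N."""
    return "".join(y if x == "N" else x for x, y in zip(a, b))


def mutational_distance(a: str, b: str) -> int:
    """Substitution differences plus gap-run-event differences.

    Columns where either sequence is 'N' are skipped (they also break gap
    runs; phased haplotypes are expected to be essentially complete).
    """
    if len(a) != len(b):
        raise UsageError("sequences must be aligned to the same length")
    n_sub = 0
    n_indel = 0
    run = 0  # 0 = no open gap run; +1 = a gapped; -1 = b gapped
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            run = 0
            continue
        xg, yg = x == GAP, y == GAP
        if xg != yg:
            orient = 1 if xg else -1
            if run != orient:  # orientation flip opens a new event
                n_indel += 1
            run = orient
        else:
            run = 0
            if not xg and x != y:
                n_sub += 1
    return n_sub + n_indel


def collapse_haplotypes(records: list[SequenceRecord]) -> HaplotypeTable:
    """Group identical phased sequences into a per-locus haplotype table.

    Haplotypes are ordered by (descending total count, first appearance);
    hap_ids are ``<locus>_H<rank>`` and stable across reruns.  Records
    carrying IUPAC ambiguity codes are rejected: heterozygous direct reads
    are not haplotypes.
    """
    if not records:
        raise UsageError("no records to collapse")
    locus = records[0].locus
    for r in records:
        if r.locus != locus:
            raise UsageError(f"mixed loci: {locus} vs {r.locus}")
        if set(r.sequence) & _AMBIG:
            raise PhasingError(
                f"record {r.sample_id} carries ambiguity codes; phase it first"
            )
    groups: list[dict] = []  # {"sequence", "counts", "order"}
    for order, r in enumerate(records):
        for g in groups:
            if sequences_match(g["sequence"], r.sequence):
                g["sequence"] = _resolve(g["sequence"], r.sequence)
                g["counts"][r.role] = g["counts"].get(r.role, 0) + 1
                break
        else:
            groups.append(
                {"sequence": r.sequence, "counts": {r.role: 1}, "order": order}
            )
    groups.sort(key=lambda g: (-sum(g["counts"].values()), g["order"]))
    haps = [
        Haplotype(
            locus=locus,
            hap_id=f"{locus}_H{i + 1}",
            sequence=g["sequence"],
            count_by_role=dict(g["counts"]),
        )
        for i, g in enumerate(groups)
    ]
    return HaplotypeTable(locus=locus, haplotypes=haps)


def classify_sharing(table: HaplotypeTable) -> HaplotypeTable:
    """Label each haplotype by role membership.

    Hybrid-borne haplotypes are classed by their parental provenance
    (parent_a_only / parent_b_only / shared_ab / hybrid_unique); purely
    parental haplotypes the hybrid does not carry are absent_in_hybrid.
    """
    for h in table.haplotypes:
        in_a = h.count("parent_a") > 0
        in_b = h.count("parent_b") > 0
        in_h = h.count("hybrid") > 0
        if not in_h:
            h.sharing = "absent_in_hybrid"
        elif in_a and in_b:
            h.sharing = "shared_ab"
        elif in_a:
            h.sharing = "parent_a_only"
        elif in_b:
            h.sharing = "parent_b_only"
        else:
            h.sharing = "hybrid_unique"
    return table


def sharing_summary(table: HaplotypeTable) -> dict[str, int]:
    """Hybrid-centric sharing counts: of the hybrid's haplotypes, how many
    are shared with each parent or unique."""
    out = {"hybrid_total": 0, "shared_with_a": 0, "shared_with_b": 0,
           "shared_with_both": 0, "hybrid_unique": 0}
    for h in table.haplotypes:
        if h.count("hybrid") == 0:
            continue
        out["hybrid_total"] += 1
        in_a = h.count("parent_a") > 0
        in_b = h.count("parent_b") > 0
        if in_a and in_b:
            out["shared_with_both"] += 1
        elif in_a:
            out["shared_with_a"] += 1
        elif in_b:
            out["shared_with_b"] += 1
        else:
            out["hybrid_unique"] += 1
    return out


def min_mutational_steps(
    hap: Haplotype, panel: list[Haplotype]
) -> tuple[int, list[str]]:
    """Minimum mutational distance from ``hap`` to a panel, with all arg-mins."""
    if not panel:
        raise UsageError("panel must be non-empty")
    best = None
    ids: list[str] = []
    for other in panel:
        d = mutational_distance(hap.sequence, other.sequence)
        if best is None or d < best:
            best, ids = d, [other.hap_id]
        elif d == best:
            ids.append(other.hap_id)
    return best, ids


def phase_individual(clones: list[SequenceRecord]) -> list[str]:
    """Extract an individual's (at most two) haplotypes from its clone reads.

    Clone sequences are grouped by identity; singleton groups within one
    mutational step of a larger group are folded into it (PCR/cloning
    artifacts).  The surviving groups are ranked by (count, first
    appearance) and the top two sequences returned; a single surviving
    group means the individual is homozygous and its sequence is returned
    twice.
    """
    if not clones:
        raise UsageError("no clone reads for individual")
    groups: list[dict] = []
    for order, r in enumerate(clones):
        for g in groups:
            if sequences_match(g["sequence"], r.sequence):
                g["sequence"] = _resolve(g["sequence"], r.sequence)
                g["count"] += 1
                break
        else:
            groups.append({"sequence": r.sequence, "count": 1, "order": order})
    groups.sort(key=lambda g: (-g["count"], g["order"]))
    majors = [g for g in groups if g["count"] > 1]
    if not majors:  # all singletons: keep the two earliest
        majors = groups[:2]
        groups = groups[2:]
    else:
        groups = [g for g in groups if g["count"] == 1]
    for g in groups:  # fold singleton artifacts into the nearest major
        dists = [mutational_distance(g["sequence"], m["sequence"]) for m in majors]
        if dists and min(dists) <= 1:
            majors[dists.index(min(dists))]["count"] += g["count"]
        else:
            majors.append(g)
    majors.sort(key=lambda g: (-g["count"], g["order"]))
    majors = majors[:2]
    if len(majors) == 1:
        return [majors[0]["sequence"], majors[0]["sequence"]]
    return [majors[0]["sequence"], majors[1]["sequence"]]


def phased_records_for_hybrids(
    records: list[SequenceRecord],
) -> list[SequenceRecord]:
    """Turn hybrid clone reads into two phased records per individual.

    Parental and chloroplast records pass through untouched; hybrid
    heterozygous direct reads are dropped (only clone-phased sequences
    enter the haplotype table for hybrids).
    """
    out: list[SequenceRecord] = []
    by_sample: dict[str, list[SequenceRecord]] = {}
    for r in records:
        if r.role == "hybrid" and r.read_type == "clone":
            by_sample.setdefault(r.sample_id, []).append(r)
        elif r.role == "hybrid" and set(r.sequence) & _AMBIG:
            continue  # heterozygous direct read; phased by clones instead
        else:
            out.append(r)
    for sample_id in by_sample:
        seqs = phase_individual(by_sample[sample_id])
        for i, s in enumerate(seqs):
            out.append(
                SequenceRecord(
                    sample_id=sample_id,
                    clone_id=f"phased{i + 1}",
                    locus=by_sample[sample_id][0].locus,
                    role="hybrid",
                    read_type="clone",
                    sequence=s,
                )
            )
    return out
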