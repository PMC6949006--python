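"""Hybrid-class calls and hybridization direction.

Each putative hybrid is diploid at every nuclear locus, so its per-locus
haplotype pair is an unordered composition over origins A (parent a),
B (parent b) and U (a haplotype seen in neither parent).  Unique
haplotypes are resolved to a parent when they sit within ``t`` mutational
steps of one parent's haplotypes and strictly closer to that parent than
to the other (default t = 1: the study's unique haplotypes are one step
from a parental haplotype, consistent with unsampled parental
polymorphism).

Class rules over the resolved loci:
  * F1                      — {A,B} at every usable locus
  * parental_A / parental_B — {A,A} (resp. {B,B}) everywhere
  * later_gen_or_backcross  — a mix of {A,B} with one homozygote class only
    (F2 and BC1 are deliberately merged: they are not separable from
    composition patterns at a handful of loci)
  * ambiguous               — anything else, including zero usable loci

The chloroplast is maternally inherited, so an F1's chlorotype names its
seed parent; the default chloroplast threshold is 0 (exact match), since
hybrid chlorotypes are expected to be identical to a parental one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .haplotypes import Haplotype, HaplotypeTable, min_mutational_steps
from .seqio import SequenceRecord


class UsageError(ValueError):
    pass


@dataclass
class GenotypeComposition:
    """One individual's per-locus origin pairs (chloroplast excluded)."""

    sample_id: str
    per_locus: dict[str, tuple[str, str]]  # locus -> sorted origin pair over {A,B,U}
    resolved_u: dict[str, tuple[str, int]] = field(default_factory=dict)
    # hap_id -> (resolution in {A,B,unresolved}, distance used)


@dataclass
class HybridCall:
    sample_id: str
    hybrid_class: str
    maternal: str = "unassigned"
    n_usable_loci: int = 0
    evidence: dict[str, str] = field(default_factory=dict)  # locus -> "A/B" etc.
    dropped_loci: list[str] = field(default_factory=list)


@dataclass
class DirectionSummary:
    n_maternal_a: int
    n_maternal_b: int
    n_unassigned: int
    verdict: str  # unidirectional_a / unidirectional_b / bidirectional / undefined
    major_maternal: str | None = None


def resolve_unique(
    hap: Haplotype,
    parental_a: list[Haplotype],
    parental_b: list[Haplotype],
    t: int = 1,
) -> tuple[str, int]:
    """Attribute a hybrid-unique haplotype to the nearer parent within ``t``.

    Returns (origin, distance): origin is 'A' or 'B' when the minimum
    distance to that parent's haplotypes is <= t and strictly smaller than
    to the other parent; 'unresolved' on ties or when both minima exceed t.
    """
    if t < 0:
        raise UsageError("threshold t must be >= 0")
    da, _ = min_mutational_steps(hap, parental_a)
    db, _ = min_mutational_steps(hap, parental_b)
    if da <= t and da < db:
        return "A", da
    if db <= t and db < da:
        return "B", db
    return "unresolved", min(da, db)


def compose_genotype(
    sample_id: str,
    per_locus_haps: dict[str, tuple[Haplotype, Haplotype]],
    parental_tables: dict[str, tuple[list[Haplotype], list[Haplotype]]],
    t: int = 1,
) -> GenotypeComposition:
    """Build the origin composition for one individual.

    ``per_locus_haps`` maps each nuclear locus to the individual's two
    phased haplotypes; ``parental_tables`` maps locus -> (parent_a
    haplotypes, parent_b haplotypes).
    """
    per_locus: dict[str, tuple[str, str]] = {}
    resolved: dict[str, tuple[str, int]] = {}
    for locus, pair in per_locus_haps.items():
        pa, pb = parental_tables[locus]
        origins = []
        for hap in pair:
            in_a = any(h.sequence == hap.sequence for h in pa)
            in_b = any(h.sequence == hap.sequence for h in pb)
            if in_a and not in_b:
                origins.append("A")
            elif in_b and not in_a:
                origins.append("B")
            elif in_a and in_b:
                origins.append("U")  # shared haplotype is uninformative
                resolved[hap.hap_id] = ("unresolved", 0)
            else:
                res, d = resolve_unique(hap, pa, pb, t)
                origins.append(res if res in ("A", "B") else "U")
                resolved[hap.hap_id] = (res, d)
        per_locus[locus] = tuple(sorted(origins))  # type: ignore[assignment]
    return GenotypeComposition(sample_id, per_locus, resolved)


def call_hybrid_class(comp: GenotypeComposition) -> HybridCall:
    """Call the hybrid class from the resolved per-locus compositions.

    Loci containing an unresolved origin (U) are dropped from the call and
    listed in the evidence.
    """
    if not comp.per_locus:
        raise UsageError(f"{comp.sample_id}: no nuclear loci to classify")
    usable: dict[str, tuple[str, str]] = {}
    dropped: list[str] = []
    for locus, pair in comp.per_locus.items():
        if "U" in pair:
            dropped.append(locus)
        else:
            usable[locus] = pair
    kinds = set(usable.values())
    if not usable:
        cls = "ambiguous"
    elif kinds == {("A", "B")}:
        cls = "F1"
    elif kinds == {("A", "A")}:
        cls = "parental_A"
    elif kinds == {("B", "B")}:
        cls = "parental_B"
    elif kinds == {("A", "A"), ("A", "B")}:
        cls = "later_gen_or_backcross_A"
    elif kinds == {("A", "B"), ("B", "B")}:
        cls = "later_gen_or_backcross_B"
    else:
        cls = "ambiguous"
    return HybridCall(
        sample_id=comp.sample_id,
        hybrid_class=cls,
        n_usable_loci=len(usable),
        evidence={loc: "/".join(pair) for loc, pair in comp.per_locus.items()},
        dropped_loci=sorted(dropped),
    )


def assign_maternal(
    cp_record: SequenceRecord,
    cp_haps_a: list[Haplotype],
    cp_haps_b: list[Haplotype],
    t: int = 0,
) -> str:
    """Name the maternal parent from the chloroplast sequence.

    Exact chlorotype match wins immediately; otherwise nearest-within-t
    with strict inequality, as for nuclear unique haplotypes.
    """
    if not cp_haps_a or not cp_haps_b:
        raise UsageError("parental chlorotype lists must be non-empty")
    probe = Haplotype(
        locus=cp_record.locus, hap_id="cp_query", sequence=cp_record.sequence
    )
    da, _ = min_mutational_steps(probe, cp_haps_a)
    db, _ = min_mutational_steps(probe, cp_haps_b)
    if da == 0 and db > 0:
        return "parent_a"
    if db == 0 and da > 0:
        return "parent_b"
    if da <= t and da < db:
        return "parent_a"
    if db <= t and db < da:
        return "parent_b"
    return "unassigned"


def summarize_direction(calls: list[HybridCall]) -> DirectionSummary:
    """Count maternal assignments over non-parental calls and give a verdict."""
    hyb = [
        c
        for c in calls
        if c.hybrid_class not in ("parental_A", "parental_B")
    ]
    counts = Counter(c.maternal for c in hyb)
    n_a = counts.get("parent_a", 0)
    n_b = counts.get("parent_b", 0)
    n_u = counts.get("unassigned", 0)
    if n_a > 0 and n_b > 0:
        verdict = "bidirectional"
    elif n_a > 0:
        verdict = "unidirectional_a"
    elif n_b > 0:
        verdict = "unidirectional_b"
    else:
        verdict = "undefined"
    major = None
    if n_a != n_b and (n_a or n_b):
        major = "parent_a" if n_a > n_b else "parent_b"
    return DirectionSummary(n_a, n_b, n_u, verdict, major)
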