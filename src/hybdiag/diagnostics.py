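"""Diagnostic fixed differences between two parental panels.

A column is a *differentially fixed substitution* when each parental panel
is monomorphic for a nucleotide and the two panels differ; a *fixed indel*
is a maximal run of columns that is entirely gap in one panel and entirely
base in the other.  Indels are counted as single mutational events, not per
column.  'N' is missing data: it is ignored when assessing fixation, but a
column where a whole panel is missing is disqualified.  Columns where either
panel carries IUPAC ambiguity codes are disqualified with a warning (panels
are expected to hold phased or homozygous sequences).

Hybrid direct reads are checked for *additivity*: at a diagnostic
substitution site a true heterozygote shows superimposed chromatogram peaks
of both parental bases, coded as the IUPAC ambiguity character for the pair.
Heterozygous indels cannot be scored from a single direct read (the trace
collapses downstream of the gap), so indel sites are non-evaluable here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import AlignmentError, SequenceRecord

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
AMBIG = frozenset("RYSWKMBDHV")

#: IUPAC code for each unordered pair of distinct bases
_IUPAC_PAIR: dict[frozenset[str], str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


class UsageError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticSite:
    """A differentially fixed difference between the parental panels.

    ``start``/``end`` are 1-based inclusive alignment columns; a
    substitution occupies a single column, an indel a maximal gap run.
    For indels exactly one of ``state_a``/``state_b`` is the gap event
    (rendered as '-' * run length).
    """

    locus: str
    kind: str  # "substitution" or "indel"
    start: int
    end: int
    state_a: str
    state_b: str
    near_fixed_flag: bool = False  # True when a column failed fixation by one sequence

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "indel"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.state_a == self.state_b:
            raise ValueError("diagnostic site states must differ")

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class AdditivityReport:
    """Per-site additivity of one direct read at the diagnostic sites."""

    sample_id: str
    locus: str
    per_site: list[tuple[DiagnosticSite, str, str, bool, bool]] = field(
        default_factory=list
    )  # (site, observed, expected, additive?, evaluable?)
    all_additive: bool = False
    no_evidence: bool = False


def _column_states(panel: list[SequenceRecord], col0: int) -> set[str]:
    """Distinct non-missing states of a 0-based column within a panel."""
    return {r.sequence[col0] for r in panel} - {"N"}


def _fixed_state(panel: list[SequenceRecord], col0: int) -> str | None:
    """The single state a panel is fixed for at a column, or None."""
    states = _column_states(panel, col0)
    return next(iter(states)) if len(states) == 1 else None


def find_fixed_differences(
    parent_a: list[SequenceRecord], parent_b: list[SequenceRecord]
) -> list[DiagnosticSite]:
    """Scan the two parental panels for fixed substitutions and indel events.

    Returns sites sorted by start column; deterministic.  Columns with
    ambiguity codes in either panel are disqualified (logged).  Columns that
    miss fixation because of exactly one deviant sequence are flagged via a
    warning so near-fixed sites are visible in logs.
    """
    if not parent_a or not parent_b:
        raise UsageError("both parental panels must be non-empty")
    length = len(parent_a[0])
    for r in list(parent_a) + list(parent_b):
        if len(r) != length:
            raise AlignmentError(
                f"record {r.sample_id} has length {len(r)}, expected {length}"
            )
    locus = parent_a[0].locus

    subs: list[DiagnosticSite] = []
    # per-column indel orientation: +1 = A gapped/B base, -1 = A base/B gapped
    indel_orient: list[int] = [0] * length

    for c in range(length):
        col_a = _column_states(parent_a, c)
        col_b = _column_states(parent_b, c)
        if (col_a | col_b) & AMBIG:
            logger.warning(
                "%s col %d: ambiguity code in a parental panel; column disqualified",
                locus,
                c + 1,
            )
            continue
        if not col_a or not col_b:  # a panel entirely missing here
            continue
        if len(col_a) == 1 and len(col_b) == 1:
            a, b = next(iter(col_a)), next(iter(col_b))
            if a == b:
                continue
            if a == "-" or b == "-":
                indel_orient[c] = 1 if a == "-" else -1
            else:
                subs.append(
                    DiagnosticSite(locus, "substitution", c + 1, c + 1, a, b)
                )
        else:
            _warn_near_fixed(parent_a, parent_b, c, locus)

    sites = subs + _gap_runs_to_sites(indel_orient, locus)
    return sorted(sites, key=lambda s: (s.start, s.kind))


def _warn_near_fixed(
    parent_a: list[SequenceRecord],
    parent_b: list[SequenceRecord],
    c: int,
    locus: str,
) -> None:
    # flag columns that fail fixation by exactly one deviant sequence
    for panel, name in ((parent_a, "parent_a"), (parent_b, "parent_b")):
        states = [r.sequence[c] for r in panel if r.sequence[c] != "N"]
        if len(set(states)) == 2:
            minority = min(set(states), key=states.count)
            if states.count(minority) == 1:
                logger.warning(
                    "%s col %d: %s near-fixed (one deviant sequence)",
                    locus,
                    c + 1,
                    name,
                )


def _gap_runs_to_sites(orient: list[int], locus: str) -> list[DiagnosticSite]:
    """Collapse per-column indel orientations into maximal-run events."""
    sites: list[DiagnosticSite] = []
    c = 0
    n = len(orient)
    while c < n:
        if orient[c] == 0:
            c += 1
            continue
        start = c
        o = orient[c]
        while c < n and orient[c] == o:
            c += 1
        run = c - start
        gap = "-" * run
        # the non-gap panel's state is summarised as a run-length descriptor
        if o == 1:  # parent_a gapped
            sites.append(
                DiagnosticSite(locus, "indel", start + 1, c, gap, f"{run}bp")
            )
        else:
            sites.append(
                DiagnosticSite(locus, "indel", start + 1, c, f"{run}bp", gap)
            )
    return sites


def segregating_sites(panel: list[SequenceRecord]) -> int:
    """Intraspecific polymorphism count within one panel.

    Counts columns with >= 2 distinct non-missing, non-gap bases, plus one
    per maximal run of columns where the panel mixes gap and base (a
    segregating indel counts as one event regardless of its length).
    """
    if not panel:
        raise UsageError("panel must be non-empty")
    length = len(panel[0])
    n_sub = 0
    indel_col = [False] * length
    for c in range(length):
        states = {r.sequence[c] for r in panel} - {"N"}
        if len(states - {"-"}) >= 2:
            n_sub += 1
        if "-" in states and (states - {"-"}):
            indel_col[c] = True
    n_indel = 0
    prev = False
    for flag in indel_col:
        if flag and not prev:
            n_indel += 1
        prev = flag
    return n_sub + n_indel


def additive_consensus(state_a: str, state_b: str) -> str:
    """IUPAC character for the superimposed signal of two parental bases.

    Symmetric; returns the input base when the states are equal.
    """
    if state_a not in BASES or state_b not in BASES:
        raise ValueError(
            f"additive consensus requires plain bases, got {state_a!r},{state_b!r}"
        )
    if state_a == state_b:
        return state_a
    return _IUPAC_PAIR[frozenset((state_a, state_b))]


def check_additivity(
    read: SequenceRecord, sites: list[DiagnosticSite]
) -> AdditivityReport:
    """Score a hybrid's direct read for peak additivity at diagnostic sites.

    Substitution sites are additive when the read shows the IUPAC code for
    the parental pair.  Indel sites are marked non-evaluable.  A read with
    zero evaluable sites gets ``all_additive=False`` and ``no_evidence=True``.
    """
    if read.read_type != "direct":
        raise UsageError("additivity is scored on direct reads only")
    per_site: list[tuple[DiagnosticSite, str, str, bool, bool]] = []
    for site in sites:
        if site.end > len(read):
            raise IndexError(
                f"site column {site.end} beyond read length {len(read)}"
            )
        if site.kind == "indel":
            obs = read.sequence[site.start - 1 : site.end]
            per_site.append((site, obs, "", False, False))
            continue
        expected = additive_consensus(site.state_a, site.state_b)
        observed = read.sequence[site.start - 1]
        per_site.append((site, observed, expected, observed == expected, True))
    evaluable = [t for t in per_site if t[4]]
    no_evidence = not evaluable
    all_additive = bool(evaluable) and all(t[3] for t in evaluable)
    return AdditivityReport(
        sample_id=read.sample_id,
        locus=read.locus,
        per_site=per_site,
        all_additive=all_additive,
        no_evidence=no_evidence,
    )
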