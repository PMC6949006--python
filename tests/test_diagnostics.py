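"""Diagnostics unit tests against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from Bio.Data.IUPACData import ambiguous_dna_values
from hypothesis import given, settings, strategies as st

from hybdiag.diagnostics import (
    DiagnosticSite,
    UsageError,
    additive_consensus,
    check_additivity,
    find_fixed_differences,
    segregating_sites,
)
from conftest import make_panel, make_record


# ------------------------------------------------------------------ oracle

def oracle_fixed_differences(seqs_a, seqs_b):
    """Exhaustive column scan, written independently of the implementation.

    Returns (substitution columns 1-based with states, indel events as
    (start, end, gapped_panel)).
    """
    length = len(seqs_a[0])
    subs = []
    indel_cols = {}
    for c in range(length):
        sa = {s[c] for s in seqs_a if s[c] != "N"}
        sb = {s[c] for s in seqs_b if s[c] != "N"}
        if len(sa) != 1 or len(sb) != 1 or not sa or not sb:
            continue
        a, b = sa.pop(), sb.pop()
        if a == b:
            continue
        if a == "-":
            indel_cols[c] = "a"
        elif b == "-":
            indel_cols[c] = "b"
        else:
            subs.append((c + 1, a, b))
    events = []
    for c in sorted(indel_cols):
        if c - 1 in indel_cols and indel_cols[c - 1] == indel_cols[c]:
            events[-1] = (events[-1][0], c + 1, indel_cols[c])
        else:
            events.append((c + 1, c + 1, indel_cols[c]))
    return subs, events


def random_panels(rng, n_each=4, length=30):
    alphabet = np.array(list("ACGT-N"))
    probs = [0.25, 0.25, 0.2, 0.2, 0.07, 0.03]
    a = ["".join(rng.choice(alphabet, size=length, p=probs)) for _ in range(n_each)]
    b = ["".join(rng.choice(alphabet, size=length, p=probs)) for _ in range(n_each)]
    return a, b


def test_find_fixed_differences_matches_exhaustive_scan_on_random_panels(rng):
    for _ in range(200):
        sa, sb = random_panels(rng)
        pa = make_panel(sa, "parent_a")
        pb = make_panel(sb, "parent_b")
        sites = find_fixed_differences(pa, pb)
        exp_subs, exp_indels = oracle_fixed_differences(sa, sb)
        got_subs = [
            (s.start, s.state_a, s.state_b)
            for s in sites
            if s.kind == "substitution"
        ]
        got_indels = [
            (s.start, s.end, "a" if s.state_a.startswith("-") else "b")
            for s in sites
            if s.kind == "indel"
        ]
        assert got_subs == sorted(exp_subs)
        assert got_indels == sorted(exp_indels)


def test_planted_toy_panel_recovers_planted_sites():
    # 2 substitution columns (3, 8) and one 3-column gap run (5-7) in panel b
    a = ["ACGTAAATT", "ACGTAAATT", "ACGTAAATT"]
    b = ["ACTT---CT", "ACTT---CT", "ACTT---CT"]
    sites = find_fixed_differences(make_panel(a, "parent_a"), make_panel(b, "parent_b"))
    assert [(s.kind, s.start, s.end) for s in sites] == [
        ("substitution", 3, 3),
        ("indel", 5, 7),
        ("substitution", 8, 8),
    ]


def test_identical_panels_yield_no_sites():
    a = make_panel(["ACGT", "ACGT"], "parent_a")
    b = make_panel(["ACGT", "ACGT"], "parent_b")
    assert find_fixed_differences(a, b) == []


def test_polymorphic_column_is_never_diagnostic_even_if_disjoint():
    # panel a carries {A, C}, panel b {G}: disjoint state sets but not fixed
    a = make_panel(["A", "C"], "parent_a")
    b = make_panel(["G", "G"], "parent_b")
    assert find_fixed_differences(a, b) == []


def test_missing_data_never_creates_false_sites(rng):
    # sprinkle N over <=10% of a clean monomorphic pair of panels
    base_a, base_b = "ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGA"
    pa = [list(base_a) for _ in range(5)]
    pb = [list(base_b) for _ in range(5)]
    for panel in (pa, pb):
        for s in panel:
            for c in rng.choice(len(s), size=2, replace=False):
                s[c] = "N"
    sites = find_fixed_differences(
        make_panel(["".join(s) for s in pa], "parent_a"),
        make_panel(["".join(s) for s in pb], "parent_b"),
    )
    # only the true planted difference at the last column may be reported
    assert all(s.start == 20 for s in sites)


def test_empty_panel_is_a_usage_error():
    with pytest.raises(UsageError):
        find_fixed_differences([], make_panel(["A"], "parent_b"))


def test_ambiguity_codes_disqualify_column(caplog):
    a = make_panel(["AR", "AA"], "parent_a")
    b = make_panel(["GG", "GG"], "parent_b")
    with caplog.at_level("WARNING"):
        sites = find_fixed_differences(a, b)
    assert [(s.start, s.state_a, s.state_b) for s in sites] == [(1, "A", "G")]


# -------------------------------------------------------- segregating sites

@pytest.mark.parametrize(
    "seqs,expected",
    [
        (["ACGT", "ACGT", "ACGT"], 0),
        (["ACGT", "ACTT", "GCGT"], 2),  # columns 1 and 3 polymorphic
        (["AC--T", "ACGGT"], 1),  # one 2-column gap run = one event
        (["AC--T", "ACGGT", "ACG-T"], 1),  # overlapping runs still one run
        (["ANGT", "ANGT"], 0),  # N is missing, not a state
    ],
)
def test_segregating_sites_counts_columns_and_indel_runs(seqs, expected):
    assert segregating_sites(make_panel(seqs, "parent_a")) == expected


def test_segregating_sites_on_planted_polymorphisms():
    seqs = ["AAAAAAAAAA", "AAATAAAAAA", "CAAAAAAAGA"]
    assert segregating_sites(make_panel(seqs, "parent_a")) == 3


# ------------------------------------------------------- additive consensus

def test_additive_consensus_matches_iupac_standard_for_all_pairs():
    # independent reference: Biopython's IUPAC ambiguity table
    code_for_pair = {
        frozenset(v): k
        for k, v in ambiguous_dna_values.items()
        if len(set(v)) == 2
    }
    for a, b in itertools.product("ACGT", repeat=2):
        got = additive_consensus(a, b)
        if a == b:
            assert got == a
        else:
            assert got == code_for_pair[frozenset((a, b))]
            assert got == additive_consensus(b, a)  # symmetry


def test_additive_consensus_rejects_gaps_and_ambiguity():
    with pytest.raises(ValueError):
        additive_consensus("A", "-")
    with pytest.raises(ValueError):
        additive_consensus("R", "G")


# ------------------------------------------------------------- additivity

SITES = [
    DiagnosticSite("toy", "substitution", 2, 2, "A", "G"),
    DiagnosticSite("toy", "substitution", 5, 5, "C", "T"),
    DiagnosticSite("toy", "indel", 7, 8, "--", "2bp"),
]


def test_fully_additive_read_passes():
    read = make_record("ARGCYAGGT", role="hybrid")
    rep = check_additivity(read, SITES)
    assert rep.all_additive and not rep.no_evidence
    evaluable = [t for t in rep.per_site if t[4]]
    assert len(evaluable) == 2 and all(t[3] for t in evaluable)
    # indel site present but non-evaluable
    assert [t[4] for t in rep.per_site] == [True, True, False]


def test_parental_read_fails_with_zero_additive_sites():
    read = make_record("AAGCCAGGT", role="hybrid")
    rep = check_additivity(read, SITES)
    assert not rep.all_additive
    assert sum(1 for t in rep.per_site if t[3]) == 0


def test_partially_additive_read_reports_failing_column():
    read = make_record("ARGCCAGGT", role="hybrid")  # additive at 2, not at 5
    rep = check_additivity(read, SITES)
    assert not rep.all_additive
    failing = [t[0].start for t in rep.per_site if t[4] and not t[3]]
    assert failing == [5]


def test_zero_evaluable_sites_flags_no_evidence():
    read = make_record("ACGTACGTA", role="hybrid")
    rep = check_additivity(read, [SITES[2]])
    assert rep.no_evidence and not rep.all_additive


def test_site_beyond_read_length_is_bounds_error():
    read = make_record("ACG", role="hybrid")
    with pytest.raises(IndexError):
        check_additivity(read, SITES)


# --------------------------------------------------------------- property

@given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
@settings(max_examples=50, deadline=None)
def test_additive_consensus_symmetric_and_idempotent(a, b):
    assert additive_consensus(a, b) == additive_consensus(b, a)
    assert additive_consensus(a, a) == a
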