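"""Haplotype collapsing, sharing and distance tests with brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybdiag.haplotypes import (
    Haplotype,
    PhasingError,
    UsageError,
    classify_sharing,
    collapse_haplotypes,
    min_mutational_steps,
    mutational_distance,
    phase_individual,
    phased_records_for_hybrids,
    sharing_summary,
)
from conftest import make_panel, make_record


# ------------------------------------------------------------------ oracle

def oracle_distance(a, b):
    """All-pairs Hamming + gap-event distance, written independently."""
    subs = 0
    events = 0
    prev_event = None  # None / 'a_gap' / 'b_gap'
    for x, y in zip(a, b):
        if "N" in (x, y):
            prev_event = None
            continue
        if x == "-" and y != "-":
            if prev_event != "a_gap":
                events += 1
            prev_event = "a_gap"
        elif y == "-" and x != "-":
            if prev_event != "b_gap":
                events += 1
            prev_event = "b_gap"
        else:
            prev_event = None
            if x != y and x != "-":
                subs += 1
    return subs + events


def oracle_group(seqs):
    """Brute-force exact grouping (no N resolution needed for clean input)."""
    groups = {}
    for s in seqs:
        groups.setdefault(s, 0)
        groups[s] += 1
    return groups


# ------------------------------------------------------------- collapsing

def test_collapse_matches_bruteforce_grouping(rng):
    strings = ["ACGT-A", "ACGTTA", "AC-TTA"]
    for _ in range(50):
        picks = [strings[i] for i in rng.integers(0, 3, size=10)]
        table = collapse_haplotypes(make_panel(picks, "parent_a"))
        expected = oracle_group(picks)
        got = {h.sequence: h.total_count for h in table.haplotypes}
        assert got == expected


def test_collapse_toy_counts_and_ordering():
    seqs = ["AAA"] * 4 + ["CCC"] * 2 + ["GGG"]
    table = collapse_haplotypes(make_panel(seqs, "hybrid"))
    assert [(h.sequence, h.total_count) for h in table.haplotypes] == [
        ("AAA", 4), ("CCC", 2), ("GGG", 1),
    ]
    assert [h.hap_id for h in table.haplotypes] == ["toy_H1", "toy_H2", "toy_H3"]


def test_collapse_identical_panel_is_single_haplotype():
    table = collapse_haplotypes(make_panel(["ACGT"] * 20, "parent_a"))
    assert len(table.haplotypes) == 1
    assert table.haplotypes[0].count("parent_a") == 20


def test_collapse_resolves_n_by_joining():
    table = collapse_haplotypes(make_panel(["ACNT", "ACGT"], "parent_a"))
    assert len(table.haplotypes) == 1
    assert table.haplotypes[0].sequence == "ACGT"


def test_gap_is_a_fifth_state_separating_haplotypes():
    table = collapse_haplotypes(make_panel(["AC-T", "ACGT"], "parent_a"))
    assert len(table.haplotypes) == 2


def test_collapse_rejects_ambiguity_codes():
    with pytest.raises(PhasingError, match="s0"):
        collapse_haplotypes(make_panel(["ACRT"], "hybrid"))


def test_collapse_conserves_per_role_counts():
    records = (
        make_panel(["AAAA", "AAAT", "AAAA"], "parent_a", prefix="a")
        + make_panel(["CCCC"] * 2, "parent_b", prefix="b")
        + make_panel(["AAAA", "CCCC"], "hybrid", prefix="h")
    )
    table = collapse_haplotypes(records)
    for role, n in (("parent_a", 3), ("parent_b", 2), ("hybrid", 2)):
        assert sum(h.count(role) for h in table.haplotypes) == n


def test_collapse_idempotent():
    records = make_panel(["AAAA", "AAAT", "AAAA"], "parent_a")
    t1 = collapse_haplotypes(records)
    again = [
        make_record(h.sequence, sample_id=h.hap_id, role="parent_a")
        for h in t1.haplotypes
    ]
    t2 = collapse_haplotypes(again)
    assert [h.sequence for h in t2.haplotypes] == [h.sequence for h in t1.haplotypes]


# ---------------------------------------------------------------- sharing

def test_classify_sharing_labels_by_role_membership():
    records = (
        make_panel(["AAAA"], "parent_a", prefix="a")
        + make_panel(["CCCC"], "parent_b", prefix="b")
        + make_panel(["AAAA", "CCCC", "GGGG"], "hybrid", prefix="h")
        + make_panel(["TTTT"], "parent_a", prefix="x")
    )
    table = classify_sharing(collapse_haplotypes(records))
    by_seq = {h.sequence: h.sharing for h in table.haplotypes}
    assert by_seq == {
        "AAAA": "parent_a_only",
        "CCCC": "parent_b_only",
        "GGGG": "hybrid_unique",
        "TTTT": "absent_in_hybrid",
    }
    assert sharing_summary(table) == {
        "hybrid_total": 3, "shared_with_a": 1, "shared_with_b": 1,
        "shared_with_both": 0, "hybrid_unique": 1,
    }


def test_haplotype_in_all_roles_is_shared_ab():
    records = (
        make_panel(["AAAA"], "parent_a", prefix="a")
        + make_panel(["AAAA"], "parent_b", prefix="b")
        + make_panel(["AAAA"], "hybrid", prefix="h")
    )
    table = classify_sharing(collapse_haplotypes(records))
    assert table.haplotypes[0].sharing == "shared_ab"


# --------------------------------------------------------------- distance

def test_distance_matches_oracle_on_random_gapped_pairs(rng):
    alphabet = np.array(list("ACGT-N"))
    for _ in range(200):
        a = "".join(rng.choice(alphabet, size=25, p=[0.23, 0.23, 0.23, 0.21, 0.07, 0.03]))
        b = "".join(rng.choice(alphabet, size=25, p=[0.23, 0.23, 0.23, 0.21, 0.07, 0.03]))
        assert mutational_distance(a, b) == oracle_distance(a, b)


def test_indel_event_of_any_length_is_one_step():
    assert mutational_distance("A---T", "AGGGT") == 1
    assert mutational_distance("A-T-A", "AGTGA") == 2


def test_min_mutational_steps_finds_all_argmins():
    panel = [
        Haplotype("toy", "h1", "AAAA"),
        Haplotype("toy", "h2", "AAAT"),
        Haplotype("toy", "h3", "TAAA"),
    ]
    probe = Haplotype("toy", "q", "AAGA")
    d, ids = min_mutational_steps(probe, panel)
    assert d == 1 and ids == ["h1"]
    d, ids = min_mutational_steps(Haplotype("toy", "q2", "TAAT"), panel)
    assert d == 1 and set(ids) == {"h2", "h3"}


def test_min_steps_to_panel_containing_itself_is_zero():
    panel = [Haplotype("toy", "h1", "ACGT")]
    assert min_mutational_steps(Haplotype("toy", "q", "ACGT"), panel) == (0, ["h1"])


def test_min_steps_empty_panel_is_usage_error():
    with pytest.raises(UsageError):
        min_mutational_steps(Haplotype("toy", "q", "ACGT"), [])


GAPPED = st.text(alphabet="ACGT-", min_size=8, max_size=8)
UNGAPPED = st.text(alphabet="ACGT", min_size=8, max_size=8)


@given(GAPPED, GAPPED)
@settings(max_examples=200, deadline=None)
def test_distance_symmetry_and_identity(a, b):
    assert mutational_distance(a, b) == mutational_distance(b, a)
    assert (mutational_distance(a, b) == 0) == (a == b)


@given(UNGAPPED, UNGAPPED, UNGAPPED)
@settings(max_examples=200, deadline=None)
def test_distance_triangle_inequality_on_gap_free_sequences(a, b, c):
    # on gap-free haplotypes the distance is plain Hamming, hence a metric;
    # with gaps a k-column indel costs one step and can undercut k
    # substitutions, so the triangle inequality deliberately does not hold
    assert mutational_distance(a, c) <= mutational_distance(a, b) + mutational_distance(b, c)


# ---------------------------------------------------------------- phasing

def clones(seqs, sample_id="h1", locus="toy"):
    return [
        make_record(s, sample_id=sample_id, role="hybrid", locus=locus,
                    read_type="clone", clone_id=f"c{i}")
        for i, s in enumerate(seqs)
    ]


def test_phase_heterozygote_returns_both_majority_sequences():
    got = phase_individual(clones(["AAAA"] * 5 + ["CCCC"] * 3))
    assert sorted(got) == ["AAAA", "CCCC"]


def test_phase_homozygote_returns_sequence_twice():
    assert phase_individual(clones(["AAAA"] * 8)) == ["AAAA", "AAAA"]


def test_singleton_one_step_variant_folds_into_majority():
    # one PCR artifact one step from the first allele
    got = phase_individual(clones(["AAAA"] * 4 + ["CCCC"] * 3 + ["AAAT"]))
    assert sorted(got) == ["AAAA", "CCCC"]


def test_singleton_true_allele_far_from_majority_is_kept():
    got = phase_individual(clones(["AAAA"] * 7 + ["CCCC"]))
    assert sorted(got) == ["AAAA", "CCCC"]


def test_phased_records_drop_heterozygous_direct_reads():
    records = (
        make_panel(["AAAA"], "parent_a", prefix="a")
        + [make_record("ARAA", sample_id="h1", role="hybrid")]
        + clones(["AAAA"] * 4 + ["AGAA"] * 4)
    )
    phased = phased_records_for_hybrids(records)
    hybrid_seqs = sorted(r.sequence for r in phased if r.role == "hybrid")
    assert hybrid_seqs == ["AAAA", "AGAA"]
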