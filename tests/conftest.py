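import numpy as np
import pytest

from hybdiag.seqio import SequenceRecord
from hybdiag.synthetic import LocusSpec, CpLocusSpec, SimConfig


def make_record(seq, sample_id="s1", role="parent_a", locus="toy",
                read_type="direct", clone_id=None):
    return SequenceRecord(
        sample_id=sample_id, clone_id=clone_id, locus=locus, role=role,
        read_type=read_type, sequence=seq,
    )


def make_panel(seqs, role, locus="toy", prefix="s"):
    return [
        make_record(s, sample_id=f"{prefix}{i}", role=role, locus=locus)
        for i, s in enumerate(seqs)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture
def small_config():
    """A compact study design: 6+6 parents, 4 F1 hybrids, 3 short loci."""
    return SimConfig(
        n_parent_a=6,
        n_parent_b=6,
        n_hybrid=4,
        loci=(
            LocusSpec("locA", 120, 3, 1, (2, 1)),
            LocusSpec("locB", 100, 2, 0, (1, 2)),
            LocusSpec("locC", 90, 2, 0, (1, 1)),
        ),
        cp_locus=CpLocusSpec("cp", 150, 3),
        hybrid_class_mix={"F1": 4},
        maternal_mix={"parent_a": 1, "parent_b": 3},
        seed=7,
    )
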