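"""Synthetic datasets with the structure the hybrid-diagnosis pipeline assumes.

The generator emulates a two-species hybrid-zone Sanger study: two
divergent parental panels with per-locus fixed differences and low
intraspecific polymorphism, hybrids of known class (F1, F2, BC1) formed by
Mendelian segregation over unlinked loci, clone-phased reads (eight clones
per individual, as when PCR products are cloned to phase heterozygotes),
direct reads with IUPAC-coded heterozygous sites, and a maternally
inherited chloroplast marker.  A truth table records every planted fact so
each pipeline stage can be checked against planted truth.

Defaults mirror the study design the package was built around: panels of
20 + 20 parents and 14 hybrids; five nuclear loci (lengths 657, 505, 529,
263, 271) plus an 815 bp chloroplast spacer; per-locus fixed-difference
counts 7, 2+2 indels, 4+1, 2, 4+1 and 6 (chloroplast); all hybrids F1 with
a maternal mix of 11 from parent B and 3 from parent A.

Mutation model: uniform random substitutions under infinite sites (no
column is hit twice), indels as gap runs of 1-5 columns; loci are unlinked
with free recombination between and none within.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .diagnostics import additive_consensus
from .seqio import LocusAlignment, SampleMap, SequenceRecord, write_locus_fasta


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LocusSpec:
    """Planted structure of one nuclear locus."""

    name: str
    length: int
    n_fixed_substitutions: int
    n_fixed_indels: int = 0
    # distinct haplotypes to plant within each parental panel (1 = monomorphic)
    panel_haplotypes: tuple[int, int] = (1, 1)


@dataclass(frozen=True)
class CpLocusSpec:
    name: str
    length: int
    n_fixed_substitutions: int


@dataclass
class SimConfig:
    n_parent_a: int = 20
    n_parent_b: int = 20
    n_hybrid: int = 14
    loci: tuple[LocusSpec, ...] = (
        LocusSpec("its", 657, 7, 0, (1, 1)),
        LocusSpec("dbr1", 505, 2, 2, (5, 2)),
        LocusSpec("sos4a", 529, 4, 1, (7, 5)),
        LocusSpec("sos4b", 263, 2, 0, (5, 4)),
        LocusSpec("pcrf1", 271, 4, 1, (1, 1)),
    )
    cp_locus: CpLocusSpec = CpLocusSpec("trnv_trnm", 815, 6)
    hybrid_class_mix: dict[str, int] = field(default_factory=lambda: {"F1": 14})
    maternal_mix: dict[str, int] = field(
        default_factory=lambda: {"parent_b": 11, "parent_a": 3}
    )
    clones_per_individual: int = 8
    clone_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.hybrid_class_mix.values()) != self.n_hybrid:
            raise ConfigError("hybrid_class_mix must sum to n_hybrid")
        if sum(self.maternal_mix.values()) != self.n_hybrid:
            raise ConfigError("maternal_mix must sum to n_hybrid")
        for loc in self.loci:
            # substitutions + indels (runs up to 5) + panel variants must fit
            budget = (
                loc.n_fixed_substitutions
                + 5 * loc.n_fixed_indels
                + sum(loc.panel_haplotypes)
            )
            if budget >= loc.length:
                raise ConfigError(f"locus {loc.name}: length too short for sites")


@dataclass
class PlantedLocus:
    """Ground truth for one locus: parental haplotype pools and sites."""

    spec: LocusSpec | CpLocusSpec
    haplotypes_a: list[str]
    haplotypes_b: list[str]
    sub_columns: list[int]  # 1-based
    indel_runs: list[tuple[int, int]]  # 1-based inclusive
    assignment_a: list[int] = field(default_factory=list)  # individual -> hap index
    assignment_b: list[int] = field(default_factory=list)


@dataclass
class TruthTable:
    per_sample: dict[str, dict] = field(default_factory=dict)
    per_locus: dict[str, PlantedLocus] = field(default_factory=dict)


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _plant_locus(
    rng: np.random.Generator, spec: LocusSpec | CpLocusSpec
) -> PlantedLocus:
    """Ancestral sequence + fixed differences + intra-panel variants."""
    is_cp = isinstance(spec, CpLocusSpec)
    n_indels = 0 if is_cp else spec.n_fixed_indels
    panel_haps = (1, 1) if is_cp else spec.panel_haplotypes

    anc = _random_seq(rng, spec.length)
    used: set[int] = set()  # 0-based columns consumed (infinite sites)

    # fixed indel runs: placed first so their (1-5)-column footprint fits
    indel_runs: list[tuple[int, int]] = []
    for _ in range(n_indels):
        run_len = int(rng.integers(1, 6))
        for _attempt in range(1000):
            start = int(rng.integers(1, spec.length - run_len))
            footprint = set(range(start - 1, start + run_len + 1))  # with flanks
            if not footprint & used:
                used |= footprint
                indel_runs.append((start + 1, start + run_len))
                break
        else:
            raise ConfigError(f"cannot place indel run in locus {spec.name}")

    free = [c for c in range(spec.length) if c not in used]
    rng.shuffle(free)

    def take() -> int:
        if not free:
            raise ConfigError(f"locus {spec.name}: out of free columns")
        return free.pop()

    sub_columns = sorted(take() for _ in range(spec.n_fixed_substitutions))

    base_a = list(anc)
    base_b = list(anc)
    for c in sub_columns:
        base_b[c] = _other_base(rng, base_a[c])
    for start, end in indel_runs:
        # coin-flip which panel carries the deletion
        target = base_a if rng.integers(0, 2) == 0 else base_b
        for c in range(start - 1, end):
            target[c] = "-"
    sub_columns_1 = [c + 1 for c in sub_columns]

    def derive(panel_base: list[str], k: int) -> list[str]:
        # each extra haplotype differs from the panel base by one private
        # substitution at a fresh non-diagnostic column (infinite sites)
        haps = ["".join(panel_base)]
        for _ in range(k - 1):
            c = take()
            while panel_base[c] == "-":
                c = take()
            var = list(panel_base)
            var[c] = _other_base(rng, var[c])
            haps.append("".join(var))
        return haps

    return PlantedLocus(
        spec=spec,
        haplotypes_a=derive(base_a, panel_haps[0]),
        haplotypes_b=derive(base_b, panel_haps[1]),
        sub_columns=sub_columns_1,
        indel_runs=sorted(indel_runs),
    )


def simulate_parents(cfg: SimConfig, rng: np.random.Generator) -> TruthTable:
    """Plant all loci and assign parental individuals to haplotypes.

    Each parental individual is homozygous; the first k individuals of a
    panel carry its k planted haplotypes so every requested haplotype is
    realised, the rest draw uniformly.
    """
    truth = TruthTable()
    for spec in list(cfg.loci) + [cfg.cp_locus]:
        planted = _plant_locus(rng, spec)
        ka, kb = len(planted.haplotypes_a), len(planted.haplotypes_b)
        if ka > cfg.n_parent_a or kb > cfg.n_parent_b:
            raise ConfigError(
                f"locus {spec.name}: more panel haplotypes than individuals"
            )
        planted.assignment_a = list(range(ka)) + [
            int(rng.integers(0, ka)) for _ in range(cfg.n_parent_a - ka)
        ]
        planted.assignment_b = list(range(kb)) + [
            int(rng.integers(0, kb)) for _ in range(cfg.n_parent_b - kb)
        ]
        truth.per_locus[spec.name] = planted
    for i in range(cfg.n_parent_a):
        truth.per_sample[f"PA{i + 1:02d}"] = {"role": "parent_a", "class": "parental_A"}
    for i in range(cfg.n_parent_b):
        truth.per_sample[f"PB{i + 1:02d}"] = {"role": "parent_b", "class": "parental_B"}
    return truth


def _direct_consensus(h1: str, h2: str) -> str:
    """IUPAC-coded direct read of a diploid; gap-mismatch columns become N
    (a heterozygous indel garbles the trace downstream, so those columns are
    uncallable from a direct read)."""
    out = []
    for x, y in zip(h1, h2):
        if x == y:
            out.append(x)
        elif "-" in (x, y) or "N" in (x, y):
            out.append("N")
        else:
            out.append(additive_consensus(x, y))
    return "".join(out)


def _apply_clone_errors(
    rng: np.random.Generator, seq: str, rate: float, protected: set[int]
) -> str:
    """Per-base substitution errors, never at protected (diagnostic) columns."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for c in hits:
        if c + 1 in protected or chars[c] == "-":
            continue
        chars[c] = _other_base(rng, chars[c])
    return "".join(chars)


def simulate_hybrids(cfg: SimConfig, truth: TruthTable, rng: np.random.Generator) -> None:
    """Create hybrid genotypes by Mendelian segregation and record truth.

    F1: one haplotype from each species per locus.  BC1_A/BC1_B: an F1
    gamete (fair coin per locus) plus a gamete from the named parent.
    F2: two independent F1 gametes.  The chloroplast is copied from the
    designated mother.
    """
    classes: list[str] = []
    for cls in sorted(cfg.hybrid_class_mix):
        classes += [cls] * cfg.hybrid_class_mix[cls]
    mothers: list[str] = []
    for parent in sorted(cfg.maternal_mix):
        mothers += [parent] * cfg.maternal_mix[parent]

    for i, (cls, mother) in enumerate(zip(classes, mothers)):
        sid = f"HY{i + 1:02d}"
        per_locus: dict[str, tuple[str, str]] = {}
        origins: dict[str, tuple[str, str]] = {}
        for spec in cfg.loci:
            planted = truth.per_locus[spec.name]
            ha = planted.haplotypes_a[rng.integers(0, len(planted.haplotypes_a))]
            hb = planted.haplotypes_b[rng.integers(0, len(planted.haplotypes_b))]
            if cls == "F1":
                pair, org = (ha, hb), ("A", "B")
            elif cls in ("BC1_A", "BC1_B"):
                f1_gamete, f1_org = (ha, "A") if rng.integers(0, 2) == 0 else (hb, "B")
                if cls == "BC1_A":
                    pa = planted.haplotypes_a[
                        rng.integers(0, len(planted.haplotypes_a))
                    ]
                    pair, org = (f1_gamete, pa), (f1_org, "A")
                else:
                    pb = planted.haplotypes_b[
                        rng.integers(0, len(planted.haplotypes_b))
                    ]
                    pair, org = (f1_gamete, pb), (f1_org, "B")
            elif cls == "F2":
                g1, o1 = (ha, "A") if rng.integers(0, 2) == 0 else (hb, "B")
                ha2 = planted.haplotypes_a[rng.integers(0, len(planted.haplotypes_a))]
                hb2 = planted.haplotypes_b[rng.integers(0, len(planted.haplotypes_b))]
                g2, o2 = (ha2, "A") if rng.integers(0, 2) == 0 else (hb2, "B")
                pair, org = (g1, g2), (o1, o2)
            else:
                raise ConfigError(f"unknown hybrid class {cls!r}")
            per_locus[spec.name] = pair
            origins[spec.name] = org
        cp_planted = truth.per_locus[cfg.cp_locus.name]
        cp_seq = (
            cp_planted.haplotypes_a[0] if mother == "parent_a" else cp_planted.haplotypes_b[0]
        )
        truth.per_sample[sid] = {
            "role": "hybrid",
            "class": cls,
            "maternal": mother,
            "nuclear_haplotypes": per_locus,
            "origins": origins,
            "cp_sequence": cp_seq,
        }


def build_alignments(cfg: SimConfig, truth: TruthTable, rng: np.random.Generator
                     ) -> dict[str, LocusAlignment]:
    """Emit per-locus alignments: parental direct reads, hybrid clone reads
    (uniform over the two true haplotypes, with per-base error), hybrid
    direct reads (IUPAC consensus), and chloroplast reads for everyone."""
    alignments: dict[str, LocusAlignment] = {}
    hybrid_ids = [s for s, d in truth.per_sample.items() if d["role"] == "hybrid"]

    for spec in cfg.loci:
        planted = truth.per_locus[spec.name]
        protected = set(planted.sub_columns)
        for s, e in planted.indel_runs:
            protected |= set(range(s, e + 1))
        records: list[SequenceRecord] = []
        for i in range(cfg.n_parent_a):
            records.append(SequenceRecord(
                sample_id=f"PA{i + 1:02d}", locus=spec.name, role="parent_a",
                read_type="direct",
                sequence=planted.haplotypes_a[planted.assignment_a[i]],
            ))
        for i in range(cfg.n_parent_b):
            records.append(SequenceRecord(
                sample_id=f"PB{i + 1:02d}", locus=spec.name, role="parent_b",
                read_type="direct",
                sequence=planted.haplotypes_b[planted.assignment_b[i]],
            ))
        for sid in hybrid_ids:
            h1, h2 = truth.per_sample[sid]["nuclear_haplotypes"][spec.name]
            records.append(SequenceRecord(
                sample_id=sid, locus=spec.name, role="hybrid",
                read_type="direct", sequence=_direct_consensus(h1, h2),
            ))
            # clones drawn uniformly from the two alleles, conditioned on
            # covering both when they differ: phasing by cloning sequences
            # colonies until both alleles are recovered
            templates = [
                h1 if rng.integers(0, 2) == 0 else h2
                for _ in range(cfg.clones_per_individual)
            ]
            if h1 != h2 and cfg.clones_per_individual >= 2:
                if h1 not in templates:
                    templates[int(rng.integers(0, len(templates)))] = h1
                if h2 not in templates:
                    templates[int(rng.integers(0, len(templates)))] = h2
            for c, template in enumerate(templates):
                seq = _apply_clone_errors(
                    rng, template, cfg.clone_error_rate, protected
                )
                records.append(SequenceRecord(
                    sample_id=sid, clone_id=f"c{c + 1}", locus=spec.name,
                    role="hybrid", read_type="clone", sequence=seq,
                ))
        alignments[spec.name] = LocusAlignment(
            locus=spec.name, marker_class="nuclear", records=records
        )

    cp = truth.per_locus[cfg.cp_locus.name]
    records = []
    for i in range(cfg.n_parent_a):
        records.append(SequenceRecord(
            sample_id=f"PA{i + 1:02d}", locus=cfg.cp_locus.name, role="parent_a",
            read_type="direct", sequence=cp.haplotypes_a[0],
        ))
    for i in range(cfg.n_parent_b):
        records.append(SequenceRecord(
            sample_id=f"PB{i + 1:02d}", locus=cfg.cp_locus.name, role="parent_b",
            read_type="direct", sequence=cp.haplotypes_b[0],
        ))
    for sid in hybrid_ids:
        records.append(SequenceRecord(
            sample_id=sid, locus=cfg.cp_locus.name, role="hybrid",
            read_type="direct", sequence=truth.per_sample[sid]["cp_sequence"],
        ))
    alignments[cfg.cp_locus.name] = LocusAlignment(
        locus=cfg.cp_locus.name, marker_class="chloroplast", records=records
    )
    return alignments


def simulate(cfg: SimConfig) -> tuple[dict[str, LocusAlignment], TruthTable]:
    """Run the full generator from a config (single seeded RNG stream)."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_parents(cfg, rng)
    simulate_hybrids(cfg, truth, rng)
    alignments = build_alignments(cfg, truth, rng)
    return alignments, truth


def sample_map_for(truth: TruthTable) -> SampleMap:
    return SampleMap(
        {sid: (d["role"], sid) for sid, d in truth.per_sample.items()}
    )


def write_dataset(cfg: SimConfig, outdir: str | Path) -> Path:
    """Simulate and write FASTA per locus, sample map, truth TSV, config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignments, truth = simulate(cfg)
    for name, aln in alignments.items():
        write_locus_fasta(aln, outdir / f"{name}.fasta")
    sample_map_for(truth).write_tsv(outdir / "samples.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("sample_id\trole\tclass\tmaternal\n")
        for sid in sorted(truth.per_sample):
            d = truth.per_sample[sid]
            fh.write(
                f"{sid}\t{d['role']}\t{d.get('class', '')}\t"
                f"{d.get('maternal', '')}\n"
            )
    cfg_dict = asdict(cfg)
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg_dict, fh, indent=2, default=list, sort_keys=True)
        fh.write("\n")
    return outdir
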