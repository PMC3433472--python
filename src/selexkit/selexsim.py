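"""Synthetic SELEX round generator with ground truth.

Emulates the data a cell-internalization selection produces: a library of
random 20-nt variable regions (flanked by the constant regions and a
per-round barcode), a handful of planted enriched families whose members
sit within edit distance 1 of a founder sequence, fitness-weighted
multinomial resampling from round to round, and low-rate substitution /
indel noise that yields 18-22-nt variable regions.

Round 0 is the unselected library (uniform abundance); selection acts
from round 1 on: the true abundance of sequence i at round r is
a_r(i) ∝ a_0(i) * fitness(i)^r.  Planted family variants carry a small
fitness penalty relative to their founder (mutational load), so the
founder is the fittest — and expectedly the most enriched — member of
its family.  Sequencing/PCR errors are applied per base after sampling
(they are not heritable); a heritable mode applies them before the next
round's resampling instead.

All randomness flows from a single seeded generator in a documented draw
order (library, family planting, per-round multinomial, per-read errors),
so a fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .distfam import edit_distance
from .errors import ConfigurationError, InputError
from .seqio import FLANK3_DNA, FLANK5_DNA, ReadRecord

BASES = "ACGT"

DEFAULT_LIBRARY_SIZE = 10_000
DEFAULT_VARIABLE_LENGTH = 20
DEFAULT_DEPTHS = (10_000,) * 7  # rounds 0..6
DEFAULT_BARCODES = (
    "AACCGGTT", "ACACACAC", "AGAGAGAG", "ATATATAT",
    "CACACACA", "CAGTCAGT", "CGCGCGCG", "CTCTCTCT", "GAGAGAGA",
)


@dataclass
class PlantedFamily:
    """A founder sequence with variants <= 1 edit away, all high-fitness."""

    seed_sequence: str
    n_variants: int
    fitness: float

    def __post_init__(self) -> None:
        if self.fitness < 1:
            raise ConfigurationError("planted family fitness must be >= 1")
        if self.n_variants < 0:
            raise ConfigurationError("n_variants must be >= 0")


@dataclass
class SimConfig:
    seed: int = 0
    library_size: int = DEFAULT_LIBRARY_SIZE
    variable_length: int = DEFAULT_VARIABLE_LENGTH
    depths: Sequence[int] = DEFAULT_DEPTHS  # one per round, round 0 first
    planted_families: Sequence[PlantedFamily] = ()
    variant_fitness_factor: float = 0.9
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    heritable_errors: bool = False
    barcodes: Sequence[str] = DEFAULT_BARCODES
    flank5: str = FLANK5_DNA
    flank3: str = FLANK3_DNA

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= rate < 1:
                raise ConfigurationError("error rates must be in [0, 1)")
        if any(d <= 0 for d in self.depths):
            raise ConfigurationError("per-round depths must be positive")
        if len(self.barcodes) < len(self.depths):
            raise ConfigurationError("need one barcode per round")
        if not 0 < self.variant_fitness_factor <= 1:
            raise ConfigurationError("variant_fitness_factor must be in (0, 1]")

    @property
    def rounds(self) -> list[int]:
        return list(range(len(self.depths)))

    @property
    def barcode_map(self) -> dict[str, int]:
        return {self.barcodes[r]: r for r in self.rounds}


@dataclass
class TruthManifest:
    """Ground truth of one simulation run."""

    templates: list[str]                      # all library members
    family_of: dict[str, int]                 # member sequence -> family index
    family_seeds: list[str]                   # founder per planted family
    fitness: np.ndarray                       # per template
    true_abundance: dict[int, np.ndarray]     # round -> distribution over templates
    provenance: dict[int, list[tuple[int, int]]]  # round -> [(template idx, n errors)]


def random_variable_region(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def edit1_neighborhood_size(length: int, alphabet: int = 4) -> int:
    """Distinct strings within edit distance exactly <= 1 of a string of
    the given length (excluding the string itself), upper bound:
    substitutions + insertions + deletions before deduplication."""
    return (alphabet - 1) * length + alphabet * (length + 1) + length


def plant_family(
    seed_sequence: str, n_variants: int, rng: np.random.Generator
) -> list[str]:
    """The founder plus n_variants distinct sequences at edit distance 1.

    Draws uniformly from the full distance-1 neighborhood (substitutions,
    insertions, deletions, deduplicated); raises when more variants are
    requested than the neighborhood holds.
    """
    neighborhood = set()
    s = seed_sequence
    for i in range(len(s)):
        for b in BASES:
            if b != s[i]:
                neighborhood.add(s[:i] + b + s[i + 1 :])
        neighborhood.add(s[:i] + s[i + 1 :])  # deletion
    for i in range(len(s) + 1):
        for b in BASES:
            neighborhood.add(s[:i] + b + s[i:])  # insertion
    neighborhood.discard(s)
    if n_variants > len(neighborhood):
        raise ConfigurationError(
            f"requested {n_variants} variants but the edit-1 neighborhood "
            f"holds only {len(neighborhood)} distinct sequences")
    ordered = sorted(neighborhood)
    idx = rng.choice(len(ordered), size=n_variants, replace=False)
    return [s] + [ordered[i] for i in sorted(idx)]


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> tuple[str, int]:
    """Per-base substitution/insertion/deletion noise; returns (read, #errors)."""
    if not (config.substitution_rate or config.insertion_rate or config.deletion_rate):
        return seq, 0
    out = []
    n_err = 0
    for ch in seq:
        if config.deletion_rate and rng.random() < config.deletion_rate:
            n_err += 1
            continue
        if config.substitution_rate and rng.random() < config.substitution_rate:
            choices = [b for b in BASES if b != ch]
            ch = choices[rng.integers(0, 3)]
            n_err += 1
        out.append(ch)
        if config.insertion_rate and rng.random() < config.insertion_rate:
            out.append(BASES[rng.integers(0, 4)])
            n_err += 1
    return "".join(out), n_err


@dataclass
class SimulationResult:
    config: SimConfig
    reads: dict[int, list[ReadRecord]]  # round -> full reads (barcode+flanks)
    truth: TruthManifest

    def write_fastq(self, out_dir: str | Path) -> list[Path]:
        """One FASTQ per round (R0.fastq, R1.fastq, ...), constant quality."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for r, reads in sorted(self.reads.items()):
            path = out_dir / f"R{r}.fastq"
            with open(path, "w") as fh:
                for i, read in enumerate(reads):
                    fh.write(f"@sim_r{r}_{i}\n{read.sequence}\n+\n"
                             f"{'I' * len(read.sequence)}\n")
            paths.append(path)
        return paths


def simulate_selex(config: SimConfig) -> SimulationResult:
    """Run the generator: library -> per-round sampled reads + ground truth."""
    rng = np.random.default_rng(config.seed)

    # 1. planted families (draw order: families first, then background)
    members: list[str] = []
    family_of: dict[str, int] = {}
    seeds: list[str] = []
    fitness: list[float] = []
    for fi, fam in enumerate(config.planted_families):
        fam_members = plant_family(fam.seed_sequence, fam.n_variants, rng)
        seeds.append(fam.seed_sequence)
        for mi, m in enumerate(fam_members):
            if m in family_of:
                raise ConfigurationError(f"planted families overlap at {m}")
            family_of[m] = fi
            members.append(m)
            fitness.append(fam.fitness if mi == 0
                           else fam.fitness * config.variant_fitness_factor)

    # 2. background library, distinct from planted members
    taken = set(members)
    target = len(members) + config.library_size
    while len(members) < target:
        s = random_variable_region(rng, config.variable_length)
        if s not in taken:
            taken.add(s)
            members.append(s)
            fitness.append(1.0)

    fit = np.array(fitness)
    n_templates = len(members)
    a0 = np.full(n_templates, 1.0 / n_templates)

    true_abundance: dict[int, np.ndarray] = {}
    provenance: dict[int, list[tuple[int, int]]] = {}
    reads: dict[int, list[ReadRecord]] = {}

    abundance = a0.copy()
    for r, depth in enumerate(config.depths):
        true_abundance[r] = abundance.copy()
        counts = rng.multinomial(depth, abundance)
        round_reads: list[ReadRecord] = []
        prov: list[tuple[int, int]] = []
        barcode = config.barcodes[r]
        heritable_extra: list[str] = []
        for ti in np.flatnonzero(counts):
            for _ in range(int(counts[ti])):
                region, n_err = _apply_errors(members[ti], config, rng)
                if config.heritable_errors and n_err:
                    heritable_extra.append(region)
                full = barcode + config.flank5 + region + config.flank3
                round_reads.append(ReadRecord(full, None, r))
                prov.append((int(ti), n_err))
        reads[r] = round_reads
        provenance[r] = prov
        # next round: fitness-weighted update of the true distribution
        weights = abundance * fit
        abundance = weights / weights.sum()
        if config.heritable_errors and heritable_extra:
            # mutant lineages enter the pool at one-read weight
            unit = 1.0 / max(sum(config.depths[: r + 1]), 1)
            for region in heritable_extra:
                if region in taken:
                    continue
                taken.add(region)
                members.append(region)
                fit = np.append(fit, 1.0)
                abundance = np.append(abundance * (1 - unit), unit)
                abundance /= abundance.sum()

    truth = TruthManifest(
        templates=members,
        family_of=family_of,
        family_seeds=seeds,
        fitness=fit,
        true_abundance=true_abundance,
        provenance=provenance,
    )
    return SimulationResult(config=config, reads=reads, truth=truth)


@dataclass
class RecoveryReport:
    """How well a pipeline run recovered the planted ground truth."""

    seed_recovery: float          # planted founders present in candidate set
    member_assignment: float      # planted members put in their founder's family
    false_family_count: int       # called families with no planted member
    n_seeds: int
    n_members: int


def evaluate_recovery(
    records: Sequence, candidate_ids: Sequence[int], truth: TruthManifest,
) -> RecoveryReport:
    """Score a pipeline's candidate set and family labels against the truth.

    A planted member counts as correctly assigned when its record carries
    the same sequence-family label as its family's founder; founders count
    as recovered when their id is in the candidate set.
    """
    by_seq = {r.variable_region_dna: r for r in records}
    candidates = set(candidate_ids)

    seeds_found = 0
    for s in truth.family_seeds:
        rec = by_seq.get(s)
        if rec is not None and rec.id in candidates:
            seeds_found += 1
    n_seeds = len(truth.family_seeds)

    n_members = len(truth.family_of)
    correct = 0
    for member, fi in truth.family_of.items():
        rec = by_seq.get(member)
        seed_rec = by_seq.get(truth.family_seeds[fi])
        if (rec is not None and seed_rec is not None
                and rec.sequence_family is not None
                and rec.sequence_family == seed_rec.sequence_family):
            correct += 1

    planted_labels = set()
    for member in truth.family_of:
        rec = by_seq.get(member)
        if rec is not None and rec.sequence_family is not None:
            planted_labels.add(rec.sequence_family)
    all_labels = {r.sequence_family for r in records if r.sequence_family is not None}
    false_families = len(all_labels - planted_labels)

    return RecoveryReport(
        seed_recovery=seeds_found / n_seeds if n_seeds else 0.0,
        member_assignment=correct / n_members if n_members else 0.0,
        false_family_count=false_families,
        n_seeds=n_seeds,
        n_members=n_members,
    )
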