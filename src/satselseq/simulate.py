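"""Synthetic-data generator and ground-truth oracle for Sat-Sel-Seq.

Models the selection campaign as repeated fitness-weighted multinomial
bottlenecks: each cycle, survivors of the functional (rifampin-resistance)
selection are drawn with probability proportional to variant count times
relative fitness, then the population is regrown and sequenced. Reads are
rendered with the full leader / generational barcode / anchor / amplicon
layout and i.i.d. substitution noise, so the decoder can be validated
against exact per-read ground truth.

Relative fitness is defined at the amino-acid level by default (synonymous
codons share w; stop codons default to w = 0, the built-in negative
selection), with codon-level overrides. Growth dynamics within a cycle are
absorbed into relative fitness. One master seed drives deterministic
per-stage random streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codons import AA_SYMBOLS, STOP, translate
from .demux import GenerationBarcodeSet
from .library import NNS_CODONS, PositionalLibrary, ReferenceAmplicon, library_reference

NNS_CODONS_SORTED: tuple[str, ...] = tuple(sorted(NNS_CODONS))


class ExtinctionError(RuntimeError):
    """All fitness mass is zero: selection cannot proceed."""


@dataclass(frozen=True)
class FitnessMap:
    """Relative fitness per amino-acid symbol with codon-level overrides."""

    aa_fitness: dict[str, float] = field(default_factory=dict)
    codon_overrides: dict[str, float] = field(default_factory=dict)
    default: float = 1.0
    stop_fitness: float = 0.0

    def w(self, codon: str) -> float:
        if codon in self.codon_overrides:
            return self.codon_overrides[codon]
        aa = translate(codon)
        if aa == STOP:
            return self.aa_fitness.get(STOP, self.stop_fitness)
        return self.aa_fitness.get(aa, self.default)

    @classmethod
    def flat(cls, value: float = 1.0, stop: float | None = None) -> "FitnessMap":
        """Neutral map: every variant (optionally including stop) shares w."""
        return cls(default=value, stop_fitness=value if stop is None else stop)

    @classmethod
    def from_aa(cls, aa_fitness: dict[str, float], stop: float = 0.0) -> "FitnessMap":
        return cls(aa_fitness=dict(aa_fitness), stop_fitness=stop)

    def aa_table(self) -> pd.Series:
        vals = {}
        for aa in AA_SYMBOLS:
            if aa == STOP:
                vals[aa] = self.aa_fitness.get(STOP, self.stop_fitness)
            else:
                vals[aa] = self.aa_fitness.get(aa, self.default)
        return pd.Series(vals, name="fitness")


@dataclass
class Population:
    """Variant (codon) counts at one generation."""

    counts: dict[str, int]
    generation: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("population is empty")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        t = self.total
        return {v: n / t for v, n in self.counts.items() if n > 0}

    def aa_frequencies(self) -> pd.Series:
        vec = pd.Series(0.0, index=list(AA_SYMBOLS))
        for codon, f in self.frequencies().items():
            vec[translate(codon)] += f
        return vec


def initial_population(
    depth: int,
    skew: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Multinomial draw of the starting (G0) library over the 32 NNS codons.

    ``skew`` gives non-uniform codon probabilities (cloning bias); default
    is uniform 1/32 each.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = rng or np.random.default_rng()
    k = len(NNS_CODONS_SORTED)
    if skew is None:
        p = np.full(k, 1.0 / k)
    else:
        skew = np.asarray(skew, dtype=float)
        if skew.shape != (k,):
            raise ValueError(f"skew must have length {k}")
        p = skew / skew.sum()
    draws = rng.multinomial(depth, p)
    return Population(
        counts={c: int(n) for c, n in zip(NNS_CODONS_SORTED, draws)}, generation=0
    )


def select_generation(
    pop: Population,
    fitness: FitnessMap,
    bottleneck: int,
    rng: np.random.Generator | None = None,
) -> Population:
    """One selection cycle: multinomial bottleneck weighted by count x w."""
    rng = rng or np.random.default_rng()
    variants = sorted(v for v, n in pop.counts.items() if n > 0)
    weights = np.array([pop.counts[v] * fitness.w(v) for v in variants], dtype=float)
    mass = weights.sum()
    if mass <= 0:
        raise ExtinctionError("all surviving variants have zero fitness")
    draws = rng.multinomial(bottleneck, weights / mass)
    return Population(
        counts={v: int(n) for v, n in zip(variants, draws) if n > 0},
        generation=pop.generation + 1,
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def simulate_reads(
    pop: Population,
    library: PositionalLibrary,
    ref: ReferenceAmplicon,
    generation_label: str,
    barcodes: GenerationBarcodeSet,
    n_reads: int,
    error_rate: float = 7e-4,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Render ``n_reads`` barcoded amplicon reads from a population.

    Each read samples a variant with probability proportional to its
    population frequency, renders leader + generational barcode + anchor +
    amplicon (library barcode applied, variant codon at the randomized
    slot), then applies i.i.d. substitutions at ``error_rate`` per base
    (uniform over the three alternative bases). Returns the reads as
    ``(read_id, sequence)`` pairs — read ids encode the true
    (library, generation, codon) triple — plus the realized per-variant
    read counts (the exact truth the decoder should recover at zero
    error rate).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = rng or np.random.default_rng()
    if generation_label not in barcodes.barcodes:
        raise ValueError(f"no barcode for generation {generation_label!r}")

    scaffold = barcodes.leader + barcodes.barcodes[generation_label] + barcodes.anchor
    amplicon = library_reference(ref, library)
    s = library.nns_codon_start

    variants = sorted(pop.frequencies())
    p = np.array([pop.frequencies()[v] for v in variants])
    drawn = rng.multinomial(n_reads, p)

    templates = np.stack(
        [
            np.frombuffer((scaffold + amplicon[:s] + v + amplicon[s + 3 :]).encode(), dtype=np.uint8)
            for v in variants
        ]
    )
    rows = np.repeat(templates, drawn, axis=0)
    if error_rate > 0:
        mask = rng.random(rows.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            idx = _BASE_INDEX[rows[mask]]
            rows[mask] = _BASES[(idx + rng.integers(1, 4, size=n_err)) % 4]

    truth = {v: int(n) for v, n in zip(variants, drawn) if n > 0}
    labels = np.repeat(np.arange(len(variants)), drawn)
    reads = [
        (
            f"{library.library_id}:{generation_label}:{variants[labels[i]]}:{i}",
            rows[i].tobytes().decode(),
        )
        for i in range(n_reads)
    ]
    return reads, truth


@dataclass
class CampaignConfig:
    """Parameters of one in-silico selection campaign."""

    libraries: list[PositionalLibrary]
    ref: ReferenceAmplicon
    fitness: FitnessMap
    initial_depth: int = 10_000
    bottleneck: int = 10_000
    generations: int = 3
    reads_per_sample: int = 5_000
    error_rate: float = 7e-4
    seed: int = 0
    barcodes: GenerationBarcodeSet = field(default_factory=GenerationBarcodeSet)
    skew: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_variants = len(NNS_CODONS_SORTED)
        if self.bottleneck < 10 * n_variants:
            warnings.warn(
                f"bottleneck {self.bottleneck} is below 10-fold library "
                f"representation ({10 * n_variants})",
                stacklevel=2,
            )
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        labels = [f"G{t}" for t in range(self.generations + 1)]
        missing = [g for g in labels if g not in self.barcodes.barcodes]
        if missing:
            raise ValueError(f"barcode set lacks generations {missing}")


@dataclass
class CampaignResult:
    """Reads and ground truth for every (library, generation) sample."""

    config: CampaignConfig
    reads: dict[tuple[str, str], list[tuple[str, str]]]
    population_truth: pd.DataFrame  # library, generation, codon, pop_count, pop_frequency
    read_truth: pd.DataFrame        # library, generation, codon, read_count

    def all_reads(self) -> list[tuple[str, str]]:
        pooled = []
        for key in sorted(self.reads):
            pooled.extend(self.reads[key])
        return pooled

    def write_fastq(self, path) -> None:
        """Single pooled FASTQ (constant quality, generational barcodes inline)."""
        with open(path, "w") as fh:
            for read_id, seq in self.all_reads():
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth(self, pop_path, read_path) -> None:
        self.population_truth.to_csv(pop_path, sep="\t", index=False)
        self.read_truth.to_csv(read_path, sep="\t", index=False)


def run_campaign(config: CampaignConfig) -> CampaignResult:
    """Iterate initial library → [selection bottleneck → sequencing] cycles.

    Random streams are spawned deterministically from the master seed, one
    child per library and one grandchild per stage, so per-library results
    are independent of panel ordering changes elsewhere.
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(config.libraries))
    reads: dict[tuple[str, str], list[tuple[str, str]]] = {}
    pop_rows, read_rows = [], []

    for lib, child in zip(config.libraries, children):
        # stage streams: 0 = initial population, then (select, reads) per cycle
        streams = child.spawn(2 * config.generations + 2)
        pop = initial_population(
            config.initial_depth, skew=config.skew, rng=np.random.default_rng(streams[0])
        )
        for t in range(config.generations + 1):
            label = f"G{t}"
            if t > 0:
                pop = select_generation(
                    pop, config.fitness, config.bottleneck,
                    rng=np.random.default_rng(streams[2 * t - 1]),
                )
            sample_reads, truth = simulate_reads(
                pop, lib, config.ref, label, config.barcodes,
                config.reads_per_sample, config.error_rate,
                rng=np.random.default_rng(streams[2 * t]),
            )
            reads[(lib.library_id, label)] = sample_reads
            total = pop.total
            for codon in sorted(pop.counts):
                if pop.counts[codon] == 0:
                    continue
                pop_rows.append(
                    {
                        "library": lib.library_id, "generation": label, "codon": codon,
                        "pop_count": pop.counts[codon],
                        "pop_frequency": pop.counts[codon] / total,
                    }
                )
            for codon in sorted(truth):
                read_rows.append(
                    {
                        "library": lib.library_id, "generation": label,
                        "codon": codon, "read_count": truth[codon],
                    }
                )

    return CampaignResult(
        config=config,
        reads=reads,
        population_truth=pd.DataFrame(pop_rows),
        read_truth=pd.DataFrame(read_rows),
    )


def expected_two_variant_frequency(p0: float, w1: float, w2: float, generations: int = 1) -> float:
    """Deterministic expectation p' = p·w1 / (p·w1 + (1-p)·w2), iterated."""
    p = p0
    for _ in range(generations):
        p = p * w1 / (p * w1 + (1 - p) * w2)
    return p
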