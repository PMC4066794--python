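"""Stochastic random-mating population simulator for drive-release experiments.

Discrete, non-overlapping generations.  Each generation every female mates a
single male chosen uniformly at random (males may mate several females) and
lays a fixed number of eggs; each egg draws one gamete from each parent and a
sex by a fair coin.  All genotypes have equal survival and fertility.  If the
offspring pool exceeds the population cap, a uniform random subset of exactly
``cap`` flies founds the next generation.

A release experiment starts as trans-heterozygous ``D/target`` males
introduced into a homozygous target population; the refractory control uses
``N`` (a destroyed, non-cleavable target site) as the resident allele, in
which case no cleavage is possible and the drive allele should drift around
its release frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetics import (
    ALLELE_PAIRS,
    ALLELES,
    Allele,
    AlleleFrequencies,
    DriveParams,
    EmptyPopulationError,
    Genotype,
    Sex,
    allele_frequencies,
    offspring_pair_probabilities,
)

__all__ = [
    "Population",
    "ReleaseSpec",
    "SimConfig",
    "TrajectoryRecord",
    "Trajectory",
    "build_release_population",
    "initial_allele_frequency",
    "step_generation",
    "run_simulation",
    "summarize_trajectories",
    "trajectories_to_frame",
]


@dataclass(frozen=True)
class Population:
    """Finite population as genotype counts at one generation."""

    counts: Mapping[Genotype, int]
    generation: int = 0
    extinct: bool = False

    def __post_init__(self) -> None:
        counts = {g: int(n) for g, n in self.counts.items() if n != 0}
        if any(n < 0 for n in counts.values()):
            raise ValueError("genotype counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def size(self) -> int:
        return sum(self.counts.values())

    @property
    def n_males(self) -> int:
        return sum(n for g, n in self.counts.items() if g.sex is Sex.MALE)

    @property
    def n_females(self) -> int:
        return sum(n for g, n in self.counts.items() if g.sex is Sex.FEMALE)


@dataclass(frozen=True)
class ReleaseSpec:
    """A single release of drive-carrying males into a resident population.

    ``target_allele`` is ``T`` for a normal cleavable population and ``N``
    for the refractory (non-cleavable) control line.
    """

    n_trans_het_males: int
    n_target_males: int
    n_target_females: int
    target_allele: Allele = Allele.T

    def __post_init__(self) -> None:
        for name in ("n_trans_het_males", "n_target_males", "n_target_females"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.target_allele not in (Allele.T, Allele.N):
            raise ValueError("target_allele must be T or N")

    @property
    def total_individuals(self) -> int:
        return self.n_trans_het_males + self.n_target_males + self.n_target_females


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a stochastic release simulation."""

    release: ReleaseSpec
    cap: int
    generations: int
    iterations: int = 1
    eggs_per_female: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eggs_per_female < 1:
            raise ValueError("eggs_per_female must be >= 1")
        if self.cap < 2:
            raise ValueError("cap must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def build_release_population(release: ReleaseSpec) -> Population:
    """Generation-0 population for a release experiment."""
    t = release.target_allele
    counts = {
        Genotype.of(Allele.D, t, Sex.MALE): release.n_trans_het_males,
        Genotype.of(t, t, Sex.MALE): release.n_target_males,
        Genotype.of(t, t, Sex.FEMALE): release.n_target_females,
    }
    return Population(counts=counts, generation=0)


def initial_allele_frequency(release: ReleaseSpec) -> float:
    """Drive (D) allele frequency at release.

    For a cleavable (``T``) resident population this equals the initial
    GFP-negative allele fraction, since the trans-heterozygous males carry
    the only GFP-negative alleles.
    """
    total = release.total_individuals
    if total == 0:
        raise EmptyPopulationError("release specifies an empty population")
    return release.n_trans_het_males / (2.0 * total)


def step_generation(
    pop: Population,
    params: DriveParams,
    eggs_per_female: int,
    cap: int,
    rng: np.random.Generator,
) -> Population:
    """Advance one generation of random mating, reproduction and capping.

    Each female is assigned one father sampled (with replacement across
    females) proportional to male genotype counts.  Each mating produces
    ``eggs_per_female`` offspring whose genotypes are drawn from the cross's
    offspring distribution and whose sexes are fair coin flips.  If either
    sex is absent, the returned population is empty and flagged extinct.
    """
    male_items = [(g, n) for g, n in pop.counts.items() if g.sex is Sex.MALE]
    female_items = [(g, n) for g, n in pop.counts.items() if g.sex is Sex.FEMALE]
    if not male_items or not female_items:
        return Population(counts={}, generation=pop.generation + 1, extinct=True)

    male_counts = np.array([n for _, n in male_items], dtype=float)
    male_probs = male_counts / male_counts.sum()

    pair_counts = np.zeros(len(ALLELE_PAIRS), dtype=np.int64)
    for mother, n_females in female_items:
        fathers = rng.multinomial(n_females, male_probs)
        for (father, _), k in zip(male_items, fathers):
            if k == 0:
                continue
            probs = offspring_pair_probabilities(
                mother.alleles, father.alleles, params
            )
            pair_counts += rng.multinomial(k * eggs_per_female, probs)

    total = int(pair_counts.sum())
    if total > cap:
        pair_counts = rng.multivariate_hypergeometric(pair_counts, cap)

    counts: Dict[Genotype, int] = {}
    for pair, n in zip(ALLELE_PAIRS, pair_counts):
        n = int(n)
        if n == 0:
            continue
        n_male = int(rng.binomial(n, 0.5))
        if n_male:
            counts[Genotype(pair, Sex.MALE)] = n_male
        if n - n_male:
            counts[Genotype(pair, Sex.FEMALE)] = n - n_male
    return Population(counts=counts, generation=pop.generation + 1)


@dataclass(frozen=True)
class TrajectoryRecord:
    """State of one simulated population at one generation."""

    generation: int
    size: int
    counts: Mapping[Genotype, int]
    frequencies: AlleleFrequencies
    extinct: bool = False

    @property
    def gfp_negative(self) -> float:
        return self.frequencies.gfp_negative


@dataclass(frozen=True)
class Trajectory:
    """Per-generation records of a single simulation iteration."""

    iteration: int
    seed: Tuple[int, ...]
    records: Tuple[TrajectoryRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def gfp_negative_series(self) -> np.ndarray:
        return np.array([r.gfp_negative for r in self.records])

    def frequency_series(self, allele: Allele) -> np.ndarray:
        return np.array([r.frequencies[allele] for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "generation": r.generation,
                    "iteration": self.iteration,
                    "n": r.size,
                    **{f"freq_{a.value}": r.frequencies[a] for a in ALLELES},
                    "gfp_negative": r.gfp_negative,
                    "extinct": r.extinct,
                }
            )
        return pd.DataFrame(rows)


def _record(pop: Population, extinct: bool = False) -> TrajectoryRecord:
    return TrajectoryRecord(
        generation=pop.generation,
        size=pop.size,
        counts=dict(pop.counts),
        frequencies=allele_frequencies(pop),
        extinct=extinct,
    )


def run_simulation(config: SimConfig, params: DriveParams) -> List[Trajectory]:
    """Run ``config.iterations`` independent seeded simulation iterations.

    Each iteration uses an independent random substream derived from
    ``(config.seed, iteration)``, so identical configurations reproduce
    identical trajectories and iteration results do not depend on how many
    iterations are run.  A trajectory holds ``generations + 1`` records
    (generation 0 is the release population).  If an iteration loses one sex
    entirely, its remaining generations repeat the terminal record flagged
    extinct.
    """
    trajectories: List[Trajectory] = []
    for i in range(config.iterations):
        seed = (config.seed, i)
        rng = np.random.default_rng(seed)
        pop = build_release_population(config.release)
        records = [_record(pop)]
        for _ in range(config.generations):
            nxt = step_generation(
                pop, params, config.eggs_per_female, config.cap, rng
            )
            if nxt.size == 0:
                # one sex (or everyone) is gone: freeze the last real state
                terminal = replace(records[-1], extinct=True)
                while len(records) < config.generations + 1:
                    terminal = replace(
                        terminal, generation=terminal.generation + 1
                    )
                    records.append(terminal)
                break
            pop = nxt
            records.append(_record(pop))
        trajectories.append(
            Trajectory(iteration=i, seed=seed, records=tuple(records))
        )
    return trajectories


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format table of all trajectories, one row per generation."""
    if not trajectories:
        raise ValueError("no trajectories supplied")
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)


def summarize_trajectories(
    trajectories: Sequence[Trajectory],
    quantiles: Sequence[float] = (0.25, 0.75),
) -> pd.DataFrame:
    """Per-generation summary of the GFP-negative allele fraction.

    Returns one row per generation with the mean, median, min, max and the
    requested quantiles across iterations.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    lengths = {len(t) for t in trajectories}
    if len(lengths) != 1:
        raise ValueError("trajectories have unequal lengths")
    series = np.vstack([t.gfp_negative_series() for t in trajectories])
    generations = [r.generation for r in trajectories[0].records]
    out = pd.DataFrame(
        {
            "generation": generations,
            "mean": series.mean(axis=0),
            "median": np.median(series, axis=0),
            "min": series.min(axis=0),
            "max": series.max(axis=0),
        }
    )
    for q in quantiles:
        out[f"q{int(round(q * 100)):02d}"] = np.quantile(series, q, axis=0)
    return out
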