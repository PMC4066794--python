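"""Four-allele genetics of a homing-based synthetic selfish element.

The model tracks four heritable allele classes at a single autosomal locus:

``T``
    wild-type target site; carries the intact GFP reporter and is the only
    class the nuclease can cleave.
``D``
    functional drive donor — the nuclease cassette, pooling the original
    donor chromosome with functionally homed target chromosomes.
``DN``
    non-functional homed donor: the cassette was copied but damaged in the
    process; it is transmitted Mendelianly and cannot home again.
``N``
    out-of-frame end-joining (NHEJ) repair product: the target site is
    destroyed, so the allele is resistant to further cleavage — a classic
    drive-resistance allele.

Homing happens only in the germline of male ``D/T`` trans-heterozygotes.
There, each target chromosome is cleaved with probability ``c``; a cleaved
chromosome is resolved by homologous recombination ("homing") with
probability ``h`` (otherwise end-joining yields ``N``); a homing event copies
a functional cassette with probability ``phi`` (otherwise ``DN``).  Every
other genotype — including all females — segregates Mendelianly, and all
genotypes have equal survival and fertility.

The module also provides the deterministic infinite-population recursion,
which is the expectation of the stochastic simulator in
:mod:`ssedrive.population` and serves as its oracle in tests.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Allele",
    "Sex",
    "Genotype",
    "DriveParams",
    "GameteDistribution",
    "SexStructuredState",
    "AlleleFrequencies",
    "DeterministicTrajectory",
    "EmptyPopulationError",
    "ALLELES",
    "ALLELE_PAIRS",
    "all_genotypes",
    "gamete_distribution",
    "offspring_distribution",
    "recursion_step",
    "run_recursion",
    "allele_frequencies",
    "TALELAT_PARAMS",
    "ZFN_AAVS1_PARAMS",
    "ZFN_AAVS1_LONG_PARAMS",
]


class Allele(enum.Enum):
    """One of the four heritable allele classes."""

    T = "T"
    D = "D"
    DN = "DN"
    N = "N"

    @property
    def gfp_positive(self) -> bool:
        """Only the intact target site expresses the GFP reporter."""
        return self is Allele.T

    @property
    def cleavable(self) -> bool:
        """Only the intact target site can be cut by the nuclease."""
        return self is Allele.T

    @property
    def drive_capable(self) -> bool:
        """Only the functional donor can perform homing."""
        return self is Allele.D

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Allele.{self.name}"


#: Canonical allele ordering used for vectors and sorted pairs.
ALLELES: Tuple[Allele, ...] = (Allele.T, Allele.D, Allele.DN, Allele.N)
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

#: The ten unordered diploid allele pairs, in canonical order.
ALLELE_PAIRS: Tuple[Tuple[Allele, Allele], ...] = tuple(
    itertools.combinations_with_replacement(ALLELES, 2)
)
_PAIR_INDEX = {p: i for i, p in enumerate(ALLELE_PAIRS)}


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


def _sort_pair(a1: Allele, a2: Allele) -> Tuple[Allele, Allele]:
    if _ALLELE_INDEX[a1] <= _ALLELE_INDEX[a2]:
        return (a1, a2)
    return (a2, a1)


@dataclass(frozen=True)
class Genotype:
    """An unordered diploid allele pair with sex.

    Parent-of-origin is not tracked: ``D/T`` and ``T/D`` are the same
    genotype.  10 unordered pairs x 2 sexes = 20 possible genotypes.
    """

    alleles: Tuple[Allele, Allele]
    sex: Sex

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", _sort_pair(*self.alleles))

    @classmethod
    def of(cls, a1: Allele, a2: Allele, sex: Sex) -> "Genotype":
        return cls((a1, a2), sex)

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] is self.alleles[1]

    def count_of(self, allele: Allele) -> int:
        return sum(1 for a in self.alleles if a is allele)

    def label(self) -> str:
        return f"{self.alleles[0].value}/{self.alleles[1].value} {self.sex.value}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Genotype({self.label()})"


def all_genotypes() -> List[Genotype]:
    """All 20 genotypes (10 unordered pairs x 2 sexes)."""
    return [Genotype(pair, sex) for sex in Sex for pair in ALLELE_PAIRS]


@dataclass(frozen=True)
class DriveParams:
    """Drive activity parameters, as measured in the homing assay.

    Parameters
    ----------
    c : float
        Cleavage rate — fraction of target chromosomes scored as modified
        (GFP loss) in progeny of a drive-bearing male.
    h : float
        Homing fraction — fraction of cleaved chromosomes resolved by
        homologous recombination rather than end-joining.
    phi : float
        Functional-homing fraction — fraction of homing events yielding a
        cassette able to drive again (the rest yield ``DN``).
    """

    c: float
    h: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("c", "h", "phi"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValueError(
                    f"drive parameter {name}={v!r} outside the unit interval"
                )

    @property
    def misrepair_fraction(self) -> float:
        """Fraction of cleaved chromosomes resolved by end-joining, 1 - h."""
        return 1.0 - self.h


# Point estimates from the homing assay (male trans-heterozygote crosses).
TALELAT_PARAMS = DriveParams(c=998 / 1422, h=697 / 998, phi=15 / 36)
ZFN_AAVS1_PARAMS = DriveParams(c=366 / 425, h=117 / 296, phi=15 / 20)
ZFN_AAVS1_LONG_PARAMS = DriveParams(c=483 / 565, h=173 / 435, phi=15 / 20)


@dataclass(frozen=True)
class GameteDistribution:
    """Probability vector over allele classes emitted by one parent."""

    probabilities: Mapping[Allele, float]

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        for a in ALLELES:
            probs.setdefault(a, 0.0)
        if any(p < 0 for p in probs.values()):
            raise ValueError("gamete probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise ValueError("gamete probabilities must sum to 1")
        object.__setattr__(self, "probabilities", probs)

    def __getitem__(self, allele: Allele) -> float:
        return self.probabilities[allele]

    def as_array(self) -> np.ndarray:
        """Probabilities in canonical :data:`ALLELES` order."""
        return np.array([self.probabilities[a] for a in ALLELES])


def gamete_distribution(genotype: Genotype, params: DriveParams) -> GameteDistribution:
    """Gamete allele-class probabilities for one parent.

    A male ``D/T`` trans-heterozygote emits the four classes at

    ==== ==========================
    D    1/2 + (1/2) c h phi
    DN   (1/2) c h (1 - phi)
    N    (1/2) c (1 - h)
    T    (1/2)(1 - c)
    ==== ==========================

    i.e. the donor chromosome is always transmitted intact while the target
    chromosome is cleaved with probability ``c`` and the break resolved by
    homing (functional or not) or end-joining.  Every other genotype —
    including all females — is Mendelian: each allele with probability 1/2.
    """
    a1, a2 = genotype.alleles
    if genotype.sex is Sex.MALE and {a1, a2} == {Allele.D, Allele.T}:
        c, h, phi = params.c, params.h, params.phi
        return GameteDistribution(
            {
                Allele.D: 0.5 + 0.5 * c * h * phi,
                Allele.DN: 0.5 * c * h * (1.0 - phi),
                Allele.N: 0.5 * c * (1.0 - h),
                Allele.T: 0.5 * (1.0 - c),
            }
        )
    probs: Dict[Allele, float] = {a: 0.0 for a in ALLELES}
    probs[a1] += 0.5
    probs[a2] += 0.5
    return GameteDistribution(probs)


@lru_cache(maxsize=None)
def _gamete_array(pair: Tuple[Allele, Allele], sex: Sex, params: DriveParams) -> np.ndarray:
    arr = gamete_distribution(Genotype(pair, sex), params).as_array()
    arr.setflags(write=False)
    return arr


@lru_cache(maxsize=None)
def offspring_pair_probabilities(
    mother_pair: Tuple[Allele, Allele],
    father_pair: Tuple[Allele, Allele],
    params: DriveParams,
) -> np.ndarray:
    """Offspring unordered-pair probabilities in :data:`ALLELE_PAIRS` order.

    Outer product of the maternal (Mendelian) and paternal (possibly driving)
    gamete distributions, collapsed over allele order.
    """
    gm = _gamete_array(_sort_pair(*mother_pair), Sex.FEMALE, params)
    gf = _gamete_array(_sort_pair(*father_pair), Sex.MALE, params)
    outer = np.outer(gm, gf)
    out = np.zeros(len(ALLELE_PAIRS))
    for i, ai in enumerate(ALLELES):
        for j, aj in enumerate(ALLELES):
            out[_PAIR_INDEX[_sort_pair(ai, aj)]] += outer[i, j]
    out.setflags(write=False)
    return out


def offspring_distribution(
    mother: Genotype, father: Genotype, params: DriveParams
) -> Dict[Tuple[Allele, Allele], float]:
    """Offspring genotype (unordered allele pair) distribution for one cross."""
    if mother.sex is not Sex.FEMALE or father.sex is not Sex.MALE:
        raise ValueError("offspring_distribution requires a female mother and male father")
    probs = offspring_pair_probabilities(mother.alleles, father.alleles, params)
    return {pair: float(p) for pair, p in zip(ALLELE_PAIRS, probs)}


class EmptyPopulationError(ValueError):
    """Raised when allele frequencies are requested of an empty population."""


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele-class frequencies plus the GFP-negative aggregate."""

    by_class: Mapping[Allele, float]

    def __post_init__(self) -> None:
        probs = {a: float(self.by_class.get(a, 0.0)) for a in ALLELES}
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total!r}, not 1")
        object.__setattr__(self, "by_class", probs)

    def __getitem__(self, allele: Allele) -> float:
        return self.by_class[allele]

    @property
    def gfp_negative(self) -> float:
        """Frequency of all alleles lacking the intact GFP target: D+DN+N."""
        return 1.0 - self.by_class[Allele.T]

    def as_array(self) -> np.ndarray:
        return np.array([self.by_class[a] for a in ALLELES])


@dataclass(frozen=True)
class SexStructuredState:
    """Infinite-population genotype frequencies, one map per sex."""

    male_freqs: Mapping[Genotype, float]
    female_freqs: Mapping[Genotype, float]
    generation: int = 0

    def __post_init__(self) -> None:
        for name, freqs, sex in (
            ("male_freqs", self.male_freqs, Sex.MALE),
            ("female_freqs", self.female_freqs, Sex.FEMALE),
        ):
            if any(v < 0 for v in freqs.values()):
                raise ValueError(f"{name} contains negative frequencies")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies do not sum to 1")
            if any(g.sex is not sex for g in freqs):
                raise ValueError(f"{name} keyed by genotypes of the wrong sex")
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    @classmethod
    def from_pair_freqs(
        cls,
        male_pairs: Mapping[Tuple[Allele, Allele], float],
        female_pairs: Mapping[Tuple[Allele, Allele], float],
        generation: int = 0,
    ) -> "SexStructuredState":
        return cls(
            male_freqs={Genotype(p, Sex.MALE): f for p, f in male_pairs.items()},
            female_freqs={Genotype(p, Sex.FEMALE): f for p, f in female_pairs.items()},
            generation=generation,
        )


def recursion_step(state: SexStructuredState, params: DriveParams) -> SexStructuredState:
    """One generation of the deterministic expectation recursion.

    Each female mates a single random male, so the offspring genotype
    distribution is the female-frequency x male-frequency mixture of the
    per-cross offspring distributions.  Offspring sex is independent of
    genotype, hence the returned male and female maps are equal.
    """
    offspring = np.zeros(len(ALLELE_PAIRS))
    for mother, fm in state.female_freqs.items():
        if fm == 0.0:
            continue
        for father, ff in state.male_freqs.items():
            if ff == 0.0:
                continue
            offspring += fm * ff * offspring_pair_probabilities(
                mother.alleles, father.alleles, params
            )
    pair_freqs = {pair: float(p) for pair, p in zip(ALLELE_PAIRS, offspring)}
    return SexStructuredState.from_pair_freqs(
        pair_freqs, pair_freqs, generation=state.generation + 1
    )


def allele_frequencies(obj) -> AlleleFrequencies:
    """Allele-class frequencies of a state or a finite population.

    Accepts a :class:`SexStructuredState` (sexes weighted equally) or any
    object with a ``counts: Mapping[Genotype, int]`` attribute such as
    :class:`ssedrive.population.Population`.
    """
    if isinstance(obj, SexStructuredState):
        # each sex weighs 1/2; each allele of a pair is half its genotype
        freqs = {a: 0.0 for a in ALLELES}
        for gmap in (obj.male_freqs, obj.female_freqs):
            for g, f in gmap.items():
                for a in g.alleles:
                    freqs[a] += 0.25 * f
        return AlleleFrequencies(freqs)
    counts = getattr(obj, "counts", None)
    if counts is None:
        raise TypeError("expected a SexStructuredState or an object with .counts")
    total = sum(counts.values())
    if total == 0:
        raise EmptyPopulationError("cannot compute allele frequencies of an empty population")
    tallies = {a: 0 for a in ALLELES}
    for g, n in counts.items():
        for a in g.alleles:
            tallies[a] += n
    return AlleleFrequencies({a: t / (2.0 * total) for a, t in tallies.items()})


@dataclass(frozen=True)
class DeterministicTrajectory:
    """Per-generation states and allele frequencies of the recursion."""

    states: Tuple[SexStructuredState, ...]
    frequencies: Tuple[AlleleFrequencies, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.frequencies:
            object.__setattr__(
                self,
                "frequencies",
                tuple(allele_frequencies(s) for s in self.states),
            )

    def __len__(self) -> int:
        return len(self.states)

    def gfp_negative_series(self) -> np.ndarray:
        return np.array([f.gfp_negative for f in self.frequencies])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state, freqs in zip(self.states, self.frequencies):
            rows.append(
                {
                    "generation": state.generation,
                    **{f"freq_{a.value}": freqs[a] for a in ALLELES},
                    "gfp_negative": freqs.gfp_negative,
                }
            )
        return pd.DataFrame(rows)


def run_recursion(
    initial: SexStructuredState, params: DriveParams, generations: int
) -> DeterministicTrajectory:
    """Iterate the deterministic recursion for ``generations`` steps.

    The returned trajectory includes generation 0 (the initial state), so it
    has ``generations + 1`` entries.
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    states = [initial]
    for _ in range(generations):
        states.append(recursion_step(states[-1], params))
    return DeterministicTrajectory(states=tuple(states))
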