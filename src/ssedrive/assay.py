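"""Homing-assay readout: progeny classification, rate estimation, F2 tests.

The homing assay crosses a drive/target trans-heterozygote to background
flies and reads the fate of each transmitted target chromosome off a panel of
markers: the dominant ``mini-white`` eye marker distinguishes donor-bearing
(``w+``) from target-derived (``w-``) progeny; GFP reports an intact target
site; a gain of RFP (or a positive junction PCR for lines without the RFP
reporter) reports a homed cassette; and the recessive ``curled`` wing marker
resolves true donor inheritance from marker co-conversion.

From the resulting counts the assay estimates

* cleavage rate  ``c = n_gfp_loss / n_target_total``,
* homing fraction ``h = n_homed / n_homing_assayed``,
* total homed fraction ``c * h`` and end-joining fraction ``c * (1 - h)``,

with Wilson score confidence intervals.  F2 crosses of individually homed
flies to fresh targets test whether the copied cassette still drives: a
significant chi-square deficit of GFP-positive progeny from the Mendelian
1:1 expectation marks a functional secondary homing event.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Phenotype",
    "MarkerMap",
    "ChromosomeClass",
    "AssayCounts",
    "RateEstimates",
    "SegregationTest",
    "F2Summary",
    "ClassificationError",
    "TALELAT_MARKERS",
    "ZFN_MARKERS",
    "classify_phenotype",
    "tabulate_cross",
    "estimate_rates",
    "chi_square_1to1",
    "functional_homing_fraction",
]


class ClassificationError(ValueError):
    """A phenotype inconsistent with the marker model."""


@dataclass(frozen=True)
class Phenotype:
    """Observable markers of a single progeny fly.

    ``rfp_or_pcr`` is RFP expression for lines carrying the RFP reporter and
    junction-PCR positivity for lines scored molecularly.
    """

    white_plus: bool
    curled: bool
    gfp: bool
    rfp_or_pcr: bool


@dataclass(frozen=True)
class MarkerMap:
    """How markers map to chromosomes for a given drive line.

    ``cu_on_donor`` is true when the recessive ``curled`` marker sits on the
    donor chromosome (so donor-inheriting progeny over a ``cu`` background
    are curled); false when it marks the target chromosome instead.
    """

    cu_on_donor: bool
    homing_readout: str = "rfp"

    def __post_init__(self) -> None:
        if self.homing_readout not in ("rfp", "pcr"):
            raise ValueError("homing_readout must be 'rfp' or 'pcr'")


TALELAT_MARKERS = MarkerMap(cu_on_donor=True, homing_readout="rfp")
ZFN_MARKERS = MarkerMap(cu_on_donor=False, homing_readout="pcr")


class ChromosomeClass(enum.Enum):
    """Fate of the chromosome a progeny fly inherited from the assayed parent."""

    DONOR_INHERITED = "donor_inherited"
    UNMODIFIED_TARGET = "unmodified_target"
    HOMED = "homed"
    MISREPAIR = "misrepair"
    CO_CONVERSION = "co_conversion"


def classify_phenotype(p: Phenotype, m: MarkerMap) -> ChromosomeClass:
    """Assign a progeny fly to a chromosome-fate class from its markers.

    ``w-`` flies inherited a target-derived chromosome: GFP+ means the target
    site survived intact (unmodified), GFP- with the homing readout positive
    means the cassette was copied in (homed), GFP- with both reporters
    negative means end-joining destroyed the site (misrepair).  ``w+`` flies
    carry the donor chromosome itself; when the donor line carries the
    ``curled`` marker, a ``w+`` non-curled fly with the homing readout
    positive reveals co-conversion of the ``mini-white`` marker rather than
    vertical donor transmission.
    """
    if not p.white_plus:
        if p.gfp and p.rfp_or_pcr:
            raise ClassificationError(
                "w- fly scored both GFP-positive and homing-readout-positive"
            )
        if p.gfp:
            return ChromosomeClass.UNMODIFIED_TARGET
        if p.rfp_or_pcr:
            return ChromosomeClass.HOMED
        return ChromosomeClass.MISREPAIR
    # w+ progeny carry a mini-white+ chromosome
    donor_pattern_curled = m.cu_on_donor
    if p.rfp_or_pcr and p.curled != donor_pattern_curled:
        return ChromosomeClass.CO_CONVERSION
    return ChromosomeClass.DONOR_INHERITED


@dataclass(frozen=True)
class AssayCounts:
    """Progeny-class counts over the target-chromosome (``w-``) progeny.

    ``n_homing_assayed`` is the denominator actually scored for homing; it
    defaults to ``n_gfp_loss`` but may be smaller when only a subset of the
    GFP-loss flies was assayed molecularly (as with PCR-scored lines).
    """

    n_target_total: int
    n_gfp_loss: int
    n_homed: int
    n_homing_assayed: int

    def __post_init__(self) -> None:
        if not (
            0
            <= self.n_homed
            <= self.n_homing_assayed
            <= self.n_gfp_loss
            <= self.n_target_total
        ):
            raise ValueError(
                "assay counts must satisfy 0 <= n_homed <= n_homing_assayed"
                " <= n_gfp_loss <= n_target_total, got "
                f"({self.n_target_total}, {self.n_gfp_loss}, "
                f"{self.n_homed}, {self.n_homing_assayed})"
            )


def tabulate_cross(
    phenotypes: Iterable[Phenotype],
    m: MarkerMap,
    n_homing_assayed: Optional[int] = None,
) -> AssayCounts:
    """Aggregate per-fly phenotypes into assay counts.

    Only ``w-`` (target-chromosome) progeny enter the counts.  Supply
    ``n_homing_assayed`` when homing was scored on a subset of the GFP-loss
    flies; by default every GFP-loss fly counts toward the homing
    denominator.
    """
    n_target = n_loss = n_homed = 0
    for p in phenotypes:
        cls = classify_phenotype(p, m)
        if cls in (
            ChromosomeClass.DONOR_INHERITED,
            ChromosomeClass.CO_CONVERSION,
        ):
            continue
        n_target += 1
        if cls is ChromosomeClass.HOMED:
            n_loss += 1
            n_homed += 1
        elif cls is ChromosomeClass.MISREPAIR:
            n_loss += 1
    return AssayCounts(
        n_target_total=n_target,
        n_gfp_loss=n_loss,
        n_homed=n_homed,
        n_homing_assayed=n_loss if n_homing_assayed is None else n_homing_assayed,
    )


Interval = Tuple[float, float]


def _wilson(count: int, nobs: int, alpha: float = 0.05) -> Interval:
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    # guard against floating-point noise at the boundaries (e.g. count=0)
    p = count / nobs
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return (lo, hi)


@dataclass(frozen=True)
class RateEstimates:
    """Point estimates and 95% Wilson intervals from one homing assay.

    ``homing_fraction`` (and the quantities derived from it) is ``None`` when
    no chromosomes were assayed for homing — an undefined estimate is flagged
    rather than silently reported as zero.
    """

    cleavage_rate: float
    cleavage_ci: Interval
    homing_fraction: Optional[float]
    homing_ci: Optional[Interval]
    total_homed: Optional[float]
    nhej_fraction: Optional[float]
    counts: AssayCounts


def estimate_rates(a: AssayCounts, alpha: float = 0.05) -> RateEstimates:
    """Cleavage, homing, total-homed and end-joining rates from counts.

    ``total_homed = c_hat * h_hat`` expresses homing as a fraction of all
    target chromosomes; ``nhej_fraction = c_hat * (1 - h_hat)`` is the
    complementary fraction of cleaved chromosomes resolved by end-joining.
    """
    if a.n_target_total <= 0:
        raise ValueError("n_target_total must be positive to estimate rates")
    c_hat = a.n_gfp_loss / a.n_target_total
    c_ci = _wilson(a.n_gfp_loss, a.n_target_total, alpha)
    if a.n_homing_assayed > 0:
        h_hat: Optional[float] = a.n_homed / a.n_homing_assayed
        h_ci: Optional[Interval] = _wilson(a.n_homed, a.n_homing_assayed, alpha)
        total = c_hat * h_hat
        nhej = c_hat * (1.0 - h_hat)
    else:
        h_hat = h_ci = total = nhej = None
    return RateEstimates(
        cleavage_rate=c_hat,
        cleavage_ci=c_ci,
        homing_fraction=h_hat,
        homing_ci=h_ci,
        total_homed=total,
        nhej_fraction=nhej,
        counts=a,
    )


@dataclass(frozen=True)
class SegregationTest:
    """Chi-square test of a 1:1 segregation ratio."""

    statistic: float
    p_value: float
    significant: bool


def chi_square_1to1(n_a: int, n_b: int, alpha: float = 0.05) -> SegregationTest:
    """Goodness-of-fit chi-square against a 1:1 expectation, df=1.

    No continuity correction is applied.  ``significant`` is ``p < alpha``.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    total = n_a + n_b
    if total == 0:
        raise ValueError("cannot test segregation of zero progeny")
    expected = total / 2.0
    statistic = (n_a - expected) ** 2 / expected + (n_b - expected) ** 2 / expected
    p_value = float(stats.chi2.sf(statistic, df=1))
    return SegregationTest(
        statistic=float(statistic), p_value=p_value, significant=p_value < alpha
    )


@dataclass(frozen=True)
class F2Summary:
    """Fraction of F2 crosses showing significant GFP loss."""

    n_significant: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_significant / self.n_total


def functional_homing_fraction(
    crosses: Sequence[Tuple[int, int]],
    alpha: float = 0.05,
    require_deficit: bool = True,
) -> F2Summary:
    """Fraction of F2 crosses whose progeny deviate from 1:1 by losing GFP.

    Each cross is a ``(gfp_pos, gfp_neg)`` progeny count pair.  A cross
    counts as a functional homing event when the chi-square test rejects 1:1
    at ``alpha`` and — because the biological readout is *loss* of GFP — the
    deviation is a GFP deficit.  Set ``require_deficit=False`` to count any
    significant deviation regardless of direction.
    """
    crosses = list(crosses)
    if not crosses:
        raise ValueError("no F2 crosses supplied")
    n_sig = 0
    for gfp_pos, gfp_neg in crosses:
        test = chi_square_1to1(gfp_pos, gfp_neg, alpha=alpha)
        if test.significant and (gfp_pos < gfp_neg or not require_deficit):
            n_sig += 1
    return F2Summary(n_significant=n_sig, n_total=len(crosses))
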