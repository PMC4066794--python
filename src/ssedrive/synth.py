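"""Synthetic homing-assay and F2 data with the structure the analysis assumes.

Two generators:

* :func:`simulate_assay_progeny` draws the fates of the target chromosomes
  transmitted by a drive/target trans-heterozygous male as one multinomial
  over four outcome classes — unmodified ``1-c``, functionally homed
  ``c*h*phi``, non-functionally homed ``c*h*(1-phi)`` and misrepaired
  ``c*(1-h)`` — and can emit the matching per-fly phenotype table.
* :func:`simulate_f2_crosses` draws F2 segregation outcomes as a binomial
  mixture: a fraction ``phi`` of homed cassettes are functional and deplete
  GFP-positive progeny below 1:1; the rest segregate Mendelianly.

Both are seeded and feed directly into :mod:`ssedrive.assay`, enabling
parameter-recovery and coverage tests with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .assay import AssayCounts, MarkerMap, Phenotype, TALELAT_MARKERS
from .genetics import DriveParams

__all__ = [
    "AssaySimSpec",
    "F2SimSpec",
    "simulate_assay_progeny",
    "simulate_f2_crosses",
]


@dataclass(frozen=True)
class AssaySimSpec:
    """Specification of one simulated homing-assay cross."""

    params: DriveParams
    n_target_chromosomes: int
    marker_map: MarkerMap = TALELAT_MARKERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_chromosomes < 1:
            raise ValueError("n_target_chromosomes must be >= 1")


def simulate_assay_progeny(
    spec: AssaySimSpec,
    return_phenotypes: bool = False,
) -> AssayCounts | Tuple[AssayCounts, List[Phenotype]]:
    """Draw target-chromosome outcome counts for one assay cross.

    A single multinomial of size ``n_target_chromosomes`` over
    (unmodified, homed-functional, homed-nonfunctional, misrepair) with
    probabilities ``(1-c, c*h*phi, c*h*(1-phi), c*(1-h))``.  Both homed
    classes present identically in the marker readout (homing-readout
    positive, GFP-negative); functionality only reveals itself in F2.

    With ``return_phenotypes=True`` the matching per-fly ``w-`` phenotype
    rows are returned alongside the counts.
    """
    c, h, phi = spec.params.c, spec.params.h, spec.params.phi
    probs = np.array(
        [1.0 - c, c * h * phi, c * h * (1.0 - phi), c * (1.0 - h)]
    )
    rng = np.random.default_rng(spec.seed)
    unmodified, homed_func, homed_nonfunc, misrepair = rng.multinomial(
        spec.n_target_chromosomes, probs
    )
    homed = int(homed_func + homed_nonfunc)
    counts = AssayCounts(
        n_target_total=int(spec.n_target_chromosomes),
        n_gfp_loss=homed + int(misrepair),
        n_homed=homed,
        n_homing_assayed=homed + int(misrepair),
    )
    if not return_phenotypes:
        return counts
    # target-chromosome progeny are w-; over a cu background they are curled
    # exactly when the target chromosome itself carries the cu marker
    curled = not spec.marker_map.cu_on_donor
    phenotypes = (
        [Phenotype(False, curled, True, False)] * int(unmodified)
        + [Phenotype(False, curled, False, True)] * homed
        + [Phenotype(False, curled, False, False)] * int(misrepair)
    )
    return counts, phenotypes


@dataclass(frozen=True)
class F2SimSpec:
    """Specification of a batch of simulated F2 segregation crosses.

    ``functional_prob`` is the probability that a homed cassette is still
    able to drive (``phi``); ``active_gfp_loss_rate`` is the expected
    GFP-negative fraction among progeny of a functional cross, so the
    expected GFP-positive fraction there is ``1 - active_gfp_loss_rate``.
    The default matches a strongly driving cassette whose crosses leave
    roughly 14% of progeny GFP-positive.
    """

    n_crosses: int
    progeny_per_cross: int
    functional_prob: float
    active_gfp_loss_rate: float = 1.0 - 0.138
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crosses < 1:
            raise ValueError("n_crosses must be >= 1")
        if self.progeny_per_cross < 1:
            raise ValueError("progeny_per_cross must be >= 1")
        for name in ("functional_prob", "active_gfp_loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside the unit interval")


def simulate_f2_crosses(spec: F2SimSpec) -> List[Tuple[int, int]]:
    """Draw per-cross (gfp_pos, gfp_neg) F2 progeny counts.

    Each cross is functional with probability ``functional_prob``; functional
    crosses draw their GFP-positive count from
    ``Binomial(progeny_per_cross, 1 - active_gfp_loss_rate)`` and
    non-functional crosses from ``Binomial(progeny_per_cross, 1/2)``.
    """
    rng = np.random.default_rng(spec.seed)
    out: List[Tuple[int, int]] = []
    for _ in range(spec.n_crosses):
        functional = rng.random() < spec.functional_prob
        p_pos = (1.0 - spec.active_gfp_loss_rate) if functional else 0.5
        gfp_pos = int(rng.binomial(spec.progeny_per_cross, p_pos))
        out.append((gfp_pos, spec.progeny_per_cross - gfp_pos))
    return out
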