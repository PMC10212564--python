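"""Parameter containers for the branched hematopoiesis lineage model.

The normal lineage has four compartments — stem cells (S), multipotent
progenitors (P) and terminally differentiated lymphoid (TDl) and myeloid
(TDm) cells — with five regulated quantities: the stem self-renewal
fraction ``p0``, the progenitor self-renewal fraction ``p1``, the
lymphoid branching fraction ``q1`` and the two division rates ``eta1``
and ``eta2``.  Each regulated quantity is suppressed by one regulator
population through a decreasing Hill factor ``max / (1 + gamma * X)``:

==========  =========  ==============
quantity    regulator  gain
==========  =========  ==============
p0          P (total)  gamma1
eta1        S (total)  gamma2
p1          TDm        gamma3
q1          TDm        gamma4
eta2        S (total)  gamma5
==========  =========  ==============

Time unit is days throughout; one reporting "month" is 30 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

__all__ = [
    "NormalParameterSet",
    "LeukemicParameterSet",
    "DualParameterSet",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.0

_FIELDS = (
    "p0_max",
    "p1_max",
    "q1_max",
    "eta1_max",
    "eta2_max",
    "d_l",
    "d_m",
    "gamma1",
    "gamma2",
    "gamma3",
    "gamma4",
    "gamma5",
)


@dataclass(frozen=True)
class NormalParameterSet:
    """One virtual patient's normal-lineage rates, fractions and gains.

    Invariants enforced at construction:

    * every field strictly positive,
    * ``0.5 < p0_max <= 1`` (so the stem equation can equilibrate at
      an effective self-renewal of exactly one half with a positive
      regulator level),
    * ``p1_max + q1_max <= 1`` (so the myeloid branching fraction
      ``1 - p1 - q1`` is never negative).
    """

    p0_max: float
    p1_max: float
    q1_max: float
    eta1_max: float  # 1/day
    eta2_max: float  # 1/day
    d_l: float  # 1/day
    d_m: float  # 1/day
    gamma1: float  # 1/cell
    gamma2: float
    gamma3: float
    gamma4: float
    gamma5: float

    # lower bound on p0_max; the leukemic subclass relaxes it because
    # the sweeps scale p0_maxL below the homeostatic threshold
    _P0_LOWER = 0.5

    def __post_init__(self) -> None:
        for name in _FIELDS:
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (self._P0_LOWER < self.p0_max <= 1.0):
            raise ValueError(
                f"p0_max must lie in ({self._P0_LOWER}, 1], got {self.p0_max!r}"
            )
        if self.p1_max + self.q1_max > 1.0 + 1e-12:
            raise ValueError(
                f"p1_max + q1_max must be <= 1, got {self.p1_max + self.q1_max!r}"
            )

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "NormalParameterSet":
        return cls(**{k: float(data[k]) for k in _FIELDS})

    def replace(self, **changes: float) -> "NormalParameterSet":
        return replace(self, **changes)


@dataclass(frozen=True)
class LeukemicParameterSet(NormalParameterSet):
    """Leukemic-lineage parameters plus TKI sensitivities.

    ``tki_death_S`` and ``tki_death_P`` multiply the leukemic stem and
    progenitor division rates to form proliferation-dependent kill
    fluxes under TKI; ``tki_division_factor`` scales the maximal
    leukemic stem division rate during TKI (drug-induced quiescence).
    """

    tki_death_S: float = 0.0
    tki_death_P: float = 0.0
    tki_division_factor: float = 1.0

    _P0_LOWER = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.tki_death_S < 0.0 or self.tki_death_P < 0.0:
            raise ValueError("TKI kill multipliers must be non-negative")
        if not (0.0 < self.tki_division_factor <= 1.0):
            raise ValueError(
                f"tki_division_factor must lie in (0, 1], got {self.tki_division_factor!r}"
            )


@dataclass(frozen=True)
class DualParameterSet:
    """Paired normal and leukemic lineage parameters.

    The two lineages share the feedback architecture and regulate each
    other through total (normal + leukemic) populations.  The leukemic
    maximal self-renewal may not exceed the normal one.
    """

    normal: NormalParameterSet
    leukemic: LeukemicParameterSet

    def __post_init__(self) -> None:
        if self.leukemic.p0_max > self.normal.p0_max + 1e-12:
            raise ValueError(
                "leukemic p0_max must not exceed the paired normal p0_max"
            )

    @classmethod
    def minimal_difference(
        cls,
        normal: NormalParameterSet,
        gamma1L_ratio: float = 0.5,
        p0maxL_ratio: float = 1.0,
        tki_death_S: float = 0.0,
        tki_death_P: float = 0.0,
        tki_division_factor: float = 1.0,
    ) -> "DualParameterSet":
        """Leukemic lineage identical to the normal one except for a
        weaker stem self-renewal feedback gain (and optionally a lower
        maximal self-renewal)."""
        if not 0.0 < gamma1L_ratio:
            raise ValueError("gamma1L_ratio must be positive")
        if not 0.0 < p0maxL_ratio <= 1.0:
            raise ValueError("p0maxL_ratio must lie in (0, 1]")
        leukemic = LeukemicParameterSet(
            **{
                **normal.to_dict(),
                "gamma1": normal.gamma1 * gamma1L_ratio,
                "p0_max": normal.p0_max * p0maxL_ratio,
            },
            tki_death_S=tki_death_S,
            tki_death_P=tki_death_P,
            tki_division_factor=tki_division_factor,
        )
        return cls(normal=normal, leukemic=leukemic)
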