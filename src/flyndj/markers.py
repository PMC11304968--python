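"""Marked X-chromosome maps and haplotype codes.

The assays in this package all run on an X chromosome carrying the classical
recessive visible markers *y sc cv v f car*, held over an unmarked (*y*-only)
homolog.  Loci are ordered distal → proximal with the centromere (``CEN``)
as a terminal pseudo-locus; ``car`` is the centromere-proximal scored marker.

A *haplotype code* is the fixed-width string read off a male's phenotype at
the scored loci, one character per locus in map order: ``'m'`` for the mutant
(marked-chromosome) allele, ``'+'`` for wild type.  With the default scored
loci (sc, cv, f, car) the two parental arrangements are ``"++++"`` and
``"mmmm"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CENTROMERE = "CEN"

#: Standard-map placeholder recombination fractions for the scored intervals
#: sc–cv, cv–f and f–car (chromatid level, unitless).
STANDARD_SCORED_R = {"sc-cv": 0.137, "cv-f": 0.23, "f-car": 0.058}

# cv–f is physically split by v.  Splitting its 0.23 recombinant fraction
# into two equal sub-intervals r* with r* + r* - 2 r*^2 = 0.23 keeps the
# chromatid-level cv–f fraction exact while letting double crossovers occur
# inside the interval (they are invisible to the scored loci).
_R_CV_F_HALF = 0.5 * (1.0 - math.sqrt(1.0 - 2.0 * STANDARD_SCORED_R["cv-f"]))


class MarkerMapError(ValueError):
    """Raised for an inconsistent marker map definition."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker loci with per-interval recombination fractions.

    Parameters
    ----------
    loci:
        Locus names distal → proximal; the last entry must be ``"CEN"``.
    interval_r:
        Chromatid-level recombination fraction for each adjacent interval,
        ``len(loci) - 1`` values in ``[0, 0.5]``.
    scored_loci:
        The subset of loci read in genotyping crosses (map order).
    """

    loci: tuple[str, ...] = ("y", "sc", "cv", "v", "f", "car", CENTROMERE)
    interval_r: tuple[float, ...] = (
        0.0,
        STANDARD_SCORED_R["sc-cv"],
        _R_CV_F_HALF,
        _R_CV_F_HALF,
        STANDARD_SCORED_R["f-car"],
        0.0,
    )
    scored_loci: tuple[str, ...] = ("sc", "cv", "f", "car")

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "interval_r", tuple(float(r) for r in self.interval_r))
        object.__setattr__(self, "scored_loci", tuple(self.scored_loci))
        if len(self.loci) < 2:
            raise MarkerMapError("a marker map needs at least one interval")
        if self.loci[-1] != CENTROMERE:
            raise MarkerMapError(f"last locus must be {CENTROMERE!r}, got {self.loci[-1]!r}")
        if len(set(self.loci)) != len(self.loci):
            raise MarkerMapError("duplicate locus names")
        if len(self.interval_r) != len(self.loci) - 1:
            raise MarkerMapError(
                f"interval_r has {len(self.interval_r)} entries for "
                f"{len(self.loci) - 1} intervals"
            )
        for name, r in zip(self.interval_names, self.interval_r):
            if not 0.0 <= r <= 0.5:
                raise MarkerMapError(f"interval_r[{name}] = {r} outside [0, 0.5]")
        missing = [m for m in self.scored_loci if m not in self.loci]
        if missing:
            raise MarkerMapError(f"scored loci not on the map: {missing}")
        if CENTROMERE in self.scored_loci:
            raise MarkerMapError("the centromere cannot be a scored locus")
        order = [self.loci.index(m) for m in self.scored_loci]
        if order != sorted(order):
            raise MarkerMapError("scored_loci must be in map order")

    # -- basic geometry -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_intervals(self) -> int:
        return len(self.loci) - 1

    @property
    def interval_names(self) -> tuple[str, ...]:
        return tuple(f"{a}-{b}" for a, b in zip(self.loci[:-1], self.loci[1:]))

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise MarkerMapError(f"unknown locus {locus!r}") from None

    @property
    def scored_indices(self) -> np.ndarray:
        return np.array([self.locus_index(m) for m in self.scored_loci])

    @property
    def n_scored(self) -> int:
        return len(self.scored_loci)

    @property
    def scored_interval_names(self) -> tuple[str, ...]:
        """Names of the intervals between consecutive scored loci."""
        return tuple(
            f"{a}-{b}" for a, b in zip(self.scored_loci[:-1], self.scored_loci[1:])
        )

    def intervals_between(self, left: str, right: str) -> list[int]:
        """Physical interval indices lying between two loci (left distal)."""
        i, j = self.locus_index(left), self.locus_index(right)
        if i >= j:
            raise MarkerMapError(f"{left!r} is not distal to {right!r}")
        return list(range(i, j))

    def chromatid_recombination_fraction(self, left: str, right: str) -> float:
        """Chromatid-level probability of an odd number of exchanges between two loci.

        Crossovers in distinct physical intervals are independent in this
        model, so the composite follows the standard no-interference
        combination rule ``(1 - prod(1 - 2 r_i)) / 2``.
        """
        prod = 1.0
        for i in self.intervals_between(left, right):
            prod *= 1.0 - 2.0 * self.interval_r[i]
        return 0.5 * (1.0 - prod)

    # -- parental haplotype codes ---------------------------------------

    @property
    def parental_codes(self) -> tuple[str, str]:
        """Scored-locus codes of the two parental arrangements (wild type, marked)."""
        return "+" * self.n_scored, "m" * self.n_scored


def standard_map(
    r_sc_cv: float = STANDARD_SCORED_R["sc-cv"],
    r_cv_f: float = STANDARD_SCORED_R["cv-f"],
    r_f_car: float = 0.058,
    include_v: bool = True,
) -> MarkerMap:
    """Build a map with given scored-interval recombination fractions.

    With ``include_v`` the cv–f fraction is split equally across cv–v and
    v–f (allowing intra-interval double crossovers); otherwise cv–f is a
    single atomic interval, which is what the exhaustive classifier
    enumeration uses.
    """
    if include_v:
        if not 0.0 <= r_cv_f <= 0.5:
            raise MarkerMapError(f"r_cv_f = {r_cv_f} outside [0, 0.5]")
        half = 0.5 * (1.0 - math.sqrt(1.0 - 2.0 * r_cv_f))
        return MarkerMap(
            loci=("y", "sc", "cv", "v", "f", "car", CENTROMERE),
            interval_r=(0.0, r_sc_cv, half, half, r_f_car, 0.0),
        )
    return MarkerMap(
        loci=("y", "sc", "cv", "f", "car", CENTROMERE),
        interval_r=(0.0, r_sc_cv, r_cv_f, r_f_car, 0.0),
    )


DEFAULT_MAP = MarkerMap()


# -- haplotype code helpers ---------------------------------------------


def code_from_bools(marked: Sequence[bool] | np.ndarray) -> str:
    """Turn per-locus marked-allele booleans into an 'm'/'+' code string."""
    return "".join("m" if bool(x) else "+" for x in marked)


def bools_from_code(code: str) -> np.ndarray:
    """Parse an 'm'/'+' code string into a boolean array (True = marked)."""
    bad = set(code) - {"m", "+"}
    if bad:
        raise ValueError(f"invalid haplotype code {code!r}: characters {sorted(bad)}")
    return np.array([c == "m" for c in code], dtype=bool)


def validate_code(code: str, n_scored: int) -> str:
    if len(code) != n_scored or set(code) - {"m", "+"}:
        raise ValueError(
            f"haplotype code {code!r} is not a {n_scored}-character 'm'/'+' string"
        )
    return code
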