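"""Crossover-frequency assay: interval recombinant fractions and map distances.

Sons of heterozygously marked females report one gametic chromatid each.
A son is recombinant in a scored interval iff his alleles at the flanking
scored loci derive from different parental arrangements.  Map distance is
reported as the raw recombinant percentage (cM) per interval — no mapping
function, because the assay compares raw distances between genotypes —
and the total map is the sum over intervals.  Haldane's correction is
available behind a flag for readers who want additive distances under the
no-interference model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .markers import DEFAULT_MAP, MarkerMap
from .stats import fisher_exact_2x2

__all__ = [
    "IntervalCounts",
    "MapDistances",
    "score_crossovers",
    "map_distances",
    "compare_maps",
]


@dataclass(frozen=True)
class IntervalCounts:
    """Recombinant tally for one scored interval."""

    interval: str
    n_recombinant: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_recombinant <= self.n_total:
            raise ValueError(
                f"{self.interval}: {self.n_recombinant} recombinants of "
                f"{self.n_total} scored"
            )


def score_crossovers(
    son_haplotypes: Sequence[str], marker_map: MarkerMap = DEFAULT_MAP
) -> list[IntervalCounts]:
    """Count recombinant sons per scored interval.

    Malformed haplotype codes (wrong length or characters outside 'm'/'+')
    are skipped with a warning rather than aborting the tally.
    """
    S = marker_map.n_scored
    names = marker_map.scored_interval_names
    rec = [0] * len(names)
    total = 0
    skipped = 0
    for code in son_haplotypes:
        if len(code) != S or set(code) - {"m", "+"}:
            skipped += 1
            continue
        total += 1
        for j in range(len(names)):
            if code[j] != code[j + 1]:
                rec[j] += 1
    if skipped:
        warnings.warn(
            f"skipped {skipped} son record(s) missing a scored locus", stacklevel=2
        )
    return [IntervalCounts(names[j], rec[j], total) for j in range(len(names))]


@dataclass(frozen=True)
class MapDistances:
    """Per-interval and total map distance in centiMorgans."""

    per_interval: Mapping[str, float]
    total_cM: float
    n_scored: int


def map_distances(
    counts: Sequence[IntervalCounts], mapping_function: str = "none"
) -> MapDistances:
    """cM = 100 * recombinants / scored per interval; total = sum.

    ``mapping_function='haldane'`` applies d = -50 ln(1 - 2 r) instead of
    the raw percentage (off by default; the assay compares raw distances).
    """
    if not counts:
        raise ValueError("no interval counts supplied")
    per: dict[str, float] = {}
    for c in counts:
        if c.n_total < 1:
            raise ValueError(f"{c.interval}: zero sons scored")
        r = c.n_recombinant / c.n_total
        if mapping_function == "none":
            per[c.interval] = 100.0 * r
        elif mapping_function == "haldane":
            if r >= 0.5:
                raise ValueError(
                    f"{c.interval}: recombinant fraction {r} >= 0.5 has no "
                    "finite Haldane distance"
                )
            per[c.interval] = -50.0 * math.log(1.0 - 2.0 * r)
        else:
            raise ValueError(f"unknown mapping function {mapping_function!r}")
    return MapDistances(
        per_interval=per,
        total_cM=sum(per.values()),
        n_scored=counts[0].n_total,
    )


def compare_maps(
    a: Sequence[IntervalCounts], b: Sequence[IntervalCounts]
) -> dict[str, float]:
    """Two-sided Fisher's exact p per interval plus a pooled total-map test.

    Each interval contributes a (recombinant, parental) x (group) table;
    the ``'total'`` entry pools recombinant events across intervals into a
    single 2x2 table.
    """
    names_a = [c.interval for c in a]
    names_b = [c.interval for c in b]
    if names_a != names_b:
        raise ValueError(f"interval sets differ: {names_a} vs {names_b}")
    out: dict[str, float] = {}
    pooled_a = [0, 0]
    pooled_b = [0, 0]
    for ca, cb in zip(a, b):
        out[ca.interval] = fisher_exact_2x2(
            [
                [ca.n_recombinant, ca.n_total - ca.n_recombinant],
                [cb.n_recombinant, cb.n_total - cb.n_recombinant],
            ]
        )
        pooled_a[0] += ca.n_recombinant
        pooled_a[1] += ca.n_total - ca.n_recombinant
        pooled_b[0] += cb.n_recombinant
        pooled_b[1] += cb.n_total - cb.n_recombinant
    out["total"] = fisher_exact_2x2([pooled_a, pooled_b])
    return out
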