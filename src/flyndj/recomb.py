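"""Recombinational-history assay: deduce a Diplo-X female's two chromatids.

A Diplo-X female arising from an NDJ event carries two maternal X
chromatids.  Her visible phenotype shows a recessive marker only where she
is homozygous for it, and each of her sons reports one chromatid directly.
The deduction rules are:

* at most two distinct son haplotype classes can occur — more is an
  inconsistent record;
* a locus mutant in the mother's phenotype must be mutant on both
  chromatids (and hence in every son) — a wild-type son allele there is a
  contradiction;
* the centromere-proximal marker *car* distinguishes the error type:
  differing car alleles mean two homologs (MI error), identical car
  alleles mean two sisters (MII error);
* a chromatid is recombinant iff its scored alleles match neither parental
  arrangement (all-wild-type vs fully marked).  *y* is shared by both
  maternal X's and never informative; *v* is carried in the genotype but
  not scored.

The per-mille missegregation frequency of recombinant chromosomes divides
the number of Diplo-X females that inherited at least one recombinant
chromatid by the total viable progeny of the NDJ test, times 1000.  The
assay undercounts by construction: only two of a bivalent's four
chromatids are genotyped, and double crossovers between cv and f are
invisible at the scored loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .markers import DEFAULT_MAP, MarkerMap, validate_code
from .stats import fisher_exact_2x2

__all__ = [
    "InconsistentRecordError",
    "DeducedPair",
    "DiploXRecord",
    "RecombFreqResult",
    "RecombComparison",
    "deduce_chromatid_pair",
    "classify_missegregation",
    "analyze_diplo_female",
    "recombinant_missegregation_frequency",
]

#: Sons needed before a single observed haplotype class is trusted as a
#: homozygous pair: P(missing a second class at 1/2 transmission) < 0.004.
MIN_SONS_FOR_CONFIDENT_CALL = 8


class InconsistentRecordError(ValueError):
    """A Diplo-X record that cannot arise from two-chromatid transmission."""


@dataclass(frozen=True)
class DeducedPair:
    """Deduction outcome: the two chromatid codes plus a confidence grade."""

    pair: tuple[str, str]
    confidence: str  # 'high' | 'low'
    n_sons: int
    note: str = ""


def deduce_chromatid_pair(
    female_phenotype: str,
    son_haplotypes: Sequence[str],
    min_sons: int = MIN_SONS_FOR_CONFIDENT_CALL,
    marker_map: MarkerMap = DEFAULT_MAP,
) -> DeducedPair:
    """Deduce the two X chromatids of a Diplo-X female.

    Parameters
    ----------
    female_phenotype:
        'm'/'+' code over the scored loci; 'm' means the recessive marker
        is visible, i.e. the female is homozygous mutant there.
    son_haplotypes:
        Scored haplotype codes of her male progeny (one chromatid each).
    """
    S = marker_map.n_scored
    loci = marker_map.scored_loci
    validate_code(female_phenotype, S)
    if not son_haplotypes:
        raise ValueError("at least one son haplotype is required")
    sons = [validate_code(s, S) for s in son_haplotypes]

    classes = sorted(set(sons))
    if len(classes) > 2:
        raise InconsistentRecordError(
            f"{len(classes)} distinct son haplotypes {classes}: "
            "impossible under two-chromatid transmission"
        )

    # phenotype consistency
    for i, locus in enumerate(loci):
        if female_phenotype[i] == "m":
            for c in classes:
                if c[i] != "m":
                    raise InconsistentRecordError(
                        f"mother shows {locus} but son haplotype {c!r} is "
                        f"wild type at {locus}"
                    )
        else:
            if len(classes) == 2 and all(c[i] == "m" for c in classes):
                raise InconsistentRecordError(
                    f"both son classes are mutant at {locus} but the mother "
                    f"does not show {locus}"
                )

    if len(classes) == 2:
        return DeducedPair((classes[0], classes[1]), "high", len(sons))

    # single observed class: the pair is homozygous only if the phenotype
    # pins every locus where the classes could differ
    c = classes[0]
    hidden = [
        loci[i]
        for i in range(S)
        if female_phenotype[i] == "+" and c[i] == "m"
    ]
    if hidden:
        # a second, unobserved chromatid must exist (wild type at `hidden`);
        # reconstruct the forced alleles and call the record low confidence
        partner = "".join(
            "m" if female_phenotype[i] == "m" else ("+" if c[i] == "m" else c[i])
            for i in range(S)
        )
        return DeducedPair(
            (c, partner),
            "low",
            len(sons),
            note=f"second chromatid unobserved; forced wild type at {hidden}",
        )
    if len(sons) >= min_sons or c == "m" * S:
        return DeducedPair((c, c), "high", len(sons))
    return DeducedPair(
        (c, c),
        "low",
        len(sons),
        note=f"only {len(sons)} sons; a second haplotype class may be unsampled",
    )


@dataclass(frozen=True)
class MissegClass:
    error_type: str  # 'MI' | 'MII'
    recomb_flags: tuple[bool, bool]


def classify_missegregation(
    pair: tuple[str, str], marker_map: MarkerMap = DEFAULT_MAP
) -> MissegClass:
    """MI/MII call from *car* heterozygosity plus per-chromatid recombinant flags.

    Differing car alleles mean the female inherited two homologs (MI
    error); identical car alleles mean two sisters (MII error).  Each
    chromatid is flagged recombinant iff its scored alleles match neither
    parental arrangement.
    """
    S = marker_map.n_scored
    a, b = (validate_code(c, S) for c in pair)
    wt, mut = marker_map.parental_codes
    error_type = "MI" if a[-1] != b[-1] else "MII"
    flags = tuple(c not in (wt, mut) for c in (a, b))
    return MissegClass(error_type, flags)


@dataclass(frozen=True)
class DiploXRecord:
    """One analyzed Diplo-X female.

    ``error_type`` is 'ambiguous' for low-confidence deductions, which are
    excluded from frequency numerators and denominators.
    """

    female_id: str
    phenotype: str
    sons: tuple[str, ...]
    pair: tuple[str, str]
    confidence: str
    error_type: str
    recomb_flags: tuple[bool, bool]
    note: str = ""

    @property
    def any_recombinant(self) -> bool:
        return any(self.recomb_flags)

    @property
    def confident(self) -> bool:
        return self.confidence == "high"


def analyze_diplo_female(
    female_id: str,
    phenotype: str,
    sons: Sequence[str],
    min_sons: int = MIN_SONS_FOR_CONFIDENT_CALL,
    marker_map: MarkerMap = DEFAULT_MAP,
) -> DiploXRecord:
    """Run deduction + classification for one Diplo-X female."""
    ded = deduce_chromatid_pair(phenotype, sons, min_sons, marker_map)
    cls = classify_missegregation(ded.pair, marker_map)
    error_type = cls.error_type if ded.confidence == "high" else "ambiguous"
    return DiploXRecord(
        female_id=str(female_id),
        phenotype=phenotype,
        sons=tuple(sons),
        pair=ded.pair,
        confidence=ded.confidence,
        error_type=error_type,
        recomb_flags=cls.recomb_flags,
        note=ded.note,
    )


@dataclass(frozen=True)
class RecombFreqResult:
    """Per-group recombinant-missegregation summary (rates per 1000 progeny)."""

    n_records: int
    n_confident: int
    r_count: int  # Diplo-X females with >=1 recombinant chromatid
    mi_recomb: int
    mii_recomb: int
    total_progeny: int
    freq_per_1000: float
    mi_freq_per_1000: float
    mii_freq_per_1000: float


def _summarize(records: Sequence[DiploXRecord], total: int) -> RecombFreqResult:
    confident = [r for r in records if r.confident]
    rec = [r for r in confident if r.any_recombinant]
    mi = sum(r.error_type == "MI" for r in rec)
    mii = sum(r.error_type == "MII" for r in rec)
    scale = 1000.0 / total
    return RecombFreqResult(
        n_records=len(records),
        n_confident=len(confident),
        r_count=len(rec),
        mi_recomb=mi,
        mii_recomb=mii,
        total_progeny=total,
        freq_per_1000=len(rec) * scale,
        mi_freq_per_1000=mi * scale,
        mii_freq_per_1000=mii * scale,
    )


@dataclass(frozen=True)
class RecombComparison:
    """KD-vs-control comparison of recombinant-missegregation frequencies."""

    group: RecombFreqResult
    control: RecombFreqResult | None = None
    p_vs_control: float | None = None
    p_mi: float | None = None
    p_mii: float | None = None


def recombinant_missegregation_frequency(
    records: Sequence[DiploXRecord],
    total_progeny: int,
    control_records: Sequence[DiploXRecord] | None = None,
    control_total: int | None = None,
) -> RecombComparison:
    """Per-1000 missegregation frequency of recombinant chromosomes.

    The numerator counts confidently deduced Diplo-X females with at least
    one recombinant chromatid; the denominator is the total viable progeny
    of the originating NDJ test.  With a control group, two-sided Fisher's
    exact tests compare the overall, MI and MII recombinant counts at the
    two totals.
    """
    if total_progeny <= 0:
        raise ValueError(f"total_progeny must be positive (got {total_progeny})")
    if total_progeny < len(records):
        raise ValueError(
            f"total_progeny ({total_progeny}) below number of Diplo-X "
            f"records ({len(records)})"
        )
    group = _summarize(records, total_progeny)
    if control_records is None:
        return RecombComparison(group)
    if control_total is None or control_total <= 0:
        raise ValueError("control_total must be positive when control records given")
    if control_total < len(control_records):
        raise ValueError("control_total below number of control Diplo-X records")
    control = _summarize(control_records, control_total)

    def _fisher(k_a: int, k_b: int) -> float:
        return fisher_exact_2x2(
            [
                [k_a, total_progeny - k_a],
                [k_b, control_total - k_b],
            ]
        )

    return RecombComparison(
        group=group,
        control=control,
        p_vs_control=_fisher(group.r_count, control.r_count),
        p_mi=_fisher(group.mi_recomb, control.mi_recomb),
        p_mii=_fisher(group.mii_recomb, control.mii_recomb),
    )
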