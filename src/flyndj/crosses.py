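"""The two crossing schemes that turn ova into scored progeny.

NDJ test cross
    Assay females are crossed to attached-X^Y males carrying the dominant
    Bar eye marker.  Sperm are X^Y or nullo-X with equal probability, so a
    zygote's X dosage (and hence viability, sex and Bar phenotype) reports
    the maternal ovum class: normal ova give normal females (X/X^Y, Bar) or
    males (X/0); diplo-X ova give viable non-Bar Diplo-X females or dead
    metafemales; nullo-X ova give viable Bar X^Y males or dead nullo-X
    zygotes.  Exactly half of exceptional zygotes die, which is why the
    exceptional count E is doubled in the %NDJ estimator.

Diplo-X genotyping cross
    Each surviving Diplo-X female is mated to *y w* males and her sons are
    scored for the visible markers.  Each son inherits one of her two X
    chromatids with probability 1/2; sons are read as direct reporters of
    the two chromatids (no further recombination is modelled, matching how
    the assay deduces the mother's genotype).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .markers import code_from_bools
from .meiosis import Chromatid, OvaTable, Ovum

__all__ = [
    "ProgenyRecord",
    "NDJCounts",
    "VIABLE_CLASSES",
    "fertilize_ndj_cross",
    "ndj_cross_classes",
    "tally_progeny",
    "tally_classes",
    "genotyping_cross",
    "genotype_sons",
    "maternal_phenotype",
]

# progeny class codes (viable classes first)
NORMAL_FEMALE, NORMAL_MALE, DIPLOX_FEMALE, XY_BAR_MALE = 0, 1, 2, 3
DEAD_METAFEMALE, DEAD_NULLOX = 4, 5

CLASS_LABELS = (
    "normal_female",
    "normal_male",
    "diploX_female",
    "XY_bar_male",
    "dead_metafemale",
    "dead_nulloX",
)
VIABLE_CLASSES = frozenset(CLASS_LABELS[:4])


@dataclass(frozen=True)
class ProgenyRecord:
    """One zygote of the NDJ test cross."""

    progeny_class: str
    chromatids: tuple[Chromatid, ...]
    sex: str  # 'female' / 'male' / 'dead'
    bar: bool

    @property
    def viable(self) -> bool:
        return self.progeny_class in VIABLE_CLASSES


@dataclass(frozen=True)
class NDJCounts:
    """Viable progeny tallies of one NDJ test cross."""

    n_normal: int
    e_diploX: int
    e_XY: int

    def __post_init__(self) -> None:
        for name in ("n_normal", "e_diploX", "e_XY"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (got {getattr(self, name)})")

    @property
    def E(self) -> int:
        """Total exceptional progeny (Diplo-X females + X^Y Bar males)."""
        return self.e_diploX + self.e_XY

    @property
    def total(self) -> int:
        return self.n_normal + self.E

    def __add__(self, other: "NDJCounts") -> "NDJCounts":
        return NDJCounts(
            self.n_normal + other.n_normal,
            self.e_diploX + other.e_diploX,
            self.e_XY + other.e_XY,
        )


def fertilize_ndj_cross(ovum: Ovum, rng: np.random.Generator) -> ProgenyRecord:
    """Fertilize one ovum with an X^Y (probability 1/2) or nullo sperm."""
    n = len(ovum.chromatids)
    if n > 2:
        raise ValueError(f"ovum carries {n} X chromatids; at most 2 possible")
    xy_sperm = rng.random() < 0.5
    if n == 1:
        if xy_sperm:
            return ProgenyRecord("normal_female", ovum.chromatids, "female", True)
        return ProgenyRecord("normal_male", ovum.chromatids, "male", False)
    if n == 2:
        if xy_sperm:
            return ProgenyRecord("dead_metafemale", ovum.chromatids, "dead", True)
        return ProgenyRecord("diploX_female", ovum.chromatids, "female", False)
    if xy_sperm:
        return ProgenyRecord("XY_bar_male", (), "male", True)
    return ProgenyRecord("dead_nulloX", (), "dead", False)


def ndj_cross_classes(ova: OvaTable, rng: np.random.Generator) -> np.ndarray:
    """Vectorized NDJ cross: per-ovum progeny class codes."""
    n = len(ova)
    xy = rng.random(n) < 0.5
    nc = ova.n_chromatids
    return np.where(
        nc == 1,
        np.where(xy, NORMAL_FEMALE, NORMAL_MALE),
        np.where(
            nc == 2,
            np.where(xy, DEAD_METAFEMALE, DIPLOX_FEMALE),
            np.where(xy, XY_BAR_MALE, DEAD_NULLOX),
        ),
    ).astype(np.int8)


def tally_progeny(records: Sequence[ProgenyRecord]) -> NDJCounts:
    """Tally viable progeny into normal and exceptional classes.

    Dead classes (metafemales, nullo-X zygotes) never reach the counting
    bottle and are excluded from every count.
    """
    labels = [r.progeny_class for r in records]
    return NDJCounts(
        n_normal=sum(l in ("normal_female", "normal_male") for l in labels),
        e_diploX=labels.count("diploX_female"),
        e_XY=labels.count("XY_bar_male"),
    )


def tally_classes(classes: np.ndarray) -> NDJCounts:
    """Vectorized counterpart of :func:`tally_progeny` on class codes."""
    return NDJCounts(
        n_normal=int(((classes == NORMAL_FEMALE) | (classes == NORMAL_MALE)).sum()),
        e_diploX=int((classes == DIPLOX_FEMALE).sum()),
        e_XY=int((classes == XY_BAR_MALE).sum()),
    )


def genotyping_cross(
    diplo_female: ProgenyRecord, n_sons: int, rng: np.random.Generator
) -> list[str]:
    """Scored haplotype codes of a Diplo-X female's sons.

    Each son independently inherits one of the mother's two X chromatids
    with probability 1/2 and is phenotyped at the scored loci only.
    """
    if diplo_female.progeny_class != "diploX_female":
        raise ValueError(
            f"genotyping cross requires a diploX_female "
            f"(got {diplo_female.progeny_class})"
        )
    if n_sons < 1:
        raise ValueError(f"n_sons must be >= 1 (got {n_sons})")
    picks = rng.integers(0, 2, size=n_sons)
    return [diplo_female.chromatids[int(p)].scored_code for p in picks]


def genotype_sons(
    scored_origin: np.ndarray, n_sons: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized genotyping cross for a batch of Diplo-X mothers.

    Parameters
    ----------
    scored_origin:
        bool array [n_mothers, 2, n_scored] of the mothers' chromatid pairs.

    Returns
    -------
    bool array [n_mothers, n_sons, n_scored] of son marker states
    (True = marked allele).
    """
    m = scored_origin.shape[0]
    if n_sons < 1:
        raise ValueError(f"n_sons must be >= 1 (got {n_sons})")
    picks = rng.integers(0, 2, size=(m, n_sons))
    return np.take_along_axis(scored_origin, picks[:, :, None], axis=1)


def maternal_phenotype(scored_origin: np.ndarray) -> list[str]:
    """Visible phenotype codes of Diplo-X mothers (mutant iff homozygous).

    ``scored_origin`` is bool [n_mothers, 2, n_scored]; a recessive marker
    shows only when both chromatids carry it.
    """
    both = scored_origin.all(axis=1)
    return [code_from_bools(row) for row in both]
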