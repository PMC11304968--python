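"""Forward simulation of single-oocyte female meiosis on a marked X bivalent.

Model
-----
A bivalent is four chromatids: two sisters of the wild-type-marked homolog
(slots 0, 1) and two of the fully marked homolog (slots 2, 3).  Each
physical map interval independently receives at most one crossover, with
bivalent probability ``2 r`` so that the chromatid-level recombinant
fraction equals ``r``; the crossover joins a uniformly chosen non-sister
pair and exchanges the segments distal to the interval.  No chromatid or
crossover interference is modelled.

Segregation then proceeds in two error-prone steps:

* **MI** — a chiasmate bivalent whose chiasma survives (probability
  ``1 - p_arm_loss``) segregates normally.  An achiasmate bivalent, or one
  whose chiasma is destroyed by premature arm-cohesion loss, is rescued by
  the heterochromatin-mediated achiasmate backup pathway with probability
  ``backup_efficiency`` (if enabled; the pathway is disabled in
  *mtrm*:sup:`KG`/+ oocytes).  Otherwise the two homologs segregate
  independently: both retained gives a diplo-X MI ovum (one chromatid
  sampled per homolog), both lost a nullo-X MI ovum.
* **MII** — with probability ``p_mii_loss`` premature pericentric
  (sister) cohesion loss lets the two sisters segregate independently,
  giving a diplo-X MII ovum (both sisters) or a nullo-X ovum with
  probability 1/4 each.

Ground truth (homolog of origin, per-chromatid exchange history, bivalent
crossover count) is carried through so downstream classifiers can be scored
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .markers import DEFAULT_MAP, MarkerMap, code_from_bools

__all__ = [
    "SimConfig",
    "Chromatid",
    "Bivalent",
    "Ovum",
    "OvaTable",
    "build_bivalent",
    "apply_crossovers",
    "resolve_meiosis",
    "simulate_oocytes",
    "enumerate_diplo_ova",
]

#: The four non-sister chromatid pairs a crossover can join.
NON_SISTER_PAIRS: tuple[tuple[int, int], ...] = ((0, 2), (0, 3), (1, 2), (1, 3))

ERROR_NONE, ERROR_MI, ERROR_MII = 0, 1, 2
ERROR_LABELS = np.array(["none", "MI", "MII"])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated oocyte population.

    Attributes
    ----------
    marker_map:
        Marked-X map used for crossover placement and scoring.
    p_arm_loss:
        Probability that a chiasmate bivalent loses its chiasma through
        premature arm-cohesion loss (whole-bivalent, binary).
    p_mii_loss:
        Probability of premature pericentric cohesion loss at MII.
    backup_enabled:
        Whether the achiasmate backup pathway operates (False models the
        *mtrm*:sup:`KG`/+ sensitized background).
    backup_efficiency:
        Rescue probability of the backup pathway when enabled.
    obligate_chiasma:
        Resample crossovers until the bivalent is chiasmate, emulating
        crossover assurance without modelling interference.
    n_oocytes, seed:
        Population size and the single integer seed of the run.
    """

    marker_map: MarkerMap = field(default_factory=MarkerMap)
    p_arm_loss: float = 0.0
    p_mii_loss: float = 0.0
    backup_enabled: bool = True
    backup_efficiency: float = 0.95
    obligate_chiasma: bool = False
    n_oocytes: int = 1000
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("p_arm_loss", "p_mii_loss", "backup_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if int(self.n_oocytes) < 1:
            raise ValueError(f"n_oocytes must be >= 1 (got {self.n_oocytes})")
        if self.obligate_chiasma and not any(r > 0 for r in self.marker_map.interval_r):
            raise ValueError(
                "obligate_chiasma requires at least one interval with r > 0"
            )
        return self


@dataclass(frozen=True)
class Chromatid:
    """One chromatid: per-locus parental origin plus immutable truth tags.

    ``origin`` is a boolean per map locus (centromere included, last):
    True where the segment derives from the fully marked homolog.  The
    centromere entry never changes under crossing over and is the MI/MII
    ground truth.
    """

    origin: np.ndarray
    marker_map: MarkerMap = field(default_factory=MarkerMap, repr=False)
    sister_id: int = 1

    @property
    def homolog_origin(self) -> int:
        """1 for the wild-type-marked homolog, 2 for the fully marked one."""
        return 2 if bool(self.origin[-1]) else 1

    @property
    def alleles(self) -> tuple[str, ...]:
        """Per-locus allele, 'mut' or 'wt' (both homologs are *y*-marked)."""
        out = []
        for locus, from_marked in zip(self.marker_map.loci[:-1], self.origin[:-1]):
            mut = bool(from_marked) or locus == "y"
            out.append("mut" if mut else "wt")
        return tuple(out)

    @property
    def breakpoints(self) -> tuple[int, ...]:
        """Interval indices where parental origin switches along the chromatid."""
        o = np.asarray(self.origin, dtype=bool)
        return tuple(int(i) for i in np.nonzero(o[:-1] != o[1:])[0])

    @property
    def is_recombinant(self) -> bool:
        return len(self.breakpoints) > 0

    @property
    def scored_code(self) -> str:
        """'m'/'+' code over the scored loci (reads the mother's chromatid
        directly; *y* is uninformative and excluded from scoring)."""
        return code_from_bools(self.origin[self.marker_map.scored_indices])


@dataclass(frozen=True)
class Bivalent:
    """Four chromatids plus the crossover events that shaped them."""

    chromatids: tuple[Chromatid, Chromatid, Chromatid, Chromatid]
    crossover_events: tuple[tuple[int, tuple[int, int]], ...]
    marker_map: MarkerMap = field(default_factory=MarkerMap, repr=False)

    @property
    def chiasmate(self) -> bool:
        return len(self.crossover_events) > 0

    @property
    def n_crossovers(self) -> int:
        return len(self.crossover_events)


@dataclass(frozen=True)
class Ovum:
    """One meiotic product: 0, 1 or 2 maternal X chromatids.

    ``error_class`` is simulation truth: 'none' for a normal single-X ovum,
    'MI'/'MII' for diplo or nullo exceptional ova.
    """

    chromatids: tuple[Chromatid, ...]
    error_class: str
    truth_n_crossovers: int | None = None

    def __post_init__(self) -> None:
        n = len(self.chromatids)
        if n > 2:
            raise ValueError(f"an ovum carries at most 2 X chromatids (got {n})")
        if (n == 1) != (self.error_class == "none"):
            raise ValueError(
                f"{n} chromatid(s) inconsistent with error_class {self.error_class!r}"
            )


def _initial_origin(marker_map: MarkerMap) -> np.ndarray:
    origin = np.zeros((4, marker_map.n_loci), dtype=bool)
    origin[2:, :] = True
    return origin


def apply_crossovers(
    marker_map: MarkerMap,
    events: Sequence[tuple[int, tuple[int, int]]],
) -> Bivalent:
    """Deterministically build a bivalent from explicit crossover events.

    Events are ``(interval_index, (chromatid_a, chromatid_b))`` with one
    chromatid from each homolog; they are applied distal → proximal, each
    exchanging the segments distal to its interval.
    """
    events = sorted(((int(i), (int(a), int(b))) for i, (a, b) in events), key=lambda e: e[0])
    seen_intervals = [i for i, _ in events]
    if len(set(seen_intervals)) != len(seen_intervals):
        raise ValueError("at most one crossover per interval")
    origin = _initial_origin(marker_map)
    for interval, (a, b) in events:
        if not 0 <= interval < marker_map.n_intervals:
            raise ValueError(f"interval index {interval} out of range")
        if tuple(sorted((a, b))) not in NON_SISTER_PAIRS:
            raise ValueError(f"crossover pair {(a, b)} is not a non-sister pair")
        distal = slice(0, interval + 1)
        tmp = origin[a, distal].copy()
        origin[a, distal] = origin[b, distal]
        origin[b, distal] = tmp
    chromatids = tuple(
        Chromatid(origin=origin[i].copy(), marker_map=marker_map, sister_id=(i % 2) + 1)
        for i in range(4)
    )
    return Bivalent(
        chromatids=chromatids,
        crossover_events=tuple((i, tuple(sorted(p))) for i, p in events),
        marker_map=marker_map,
    )


def build_bivalent(marker_map: MarkerMap, rng: np.random.Generator) -> Bivalent:
    """Sample crossovers interval by interval (bivalent probability 2·r each)."""
    events = []
    for i, r in enumerate(marker_map.interval_r):
        if rng.random() < min(2.0 * r, 1.0):
            events.append((i, NON_SISTER_PAIRS[rng.integers(4)]))
    return apply_crossovers(marker_map, events)


def resolve_meiosis(
    bivalent: Bivalent, cfg: SimConfig, rng: np.random.Generator
) -> Ovum:
    """Segregate one bivalent through MI and MII (scalar reference path).

    Mirrors the vectorized sampler's logic; the two are checked against each
    other statistically, not draw for draw.
    """
    chroms = bivalent.chromatids
    n_co = bivalent.n_crossovers

    unconnected = True
    if bivalent.chiasmate:
        unconnected = rng.random() < cfg.p_arm_loss
    if unconnected and cfg.backup_enabled and rng.random() < cfg.backup_efficiency:
        unconnected = False  # backup pathway rescues the segregation outcome

    if unconnected:
        keep1, keep2 = rng.random() < 0.5, rng.random() < 0.5
        if keep1 and keep2:
            c1 = chroms[rng.integers(2)]
            c2 = chroms[2 + rng.integers(2)]
            return Ovum((c1, c2), "MI", n_co)
        if not keep1 and not keep2:
            return Ovum((), "MI", n_co)
        homolog = 0 if keep1 else 1
    else:
        homolog = int(rng.integers(2))

    sisters = (chroms[2 * homolog], chroms[2 * homolog + 1])
    if rng.random() < cfg.p_mii_loss:
        keep_a, keep_b = rng.random() < 0.5, rng.random() < 0.5
        if keep_a and keep_b:
            return Ovum(sisters, "MII", n_co)
        if not keep_a and not keep_b:
            return Ovum((), "MII", n_co)
        return Ovum((sisters[0] if keep_a else sisters[1],), "none", n_co)
    return Ovum((sisters[int(rng.integers(2))],), "none", n_co)


def enumerate_diplo_ova(bivalent: Bivalent) -> list[Ovum]:
    """Every diplo-X ovum the bivalent can produce, with truth labels.

    MI diplo ova take one chromatid from each homolog (4 combinations);
    MII diplo ova take both sisters of one homolog (2 combinations).
    """
    chroms = bivalent.chromatids
    out = []
    for a in range(2):
        for b in range(2, 4):
            out.append(Ovum((chroms[a], chroms[b]), "MI", bivalent.n_crossovers))
    for h in range(2):
        out.append(
            Ovum((chroms[2 * h], chroms[2 * h + 1]), "MII", bivalent.n_crossovers)
        )
    return out


# -- vectorized population sampler --------------------------------------


@dataclass
class OvaTable:
    """Column-oriented batch of simulated ova (the fast path).

    ``origin`` holds the parental-origin vectors of up to two chromatids per
    ovum; slot validity follows ``n_chromatids``.  ``co`` is the bivalent
    crossover indicator per physical interval (simulation truth).
    """

    marker_map: MarkerMap
    n_chromatids: np.ndarray  # int8 [n]
    error_class: np.ndarray  # int8 [n], 0 none / 1 MI / 2 MII
    origin: np.ndarray  # bool [n, 2, n_loci]
    co: np.ndarray  # bool [n, n_intervals]

    def __len__(self) -> int:
        return int(self.n_chromatids.shape[0])

    @property
    def error_labels(self) -> np.ndarray:
        return ERROR_LABELS[self.error_class]

    @property
    def is_exceptional(self) -> np.ndarray:
        return self.n_chromatids != 1

    @property
    def truth_n_crossovers(self) -> np.ndarray:
        return self.co.sum(axis=1)

    @property
    def homolog_origin(self) -> np.ndarray:
        """1/2 per carried chromatid slot (centromere origin)."""
        return np.where(self.origin[:, :, -1], 2, 1)

    @property
    def chromatid_recombinant(self) -> np.ndarray:
        """Truth recombinant flag per carried chromatid slot."""
        return (self.origin != self.origin[:, :, -1:]).any(axis=2)

    @property
    def scored_origin(self) -> np.ndarray:
        """bool [n, 2, n_scored]: marked-allele state at the scored loci."""
        return self.origin[:, :, self.marker_map.scored_indices]

    def subset(self, index: np.ndarray) -> "OvaTable":
        return OvaTable(
            marker_map=self.marker_map,
            n_chromatids=self.n_chromatids[index],
            error_class=self.error_class[index],
            origin=self.origin[index],
            co=self.co[index],
        )

    def ovum(self, i: int) -> Ovum:
        n = int(self.n_chromatids[i])
        chroms = tuple(
            Chromatid(origin=self.origin[i, j].copy(), marker_map=self.marker_map)
            for j in range(n)
        )
        return Ovum(chroms, str(ERROR_LABELS[self.error_class[i]]), int(self.co[i].sum()))

    def __iter__(self) -> Iterator[Ovum]:
        return (self.ovum(i) for i in range(len(self)))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form export: one row per ovum, allele codes per chromatid."""
        codes = []
        scored = self.scored_origin
        for j in range(2):
            codes.append(
                np.where(
                    self.n_chromatids > j,
                    ["".join("m" if x else "+" for x in row) for row in scored[:, j]],
                    "",
                )
            )
        return pd.DataFrame(
            {
                "ovum_id": np.arange(len(self)),
                "n_chromatids": self.n_chromatids,
                "error_class": self.error_labels,
                "chromatid1": codes[0],
                "chromatid2": codes[1],
                "n_crossovers": self.truth_n_crossovers,
            }
        )


def _sample_crossovers(
    marker_map: MarkerMap, n: int, rng: np.random.Generator, obligate: bool
) -> tuple[np.ndarray, np.ndarray]:
    p_co = np.minimum(2.0 * np.asarray(marker_map.interval_r), 1.0)
    co = rng.random((n, marker_map.n_intervals)) < p_co
    if obligate:
        pending = np.nonzero(~co.any(axis=1))[0]
        while pending.size:
            co[pending] = rng.random((pending.size, marker_map.n_intervals)) < p_co
            pending = pending[~co[pending].any(axis=1)]
    pairs = rng.integers(0, 4, size=(n, marker_map.n_intervals))
    return co, pairs


def _simulate_batch(cfg: SimConfig, n: int, rng: np.random.Generator) -> OvaTable:
    mm = cfg.marker_map
    L, I = mm.n_loci, mm.n_intervals
    co, pairs = _sample_crossovers(mm, n, rng, cfg.obligate_chiasma)

    origin = np.zeros((n, 4, L), dtype=bool)
    origin[:, 2:, :] = True
    pair_a = np.array([p[0] for p in NON_SISTER_PAIRS])
    pair_b = np.array([p[1] for p in NON_SISTER_PAIRS])
    for i in range(I):  # distal -> proximal, exchanging distal segments
        for p in range(4):
            m = co[:, i] & (pairs[:, i] == p)
            if m.any():
                a, b = pair_a[p], pair_b[p]
                tmp = origin[m, a, : i + 1].copy()
                origin[m, a, : i + 1] = origin[m, b, : i + 1]
                origin[m, b, : i + 1] = tmp

    chiasmate = co.any(axis=1)
    lost = chiasmate & (rng.random(n) < cfg.p_arm_loss)
    unconnected = ~chiasmate | lost
    rescued = (
        unconnected & (rng.random(n) < cfg.backup_efficiency)
        if cfg.backup_enabled
        else np.zeros(n, dtype=bool)
    )
    randseg = unconnected & ~rescued

    keep_h = rng.integers(0, 2, size=(n, 2)).astype(bool)
    diplo_mi = randseg & keep_h[:, 0] & keep_h[:, 1]
    nullo_mi = randseg & ~keep_h[:, 0] & ~keep_h[:, 1]
    single = ~diplo_mi & ~nullo_mi

    h_normal = rng.integers(0, 2, size=n)
    h = np.where(randseg, np.where(keep_h[:, 0], 0, 1), h_normal)

    mii = single & (rng.random(n) < cfg.p_mii_loss)
    keep_s = rng.integers(0, 2, size=(n, 2)).astype(bool)
    diplo_mii = mii & keep_s[:, 0] & keep_s[:, 1]
    nullo_mii = mii & ~keep_s[:, 0] & ~keep_s[:, 1]

    s_normal = rng.integers(0, 2, size=n)
    s = np.where(mii, np.where(keep_s[:, 0], 0, 1), s_normal)

    sis_mi = rng.integers(0, 2, size=(n, 2))

    n_chrom = np.ones(n, dtype=np.int8)
    err = np.zeros(n, dtype=np.int8)
    n_chrom[diplo_mi | diplo_mii] = 2
    n_chrom[nullo_mi | nullo_mii] = 0
    err[diplo_mi | nullo_mi] = ERROR_MI
    err[diplo_mii | nullo_mii] = ERROR_MII

    c0 = np.where(diplo_mi, sis_mi[:, 0], np.where(diplo_mii, 2 * h, 2 * h + s))
    c1 = np.where(diplo_mi, 2 + sis_mi[:, 1], np.where(diplo_mii, 2 * h + 1, 0))
    idx = np.arange(n)
    out_origin = origin[idx[:, None], np.stack([c0, c1], axis=1), :]
    out_origin[n_chrom == 0, :, :] = False
    out_origin[n_chrom == 1, 1, :] = False

    return OvaTable(
        marker_map=mm,
        n_chromatids=n_chrom,
        error_class=err,
        origin=out_origin,
        co=co,
    )


def simulate_oocytes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> OvaTable:
    """Simulate ``cfg.n_oocytes`` ova; deterministic given ``cfg.seed``.

    A caller-supplied generator overrides the config seed, which lets
    pipelines draw everything from one reproducible stream.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return _simulate_batch(cfg, int(cfg.n_oocytes), rng)
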