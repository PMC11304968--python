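"""End-to-end simulated assays: oocytes -> crosses -> scored tables.

These pipelines glue the meiosis sampler to the crossing schemes the way
the bench assays run them, and keep simulation truth alongside every
scored record so the inference modules can be validated against it.
Progeny are collected until a target number of *viable* flies is reached,
mirroring how real crosses are scored to a total rather than to a fixed
number of ova.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .crosses import (
    DIPLOX_FEMALE,
    NDJCounts,
    genotype_sons,
    maternal_phenotype,
    ndj_cross_classes,
    tally_classes,
)
from .markers import DEFAULT_MAP, MarkerMap, code_from_bools
from .meiosis import OvaTable, SimConfig, _simulate_batch
from .recomb import MIN_SONS_FOR_CONFIDENT_CALL, DiploXRecord, analyze_diplo_female

__all__ = [
    "DEFAULT_BASELINE_ARM_LOSS",
    "ndj_experiment_config",
    "simulate_ndj_counts",
    "RecombExperiment",
    "simulate_recomb_experiment",
    "simulate_sons",
]

#: Residual arm-cohesion loss of an unperturbed (control) arm.  Chosen so a
#: backup-disabled control cross sits at the few-percent %NDJ typical of
#: the sensitized background; the true value is a free parameter.
DEFAULT_BASELINE_ARM_LOSS = 0.04


def ndj_experiment_config(
    p_arm_loss: float = DEFAULT_BASELINE_ARM_LOSS,
    p_mii_loss: float = 0.0,
    marker_map: MarkerMap = DEFAULT_MAP,
    backup_enabled: bool = False,
    backup_efficiency: float = 0.0,
    obligate_chiasma: bool = True,
) -> SimConfig:
    """Config for one assay arm.

    Defaults model the screen's sensitized background: the achiasmate
    backup pathway disabled (*mtrm*:sup:`KG`/+) and crossover assurance on,
    so control NDJ stays near real-fly levels and every bivalent is
    informative for arm-cohesion perturbations.
    """
    return SimConfig(
        marker_map=marker_map,
        p_arm_loss=p_arm_loss,
        p_mii_loss=p_mii_loss,
        backup_enabled=backup_enabled,
        backup_efficiency=backup_efficiency,
        obligate_chiasma=obligate_chiasma,
        n_oocytes=1,
    )


def _collect_viable(
    cfg: SimConfig, n_progeny: int, rng: np.random.Generator
) -> tuple[OvaTable, np.ndarray]:
    """Simulate ova until ``n_progeny`` viable flies eclose.

    Returns the ova backing exactly those viable progeny (in production
    order) and their progeny class codes.
    """
    if n_progeny < 1:
        raise ValueError(f"n_progeny must be >= 1 (got {n_progeny})")
    cfg.validate()
    tables: list[OvaTable] = []
    classes: list[np.ndarray] = []
    got = 0
    while got < n_progeny:
        batch_n = max(64, int((n_progeny - got) * 1.3) + 16)
        ova = _simulate_batch(cfg, batch_n, rng)
        cls = ndj_cross_classes(ova, rng)
        viable = cls <= 3
        take = np.nonzero(viable)[0]
        need = n_progeny - got
        take = take[:need]
        tables.append(ova.subset(take))
        classes.append(cls[take])
        got += take.size
    if len(tables) == 1:
        return tables[0], classes[0]
    merged = OvaTable(
        marker_map=cfg.marker_map,
        n_chromatids=np.concatenate([t.n_chromatids for t in tables]),
        error_class=np.concatenate([t.error_class for t in tables]),
        origin=np.concatenate([t.origin for t in tables]),
        co=np.concatenate([t.co for t in tables]),
    )
    return merged, np.concatenate(classes)


def simulate_ndj_counts(
    cfg: SimConfig, n_progeny: int, rng: np.random.Generator
) -> NDJCounts:
    """NDJ test cross of one arm, scored to ``n_progeny`` viable flies."""
    _, cls = _collect_viable(cfg, n_progeny, rng)
    return tally_classes(cls)


@dataclass
class RecombExperiment:
    """One arm of the recombinational-history assay with simulation truth.

    ``records`` aligns index-for-index with the truth arrays; truth refers
    to the Diplo-X female's *source ovum* (bivalent crossover count, true
    MI/MII class, sampled-chromatid recombinant flags).
    """

    counts: NDJCounts
    records: list[DiploXRecord]
    truth_error: np.ndarray  # 'MI' / 'MII' per record
    truth_n_crossovers: np.ndarray  # bivalent crossover count per record
    truth_sampled_recombinant: np.ndarray  # bool [n_records, 2]
    truth_double_co_cv_f: np.ndarray  # bool per record

    @property
    def total_progeny(self) -> int:
        return self.counts.total


def _double_co_cv_f(ova: OvaTable) -> np.ndarray:
    mm = ova.marker_map
    try:
        inner = mm.intervals_between("cv", "f")
    except Exception:
        return np.zeros(len(ova), dtype=bool)
    return ova.co[:, inner].sum(axis=1) >= 2


def simulate_recomb_experiment(
    cfg: SimConfig,
    n_progeny: int,
    rng: np.random.Generator,
    n_sons: int = 12,
    min_sons: int = MIN_SONS_FOR_CONFIDENT_CALL,
) -> RecombExperiment:
    """Run one arm end to end: NDJ cross, then genotype every Diplo-X female.

    Each Diplo-X female is phenotyped at the scored loci (mutant iff
    homozygous) and mated to unmarked males; ``n_sons`` sons per female are
    scored and the deduction/classification rules applied.
    """
    ova, cls = _collect_viable(cfg, n_progeny, rng)
    counts = tally_classes(cls)
    diplo_idx = np.nonzero(cls == DIPLOX_FEMALE)[0]
    diplo = ova.subset(diplo_idx)

    scored = diplo.scored_origin
    phenos = maternal_phenotype(scored)
    son_states = genotype_sons(scored, n_sons, rng) if len(diplo) else None

    records: list[DiploXRecord] = []
    for i in range(len(diplo)):
        sons = [code_from_bools(son_states[i, j]) for j in range(n_sons)]
        records.append(
            analyze_diplo_female(
                female_id=f"dx{i:04d}",
                phenotype=phenos[i],
                sons=sons,
                min_sons=min_sons,
                marker_map=cfg.marker_map,
            )
        )

    return RecombExperiment(
        counts=counts,
        records=records,
        truth_error=diplo.error_labels,
        truth_n_crossovers=diplo.truth_n_crossovers,
        truth_sampled_recombinant=diplo.chromatid_recombinant,
        truth_double_co_cv_f=_double_co_cv_f(diplo),
    )


def simulate_sons(
    cfg: SimConfig, n_sons: int, rng: np.random.Generator
) -> list[str]:
    """Sons of the crossover-frequency cross: gametes of error-free meiosis.

    Cohesion-loss parameters are forced to zero — the mapping cross scores
    every son, so segregation errors are irrelevant — and each son is one
    gametic chromatid read at the scored loci.
    """
    quiet = replace(
        cfg, p_arm_loss=0.0, p_mii_loss=0.0, n_oocytes=max(int(n_sons), 1)
    )
    ova = _simulate_batch(quiet.validate(), int(n_sons), rng)
    scored = ova.scored_origin[:, 0, :]
    return [code_from_bools(row) for row in scored]
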