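"""Screen hit calling: three-arm NDJ comparison and outcome categories.

Each screened gene is assayed in three arms — hairpin with no driver
(control), nanos-driven knockdown (expressed from premeiotic S phase
onward) and matα-driven knockdown (meiotic prophase only) — all in the
sensitized *mtrm*:sup:`KG`/+ background.  Per-gene decision logic:

1. a knockdown arm with fewer viable progeny than the sterility threshold
   cannot be called prophase-specific → ``sterile_excluded``;
2. significant NDJ increase with matα but not nanos → ``prophase_specific``
   (the cohesion-rejuvenation signature);
3. significant with both drivers → compare drivers: significantly higher
   with nanos → ``both_sig_nanos_higher`` (S-phase establishment plus
   prophase signature), else ``both_sig_equal``;
4. significant with nanos only → ``nanos_only``;
5. a significant *decrease* in either arm → ``ndj_decreased``;
6. otherwise ``negative``.

"Significant increase" means two-sided p < α with the knockdown point
estimate above the control's; decisions use the Monte-Carlo p-value.  No
cross-gene multiple-testing correction is applied (per-gene p < 0.05 is
the screen's decision rule); pass each p-value list through your favourite
correction first if you want one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crosses import NDJCounts
from .experiments import (
    DEFAULT_BASELINE_ARM_LOSS,
    ndj_experiment_config,
    simulate_ndj_counts,
)
from .markers import DEFAULT_MAP, MarkerMap
from .stats import compare_ndj, estimate_ndj

__all__ = [
    "ARMS",
    "CATEGORIES",
    "MECHANISMS",
    "DEFAULT_STERILITY_THRESHOLD",
    "ScreenGeneResult",
    "classify_gene",
    "generate_synthetic_screen",
    "run_screen",
    "expected_category",
]

ARMS = ("control", "nanos", "mata")

CATEGORIES = (
    "prophase_specific",
    "both_sig_nanos_higher",
    "both_sig_equal",
    "nanos_only",
    "sterile_excluded",
    "ndj_decreased",
    "negative",
)

#: Viable progeny below this makes an arm "sterile or nearly sterile".
DEFAULT_STERILITY_THRESHOLD = 50

#: Truth mechanisms for the synthetic screen generator.
MECHANISMS = (
    "null",
    "rejuvenation_only",
    "s_phase_and_prophase",
    "s_phase_only",
    "sterile",
)

_EXPECTED_CATEGORY = {
    "null": "negative",
    "rejuvenation_only": "prophase_specific",
    "s_phase_and_prophase": "both_sig_nanos_higher",
    "s_phase_only": "nanos_only",
    "sterile": "sterile_excluded",
}


def expected_category(mechanism: str) -> str:
    """The category a mechanism implies when effects are strong."""
    return _EXPECTED_CATEGORY[mechanism]


@dataclass(frozen=True)
class ScreenGeneResult:
    """Per-gene screen outcome."""

    gene: str
    counts: Mapping[str, NDJCounts]
    pct_ndj: Mapping[str, float]
    fertile: Mapping[str, bool]
    p_nanos_vs_control: float | None
    p_mata_vs_control: float | None
    p_mata_vs_nanos: float | None
    category: str
    alpha: float = 0.05


def classify_gene(
    gene: str,
    counts: Mapping[str, NDJCounts],
    alpha: float = 0.05,
    sterility_threshold: int = DEFAULT_STERILITY_THRESHOLD,
    n_replicates: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ScreenGeneResult:
    """Assign one gene its screen category from three-arm NDJ counts."""
    missing = [arm for arm in ARMS if arm not in counts]
    if missing:
        raise KeyError(f"gene {gene!r}: missing arm(s) {missing}")
    if rng is None:
        rng = np.random.default_rng(seed)

    control = counts["control"]
    if control.total < 1:
        raise ValueError(f"gene {gene!r}: control arm has no viable progeny")
    if control.total < sterility_threshold:
        raise ValueError(
            f"gene {gene!r}: control arm below sterility threshold "
            f"({control.total} < {sterility_threshold})"
        )

    fertile = {
        arm: counts[arm].total >= sterility_threshold for arm in ("nanos", "mata")
    }
    fertile["control"] = True
    pct = {
        arm: (estimate_ndj(counts[arm]).pct_ndj if counts[arm].total else float("nan"))
        for arm in ARMS
    }

    p_vals: dict[str, float | None] = {"nanos": None, "mata": None, "mvn": None}
    sig_up: dict[str, bool] = {}
    sig_down: dict[str, bool] = {}
    for arm in ("nanos", "mata"):
        if fertile[arm]:
            res = compare_ndj(counts[arm], control, n_replicates, rng=rng)
            p_vals[arm] = res.p_monte_carlo
            sig_up[arm] = res.p_monte_carlo < alpha and pct[arm] > pct["control"]
            sig_down[arm] = res.p_monte_carlo < alpha and pct[arm] < pct["control"]
        else:
            sig_up[arm] = sig_down[arm] = False

    if not (fertile["nanos"] and fertile["mata"]):
        category = "sterile_excluded"
    elif sig_up["mata"] and not sig_up["nanos"]:
        category = "prophase_specific"
    elif sig_up["mata"] and sig_up["nanos"]:
        res = compare_ndj(counts["mata"], counts["nanos"], n_replicates, rng=rng)
        p_vals["mvn"] = res.p_monte_carlo
        if res.p_monte_carlo < alpha and pct["nanos"] > pct["mata"]:
            category = "both_sig_nanos_higher"
        else:
            category = "both_sig_equal"
    elif sig_up["nanos"]:
        category = "nanos_only"
    elif sig_down["mata"] or sig_down["nanos"]:
        category = "ndj_decreased"
    else:
        category = "negative"

    return ScreenGeneResult(
        gene=gene,
        counts=dict(counts),
        pct_ndj=pct,
        fertile=fertile,
        p_nanos_vs_control=p_vals["nanos"],
        p_mata_vs_control=p_vals["mata"],
        p_mata_vs_nanos=p_vals["mvn"],
        category=category,
        alpha=alpha,
    )


# -- synthetic screen generator -----------------------------------------


@dataclass(frozen=True)
class EffectSizes:
    """Arm-cohesion-loss probabilities the truth mechanisms map to."""

    baseline: float = DEFAULT_BASELINE_ARM_LOSS
    strong: float = 0.5
    sp_mata: float = 0.4  # s_phase_and_prophase, prophase-restricted driver
    sp_nanos: float = 0.7  # s_phase_and_prophase, S-phase driver hits harder
    sterile_progeny: int = 12  # viable flies a "sterile or nearly" arm yields


def _arm_params(mechanism: str, fx: EffectSizes) -> dict[str, tuple[float, int | None]]:
    """(p_arm_loss, progeny override) per arm for one truth mechanism."""
    b = fx.baseline
    if mechanism == "null":
        return {"control": (b, None), "nanos": (b, None), "mata": (b, None)}
    if mechanism == "rejuvenation_only":
        return {"control": (b, None), "nanos": (b, None), "mata": (fx.strong, None)}
    if mechanism == "s_phase_and_prophase":
        return {
            "control": (b, None),
            "nanos": (fx.sp_nanos, None),
            "mata": (fx.sp_mata, None),
        }
    if mechanism == "s_phase_only":
        return {"control": (b, None), "nanos": (fx.strong, None), "mata": (b, None)}
    if mechanism == "sterile":
        return {
            "control": (b, None),
            "nanos": (b, fx.sterile_progeny),
            "mata": (fx.strong, None),
        }
    raise ValueError(f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}")


def generate_synthetic_screen(
    truth_mix: Mapping[str, str] | Sequence[str],
    n_progeny_per_arm: int = 1000,
    seed: int = 0,
    marker_map: MarkerMap = DEFAULT_MAP,
    effects: EffectSizes = EffectSizes(),
    p_mii_loss: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full three-arm screen with known per-gene truth.

    ``truth_mix`` maps gene label -> mechanism (or is a sequence of
    mechanisms, auto-labelled g01, g02, ...).  Every arm is simulated
    through the meiosis sampler and NDJ cross in the backup-disabled
    sensitized background; drivers enter only through which arm's
    arm-cohesion-loss parameter is perturbed.

    Returns the screen manifest (one row per gene x arm) and the truth
    table with each gene's mechanism and implied category.
    """
    if not isinstance(truth_mix, Mapping):
        truth_mix = {f"g{i + 1:02d}": m for i, m in enumerate(truth_mix)}
    bad = [m for m in truth_mix.values() if m not in MECHANISMS]
    if bad:
        raise ValueError(f"unknown mechanism(s) {sorted(set(bad))}; expected {MECHANISMS}")
    if rng is None:
        rng = np.random.default_rng(seed)

    rows = []
    truth_rows = []
    for gene, mechanism in truth_mix.items():
        params = _arm_params(mechanism, effects)
        for arm in ARMS:
            p_arm_loss, n_override = params[arm]
            n_target = n_override if n_override is not None else n_progeny_per_arm
            cfg = ndj_experiment_config(
                p_arm_loss=p_arm_loss, p_mii_loss=p_mii_loss, marker_map=marker_map
            )
            c = simulate_ndj_counts(cfg, n_target, rng)
            rows.append(
                {
                    "gene": gene,
                    "arm": arm,
                    "n_normal": c.n_normal,
                    "e_diploX": c.e_diploX,
                    "e_XY": c.e_XY,
                }
            )
        truth_rows.append(
            {
                "gene": gene,
                "mechanism": mechanism,
                "expected_category": expected_category(mechanism),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def run_screen(
    manifest: pd.DataFrame,
    alpha: float = 0.05,
    n_replicates: int = 10_000,
    seed: int = 0,
    sterility_threshold: int = DEFAULT_STERILITY_THRESHOLD,
) -> pd.DataFrame:
    """Classify every gene of a screen manifest; deterministic given ``seed``.

    The manifest needs columns gene, arm, n_normal, e_diploX, e_XY with one
    row per gene x arm.  Monte-Carlo p-value streams are spawned per gene
    from the master seed, so per-gene results do not depend on manifest
    order beyond the gene list itself.
    """
    required = {"gene", "arm", "n_normal", "e_diploX", "e_XY"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing column(s) {sorted(missing)}")
    dup = manifest.duplicated(subset=["gene", "arm"])
    if dup.any():
        pairs = manifest.loc[dup, ["gene", "arm"]].itertuples(index=False)
        raise ValueError(f"duplicate gene/arm rows: {[tuple(p) for p in pairs]}")

    genes = list(dict.fromkeys(manifest["gene"]))
    streams = np.random.SeedSequence(seed).spawn(len(genes))
    out = []
    for gene, ss in zip(genes, streams):
        sub = manifest[manifest["gene"] == gene]
        counts = {
            row.arm: NDJCounts(int(row.n_normal), int(row.e_diploX), int(row.e_XY))
            for row in sub.itertuples(index=False)
        }
        res = classify_gene(
            gene,
            counts,
            alpha=alpha,
            sterility_threshold=sterility_threshold,
            n_replicates=n_replicates,
            rng=np.random.default_rng(ss),
        )
        row = {"gene": gene, "category": res.category}
        for arm in ARMS:
            row[f"n_{arm}"] = counts[arm].total
            row[f"pct_ndj_{arm}"] = res.pct_ndj[arm]
            row[f"fertile_{arm}"] = res.fertile[arm]
        row["p_nanos_vs_control"] = res.p_nanos_vs_control
        row["p_mata_vs_control"] = res.p_mata_vs_control
        row["p_mata_vs_nanos"] = res.p_mata_vs_nanos
        out.append(row)
    return pd.DataFrame(out)
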