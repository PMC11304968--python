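"""Nondisjunction statistics: the doubled-E %NDJ estimator and its tests.

Only half of the exceptional zygote classes survive (metafemales and
nullo-X zygotes die), so with N normal and E exceptional viable progeny the
gamete-level NDJ rate is estimated by doubling E::

    %NDJ = 100 * 2E / (N + 2E)

If a fraction ``pi`` of ova are exceptional, viable progeny are exceptional
with probability ``q = (pi/2) / (1 - pi/2)`` and the doubled-E transform
``p = 2q / (1 + q)`` recovers ``pi`` exactly — the estimator is the plug-in
of that algebraic identity.

Two-group comparisons come in two flavours sharing one null (a common
viable-exceptional rate ``q0``): a pooled delta-method z-test on the
doubled-E proportion (fast path) and a conditional parametric bootstrap
that redraws E per group from Binomial(T_i, q0) (reference path).  A
two-sided Fisher's exact test on 2x2 tables (the convention that sums all
hypergeometric outcomes no more probable than the observed table) is
provided for the contingency comparisons used elsewhere in the assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .crosses import NDJCounts

__all__ = [
    "NDJEstimate",
    "ComparisonResult",
    "SterileCrossError",
    "doubled_e_proportion",
    "estimate_ndj",
    "compare_ndj",
    "fisher_exact_2x2",
]


class SterileCrossError(ValueError):
    """A cross with zero viable progeny cannot be estimated (report as sterile)."""


def doubled_e_proportion(q):
    """Map the viable exceptional fraction q to the gamete NDJ proportion 2q/(1+q)."""
    q = np.asarray(q, dtype=float)
    return 2.0 * q / (1.0 + q)


@dataclass(frozen=True)
class NDJEstimate:
    """Doubled-E %NDJ point estimate with confidence bounds (percent scale)."""

    pct_ndj: float
    n_normal: int
    E: int
    ci_low: float
    ci_high: float
    ci_level: float = 0.95


def estimate_ndj(counts: NDJCounts, ci_level: float = 0.95) -> NDJEstimate:
    """%NDJ = 100·2E/(N+2E) with a CI from inverting the binomial CI on q.

    The Clopper–Pearson interval for q = E/(N+E) is pushed through the
    monotone doubled-E transform; a cross with no viable progeny raises
    :class:`SterileCrossError` rather than reporting 0%.
    """
    N, E = counts.n_normal, counts.E
    T = N + E
    if T == 0:
        raise SterileCrossError(
            "no viable progeny: sterile cross, %NDJ undefined"
        )
    alpha = 1.0 - ci_level
    q_lo = 0.0 if E == 0 else float(sps.beta.ppf(alpha / 2, E, N + 1))
    q_hi = 1.0 if N == 0 else float(sps.beta.ppf(1 - alpha / 2, E + 1, N))
    return NDJEstimate(
        pct_ndj=100.0 * float(doubled_e_proportion(E / T)),
        n_normal=N,
        E=E,
        ci_low=100.0 * float(doubled_e_proportion(q_lo)),
        ci_high=100.0 * float(doubled_e_proportion(q_hi)),
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided p-values for a two-group %NDJ comparison."""

    p_normal_approx: float
    p_monte_carlo: float
    n_replicates: int
    alpha: float = 0.05
    observed_diff: float = 0.0  # |p_hat_a - p_hat_b| on the proportion scale

    @property
    def significant(self) -> bool:
        """Decision at ``alpha`` on the Monte-Carlo (reference) p-value."""
        return self.p_monte_carlo < self.alpha


def compare_ndj(
    a: NDJCounts,
    b: NDJCounts,
    n_replicates: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided comparison of gamete-level NDJ between two crosses.

    Both p-values condition on the observed viable totals T_a, T_b and use
    the pooled viable-exceptional rate q0 = (E_a+E_b)/(T_a+T_b) as the
    null: the z path applies the delta method to the doubled-E transform
    with the pooled variance, the Monte-Carlo path redraws
    E_i* ~ Binomial(T_i, q0) and counts replicates with
    |p_a* - p_b*| >= observed, with the add-one (r+1)/(B+1) correction.
    """
    Ta, Tb = a.total, b.total
    if Ta == 0 or Tb == 0:
        raise SterileCrossError("both groups need at least one viable progeny")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1 (got {n_replicates})")
    if n_replicates < 1000:
        warnings.warn(
            f"n_replicates={n_replicates} is low; Monte-Carlo p-value will be coarse",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    # the statistic is symmetric in the two groups; canonicalize their
    # order so swapping a and b cannot change the Monte-Carlo draw order
    if (Tb, b.E) > (Ta, a.E):
        a, b = b, a
        Ta, Tb = Tb, Ta

    p_a = float(doubled_e_proportion(a.E / Ta))
    p_b = float(doubled_e_proportion(b.E / Tb))
    observed = abs(p_a - p_b)
    q0 = (a.E + b.E) / (Ta + Tb)

    if q0 <= 0.0 or q0 >= 1.0:
        # no exceptional (or no normal) progeny anywhere: nothing to compare
        return ComparisonResult(1.0, 1.0, n_replicates, alpha, observed)

    # pooled delta-method z on the doubled-E proportion
    deriv = 2.0 / (1.0 + q0) ** 2
    var = deriv**2 * q0 * (1.0 - q0) * (1.0 / Ta + 1.0 / Tb)
    z = (p_a - p_b) / np.sqrt(var)
    p_norm = float(2.0 * sps.norm.sf(abs(z)))

    ea = rng.binomial(Ta, q0, size=n_replicates)
    eb = rng.binomial(Tb, q0, size=n_replicates)
    stat = np.abs(doubled_e_proportion(ea / Ta) - doubled_e_proportion(eb / Tb))
    exceed = int((stat >= observed - 1e-12).sum())
    p_mc = (exceed + 1) / (n_replicates + 1)

    return ComparisonResult(min(p_norm, 1.0), p_mc, n_replicates, alpha, observed)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums the hypergeometric probabilities of every table (at fixed margins)
    whose probability does not exceed the observed one — the convention
    GraphPad and scipy use.  A zero margin makes the table degenerate and
    returns 1.0 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError(f"negative cell in table {t.tolist()}")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        warnings.warn(
            "zero margin in 2x2 table: test degenerate, p = 1", stacklevel=2
        )
        return 1.0
    M = int(t.sum())
    n_draw, k_succ = int(row[0]), int(col[0])
    k_min = max(0, n_draw + k_succ - M)
    k_max = min(n_draw, k_succ)
    support = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(support, M, k_succ, n_draw)
    p_obs = sps.hypergeom.pmf(int(t[0, 0]), M, k_succ, n_draw)
    # relative guard absorbs floating-point ties across the support
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)
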