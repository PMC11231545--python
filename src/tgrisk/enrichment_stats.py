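"""2x2 enrichment statistics for genetic risk-factor carriage across TG categories.

Implements the comparison machinery used throughout the pipeline: odds ratios
with Woolf (log-normal) 95% confidence intervals, a cell-count-driven choice
between the chi-square test (all cells >= 5, no continuity correction) and the
two-sided Fisher exact test, Spearman rank correlation, and the single-variant
additive linear model (ordinary least squares of natural-log TG on allele
dosage).

Table orientation: rows are case/control groups, columns exposed/unexposed —
``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed controls,
``d`` unexposed controls.  The odds ratio is ``(a*d)/(b*c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "odds_ratio_ci",
    "select_and_run_test",
    "spearman_corr",
    "additive_regression",
    "bonferroni",
]

# two-sided 95% normal quantile used for Woolf intervals
_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one enrichment comparison.

    a: exposed cases, b: unexposed cases, c: exposed controls, d: unexposed
    controls.  Counts must be non-negative integers; ``a + b`` is the case
    group size and ``c + d`` the control group size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """Result of one 2x2 comparison."""

    table: ContingencyTable2x2
    test_used: str  # "chi_square" | "fisher_exact"
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    haldane_corrected: bool = False
    label: str = ""


def odds_ratio_ci(table: ContingencyTable2x2) -> tuple[float, tuple[float, float], bool]:
    """Odds ratio with Woolf 95% CI.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Tables containing a zero cell receive the Haldane–Anscombe correction
    (+0.5 to every cell) before computing both the OR and the interval; the
    returned flag marks corrected results.
    """
    a, b, c, d = (float(x) for x in table.cells)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci = (math.exp(log_or - _Z95 * se), math.exp(log_or + _Z95 * se))
    return or_, ci, corrected


def select_and_run_test(table: ContingencyTable2x2, label: str = "") -> EnrichmentResult:
    """Run the cell-count-driven test on a 2x2 table.

    Chi-square (1 df, no continuity correction) when every observed cell is
    >= 5, otherwise the two-sided Fisher exact test (point-probability
    summation convention).  Degenerate margins (an empty case or control
    group) are an error.
    """
    a, b, c, d = table.cells
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("degenerate table: empty case or control group")
    obs = np.array([[a, b], [c, d]], dtype=float)
    if min(a, b, c, d) >= 5:
        test = "chi_square"
        _, p, _, _ = stats.chi2_contingency(obs, correction=False)
    else:
        test = "fisher_exact"
        _, p = stats.fisher_exact(obs, alternative="two-sided")
    or_, ci, corrected = odds_ratio_ci(table)
    return EnrichmentResult(
        table=table,
        test_used=test,
        odds_ratio=or_,
        ci95=ci,
        p_value=float(p),
        haldane_corrected=corrected,
        label=label,
    )


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Align two participant->value maps (or equal-length sequences) on complete pairs."""
    if isinstance(x, Mapping) and isinstance(y, Mapping):
        keys = sorted(set(x) & set(y))
        xa = np.array([x[k] for k in keys], dtype=float)
        ya = np.array([y[k] for k in keys], dtype=float)
    else:
        xa = np.asarray(list(x), dtype=float)
        ya = np.asarray(list(y), dtype=float)
        if xa.shape != ya.shape:
            raise ValueError("x and y must have the same length")
    ok = np.isfinite(xa) & np.isfinite(ya)
    return xa[ok], ya[ok]


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Accepts two participant->value mappings (aligned on shared ids) or two
    equal-length sequences.  Requires >= 3 complete pairs and non-constant
    inputs; p-value from the large-sample t approximation.
    """
    xa, ya = _paired(x, y)
    if xa.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


def additive_regression(tg, dosage) -> tuple[float, float, float]:
    """Additive-model single-variant association: OLS of ln(TG) on allele dosage.

    ``tg`` maps participant -> TG in mg/dl (> 0); ``dosage`` maps participant
    -> allele dosage in {0, 1, 2} (negative or non-finite dosages are treated
    as missing and dropped).  Returns (slope, standard error, Wald p).
    """
    ta, da = _paired(tg, dosage)
    ok = (da >= 0) & (ta > 0)
    ta, da = ta[ok], da[ok]
    if ta.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(da == da[0]):
        raise ValueError("dosage is constant; slope undefined")
    res = stats.linregress(da, np.log(ta))
    return float(res.slope), float(res.stderr), float(res.pvalue)


def bonferroni(p_values: Iterable[float]) -> list[float]:
    """Bonferroni-adjusted p-values (helper; no correction is applied by default
    anywhere in the pipeline — each comparison is reported marginally)."""
    ps: Sequence[float] = list(p_values)
    m = len(ps)
    return [min(1.0, p * m) for p in ps]
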