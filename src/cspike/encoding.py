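"""Per-cell encoding tests and the population encoding matrix.

For each cell and each task parameter (trial onset timing, primary saccade
amplitude/direction, corrective saccade amplitude/direction, error
magnitude/direction), events are split at the parameter's median into two
groups and the per-event CS rates in the parameter's window of interest are
compared with a one-tailed Wilcoxon signed-rank test (alternative: the
upper-median / preferred group fires more).  Cells firing fewer than 10 CSs
in the window of interest are not compared.  Significant flags (p < 0.05)
populate a cells-by-parameters binary matrix whose columns are then
pairwise Pearson cross-correlated over co-compared cells.

Pairing convention: the two groups are truncated to equal size and paired by
sorted within-group order.  This is a declared convention of this package;
the underlying test only asserts a paired comparison of the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EncodingTestResult", "EncodingMatrix", "median_split_test",
           "direction_test", "build_matrix", "cross_correlate", "PARAMETERS"]

MIN_CS = 10
ALPHA = 0.05

PARAMETERS = ("trial_onset", "ps_amplitude", "ps_direction",
              "corr_amplitude", "corr_direction", "error_magnitude",
              "error_direction")


@dataclass
class EncodingTestResult:
    cell_id: int
    parameter: str
    window_label: str
    p_value: float
    flag: str  # significant | nonsignificant | not_compared
    reason: str = ""


def _paired_signed_rank(upper: np.ndarray, lower: np.ndarray) -> float:
    """One-tailed signed-rank p (alternative: ``upper`` fires more).

    The two groups are truncated to equal size and paired in event order
    (the order in which events occurred within each group); pairing by rate
    value would correlate the paired differences and destroy the test's
    level.
    """
    n = min(upper.size, lower.size)
    u = np.asarray(upper, dtype=float)[:n]
    l = np.asarray(lower, dtype=float)[:n]
    d = u - l
    if np.all(d == 0):
        return 1.0
    # Pratt zero handling + continuity correction: with heavily tied
    # count-derived rates, discarding zero differences is anticonservative
    res = stats.wilcoxon(u, l, alternative="greater", zero_method="pratt",
                         correction=True)
    return float(res.pvalue)


def median_split_test(values: np.ndarray, rates: np.ndarray,
                      counts: np.ndarray, cell_id: int, parameter: str,
                      window_label: str = "") -> EncodingTestResult:
    """Median-split one-tailed signed-rank test of parameter encoding.

    ``values`` are per-event parameter values, ``rates`` the per-event CS
    rates in the window of interest, and ``counts`` the per-event CS counts
    used for the 10-CS inclusion rule.  Events at the median join the lower
    group.  The alternative hypothesis is that the upper-median group fires
    more.
    """
    values = np.asarray(values, dtype=float)
    rates = np.asarray(rates, dtype=float)
    total_cs = int(np.sum(counts))
    if total_cs < MIN_CS:
        return EncodingTestResult(cell_id, parameter, window_label,
                                  float("nan"), "not_compared",
                                  reason=f"{total_cs} CSs < {MIN_CS}")
    med = np.median(values)
    lower = rates[values <= med]
    upper = rates[values > med]
    if lower.size == 0 or upper.size == 0:
        return EncodingTestResult(cell_id, parameter, window_label,
                                  float("nan"), "not_compared",
                                  reason="degenerate median split")
    p = _paired_signed_rank(upper, lower)
    flag = "significant" if p < ALPHA else "nonsignificant"
    return EncodingTestResult(cell_id, parameter, window_label, p, flag)


def direction_test(rates_pd: np.ndarray, rates_anti: np.ndarray,
                   counts_total: int, cell_id: int, parameter: str,
                   window_label: str = "") -> EncodingTestResult:
    """One-tailed signed-rank test comparing the two opposite directions.

    The alternative is that the preferred-direction group fires more (the
    preferred direction having been chosen from the same data — a circularity
    the matrix column inherits).  Either direction absent, or fewer than 10
    CSs in the window, means no comparison.
    """
    if counts_total < MIN_CS:
        return EncodingTestResult(cell_id, parameter, window_label,
                                  float("nan"), "not_compared",
                                  reason=f"{counts_total} CSs < {MIN_CS}")
    rates_pd = np.asarray(rates_pd, dtype=float)
    rates_anti = np.asarray(rates_anti, dtype=float)
    if rates_pd.size == 0 or rates_anti.size == 0:
        return EncodingTestResult(cell_id, parameter, window_label,
                                  float("nan"), "not_compared",
                                  reason="one direction absent")
    p = _paired_signed_rank(rates_pd, rates_anti)
    flag = "significant" if p < ALPHA else "nonsignificant"
    return EncodingTestResult(cell_id, parameter, window_label, p, flag)


@dataclass
class EncodingMatrix:
    binary: pd.DataFrame       # 1/0; NaN where not compared
    p_values: pd.DataFrame
    flags: pd.DataFrame

    @property
    def parameters(self):
        return list(self.binary.columns)


def build_matrix(results: list[EncodingTestResult]) -> EncodingMatrix:
    """Assemble per-cell test results into the cells x parameters matrices."""
    seen = set()
    for r in results:
        key = (r.cell_id, r.parameter)
        if key in seen:
            raise ValueError(f"duplicate result for cell {r.cell_id}, "
                             f"parameter {r.parameter!r}")
        seen.add(key)
    cells = sorted({r.cell_id for r in results})
    params = [p for p in PARAMETERS if any(r.parameter == p for r in results)]
    params += sorted({r.parameter for r in results} - set(params))
    binary = pd.DataFrame(np.nan, index=cells, columns=params)
    pvals = pd.DataFrame(np.nan, index=cells, columns=params)
    flags = pd.DataFrame("", index=cells, columns=params)
    for r in results:
        flags.loc[r.cell_id, r.parameter] = r.flag
        pvals.loc[r.cell_id, r.parameter] = r.p_value
        if r.flag != "not_compared":
            binary.loc[r.cell_id, r.parameter] = 1.0 if r.flag == "significant" else 0.0
    return EncodingMatrix(binary, pvals, flags)


def cross_correlate(matrix: EncodingMatrix, min_cells: int = 2):
    """Pairwise Pearson correlation between binary parameter columns.

    Each pair is correlated over the cells compared for both parameters;
    zero-variance columns give NaN entries (flagged).  The result is
    symmetric with unit diagonal.
    """
    params = matrix.parameters
    n = len(params)
    corr = pd.DataFrame(np.eye(n), index=params, columns=params)
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            a = matrix.binary[params[i]]
            b = matrix.binary[params[j]]
            m = a.notna() & b.notna()
            if m.sum() < min_cells:
                corr.iloc[i, j] = corr.iloc[j, i] = np.nan
                flagged.append((params[i], params[j], "too few co-compared"))
                continue
            x, y = a[m].to_numpy(), b[m].to_numpy()
            if x.std() == 0 or y.std() == 0:
                corr.iloc[i, j] = corr.iloc[j, i] = np.nan
                flagged.append((params[i], params[j], "zero variance"))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            corr.iloc[i, j] = corr.iloc[j, i] = r
    return corr, flagged
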