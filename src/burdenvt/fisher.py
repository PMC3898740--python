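"""Exact Fisher test for 2x2 tables via hypergeometric enumeration.

The null fixes both margins, so the upper-left cell ``a`` follows a
hypergeometric law.  Two-sidedness uses the minimum-likelihood convention
(the convention of R's ``fisher.test`` and mainstream genetics software):
the p-value sums the point probabilities of every table whose probability is
at most that of the observed table, with a small relative tolerance on the
comparison so that exact ties are not lost to floating-point rounding.

Point masses are accumulated on the log scale (via the log-gamma based
hypergeometric log-pmf), which stays accurate for sample sizes in the
thousands where direct factorial products would overflow.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import hypergeom

#: Relative tolerance on the "probability <= observed probability" comparison.
TIE_RTOL = 1e-7


def _support_logpmf(total_carrier: int, case_units: int, ctrl_units: int):
    """Support of the a-cell and its hypergeometric log-pmf under fixed margins."""
    n_total = case_units + ctrl_units
    a_min = max(0, total_carrier - ctrl_units)
    a_max = min(total_carrier, case_units)
    a_vals = np.arange(a_min, a_max + 1)
    logpmf = hypergeom.logpmf(a_vals, n_total, total_carrier, case_units)
    return a_vals, logpmf


def fisher_p_all(case_units: int, ctrl_units: int, total_carrier: int) -> np.ndarray:
    """Two-sided p-value for every admissible a-cell at once.

    Returns an array aligned with the support
    ``a = max(0, K - ctrl_units) .. min(K, case_units)`` where K is the
    carrier-unit margin.  Computing the whole support in one pass is what
    makes permutation scans cheap: under label permutation the margins are
    fixed, so the permuted p-value is a lookup into this array.
    """
    if case_units < 0 or ctrl_units < 0 or total_carrier < 0:
        raise ValueError("margins must be non-negative")
    if total_carrier > case_units + ctrl_units:
        raise ValueError("carrier margin exceeds table total")
    if case_units + ctrl_units == 0:
        raise ValueError("empty table")
    a_vals, logpmf = _support_logpmf(total_carrier, case_units, ctrl_units)
    order = np.argsort(logpmf, kind="stable")
    sorted_log = logpmf[order]
    cum = np.cumsum(np.exp(sorted_log))  # ascending accumulation for accuracy
    # index of the last table whose log-pmf <= observed log-pmf (+ tie slack)
    cut = np.searchsorted(sorted_log, logpmf + math.log1p(TIE_RTOL), side="right")
    p = cum[cut - 1]
    return np.minimum(p, 1.0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for the table [[a, b], [c, d]].

    Rows are case/control, columns carrier/non-carrier units.  Returns a
    value in (0, 1]; a table with an empty carrier margin has p = 1 (the
    observed table is the only one consistent with the margins).
    """
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError(f"negative cell in 2x2 table: {(a, b, c, d)}")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    case_units, ctrl_units, k = a + b, c + d, a + c
    p_all = fisher_p_all(case_units, ctrl_units, k)
    a_min = max(0, k - ctrl_units)
    return float(p_all[a - a_min])


def fisher_exact_one_sided(a: int, b: int, c: int, d: int, enrichment: bool = True) -> float:
    """One-sided exact p: enrichment (a at least as large) or depletion."""
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError(f"negative cell in 2x2 table: {(a, b, c, d)}")
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("all-zero 2x2 table")
    k, case_units = a + c, a + b
    if enrichment:
        p = hypergeom.sf(a - 1, n_total, k, case_units)
    else:
        p = hypergeom.cdf(a, n_total, k, case_units)
    return float(min(p, 1.0))
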