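"""Cohort-comparison statistics: exact Fisher / Freeman-Halton tests for
categorical covariates and Mann-Whitney U for continuous ones.

The two-sided Fisher convention is the probability-mass rule: the p-value
sums the probabilities of all fixed-margin tables whose probability does not
exceed the observed table's (other conventions can shift the second decimal).
2x2 tables delegate to :func:`scipy.stats.fisher_exact`, which implements the
same rule; r x c tables use full Freeman-Halton enumeration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

#: tables whose fixed-margin enumeration would exceed this many cells are refused
_MAX_ENUMERATION = 5_000_000

# relative tolerance when comparing table probabilities (floating-point ties)
_PROB_TOL = 1e-10


def _log_table_prob(table: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray,
                    total: int) -> float:
    """log P(table | margins) under the fixed-margin hypergeometric model."""
    return (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums: np.ndarray, col_sums: np.ndarray):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=int)

    def fill_row(i: int, remaining_cols: np.ndarray):
        if i == r - 1:
            table[i] = remaining_cols
            yield table
            return
        target = row_sums[i]

        def fill_cell(j: int, left: int, cols: np.ndarray):
            if j == c - 1:
                if left <= cols[j]:
                    table[i, j] = left
                    new_cols = cols.copy()
                    new_cols[j] -= left
                    yield from fill_row(i + 1, new_cols)
                return
            for v in range(min(left, cols[j]) + 1):
                table[i, j] = v
                new_cols = cols.copy()
                new_cols[j] -= v
                yield from fill_cell(j + 1, left - v, new_cols)

        yield from fill_cell(0, target, remaining_cols)

    yield from fill_row(0, col_sums.copy())


def freeman_halton(table) -> float:
    """Exact two-sided Fisher p for an r x c contingency table.

    Full enumeration over all tables with the observed margins, summing the
    probabilities of tables at most as probable as the observed one.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("contingency table must be a 2-D nonnegative integer array")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    total = int(obs.sum())
    if total == 0:
        raise ValueError("contingency table is empty")
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("contingency table has an empty row or column")
    approx_size = np.prod([min(int(r), int(c)) + 1.0 for r in row_sums[:-1] for c in col_sums[:-1]])
    if approx_size > _MAX_ENUMERATION:
        raise ValueError(
            f"margin enumeration too large (~{approx_size:.2g} tables); "
            "use a Monte-Carlo or chi-square approximation instead"
        )
    log_p_obs = _log_table_prob(obs, row_sums, col_sums, total)
    cutoff = log_p_obs + _PROB_TOL
    p = 0.0
    for cand in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(cand, row_sums, col_sums, total)
        if lp <= cutoff:
            p += float(np.exp(lp))
    return min(1.0, p)


def fisher_exact_nd(table) -> float:
    """Two-sided exact Fisher p: scipy for 2x2, Freeman-Halton otherwise."""
    obs = np.asarray(table, dtype=int)
    if obs.shape == (2, 2):
        return float(stats.fisher_exact(obs, alternative="two-sided")[1])
    return freeman_halton(obs)


def mann_whitney_u(x, y, *, exact_max_n: int = 12) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when both groups have at most ``exact_max_n``
    observations and there are no ties; tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (max(x.size, y.size) <= exact_max_n and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method)[1])


def cohort_comparison(metadata: pd.DataFrame, *, group_by: str = "diagnosis",
                      categorical: tuple = ("gender", "country"),
                      continuous: tuple = ("age", "bmi")) -> pd.DataFrame:
    """Per-covariate group comparison table (counts / mean +- sd, p-values).

    Categorical covariates get the exact Fisher (Freeman-Halton for r x c)
    test; continuous ones the two-sided Mann-Whitney U test. A covariate that
    is constant across all samples is reported as not testable rather than
    crashing.
    """
    groups = [g for g, _ in metadata.groupby(group_by, sort=True)]
    if len(groups) != 2:
        raise ValueError(f"{group_by} must have exactly two groups, got {groups}")
    g0, g1 = groups
    sub0 = metadata[metadata[group_by] == g0]
    sub1 = metadata[metadata[group_by] == g1]
    rows = []
    for cov in categorical:
        tab = pd.crosstab(metadata[group_by], metadata[cov])
        levels = list(tab.columns)
        if len(levels) < 2:
            p, note = np.nan, "not testable (constant covariate)"
        else:
            p, note = fisher_exact_nd(tab.to_numpy()), ""
        summ0 = "/".join(f"{int(tab.loc[g0, lv])}{lv}" for lv in levels)
        summ1 = "/".join(f"{int(tab.loc[g1, lv])}{lv}" for lv in levels)
        rows.append({"covariate": cov, "test": "fisher_exact", g0: summ0, g1: summ1,
                     "p_value": p, "note": note})
    for cov in continuous:
        x0 = sub0[cov].dropna().to_numpy(dtype=float)
        x1 = sub1[cov].dropna().to_numpy(dtype=float)
        if np.unique(np.concatenate([x0, x1])).size < 2:
            p, note = np.nan, "not testable (constant covariate)"
        else:
            p, note = mann_whitney_u(x0, x1), ""
        rows.append({
            "covariate": cov, "test": "mann_whitney_u",
            g0: f"{x0.mean():.2f} ± {x0.std(ddof=1):.2f}",
            g1: f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
            "p_value": p, "note": note,
        })
    return pd.DataFrame(rows).set_index("covariate")
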