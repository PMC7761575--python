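"""Population-level statistics on protein isoforms.

Contingency tables of isoform co-occurrence across genes (counted over
plants), Fisher's exact test (two-sided, point-probability rule: the
p-value sums the probabilities of all tables with the observed margins
whose probability does not exceed the observed table's), marginal isoform
frequencies, and one-way ANOVA of plant height by isoform computed from
classical sums of squares.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import f as f_dist

from .io_formats import ValidationError

_TIE_TOL = 1e-7  # relative tolerance for probability ties


@dataclass
class ContingencyTable:
    """Joint isoform counts of two genes; ``full`` is kept for reporting,
    ``restricted`` (if any) is the table the exact test runs on."""

    gene_x: str
    gene_y: str
    full: pd.DataFrame
    restricted: pd.DataFrame | None = None

    @property
    def counts(self) -> np.ndarray:
        table = self.restricted if self.restricted is not None else self.full
        return table.to_numpy(dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.full.to_numpy().sum())


@dataclass(frozen=True)
class ExactTestResult:
    p_two_sided: float
    observed_probability: float
    n_tables: int


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)


def build_contingency(
    genotypes: pd.DataFrame,
    gene_x: str,
    gene_y: str,
    restrict_x: list[str] | None = None,
    restrict_y: list[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate plants by the isoforms of two genes.

    ``genotypes`` has one row per (plant, gene) with an ``isoform`` column.
    Restrictions drop the excluded isoform rows/columns (and the plants in
    them) from the tested table while the full table is kept for reporting.
    """
    for g in (gene_x, gene_y):
        if g not in set(genotypes["gene"]):
            raise ValidationError(f"unknown gene id {g!r}")
    x = genotypes[genotypes["gene"] == gene_x].set_index("plant")["isoform"]
    y = genotypes[genotypes["gene"] == gene_y].set_index("plant")["isoform"]
    joined = pd.DataFrame({"x": x, "y": y}).dropna()
    full = pd.crosstab(joined["x"], joined["y"]).sort_index(axis=0).sort_index(axis=1)
    full.index.name = gene_x
    full.columns.name = gene_y
    restricted = None
    if restrict_x or restrict_y:
        restricted = full.copy()
        if restrict_x:
            restricted = restricted.loc[[i for i in restricted.index if i in restrict_x]]
        if restrict_y:
            restricted = restricted[[c for c in restricted.columns if c in restrict_y]]
    return ContingencyTable(gene_x=gene_x, gene_y=gene_y, full=full, restricted=restricted)


# ---------------------------------------------------------------------------
# Fisher exact tests


def _as_int_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        arr = table.counts
    elif isinstance(table, pd.DataFrame):
        arr = table.to_numpy()
    else:
        arr = np.asarray(table)
    out = np.asarray(arr, dtype=np.int64)
    if (out < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    return out


def fisher_exact_2x2(table) -> ExactTestResult:
    """Two-sided Fisher exact test of a 2x2 table.

    With fixed margins the table is determined by its [0,0] cell; the
    p-value sums hypergeometric point probabilities (computed in log space)
    over all admissible cells whose probability is at most the observed
    one (within a small relative tolerance for ties).
    """
    t = _as_int_table(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {t.shape}")
    if t.sum() == 0:
        raise ValidationError("all-zero table")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    n = t.sum()
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - (c1 - ks) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    obs = float(logp[int(t[0, 0]) - lo])
    keep = logp <= obs + math.log1p(_TIE_TOL)
    p = float(np.exp(logp[keep]).sum())
    return ExactTestResult(
        p_two_sided=min(p, 1.0),
        observed_probability=float(np.exp(obs)),
        n_tables=int(len(ks)),
    )


def _log_table_prob(t: np.ndarray, row_l: np.ndarray, col_l: np.ndarray, log_n: float) -> float:
    return float(row_l.sum() + col_l.sum() - log_n - gammaln(t + 1).sum())


def fisher_exact_rxc(table, max_total: int = 200) -> ExactTestResult:
    """Two-sided Fisher exact test of an r x c table by complete enumeration
    of all tables with the observed margins (feasible for small totals)."""
    t = _as_int_table(table)
    if t.ndim != 2:
        raise ValidationError("expected a 2-dimensional table")
    n = int(t.sum())
    if n == 0:
        raise ValidationError("all-zero table")
    if n > max_total:
        raise ValidationError(
            f"total {n} too large for complete enumeration; restrict to a 2x2 table"
        )
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    r, c = t.shape
    row_l = gammaln(rows + 1)
    col_l = gammaln(cols + 1)
    log_n = float(gammaln(n + 1))
    obs = _log_table_prob(t, row_l, col_l, log_n)
    cutoff = obs + math.log1p(_TIE_TOL)

    p_sum = 0.0
    n_tables = 0

    cells = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, j: int, row_rem: np.ndarray, col_rem: np.ndarray):
        nonlocal p_sum, n_tables
        if i == r - 1:
            # last row forced by the column remainders
            if (col_rem < 0).any():
                return
            cells[i, :] = col_rem
            lp = _log_table_prob(cells, row_l, col_l, log_n)
            n_tables += 1
            if lp <= cutoff:
                p_sum += math.exp(lp)
            return
        if j == c - 1:
            v = row_rem[i]
            if v > col_rem[j]:
                return
            cells[i, j] = v
            col_rem2 = col_rem.copy()
            col_rem2[j] -= v
            row_rem2 = row_rem.copy()
            row_rem2[i] = 0
            fill(i + 1, 0, row_rem2, col_rem2)
            return
        later_cols = col_rem[j + 1 :].sum()
        lo = max(0, row_rem[i] - later_cols)
        hi = min(row_rem[i], col_rem[j])
        for v in range(lo, hi + 1):
            cells[i, j] = v
            col_rem2 = col_rem.copy()
            col_rem2[j] -= v
            row_rem2 = row_rem.copy()
            row_rem2[i] -= v
            fill(i, j + 1, row_rem2, col_rem2)

    fill(0, 0, rows.copy(), cols.copy())
    return ExactTestResult(
        p_two_sided=min(p_sum, 1.0),
        observed_probability=math.exp(obs),
        n_tables=n_tables,
    )


# ---------------------------------------------------------------------------
# Marginals and ANOVA


def isoform_marginals(table) -> dict[str, pd.Series]:
    """Row/column marginal frequencies of a contingency table.

    Returns exact fractions plus copies rounded half-up to 2 decimals for
    table-shaped reports.
    """
    if isinstance(table, ContingencyTable):
        df = table.full
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(np.asarray(table))
    total = df.to_numpy().sum()
    if total == 0:
        raise ValidationError("empty contingency table")
    row = df.sum(axis=1) / total
    col = df.sum(axis=0) / total

    def r2(s: pd.Series) -> pd.Series:
        return np.floor(s * 100 + 0.5) / 100

    return {"row": row, "col": col, "row_rounded": r2(row), "col_rounded": r2(col)}


def anova_one_way(groups: dict[str, "np.ndarray | list[float]"]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from sums of squares.

    Empty groups are dropped; fewer than two usable groups is an error.
    F = MS_between / MS_within with p from the F distribution.
    """
    cleaned = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) > 0}
    if len(cleaned) < 2:
        raise ValidationError("one-way ANOVA needs at least two non-empty groups")
    values = np.concatenate(list(cleaned.values()))
    n = len(values)
    k = len(cleaned)
    if n - k < 1:
        raise ValidationError("not enough observations beyond the group count")
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in cleaned.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in cleaned.values())
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f_stat = 0.0 if ms_b == 0 else math.inf
    else:
        f_stat = ms_b / ms_w
    p = float(f_dist.sf(f_stat, df_b, df_w)) if math.isfinite(f_stat) else 0.0
    if f_stat == 0.0:
        p = 1.0
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means={kk: float(v.mean()) for kk, v in cleaned.items()},
    )


def round_p(p: float, digits: int = 4) -> float:
    """Report-style half-up rounding of p-values (raw values kept upstream)."""
    factor = 10**digits
    return math.floor(p * factor + 0.5) / factor
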