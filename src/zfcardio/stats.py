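"""Knockdown dose-response statistics for morpholino-injected cohorts.

The lissamine fluorescence intensity (FI) of a co-injected labelled control
morpholino proxies the morpholino dose each embryo received.  This module
implements the cohort-level analyses built on that readout: FI binning,
expression normalisation against low-FI controls, Spearman rank correlation
of FI vs expression, Bonferroni-adjusted pairwise comparisons of group
means, the two-sided Student's t test, and the 2x2 chi-square test used for
the mRNA-rescue contingency table.

The test statistics are computed from their closed forms here (with an
exact permutation p-value for small-sample Spearman); standard library
implementations serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, ConfigError

__all__ = [
    "GroupComparison",
    "bin_by_fi",
    "normalize_expression",
    "spearman_corr",
    "bonferroni_pairwise",
    "t_test_two_sided",
    "chi_square_2x2",
]

#: maximum sample size for which the Spearman p-value is exact (permutation)
EXACT_SPEARMAN_N = 9


@dataclass
class GroupComparison:
    """One pairwise group comparison with its multiplicity-adjusted p."""

    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str

    def __post_init__(self) -> None:
        if self.p_adjusted < self.p_raw - 1e-15 or self.p_adjusted > 1.0 + 1e-15:
            raise AnalysisError("adjusted p must satisfy p_raw <= p_adj <= 1")


def bin_by_fi(
    records: pd.DataFrame,
    edges: tuple[float, ...] = (2.0, 4.0, 8.0),
    column: str = "FI",
    bin_column: str = "fi_bin",
) -> pd.DataFrame:
    """Assign each record to a half-open FI bin.

    With the default edges the bins are ``FI < 2``, ``2 <= FI < 4``,
    ``4 <= FI < 8`` and ``FI >= 8`` - lower edges inclusive, last bin
    unbounded.  Returns a copy with an ordered-categorical ``fi_bin``
    column; an empty record set yields empty groups.
    """
    edges = tuple(float(e) for e in edges)
    if list(edges) != sorted(set(edges)):
        raise ConfigError(f"bin edges must be strictly increasing: {edges}")
    labels = (
        [f"{column} < {edges[0]:g}"]
        + [f"{lo:g} <= {column} < {hi:g}" for lo, hi in zip(edges, edges[1:])]
        + [f"{column} >= {edges[-1]:g}"]
    )
    out = records.copy()
    cut = pd.cut(
        out[column],
        bins=[-np.inf, *edges, np.inf],
        right=False,               # [lo, hi): lower edge inclusive
        labels=labels,
    )
    out[bin_column] = cut
    return out


def normalize_expression(
    records: pd.DataFrame,
    control_fi_max: float = 1.0,
    column: str = "expression_ratio",
    fi_column: str = "FI",
    out_column: str = "relative_expression",
) -> pd.DataFrame:
    """Divide expression ratios by the mean ratio of low-FI controls.

    The control subset is ``FI < control_fi_max`` (default < 1); its mean
    ratio maps to exactly 1.  Raises :class:`AnalysisError` if the control
    subset is empty.
    """
    ctrl = records.loc[records[fi_column] < control_fi_max, column]
    ctrl = ctrl.dropna()
    if ctrl.empty:
        raise AnalysisError(
            f"no control records with {fi_column} < {control_fi_max}"
        )
    ref = float(ctrl.mean())
    if ref <= 0:
        raise AnalysisError("control mean expression must be positive")
    out = records.copy()
    out[out_column] = out[column] / ref
    return out


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise AnalysisError("constant input: Spearman correlation undefined")
    return float(rx @ ry) / denom


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    Ties receive average ranks.  For n <= 9 the p-value is exact, from the
    full permutation distribution of one rank vector; for larger n the
    usual t approximation ``t = rho sqrt((n-2)/(1-rho^2))`` on n-2 degrees
    of freedom is used.  A constant vector raises :class:`AnalysisError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise AnalysisError("need paired samples with n >= 3")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = _rank_corr(rx, ry)

    if n <= EXACT_SPEARMAN_N:
        # exact two-sided permutation p: P(|rho_perm| >= |rho_obs|).
        # sum(rxc) = 0, and every permutation of ry has the same mean and
        # sum of squares, so rho_perm = (perm(ry) . rxc) / denom vectorises
        # to one matrix product over all n! permutations.
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        perms = np.array(list(itertools.permutations(ry)))
        rhos = (perms @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return float(rho), float(min(p, 1.0))


def t_test_two_sided(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t test with pooled variance (Welch via flag).

    Degenerate zero-variance input follows the convention p = 1 when the
    group means are equal and p -> 0 (t = +/-inf) when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise AnalysisError("each group needs n >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return (0.0, 1.0) if ma == mb else (
                float(math.copysign(math.inf, ma - mb)), 0.0
            )
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / math.sqrt(se2)
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            return (0.0, 1.0) if ma == mb else (
                float(math.copysign(math.inf, ma - mb)), 0.0
            )
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return float(t), float(p)


def bonferroni_pairwise(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    metric: str | None = None,
    group_column: str = "group",
    alpha: float = 0.05,
    welch: bool = False,
) -> list[GroupComparison]:
    """All pairwise two-sided Student's t tests with Bonferroni adjustment.

    ``groups`` is either a mapping ``name -> sample`` or a tidy DataFrame
    with ``group_column`` and a ``metric`` column.  Adjusted p-values are
    ``min(1, p_raw x n_comparisons)`` where the multiplier counts the pairs
    actually tested.  Pairs containing a group with n < 2 are skipped with
    a warning.
    """
    if isinstance(groups, pd.DataFrame):
        if metric is None:
            raise ConfigError("metric column name required with DataFrame input")
        samples = {
            str(g): grp[metric].dropna().to_numpy(dtype=float)
            for g, grp in groups.groupby(group_column, observed=True)
        }
    else:
        samples = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(samples) < 2:
        raise AnalysisError("need at least two groups")

    pairs = []
    for ga, gb in itertools.combinations(sorted(samples), 2):
        if samples[ga].size < 2 or samples[gb].size < 2:
            warnings.warn(f"skipping pair ({ga}, {gb}): group with n < 2",
                          stacklevel=2)
            continue
        pairs.append((ga, gb))
    if not pairs:
        raise AnalysisError("no testable pairs (all groups have n < 2?)")
    m = len(pairs)
    out = []
    for ga, gb in pairs:
        t, p = t_test_two_sided(samples[ga], samples[gb], welch=welch)
        out.append(
            GroupComparison(
                group_a=ga,
                group_b=gb,
                statistic=t,
                p_raw=p,
                p_adjusted=min(1.0, p * m),
                method=f"{'Welch' if welch else 'Student'} t, Bonferroni x{m}",
            )
        )
    return out


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence for a 2x2 count table.

    ``chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)`` with df = 1 and an upper-tail
    p-value; no continuity correction by default (``yates=True`` applies
    the Yates correction).  Any zero margin raises :class:`AnalysisError`.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise AnalysisError(f"need a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.rint(t)):
        raise AnalysisError("table entries must be nonnegative integers")
    (a, b), (c, d) = t
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise AnalysisError("all table margins must be positive")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num * num / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p
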