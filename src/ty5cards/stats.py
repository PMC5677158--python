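"""Rank-sum comparisons and the Ty5 transposition-efficiency calculator.

The Wilcoxon/Mann-Whitney rank-sum test is used for window comparisons
because calling-cards signal is not credibly normal.  Small pooled samples
are tested exactly by enumerating every labeling; larger samples use the
tie-corrected normal approximation with continuity correction.  P-values
are mapped onto the conventional significance bands
(* 0.01-0.05, ** 0.001-0.01, *** < 0.001, NS otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .meta import WindowSummary

EXACT_POOLED_LIMIT = 16  # full enumeration up to C(16, 8) = 12870 labelings


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided rank-sum test result.

    ``u`` is the smaller of the two one-sided Mann-Whitney U statistics,
    so 0 <= u <= n1*n2/2 always holds.
    """

    u: float
    n1: int
    n2: int
    p: float
    method: str  # EXACT | NORMAL_APPROX
    stars: str  # NS | * | ** | ***


def significance_stars(p: float) -> str:
    """Map a p-value onto the conventional star bands."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    r1 = float(ranks[: x.size].sum())
    n1, n2 = x.size, y.size
    u1 = r1 - n1 * (n1 + 1) / 2
    return u1, n1 * n2 - u1


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """P(min(U1, U2) <= observed) by full enumeration of labelings."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = x.size
    n = pooled.size
    base = n1 * (n1 + 1) / 2
    n1n2 = n1 * (n - n1)
    hits = 0
    total = 0
    for combo in combinations(range(n), n1):
        u1 = ranks[list(combo)].sum() - base
        u2 = n1n2 - u1
        total += 1
        if min(u1, u2) <= u_obs + 1e-9:
            hits += 1
    return hits / total


def _normal_p(ranks: np.ndarray, n1: int, n2: int, u_min: float) -> float:
    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied
        return 1.0
    z = (u_min - n1 * n2 / 2 + 0.5) / math.sqrt(var)
    return float(min(1.0, 2 * norm.cdf(z)))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Exact enumeration of all C(n1+n2, n1) group labelings when the pooled
    sample is small (<= 16); otherwise the normal approximation with
    tie-corrected variance and 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u1, u2 = _u_statistics(x, y)
    u = min(u1, u2)
    if x.size + y.size <= EXACT_POOLED_LIMIT:
        p = _exact_p(x, y, u)
        method = "EXACT"
    else:
        ranks = rankdata(np.concatenate([x, y]))
        p = _normal_p(ranks, x.size, y.size, u)
        method = "NORMAL_APPROX"
    return WilcoxonResult(u=u, n1=x.size, n2=y.size, p=p, method=method, stars=significance_stars(p))


@dataclass(frozen=True)
class WindowComparison:
    """Rank-sum comparison of one timing window between two constructs."""

    t_lo: float
    t_hi: float
    testable: bool
    result: WilcoxonResult | None = None

    @property
    def stars(self) -> str:
        return self.result.stars if self.result else "NA"


def compare_windows(a: WindowSummary, b: WindowSummary) -> WindowComparison:
    """Rank-sum test on the per-position values of one window, two constructs.

    An empty window on either side yields an untestable flag, not an error.
    No multiple-testing adjustment is applied across windows.
    """
    if a.n_positions == 0 or b.n_positions == 0:
        return WindowComparison(a.t_lo, a.t_hi, testable=False)
    result = wilcoxon_rank_sum(a.values(), b.values())
    return WindowComparison(a.t_lo, a.t_hi, testable=True, result=result)


def compare_all_windows(
    a: Iterable[WindowSummary], b: Iterable[WindowSummary]
) -> list[WindowComparison]:
    a, b = list(a), list(b)
    if [(w.t_lo, w.t_hi) for w in a] != [(w.t_lo, w.t_hi) for w in b]:
        raise ValueError("window partitions differ between constructs")
    return [compare_windows(wa, wb) for wa, wb in zip(a, b)]


def comparisons_to_tsv(rows: list[WindowComparison], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("t_lo\tt_hi\tn1\tn2\tU\tp\tmethod\tstars\n")
        for r in rows:
            if r.testable:
                res = r.result
                fh.write(
                    f"{r.t_lo:g}\t{r.t_hi:g}\t{res.n1}\t{res.n2}\t{res.u:g}\t"
                    f"{res.p!r}\t{res.method}\t{res.stars}\n"
                )
            else:
                fh.write(f"{r.t_lo:g}\t{r.t_hi:g}\t0\t0\tNA\tNA\tNA\tNA\n")


@dataclass(frozen=True)
class EfficiencyResult:
    """Ty5 transposition efficiency from a plating assay.

    ``rate`` is integration events per plated cell: colonies on -His 5-FOA
    (cells that carry a genomic Ty5 integration and have lost the donor
    plasmid) over total viable cells on YPD, corrected for the relative
    dilution of the two platings.
    """

    foa_colonies: int
    total_viable: float
    rate: float


def transposition_efficiency(
    foa_colonies: int, total_viable: float, dilution_factor: float = 1.0
) -> EfficiencyResult:
    """Integration rate per cell from colony counts.

    ``dilution_factor`` scales the YPD count up to the pool the FOA plate
    was drawn from (e.g. 10.0 when the FOA aliquot came from a 10x more
    concentrated master than the counted YPD dilution).
    """
    if foa_colonies < 0 or total_viable < 0:
        raise ValueError("colony counts must be non-negative")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    denom = total_viable * dilution_factor
    if denom <= 0:
        raise ValueError("total viable cells must be positive")
    rate = foa_colonies / denom
    if rate > 1:
        raise ValueError("implied rate exceeds 1 per cell; check dilution accounting")
    return EfficiencyResult(foa_colonies=foa_colonies, total_viable=denom, rate=rate)
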