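"""Nonparametric statistical battery for tissue-concentration data.

The concentrations are positive, skewed and non-normal, so comparisons are
rank-based throughout: Kruskal–Wallis across ≥ 2 groups (dams, tissues,
metals), Mann–Whitney U for two-group contrasts (sex, season) and Spearman
rank correlation for associations of concentration with body size (total
length, weight). Normality screening (Lilliefors) is available as a
reporting step only; the pipeline never switches to parametric tests.

Small samples get exact permutation p-values (Kruskal–Wallis when the
pooled n ≤ 12, Spearman when n ≤ 8, Mann–Whitney via its exact null
distribution when n ≤ 20 without ties); otherwise the usual large-sample
approximations are used (χ² for KW, normal with continuity correction for
MWU, t for Spearman).

Higher-level operations mirror the study's reporting: a census of
significant size–concentration correlations per (dam, tissue, metal,
variable) cell, and per-dam seasonal letter verdicts (groups sharing a
letter are not significantly different at α = 0.05).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_data import METALS, TISSUES, SpecimenRecord

__all__ = [
    "TestResult",
    "CensusEntry",
    "CorrelationCensus",
    "SeasonalVerdict",
    "ConstantInputError",
    "kruskal_wallis",
    "mann_whitney",
    "spearman",
    "normality_screen",
    "correlation_census",
    "seasonal_flags",
]

log = logging.getLogger(__name__)

#: exact-permutation thresholds (pooled sample sizes); see module docstring
KW_EXACT_MAX_N = 12
MWU_EXACT_MAX_N = 20
SPEARMAN_EXACT_MAX_N = 8


class ConstantInputError(ValueError):
    """Correlation undefined: one of the vectors is constant."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value!r}")


def _as_arrays(groups: Sequence[Sequence[float]], min_n: int) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrs):
        if a.size < min_n:
            raise ValueError(f"group {i} has n={a.size} < {min_n}")
    return arrs


def _kw_h(ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    """Tie-corrected Kruskal–Wallis H from pooled mid-ranks."""
    n = ranks.size
    h = 0.0
    start = 0
    for m in sizes:
        r = ranks[start:start + m].sum()
        h += r * r / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else float("nan")


def _tie_correction(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "auto"
) -> TestResult:
    """Kruskal–Wallis test across ≥ 2 groups (each n ≥ 2).

    ``method``: ``"asymptotic"`` (χ², df = k−1), ``"exact"`` (full
    enumeration of group relabelings; tractable for pooled n ≤ ~12) or
    ``"auto"`` (exact when pooled n ≤ 12).
    """
    arrs = _as_arrays(groups, min_n=2)
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrs)
    sizes = [a.size for a in arrs]
    n = pooled.size
    ranks = stats.rankdata(pooled)
    tie_term = _tie_correction(pooled)
    h_obs = _kw_h(ranks, sizes, tie_term)

    if method == "auto":
        method = "exact" if n <= KW_EXACT_MAX_N else "asymptotic"
    if method == "asymptotic":
        h, p = stats.kruskal(*arrs)
        return TestResult(float(h), float(p), tuple(sizes), "kruskal-wallis chi2")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    # exact: enumerate all distinct assignments of pooled ranks to groups
    idx = set(range(n))
    count = 0
    total = 0

    def rec(remaining: frozenset, gi: int, acc: list[int]):
        nonlocal count, total
        if gi == len(sizes) - 1:
            perm = acc + sorted(remaining)
            h = _kw_h(ranks[perm], sizes, tie_term)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for comb in itertools.combinations(sorted(remaining), sizes[gi]):
            rec(remaining - set(comb), gi + 1, acc + list(comb))

    rec(frozenset(idx), 0, [])
    return TestResult(float(h_obs), count / total, tuple(sizes), "kruskal-wallis exact")


def mann_whitney(a: Sequence[float], b: Sequence[float], method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test (tie-handling, continuity-corrected).

    Exact null distribution when pooled n ≤ 20 and there are no ties;
    normal approximation with continuity correction otherwise.
    """
    xa, xb = _as_arrays([a, b], min_n=2)
    n = xa.size + xb.size
    has_ties = np.unique(np.concatenate([xa, xb])).size < n
    if method == "auto":
        method = "exact" if (n <= MWU_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        xa, xb, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), (xa.size, xb.size), f"mann-whitney {method}"
    )


def spearman(x: Sequence[float], y: Sequence[float], method: str = "auto") -> TestResult:
    """Spearman rank correlation on mid-ranks with two-sided p.

    Exact p by full permutation of ``y`` for n ≤ 8; t-approximation
    otherwise. Constant input raises :class:`ConstantInputError`.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 4:
        raise ValueError(f"spearman needs n >= 4, got {xa.size}")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        raise ConstantInputError("correlation undefined for a constant vector")
    n = xa.size
    if method == "auto":
        method = "exact" if n <= SPEARMAN_EXACT_MAX_N else "asymptotic"

    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "asymptotic":
        res = stats.spearmanr(xa, ya)
        return TestResult(float(res.statistic), float(res.pvalue), (n,), "spearman t-approx")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return TestResult(rho, count / total, (n,), "spearman exact")


def normality_screen(values: Sequence[float]) -> TestResult:
    """Lilliefors (KS with estimated mean/SD) normality check — reporting only."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("normality screen needs n >= 4")
    stat, p = lilliefors(x, dist="norm")
    return TestResult(float(stat), float(min(max(p, 0.0), 1.0)), (x.size,), "lilliefors")


# ---------------------------------------------------------------------------
# Study-level reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusEntry:
    dam_id: int
    tissue: str
    metal: str
    variable: str     # "TL" | "weight"
    rho: float
    p: float
    significant: bool
    n: int
    q: float | None = None  # optional BH-adjusted p (extension, not in the study)


@dataclass
class CorrelationCensus:
    entries: list[CensusEntry]
    total_significant: int
    skipped: list[tuple[int, str, str, str, str]] = field(default_factory=list)

    def count_by(self, attr: str) -> dict:
        out: dict = {}
        for e in self.entries:
            if e.significant:
                key = getattr(e, attr)
                out[key] = out.get(key, 0) + 1
        return out


def correlation_census(
    specimens: Iterable[SpecimenRecord],
    alpha: float = 0.05,
    min_n: int = 4,
    variables: Sequence[str] = ("TL", "weight"),
    adjust: bool = False,
) -> CorrelationCensus:
    """Census of significant size–concentration Spearman correlations.

    For every (dam, tissue, metal, variable) cell with at least ``min_n``
    specimens, correlate the concentration with total length or weight and
    count cells significant at ``alpha`` (per-test, uncorrected, as in the
    source design). ``adjust=True`` additionally attaches Benjamini–Hochberg
    q-values as a clearly-labelled extension; significance still uses raw p.
    Under-sized or constant cells are skipped and logged.
    """
    by_dam: dict[int, list[SpecimenRecord]] = {}
    for rec in specimens:
        by_dam.setdefault(rec.dam_id, []).append(rec)

    entries: list[CensusEntry] = []
    skipped: list[tuple[int, str, str, str, str]] = []
    for dam_id in sorted(by_dam):
        recs = by_dam[dam_id]
        for tissue in TISSUES:
            for metal in METALS:
                pairs = [
                    (r, r.concentrations[tissue][metal].value)
                    for r in recs
                    if tissue in r.concentrations and metal in r.concentrations[tissue]
                ]
                for var in variables:
                    xs = [
                        r.total_length_cm if var == "TL" else r.weight_g
                        for r, _ in pairs
                    ]
                    ys = [v for _, v in pairs]
                    if len(ys) < min_n:
                        if pairs:
                            skipped.append((dam_id, tissue, metal, var, f"n={len(ys)} < {min_n}"))
                            log.info("census: skipped dam %d %s %s %s (n=%d)",
                                     dam_id, tissue, metal, var, len(ys))
                        continue
                    try:
                        res = spearman(xs, ys, method="asymptotic")
                    except ConstantInputError:
                        skipped.append((dam_id, tissue, metal, var, "constant input"))
                        log.info("census: skipped dam %d %s %s %s (constant)",
                                 dam_id, tissue, metal, var)
                        continue
                    entries.append(
                        CensusEntry(dam_id, tissue, metal, var, res.statistic,
                                    res.p_value, res.p_value < alpha, len(ys))
                    )
    if adjust and entries:
        qs = stats.false_discovery_control([e.p for e in entries], method="bh")
        entries = [
            CensusEntry(e.dam_id, e.tissue, e.metal, e.variable, e.rho, e.p,
                        e.significant, e.n, q=float(q))
            for e, q in zip(entries, qs)
        ]
    total = sum(e.significant for e in entries)
    return CorrelationCensus(entries=entries, total_significant=total, skipped=skipped)


@dataclass(frozen=True)
class SeasonalVerdict:
    dam_id: int
    tissue: str
    metal: str
    verdict: str                      # "different" | "not different" | "not assessable"
    p: float | None
    letters: tuple[str, str] | None   # (dry, rainy); shared letter = not different
    n: tuple[int, int]


def seasonal_flags(
    specimens: Iterable[SpecimenRecord],
    tissue: str,
    metal: str,
    alpha: float = 0.05,
) -> list[SeasonalVerdict]:
    """Per-dam dry-vs-rainy comparison (Mann–Whitney) with letter grouping.

    Letters follow the compact-display convention: dams where the seasons
    differ at ``alpha`` get ('a', 'b'); otherwise ('a', 'a'). Dams missing a
    season (or with n < 2 in one) are "not assessable".
    """
    by_dam: dict[int, dict[str, list[float]]] = {}
    for rec in specimens:
        v = rec.concentrations.get(tissue, {}).get(metal)
        if v is None:
            continue
        by_dam.setdefault(rec.dam_id, {}).setdefault(rec.season, []).append(v.value)

    verdicts = []
    for dam_id in sorted(by_dam):
        seasons = by_dam[dam_id]
        dry = seasons.get("dry", [])
        rainy = seasons.get("rainy", [])
        if len(dry) < 2 or len(rainy) < 2:
            verdicts.append(
                SeasonalVerdict(dam_id, tissue, metal, "not assessable", None, None,
                                (len(dry), len(rainy)))
            )
            continue
        res = mann_whitney(dry, rainy)
        different = res.p_value < alpha
        verdicts.append(
            SeasonalVerdict(
                dam_id, tissue, metal,
                "different" if different else "not different",
                res.p_value,
                ("a", "b") if different else ("a", "a"),
                (len(dry), len(rainy)),
            )
        )
    return verdicts
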