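"""qPCR quantification and the nonparametric tests applied to it.

Relative expression is the 2^-dCt statistic with dCt = Ct(target) -
Ct(reference gene); duplicate wells are averaged on the Ct scale first.
Matched tumor/normal pairs are compared with the Wilcoxon signed-rank
test, tumor stages with Kruskal-Wallis, and all stage pairs with the
Steel-Dwass procedure (pairwise rank sums referred to the studentized
range). The tests are implemented here rather than delegated, including
an exact signed-rank null for small samples; scipy supplies only the
chi-square, normal and studentized-range reference distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, studentized_range

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: above this number of non-zero pairs the signed-rank test switches from
#: the exact enumerated null to the tie/continuity-corrected normal one
EXACT_WILCOXON_MAX_N = 25


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    method: str = ""

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


# ---------------------------------------------------------------------------
# 2^-dCt quantification
# ---------------------------------------------------------------------------


def relative_expression(ct_target, ct_reference):
    """2**-(Ct_target - Ct_reference); missing Ct propagates as NaN, never 0."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    out = np.power(2.0, -(ct_target - ct_reference))
    if out.ndim == 0:
        return float(out)
    return out


def qpcr_records(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a raw duplicate-well Ct table into per-sample records.

    Expects columns patient_id, tissue, stage, target, ct_rep1, ct_rep2,
    ref_ct_rep1, ref_ct_rep2. Duplicates are averaged on the Ct scale;
    if one replicate is missing the other is used alone. Adds ct_target,
    ct_reference, delta_ct and rel_expr columns.
    """
    need = [
        "patient_id", "tissue", "stage", "target",
        "ct_rep1", "ct_rep2", "ref_ct_rep1", "ref_ct_rep2",
    ]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise ValidationError(f"qPCR table missing columns: {missing}")
    bad = sorted(set(table["tissue"].astype(str)) - {"tumor", "normal"})
    if bad:
        raise ValidationError(f"unknown tissue value(s): {bad}")
    out = table.copy()
    with np.errstate(invalid="ignore"):
        out["ct_target"] = np.nanmean(
            out[["ct_rep1", "ct_rep2"]].to_numpy(float), axis=1
        )
        out["ct_reference"] = np.nanmean(
            out[["ref_ct_rep1", "ref_ct_rep2"]].to_numpy(float), axis=1
        )
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    out["rel_expr"] = np.power(2.0, -out["delta_ct"])
    return out


# ---------------------------------------------------------------------------
# rank utilities
# ---------------------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_counts(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_exact_sf_cdf(double_ranks: np.ndarray, w2: int):
    """Exact P(2W >= w2) and P(2W <= w2) by subset-sum convolution.

    ``double_ranks`` are the doubled midranks (integers), so the
    distribution of the doubled statistic is computed exactly — this is
    full enumeration of the 2^n sign assignments, organised as a DP.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = np.cumsum(counts)
    sf = 1.0 - np.concatenate(([0.0], cdf[:-1]))  # P(2W >= k)
    return float(sf[w2]), float(cdf[w2])


def wilcoxon_signed_rank(differences: Sequence[float], mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (the classical convention); tied
    absolute differences receive midranks. For ``n <= 25`` non-zero pairs
    the exact null distribution over all sign assignments is enumerated;
    above that a normal approximation with tie and continuity correction
    is used. ``mode`` forces 'exact' or 'normal'.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValidationError("no (non-missing) differences")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        logger.warning("all differences are zero; signed-rank p = 1")
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, method="degenerate")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if use_exact:
        dr = np.rint(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * w_plus))
        p_ge, p_le = _signed_rank_exact_sf_cdf(dr, w2)
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult("wilcoxon_signed_rank", w_plus, p, method=f"exact (n={n})")
    mean = n * (n + 1) / 4.0
    ties = _tie_counts(np.abs(d))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(ties**3 - ties) / 48.0
    if var <= 0:
        return TestResult("wilcoxon_signed_rank", w_plus, 1.0, method="degenerate")
    # continuity correction: shrink the deviation by 1/2 toward the mean
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult("wilcoxon_signed_rank", w_plus, p, method=f"normal (n={n})")


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]], labels=None) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi2(k-1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group must be non-empty")
    labels = tuple(labels) if labels is not None else tuple(
        f"g{i}" for i in range(len(groups))
    )
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValidationError("Kruskal-Wallis needs a total of >= 3 observations")
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    ties = _tie_counts(pooled)
    correction = 1.0 - np.sum(ties**3 - ties) / (n_total**3 - n_total)
    if correction <= 0:  # every observation identical
        return TestResult("kruskal_wallis", 0.0, 1.0, labels, "degenerate")
    h /= correction
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return TestResult("kruskal_wallis", h, p, labels, f"chi2 df={len(groups) - 1}")


# ---------------------------------------------------------------------------
# Steel-Dwass all-pairs comparison
# ---------------------------------------------------------------------------


def _pairwise_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic for two groups alone."""
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    expected = n1 * (n + 1) / 2.0
    ties = _tie_counts(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - np.sum(ties**3 - ties) / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((r1 - expected) / math.sqrt(var))


def steel_dwass(
    groups: Sequence[Sequence[float]],
    labels=None,
    method: str = "studentized",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """All-pairs Steel-Dwass comparisons with family-wise p-values.

    For every pair of groups the two groups alone are ranked, the rank sum
    is standardized with tie correction, and ``q = |z| * sqrt(2)`` is
    referred to the studentized-range distribution with k groups and
    infinite degrees of freedom. A degenerate pair (all values tied) gets
    p = 1. ``method='permutation'`` instead calibrates the same q
    statistics against their joint max-statistic permutation null
    (``n_permutations`` label shuffles), which protects the family-wise
    rate without the asymptotic appeal.

    Returns a DataFrame with one row per pair: group_a, group_b, z,
    q, p_value, method.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("Steel-Dwass needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group must have size >= 2")
    if method not in ("studentized", "permutation"):
        raise ValidationError(f"unknown method {method!r}")
    labels = tuple(labels) if labels is not None else tuple(
        f"g{i}" for i in range(len(groups))
    )
    k = len(groups)
    pairs = list(combinations(range(k), 2))
    z_obs = {(i, j): _pairwise_z(groups[i], groups[j]) for i, j in pairs}
    rows = []
    if method == "studentized":
        for i, j in pairs:
            q = abs(z_obs[(i, j)]) * math.sqrt(2.0)
            p = 1.0 if q == 0.0 else float(studentized_range.sf(q, k, np.inf))
            rows.append((labels[i], labels[j], z_obs[(i, j)], q, min(p, 1.0)))
        tag = f"studentized range (k={k}, df=inf)"
    else:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(groups)
        sizes = [g.size for g in groups]
        cuts = np.cumsum(sizes)[:-1]
        max_null = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, cuts)
            max_null[b] = max(
                abs(_pairwise_z(parts[i], parts[j])) for i, j in pairs
            )
        max_null *= math.sqrt(2.0)
        for i, j in pairs:
            q = abs(z_obs[(i, j)]) * math.sqrt(2.0)
            p = (1.0 + np.sum(max_null >= q - 1e-12)) / (n_permutations + 1.0)
            rows.append((labels[i], labels[j], z_obs[(i, j)], q, min(p, 1.0)))
        tag = f"max-statistic permutation (B={n_permutations})"
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "q", "p_value"])
    out["method"] = tag
    return out


# ---------------------------------------------------------------------------
# per-target analyses on qPCR records
# ---------------------------------------------------------------------------

STAGE_ORDER = ("CA", "I", "II", "III", "IV")


@dataclass
class StagewiseResult:
    """Kruskal-Wallis across stages plus, when significant, the
    Steel-Dwass pairwise table (None otherwise)."""

    kruskal: TestResult
    pairwise: pd.DataFrame | None
    group_sizes: Mapping[str, int]


def paired_tumor_normal_test(records: pd.DataFrame, value: str = "rel_expr") -> TestResult:
    """Wilcoxon signed-rank on matched tumor-minus-normal differences.

    Pairs with a missing value on either side are dropped with a logged
    count (an undetermined well never becomes a zero).
    """
    wide = records.pivot_table(
        index="patient_id", columns="tissue", values=value, aggfunc="mean"
    )
    if "tumor" not in wide or "normal" not in wide:
        raise ValidationError("records must contain both tumor and normal tissue")
    diffs = (wide["tumor"] - wide["normal"]).to_numpy()
    n_dropped = int(np.isnan(diffs).sum())
    if n_dropped:
        logger.warning("dropping %d pair(s) with missing values", n_dropped)
    return wilcoxon_signed_rank(diffs[~np.isnan(diffs)])


def stagewise_analysis(
    records: pd.DataFrame,
    value: str = "rel_expr",
    alpha: float = 0.05,
    min_group_size: int = 2,
) -> StagewiseResult:
    """Compare tumor expression across stages.

    Kruskal-Wallis across all stages present among tumor samples; if its
    p-value is below ``alpha``, a Steel-Dwass all-pairs table is appended,
    excluding (with a warning) stages with fewer than ``min_group_size``
    tumors.
    """
    tumors = records[records["tissue"] == "tumor"]
    stages = [s for s in STAGE_ORDER if (tumors["stage"] == s).any()]
    groups = [tumors.loc[tumors["stage"] == s, value].dropna().to_numpy() for s in stages]
    sizes = {s: g.size for s, g in zip(stages, groups)}
    kw = kruskal_wallis(groups, labels=stages)
    pairwise = None
    if kw.p_value < alpha:
        ok = [i for i, g in enumerate(groups) if g.size >= min_group_size]
        skipped = [stages[i] for i in range(len(groups)) if i not in ok]
        if skipped:
            logger.warning(
                "stage(s) %s have < %d tumors; excluded from Steel-Dwass",
                skipped,
                min_group_size,
            )
        if len(ok) >= 2:
            pairwise = steel_dwass(
                [groups[i] for i in ok], labels=[stages[i] for i in ok]
            )
    return StagewiseResult(kruskal=kw, pairwise=pairwise, group_sizes=sizes)
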