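"""Correlation-rank gene-set enrichment.

Given a target lncRNA, every candidate gene is scored by its Pearson
correlation with the target across a sample subset (tumor samples by
default, on log2(CPM + 0.5) expression) and ranked, rank 1 being the most
positively correlated. A gene set is called enriched when its members'
ranks are shifted relative to the remaining (background) genes — a
Mann-Whitney rank-shift test, exact by enumeration for small rankings and
normal-approximated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .io import CountMatrix, SampleSheet

#: rankings no longer than this use the exact Mann-Whitney null
EXACT_ENRICHMENT_MAX_M = 40


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises on length < 3 or a constant input (the caller excludes such
    features from rankings).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r needs two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("pearson_r needs length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValidationError("constant vector: correlation undefined")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def log_cpm(counts: CountMatrix, prior: float = 0.5) -> pd.DataFrame:
    """log2(counts-per-million + prior), per sample over its column sum."""
    y = counts.values.astype(float)
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("cannot compute CPM with an all-zero sample")
    return pd.DataFrame(
        np.log2(y / lib * 1e6 + prior),
        index=counts.feature_ids,
        columns=counts.sample_ids,
    )


@dataclass
class CorrelationRanking:
    """Genes ranked by correlation with one target lncRNA.

    ``table`` has columns feature_id, r, rank (dense, 1 = most positive,
    ties broken by feature id); ``excluded`` records features left out
    (zero variance) with a reason.
    """

    target: str
    table: pd.DataFrame
    n_samples: int
    excluded: pd.DataFrame

    def ranks_of(self, feature_ids) -> np.ndarray:
        lookup = self.table.set_index("feature_id")["rank"]
        return lookup.reindex(list(feature_ids)).dropna().to_numpy()


def correlate_target_vs_all(
    expr,
    target_id: str,
    candidate_ids=None,
    sheet: SampleSheet | None = None,
    sample_subset: str = "tumor",
    transform: str = "logcpm",
) -> CorrelationRanking:
    """Rank candidate genes by Pearson correlation with ``target_id``.

    ``expr`` is a CountMatrix (transformed according to ``transform``:
    'logcpm' or 'raw') or an already-normalised DataFrame. Correlations
    are computed over the ``sample_subset`` ('tumor', 'normal' or 'all';
    needs ``sheet`` unless 'all'). The target never appears in its own
    ranking; zero-variance candidates are excluded and recorded.
    """
    if isinstance(expr, CountMatrix):
        if transform == "logcpm":
            mat = log_cpm(expr)
        elif transform == "raw":
            mat = expr.to_frame().astype(float)
        else:
            raise ValidationError(f"unknown transform {transform!r}")
    else:
        mat = pd.DataFrame(expr).astype(float)

    if sample_subset != "all":
        if sheet is None:
            raise ValidationError("a sample sheet is required to subset samples")
        keep = sheet.samples_where(sample_subset)
        keep = [s for s in mat.columns if s in set(keep)]
        if not keep:
            raise ValidationError(f"no {sample_subset!r} samples to correlate over")
        mat = mat[keep]
    if mat.shape[1] < 3:
        raise ValidationError("need >= 3 samples to correlate")
    if target_id not in mat.index:
        raise ValidationError(f"target {target_id!r} not in expression matrix")

    if candidate_ids is None:
        candidate_ids = [f for f in mat.index if f != target_id]
    else:
        candidate_ids = [str(f) for f in candidate_ids if f != target_id]
        missing = [f for f in candidate_ids if f not in mat.index]
        if missing:
            raise ValidationError(f"candidates not in matrix: {missing[:5]}")

    t = mat.loc[target_id].to_numpy()
    if np.std(t) == 0.0:
        raise ValidationError(f"target {target_id!r} has zero variance")
    sub = mat.loc[candidate_ids].to_numpy()
    tc = t - t.mean()
    sc = sub - sub.mean(axis=1, keepdims=True)
    ss = np.sqrt((sc**2).sum(axis=1) * float(tc @ tc))
    defined = ss > 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((sc @ tc) / np.where(ss > 0, ss, np.nan), -1.0, 1.0)

    included = pd.DataFrame(
        {"feature_id": np.asarray(candidate_ids)[defined], "r": r[defined]}
    )
    included = included.sort_values(
        ["r", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    included["rank"] = np.arange(1, len(included) + 1)
    excluded = pd.DataFrame(
        {
            "feature_id": np.asarray(candidate_ids)[~defined],
            "reason": "zero variance",
        }
    )
    return CorrelationRanking(
        target=target_id,
        table=included,
        n_samples=mat.shape[1],
        excluded=excluded,
    )


@dataclass
class EnrichmentResult:
    set_id: str
    set_size: int
    u_statistic: float
    p_one_sided: float
    p_two_sided: float
    direction: str
    mean_rank_set: float
    mean_rank_background: float
    method: str


def _mann_whitney_exact_cdf(m: int, n1: int, rank_sum: int) -> tuple[float, float]:
    """Exact P(R <= rank_sum) and P(R >= rank_sum) where R is the rank sum
    of a uniformly random size-``n1`` subset of {1..m}.

    Subset-sum DP — equivalent to enumerating all C(m, n1) placements.
    """
    max_sum = n1 * m
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for v in range(1, m + 1):
        for k in range(min(n1, v), 0, -1):
            dp[k, v:] += dp[k - 1, : max_sum + 1 - v]
    counts = dp[n1]
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    p_le = float(cdf[rank_sum])
    p_ge = float(1.0 - (cdf[rank_sum - 1] if rank_sum >= 1 else 0.0))
    return p_le, p_ge


def rank_set_enrichment(
    ranking: CorrelationRanking, gene_set, set_id: str = "", mode: str = "auto"
) -> EnrichmentResult:
    """Mann-Whitney rank-shift test of a gene set inside a ranking.

    One-sided p is for 'the set is more positively correlated than
    background' (smaller ranks); two-sided doubles the smaller tail.
    Exact enumeration is used for rankings of up to
    ``EXACT_ENRICHMENT_MAX_M`` genes (or with ``mode='exact'``), the
    tie-free normal approximation with continuity correction otherwise.
    """
    members = set(map(str, gene_set))
    table = ranking.table
    in_set = table["feature_id"].isin(members)
    n1 = int(in_set.sum())
    m = len(table)
    if n1 == 0:
        raise ValidationError(
            f"gene set {set_id or '<unnamed>'!r} has no member in the ranking"
        )
    if n1 == m:
        raise ValidationError("gene set covers the whole ranking; empty background")
    ranks_set = table.loc[in_set, "rank"].to_numpy(float)
    ranks_bg = table.loc[~in_set, "rank"].to_numpy(float)
    rank_sum = float(ranks_set.sum())
    u = rank_sum - n1 * (n1 + 1) / 2.0  # count of (set, background) pairs won by bg

    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and m <= EXACT_ENRICHMENT_MAX_M)
    if use_exact:
        p_le, p_ge = _mann_whitney_exact_cdf(m, n1, int(round(rank_sum)))
        method = "exact"
    else:
        mean = n1 * (m + 1) / 2.0
        var = n1 * (m - n1) * (m + 1) / 12.0
        z_le = (rank_sum - mean + 0.5) / math.sqrt(var)
        z_ge = (rank_sum - mean - 0.5) / math.sqrt(var)
        p_le = float(norm.cdf(z_le))
        p_ge = float(norm.sf(z_ge))
        method = "normal"
    p_one = p_le  # small ranks = positively correlated
    p_two = min(1.0, 2.0 * min(p_le, p_ge))
    return EnrichmentResult(
        set_id=set_id,
        set_size=n1,
        u_statistic=u,
        p_one_sided=p_one,
        p_two_sided=p_two,
        direction="positive" if ranks_set.mean() < ranks_bg.mean() else "negative",
        mean_rank_set=float(ranks_set.mean()),
        mean_rank_background=float(ranks_bg.mean()),
        method=method,
    )
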