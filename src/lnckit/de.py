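"""Paired negative-binomial differential expression.

The model: counts ``y_fs ~ NB(mu_fs, phi)`` with ``log mu_fs = x_s' beta_f
+ offset_s`` where the offset is the log effective library size. For a
matched tumor/normal design the *full* model regresses on patient and
condition, the *reduced* model on patient only; the per-feature test is a
likelihood-ratio test between the two on one degree of freedom, and the
condition coefficient divided by ``log 2`` is the tumor-vs-normal log2
fold change. Multiplicity is handled by Benjamini-Hochberg.

Building blocks — TMM normalization factors, a common Cox-Reid dispersion
estimate, and an IRLS NB GLM fitter vectorised across features — are
exposed individually; :func:`lrt_paired_test` chains them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import FitError, ValidationError
from .io import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

# log-mean clamp: keeps IRLS finite when a coefficient diverges (e.g. a
# condition with all-zero counts, whose MLE sits at -infinity); the
# log-likelihood at the clamp is within ~1e-12 of its supremum
_ETA_MIN, _ETA_MAX = -30.0, 30.0
_MAX_ITER = 100
_BETA_TOL = 1e-8
_LL_TOL = 1e-11


# ---------------------------------------------------------------------------
# normalization (TMM)
# ---------------------------------------------------------------------------


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors.

    Scaling factors have geometric mean 1; the effective library size is
    ``lib_size * factor``.
    """

    sample_ids: list[str]
    lib_size: np.ndarray
    factor: np.ndarray

    @property
    def effective_lib_size(self) -> np.ndarray:
        return self.lib_size * self.factor

    def offsets(self) -> np.ndarray:
        """Log effective library sizes, the GLM offset vector."""
        return np.log(self.effective_lib_size)


def tmm_normalize(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample against a reference sample, per-feature log-ratios
    (M) and average log-abundances (A) are computed over features positive
    in both; features in the extreme ``trim_m`` tails of M and ``trim_a``
    tails of A (per tail) are discarded, and the factor is 2 to the
    precision-weighted mean of the surviving M values. The reference is
    the sample whose 75th count-fraction percentile is closest to the
    mean across samples. Factors are rescaled to geometric mean 1.
    """
    y = counts.values.astype(float)
    if y.shape[1] < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        dead = [s for s, n in zip(counts.sample_ids, lib) if n == 0]
        raise ValidationError(f"all-zero sample(s): {dead}")

    frac = y / lib
    with np.errstate(invalid="ignore"):
        uq = np.array([np.quantile(frac[y[:, j] > 0, j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(list(counts.sample_ids), lib.astype(np.int64), factors)


def _tmm_pair(y, y_ref, n, n_ref, trim_m, trim_a) -> float:
    ok = (y > 0) & (y_ref > 0)
    if ok.sum() < 1:
        return 1.0
    p, p_ref = y[ok] / n, y_ref[ok] / n_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    # asymptotic precision of each M value (delta method on two binomials);
    # a feature carrying a whole library has zero asymptotic variance and
    # would get infinite weight, so clamp to the largest finite one
    with np.errstate(divide="ignore"):
        w = 1.0 / ((n - y[ok]) / (n * y[ok]) + (n_ref - y_ref[ok]) / (n_ref * y_ref[ok]))
    if np.any(~np.isfinite(w)):
        finite_max = w[np.isfinite(w)].max(initial=1.0)
        w = np.where(np.isfinite(w), w, finite_max)
    if np.allclose(m, m[0]):
        return float(2.0 ** m[0])
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        keep = np.ones_like(m, dtype=bool)
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


# ---------------------------------------------------------------------------
# NB log-likelihood and batch IRLS
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Exact NB log-likelihood per feature (rows); Poisson in the phi->0
    limit. ``phi`` may be a scalar or a per-feature array."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    if np.isscalar(phi) or np.ndim(phi) == 0:
        if phi < 1e-12:
            return np.sum(y * np.log(mu) - mu - gammaln(y + 1.0), axis=-1)
        r = np.asarray(1.0 / phi)
    else:
        r = 1.0 / np.maximum(np.asarray(phi, dtype=float), 1e-12)
    if r.ndim == 1:
        r = r[:, None]
    return np.sum(
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=-1,
    )


@dataclass
class GlmFit:
    """A fitted NB GLM for one feature (or a batch; arrays gain a leading axis)."""

    beta: np.ndarray
    mu: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    n_iter: int


def fit_nb_glm_batch(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: float,
    max_iter: int = _MAX_ITER,
    tol: float = _BETA_TOL,
) -> GlmFit:
    """Fit log-link NB GLMs for many features sharing one design matrix.

    Plain IRLS with working weights ``mu/(1+phi*mu)``. A fit is declared
    converged when the coefficient step drops below ``tol`` or the
    log-likelihood plateaus (which is where IRLS lands when an MLE sits at
    infinity, e.g. all-zero counts in one condition; the likelihood still
    attains its supremum there).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    nf, ns = Y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise FitError("design matrix is rank deficient")
    phi_arr = np.asarray(phi, dtype=float)
    scalar_phi = phi_arr.ndim == 0

    def _phi_for(mask):
        return phi_arr if scalar_phi else phi_arr[mask]

    def _phi_col(mask):
        return phi_arr if scalar_phi else phi_arr[mask][:, None]

    # start from a log-linear fit to shrunken counts
    z0 = np.log(Y + 0.5) - offsets
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (nf, p)

    eta = np.clip(beta @ X.T + offsets, _ETA_MIN, _ETA_MAX)
    mu = np.exp(eta)
    ll = nb_loglik(Y, mu, phi_arr)
    converged = np.zeros(nf, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        active = ~converged
        if not active.any():
            break
        w = mu[active] / (1.0 + _phi_col(active) * mu[active])
        z = (eta[active] - offsets) + (Y[active] - mu[active]) / mu[active]
        xtwx = np.einsum("si,fs,sj->fij", X, w, X)
        xtwz = np.einsum("si,fs,fs->fi", X, w, z)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # ridge fallback for singular working weights
            xtwx = xtwx + 1e-8 * np.eye(p)
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        step = np.max(np.abs(new_beta - beta[active]), axis=1)
        beta[active] = new_beta
        eta[active] = np.clip(new_beta @ X.T + offsets, _ETA_MIN, _ETA_MAX)
        mu[active] = np.exp(eta[active])
        new_ll = nb_loglik(Y[active], mu[active], _phi_for(active))
        plateau = np.abs(new_ll - ll[active]) < _LL_TOL * (np.abs(new_ll) + 1.0)
        ll[active] = new_ll
        done = (step < tol) | plateau
        converged[np.flatnonzero(active)[done]] = True
    return GlmFit(beta=beta, mu=mu, loglik=ll, converged=converged, n_iter=it)


def fit_nb_glm(y, design_matrix, offsets, phi) -> GlmFit:
    """Single-feature convenience wrapper around :func:`fit_nb_glm_batch`."""
    fit = fit_nb_glm_batch(np.asarray(y)[None, :], design_matrix, offsets, phi)
    return GlmFit(
        beta=fit.beta[0],
        mu=fit.mu[0],
        loglik=float(fit.loglik[0]),
        converged=bool(fit.converged[0]),
        n_iter=fit.n_iter,
    )


# ---------------------------------------------------------------------------
# dispersion (Cox-Reid adjusted profile likelihood)
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimate:
    """Common dispersion, optionally with shrunken per-feature values.

    ``per_feature`` (aligned with ``feature_ids``) holds per-feature
    Cox-Reid estimates shrunk on the log scale toward the common value;
    features absent from it fall back to the common estimate.
    """

    common: float
    per_feature: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)

    def for_features(self, feature_ids: list[str]):
        """Scalar (common mode) or per-feature array aligned to ``feature_ids``."""
        if self.per_feature is None:
            return self.common
        lookup = dict(zip(self.feature_ids, self.per_feature))
        return np.array([lookup.get(f, self.common) for f in feature_ids])


def _cr_apl(Y, X, offsets, phi) -> float:
    """Summed Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    fit = fit_nb_glm_batch(Y, X, offsets, phi)
    w = fit.mu / (1.0 + phi * fit.mu)
    xtwx = np.einsum("si,fs,sj->fij", X, w, X)
    sign, logdet = np.linalg.slogdet(xtwx)
    if np.any(sign <= 0):
        raise FitError("non-positive-definite information matrix in CR adjustment")
    return float(np.sum(fit.loglik - 0.5 * logdet))


def _cr_apl_per_feature(Y, X, offsets, phi) -> np.ndarray:
    fit = fit_nb_glm_batch(Y, X, offsets, phi)
    w = fit.mu / (1.0 + phi * fit.mu)
    xtwx = np.einsum("si,fs,sj->fij", X, w, X)
    _, logdet = np.linalg.slogdet(xtwx)
    return fit.loglik - 0.5 * logdet


def estimate_dispersion(
    counts: CountMatrix,
    design: SampleSheet,
    norm: NormalizationFactors,
    paired: bool = True,
    log10_bounds: tuple[float, float] = (-6.0, 1.0),
    mode: str = "common",
    shrink_weight: float = 0.7,
) -> DispersionEstimate:
    """Common NB dispersion maximising the Cox-Reid adjusted profile
    likelihood under the full (patient + condition, or condition-only)
    model, via bounded scalar search on log10 phi.

    ``mode='shrunk'`` additionally maximises the per-feature Cox-Reid
    profile likelihood on a log grid and shrinks each estimate toward
    the common value on the log scale with weight ``shrink_weight``
    (1 = fully common); with a handful of samples per feature, unshrunk
    tagwise estimates are far too noisy to use directly.

    Features carrying no information (identical counts in every sample)
    are excluded from the estimation and logged.
    """
    if mode not in ("common", "shrunk"):
        raise ValidationError(f"unknown dispersion mode {mode!r}")
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValidationError("shrink_weight must lie in [0, 1]")
    X = build_design(design, counts.sample_ids, paired=paired, full=True)
    Y = counts.values.astype(float)
    informative = ~np.all(Y == Y[:, :1], axis=1)
    n_dropped = int((~informative).sum())
    if n_dropped:
        logger.info("dispersion: excluding %d uninformative feature(s)", n_dropped)
    Y = Y[informative]
    if Y.shape[0] == 0:
        raise FitError("no informative features for dispersion estimation")
    offsets = norm.offsets()

    def objective(log10_phi: float) -> float:
        return -_cr_apl(Y, X, offsets, 10.0 ** log10_phi)

    res = minimize_scalar(
        objective, bounds=log10_bounds, method="bounded", options={"xatol": 1e-3}
    )
    if not np.isfinite(res.fun):
        raise FitError("dispersion search did not produce a finite objective")
    phi = float(10.0 ** res.x)
    # the lower bound doubles as "effectively Poisson"
    if res.x <= log10_bounds[0] + 1e-6:
        phi = 10.0 ** log10_bounds[0]
    if mode == "common":
        return DispersionEstimate(common=phi)

    grid = np.linspace(log10_bounds[0], log10_bounds[1], 29)
    apl = np.stack([_cr_apl_per_feature(Y, X, offsets, 10.0 ** g) for g in grid])
    tagwise = 10.0 ** grid[np.argmax(apl, axis=0)]
    shrunk = np.exp(
        shrink_weight * math.log(phi) + (1.0 - shrink_weight) * np.log(tagwise)
    )
    ids = [f for f, keep in zip(counts.feature_ids, informative) if keep]
    return DispersionEstimate(common=phi, per_feature=shrunk, feature_ids=ids)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def build_design(
    sheet: SampleSheet, sample_ids: list[str], paired: bool, full: bool
) -> np.ndarray:
    """Design matrix rows ordered like ``sample_ids``.

    Paired full model: intercept + patient indicators (first patient as
    reference) + tumor indicator; the reduced model drops the tumor
    column. Unpaired: intercept (+ tumor indicator when ``full``). The
    tumor indicator is always the last column.
    """
    tab = sheet.table.set_index("sample_id").loc[sample_ids]
    cols = [np.ones(len(sample_ids))]
    if paired:
        patients = sorted(tab["patient_id"].unique())
        for pat in patients[1:]:
            cols.append((tab["patient_id"] == pat).to_numpy(float))
    if full:
        cols.append((tab["condition"] == "tumor").to_numpy(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# the likelihood-ratio test
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (NaN) are propagated and do not count toward the
    number of tests. Output is monotone in p and always >= p.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def lrt_paired_test(
    counts: CountMatrix,
    sheet: SampleSheet,
    norm: NormalizationFactors | None = None,
    phi: float | DispersionEstimate | None = None,
    min_expressed_samples: int = 2,
    dispersion_mode: str = "common",
) -> pd.DataFrame:
    """Paired tumor-vs-normal likelihood-ratio test; see module docstring.

    Returns one row per input feature with columns feature_id, log2fc,
    lrt_stat, p_value, fdr, direction, tested. Features failing the
    low-count filter keep their row with ``tested=False`` and missing
    statistics, so feature accounting stays exact. ``dispersion_mode``
    ('common' or 'shrunk') applies when ``phi`` is not supplied.
    """
    return _lrt(counts, sheet, norm, phi, min_expressed_samples, paired=True,
                dispersion_mode=dispersion_mode)


def lrt_group_test(
    counts: CountMatrix,
    sheet: SampleSheet,
    norm: NormalizationFactors | None = None,
    phi: float | DispersionEstimate | None = None,
    min_expressed_samples: int = 2,
    dispersion_mode: str = "common",
) -> pd.DataFrame:
    """Unpaired two-group (tumor vs normal) NB LRT with the same contract."""
    return _lrt(counts, sheet, norm, phi, min_expressed_samples, paired=False,
                dispersion_mode=dispersion_mode)


def _lrt(counts, sheet, norm, phi, min_expressed_samples, paired, dispersion_mode="common") -> pd.DataFrame:
    sheet.validate_against(counts)
    if paired:
        sheet.pairs()  # raises PairingError when the design is not 1+1
    if norm is None:
        norm = tmm_normalize(counts)
    Y = counts.values.astype(float)
    tested = (Y > 0).sum(axis=1) >= min_expressed_samples
    if phi is None:
        phi = estimate_dispersion(counts, sheet, norm, paired=paired, mode=dispersion_mode)
    if isinstance(phi, DispersionEstimate):
        phi_val = phi.for_features(counts.feature_ids)
    else:
        phi_val = float(phi)

    X_full = build_design(sheet, counts.sample_ids, paired=paired, full=True)
    X_red = build_design(sheet, counts.sample_ids, paired=paired, full=False)
    offsets = norm.offsets()

    nf = Y.shape[0]
    log2fc = np.full(nf, np.nan)
    stat = np.full(nf, np.nan)
    pval = np.full(nf, np.nan)
    idx = np.flatnonzero(tested)
    if idx.size:
        phi_sub = phi_val[idx] if np.ndim(phi_val) else phi_val
        full = fit_nb_glm_batch(Y[idx], X_full, offsets, phi_sub)
        red = fit_nb_glm_batch(Y[idx], X_red, offsets, phi_sub)
        s = 2.0 * (full.loglik - red.loglik)
        if np.any(s < -1e-4 * (np.abs(full.loglik) + 1.0)):
            worst = idx[int(np.argmin(s))]
            raise FitError(
                "reduced model log-likelihood exceeds the full model beyond "
                f"numerical tolerance at feature {counts.feature_ids[worst]!r}"
            )
        s = np.maximum(s, 0.0)
        ok = full.converged & red.converged
        log2fc[idx] = full.beta[:, -1] / LN2
        stat[idx[ok]] = s[ok]
        pval[idx[ok]] = chi2.sf(s[ok], df=1)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%d feature(s) did not converge; p set missing", n_bad)

    fdr = bh_adjust(pval)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", ""))
    direction = np.where(np.isnan(log2fc), "", direction)
    return pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "log2fc": log2fc,
            "lrt_stat": stat,
            "p_value": pval,
            "fdr": fdr,
            "direction": direction,
            "tested": tested,
        }
    )


def write_de_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_results(path) -> pd.DataFrame:
    from .io import _read_tsv

    df = _read_tsv(path)
    need = ["feature_id", "log2fc", "fdr"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValidationError(f"DE results missing columns: {missing}")
    df["feature_id"] = df["feature_id"].astype(str)
    return df
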