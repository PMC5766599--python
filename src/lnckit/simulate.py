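"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators cover the three kinds of data the analysis consumes:

* :func:`simulate_discovery_cohort` — a small matched tumor/normal design
  with negative-binomial counts, per-patient effects shared by each pair,
  shallow lncRNAs, and planted log2 fold changes;
* :func:`simulate_confirmation_cohort` — a large unpaired cohort with the
  same effect directions plus a latent factor that co-expresses one target
  lncRNA with a planted protein-coding gene set in tumor samples;
* :func:`simulate_qpcr_cohort` — paired Ct measurements (duplicate wells,
  a reference gene) across tumor stages.

Counts follow the NB parameterisation Var = mu + phi*mu^2 and are drawn as
a gamma-Poisson mixture, so the dispersion phi matches what the
differential-expression module estimates. All randomness flows from a
single seed; identical configuration and seed give bit-identical output.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigurationError, ValidationError
from .io import CountMatrix, FeatureAnnotation, GeneSetCollection, SampleSheet, _read_tsv

LN2 = math.log(2.0)

#: set id under which the planted co-expressed protein-coding genes are
#: exported (a stand-in for a GO term such as "cell cycle").
PLANTED_SET_ID = "SET:PLANTED"

_LNC_BIOTYPES = ("lincRNA", "antisense", "retained_intron", "sense_intronic")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent child streams so the confirmation draw does not depend on
    # how many variates the discovery draw consumed
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) counts via the gamma-Poisson mixture; phi=0 is Poisson."""
    if phi <= 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mu * phi)
    return rng.poisson(lam)


def _feature_frame(cfg: SimulationConfig, rng: np.random.Generator):
    """Feature ids, lncRNA flags, baselines, DE assignment and planted set."""
    n_lnc = int(round(cfg.frac_lncRNA * cfg.n_features))
    n_pcg = cfg.n_features - n_lnc
    ids = [f"LNC{i + 1:05d}" for i in range(n_lnc)] + [
        f"PCG{i + 1:05d}" for i in range(n_pcg)
    ]
    is_lnc = np.zeros(cfg.n_features, dtype=bool)
    is_lnc[:n_lnc] = True
    baseline = np.where(is_lnc, cfg.lnc_mean_count, cfg.pcg_mean_count)

    # planted effects: DE features split between classes in proportion to
    # frac_lncRNA; the planted co-expression set must fit inside the
    # protein-coding DE features (its members are DE in both cohorts, so
    # they survive the network's vertex filter)
    n_de_lnc = min(n_lnc, int(round(cfg.n_true_de * cfg.frac_lncRNA)))
    n_de_pcg = min(n_pcg, cfg.n_true_de - n_de_lnc)
    n_de_lnc = cfg.n_true_de - n_de_pcg
    if n_de_lnc > n_lnc:
        raise ConfigurationError(
            "SimulationConfig.n_true_de: too many DE features for the class sizes"
        )
    if cfg.planted_set_size > max(n_de_pcg, 0) and cfg.n_true_de > 0:
        raise ConfigurationError(
            "SimulationConfig.planted_set_size: exceeds the number of "
            f"protein-coding DE features ({n_de_pcg})"
        )
    de_idx = np.concatenate(
        [
            rng.choice(n_lnc, size=n_de_lnc, replace=False) if n_de_lnc else [],
            n_lnc + rng.choice(n_pcg, size=n_de_pcg, replace=False) if n_de_pcg else [],
        ]
    ).astype(int)
    is_de = np.zeros(cfg.n_features, dtype=bool)
    is_de[de_idx] = True

    lfc = np.zeros(cfg.n_features)
    signs = rng.choice([-1.0, 1.0], size=de_idx.size)
    lo, hi = cfg.logfc_range
    plo, phi_ = cfg.pcg_logfc_range
    magnitudes = np.where(
        is_lnc[de_idx],
        rng.uniform(lo, hi, size=de_idx.size),
        rng.uniform(plo, phi_, size=de_idx.size),
    )
    lfc[de_idx] = signs * magnitudes

    # the designated target lncRNA is the lowest-id DE lncRNA, forced up
    de_lnc_idx = np.flatnonzero(is_de & is_lnc)
    if de_lnc_idx.size:
        tgt = de_lnc_idx[0]
        lfc[tgt] = abs(lfc[tgt])

    in_planted = np.zeros(cfg.n_features, dtype=bool)
    de_pcg_idx = np.flatnonzero(is_de & ~is_lnc)
    if cfg.n_true_de > 0 and cfg.planted_set_size > 0:
        in_planted[de_pcg_idx[: cfg.planted_set_size]] = True

    truth = pd.DataFrame(
        {
            "feature_id": ids,
            "is_de": is_de,
            "true_log2fc": lfc,
            "is_lncRNA": is_lnc,
            "in_planted_set": in_planted,
        }
    )

    biotype = np.where(is_lnc, "", "protein_coding").astype(object)
    biotype[is_lnc] = rng.choice(
        _LNC_BIOTYPES, size=n_lnc, p=(0.45, 0.30, 0.15, 0.10)
    )
    annotation = FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": ids,
                "symbol": [i.replace("0", "-", 1) for i in ids],
                "biotype": biotype,
                "is_lncRNA": is_lnc,
            }
        )
    )
    return truth, annotation, baseline


def simulate_discovery_cohort(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, SampleSheet, FeatureAnnotation, pd.DataFrame]:
    """Matched tumor/normal discovery cohort.

    Returns (counts, sample sheet, feature annotation, truth table). The
    log mean of feature *f* in sample *s* is

        log baseline_f + patient_effect_{p(s)} + 1[tumor_s] * lfc_f * ln 2
        + log depth_s

    with NB(phi) sampling noise on top.
    """
    rng = _rng(cfg.seed, 0)
    truth, annotation, baseline = _feature_frame(cfg, rng)

    n = cfg.n_pairs_discovery
    patients = [f"P{i + 1:02d}" for i in range(n)]
    sample_ids, patient_col, condition, stage = [], [], [], []
    for p in patients:
        for cond, suffix in (("tumor", "T"), ("normal", "N")):
            sample_ids.append(f"{p}_{suffix}")
            patient_col.append(p)
            condition.append(cond)
    stage_draw = rng.choice(["I", "II", "III", "IV"], size=n)
    for i in range(n):
        stage.extend([stage_draw[i], "NA"])
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": patient_col,
                "condition": condition,
                "stage": stage,
            }
        )
    )

    pat_eff = rng.normal(0.0, cfg.patient_effect_sd, size=n)
    depth = (
        rng.lognormal(0.0, cfg.libsize_log_sd, size=2 * n)
        if cfg.libsize_log_sd > 0
        else np.ones(2 * n)
    )
    is_tumor = np.array([c == "tumor" for c in condition], dtype=float)
    pat_index = np.repeat(np.arange(n), 2)

    log_mu = (
        np.log(baseline)[:, None]
        + pat_eff[pat_index][None, :]
        + truth["true_log2fc"].to_numpy()[:, None] * is_tumor[None, :] * LN2
        + np.log(depth)[None, :]
    )
    counts = _nb_counts(rng, np.exp(log_mu), cfg.dispersion)
    cm = CountMatrix(pd.DataFrame(counts, index=truth["feature_id"], columns=sample_ids))
    return cm, sheet, annotation, truth


def simulate_confirmation_cohort(
    cfg: SimulationConfig, truth: pd.DataFrame
) -> tuple[CountMatrix, SampleSheet]:
    """Large unpaired confirmation cohort consistent with ``truth``.

    True DE features keep their discovery-direction effect. In tumor
    samples a standard-normal latent factor, scaled by
    ``cfg.latent_factor_loading``, is added to the log mean of the target
    lncRNA and of every planted-set gene, inducing co-expression among
    them (and none elsewhere).
    """
    rng = _rng(cfg.seed, 1)
    n_t, n_n = cfg.n_tumor_confirm, cfg.n_normal_confirm
    sample_ids = [f"T{i + 1:04d}" for i in range(n_t)] + [
        f"N{i + 1:04d}" for i in range(n_n)
    ]
    condition = ["tumor"] * n_t + ["normal"] * n_n
    stages = list(rng.choice(["I", "II", "III", "IV"], size=n_t)) + ["NA"] * n_n
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": sample_ids,  # unpaired: one sample per patient
                "condition": condition,
                "stage": stages,
            }
        )
    )

    is_lnc = truth["is_lncRNA"].to_numpy()
    baseline = np.where(is_lnc, cfg.lnc_mean_count, cfg.pcg_mean_count)
    lfc = truth["true_log2fc"].to_numpy()
    n_s = n_t + n_n
    subj_eff = rng.normal(0.0, cfg.patient_effect_sd, size=n_s)
    depth = (
        rng.lognormal(0.0, cfg.libsize_log_sd, size=n_s)
        if cfg.libsize_log_sd > 0
        else np.ones(n_s)
    )
    is_tumor = np.array([c == "tumor" for c in condition], dtype=float)

    log_mu = (
        np.log(baseline)[:, None]
        + subj_eff[None, :]
        + lfc[:, None] * is_tumor[None, :] * LN2
        + np.log(depth)[None, :]
    )

    target = target_lncrna(truth)
    planted = truth["in_planted_set"].to_numpy()
    if cfg.latent_factor_loading != 0.0 and (target is not None or planted.any()):
        factor = rng.normal(0.0, 1.0, size=n_t)
        loaded = planted.copy()
        if target is not None:
            loaded |= (truth["feature_id"] == target).to_numpy()
        log_mu[np.ix_(loaded, is_tumor.astype(bool))] += (
            cfg.latent_factor_loading * factor[None, :]
        )

    counts = _nb_counts(rng, np.exp(log_mu), cfg.dispersion)
    cm = CountMatrix(
        pd.DataFrame(counts, index=truth["feature_id"], columns=sample_ids)
    )
    return cm, sheet


def target_lncrna(truth: pd.DataFrame) -> str | None:
    """The designated target lncRNA: lowest-id up-regulated DE lncRNA."""
    m = truth["is_de"] & truth["is_lncRNA"] & (truth["true_log2fc"] > 0)
    ids = truth.loc[m, "feature_id"]
    return None if ids.empty else sorted(ids)[0]


def planted_gene_set(truth: pd.DataFrame) -> GeneSetCollection:
    members = tuple(truth.loc[truth["in_planted_set"], "feature_id"])
    return GeneSetCollection({PLANTED_SET_ID: members})


# ---------------------------------------------------------------------------
# qPCR cohort
# ---------------------------------------------------------------------------

DEFAULT_STAGE_DISTRIBUTION: Mapping[str, float] = {
    "CA": 5,
    "I": 30,
    "II": 40,
    "III": 40,
    "IV": 24,
}


def simulate_qpcr_cohort(
    n_pairs: int,
    stage_distribution: Mapping[str, float] | None = None,
    effect_delta_ct: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    stage_effects: Mapping[str, float] | None = None,
    target_name: str = "LNC-TARGET",
    pair_sd: float = 1.0,
    base_ct_reference: float = 20.0,
    base_delta_ct: float = 8.0,
) -> pd.DataFrame:
    """Paired qPCR Ct table (duplicate wells) for one target transcript.

    Tumor dCt is shifted by ``-effect_delta_ct`` relative to the matched
    normal (up-regulation: lower dCt means more transcript), plus an
    optional per-stage shift from ``stage_effects``. With ``noise_sd=0``
    tumor relative expression is exactly ``2**effect_delta_ct`` times the
    matched normal. Replicate wells are jittered symmetrically around the
    true Ct, so their mean is exact.

    Returns a DataFrame with columns patient_id, tissue, stage, target,
    ct_rep1, ct_rep2, ref_ct_rep1, ref_ct_rep2.
    """
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    dist = dict(stage_distribution or DEFAULT_STAGE_DISTRIBUTION)
    bad = set(dist) - {"CA", "I", "II", "III", "IV"}
    if bad:
        raise ConfigurationError(f"unknown stage(s) in stage_distribution: {sorted(bad)}")
    total = float(sum(dist.values()))
    if total <= 0:
        raise ConfigurationError("stage_distribution weights must sum to > 0")
    stage_effects = dict(stage_effects or {})

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    stage_names = sorted(dist)
    probs = np.array([dist[s] for s in stage_names]) / total
    stages = rng.choice(stage_names, size=n_pairs, p=probs)
    pair_eff = rng.normal(0.0, pair_sd, size=n_pairs)

    rows = []
    for i in range(n_pairs):
        pid = f"Q{i + 1:03d}"
        for tissue in ("tumor", "normal"):
            ref_ct = base_ct_reference + rng.normal(0.0, noise_sd)
            dct = base_delta_ct + pair_eff[i] + rng.normal(0.0, noise_sd)
            if tissue == "tumor":
                dct -= effect_delta_ct + stage_effects.get(stages[i], 0.0)
            tgt_ct = ref_ct + dct
            jit_t = rng.normal(0.0, noise_sd / 2.0) if noise_sd > 0 else 0.0
            jit_r = rng.normal(0.0, noise_sd / 2.0) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "patient_id": pid,
                    "tissue": tissue,
                    "stage": stages[i] if tissue == "tumor" else "NA",
                    "target": target_name,
                    "ct_rep1": tgt_ct + jit_t,
                    "ct_rep2": tgt_ct - jit_t,
                    "ref_ct_rep1": ref_ct + jit_r,
                    "ref_ct_rep2": ref_ct - jit_r,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth-table round trip
# ---------------------------------------------------------------------------


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = ["feature_id", "is_de", "true_log2fc", "is_lncRNA", "in_planted_set"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"truth table missing columns: {missing}")
    for col in ("is_de", "is_lncRNA", "in_planted_set"):
        df[col] = df[col].astype(str).map({"True": True, "False": False}).astype(bool)
    df["feature_id"] = df["feature_id"].astype(str)
    df["true_log2fc"] = df["true_log2fc"].astype(float)
    return df[required]
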