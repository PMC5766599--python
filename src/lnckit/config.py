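"""Configuration objects for the synthetic cohort generators and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

from .errors import ConfigurationError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design this package targets: a tiny
    matched discovery cohort (3 tumor/normal pairs) in which lncRNAs are
    shallowly sequenced (mean counts below 10), a large unpaired
    confirmation cohort (682 tumors, 41 normals), planted fold changes of
    |log2FC| between 3 and 8, and a latent co-expression factor tying one
    target lncRNA to a planted protein-coding gene set in tumor samples.

    Attributes
    ----------
    n_pairs_discovery:
        Matched tumor/normal pairs in the discovery cohort.
    n_tumor_confirm, n_normal_confirm:
        Unpaired sample counts in the confirmation cohort.
    n_features:
        Total simulated features (lncRNA + protein-coding).
    frac_lncRNA:
        Fraction of features flagged as lncRNA.
    n_true_de:
        Features with a planted tumor/normal effect.
    logfc_range:
        (lo, hi) of planted |log2FC| for lncRNA features; signs are
        random. The extreme fold changes seen for lncRNAs arise from
        their near-zero baselines.
    pcg_logfc_range:
        (lo, hi) of planted |log2FC| for protein-coding features, milder
        than the lncRNA range as befits well-expressed genes.
    lnc_mean_count, pcg_mean_count:
        Baseline (normal tissue) mean counts for lncRNA and protein-coding
        features. lncRNAs are deliberately shallow (default 5 reads).
    dispersion:
        Negative-binomial dispersion phi in Var = mu + phi*mu^2.
        Default 0.16 corresponds to a biological CV of 0.4, typical for
        human tissue samples.
    patient_effect_sd:
        SD of the per-patient log-scale effect shared by a matched pair.
    libsize_log_sd:
        SD of the log-normal per-sample depth factor (0 disables).
    latent_factor_loading:
        Loading of the shared latent factor (log scale, tumor samples of
        the confirmation cohort only) on the target lncRNA and the
        planted gene set; 0 disables co-expression.
    planted_set_size:
        Number of protein-coding DE features forming the planted
        ("cell-cycle-like") co-expressed set.
    seed:
        Seed of the single random stream all generators derive from.
    """

    n_pairs_discovery: int = 3
    n_tumor_confirm: int = 682
    n_normal_confirm: int = 41
    n_features: int = 2000
    frac_lncRNA: float = 0.3
    n_true_de: int = 150
    logfc_range: tuple[float, float] = (3.0, 8.0)
    pcg_logfc_range: tuple[float, float] = (1.0, 3.0)
    lnc_mean_count: float = 5.0
    pcg_mean_count: float = 200.0
    dispersion: float = 0.16
    patient_effect_sd: float = 0.5
    libsize_log_sd: float = 0.3
    latent_factor_loading: float = 0.6
    planted_set_size: int = 25
    seed: int = 0

    def __post_init__(self):
        def bad(name, why):
            raise ConfigurationError(f"SimulationConfig.{name}: {why}")

        for name in (
            "n_pairs_discovery",
            "n_tumor_confirm",
            "n_normal_confirm",
            "n_features",
        ):
            if int(getattr(self, name)) < 1:
                bad(name, "must be >= 1")
        if not 0.0 <= self.frac_lncRNA <= 1.0:
            bad("frac_lncRNA", "must lie in [0, 1]")
        if not 0 <= self.n_true_de <= self.n_features:
            bad("n_true_de", "must lie in [0, n_features]")
        import math

        for name in ("logfc_range", "pcg_logfc_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi or lo < 0:
                bad(name, "bounds must be finite with 0 <= lo <= hi")
        if self.lnc_mean_count <= 0 or self.pcg_mean_count <= 0:
            bad("lnc_mean_count/pcg_mean_count", "baseline means must be positive")
        if self.dispersion < 0:
            bad("dispersion", "must be >= 0")
        if self.patient_effect_sd < 0:
            bad("patient_effect_sd", "must be >= 0")
        if self.libsize_log_sd < 0:
            bad("libsize_log_sd", "must be >= 0")
        if self.planted_set_size < 0:
            bad("planted_set_size", "must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        from dataclasses import replace

        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown SimulationConfig field(s): {sorted(unknown)}"
            )
        d = dict(d)
        for name in ("logfc_range", "pcg_logfc_range"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)
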