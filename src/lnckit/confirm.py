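"""Dual-cohort confirmation, direction partition and novelty annotation.

A discovery-cohort hit (small matched design, lenient FDR < 0.2) is
*confirmed* when the same feature is significant in an independent
confirmation cohort (FDR < 0.05) with, by default, the same direction of
change. Confirmed hits are then split into up- and down-regulated lists
and flagged as novel unless their symbol appears in a user-supplied list
of literature-known lncRNAs.

A transcribed copy of the published worked example (49 confirmed
transcripts with both cohorts' FDRs) ships with the package; see
:func:`load_table2`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import _read_tsv, read_id_list


def _check_unique(df: pd.DataFrame, what: str) -> None:
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValidationError(f"duplicate feature id(s) in {what}: {dups[:5]}")


def confirm(
    discovery: pd.DataFrame,
    confirmation: pd.DataFrame,
    fdr_disc: float = 0.2,
    fdr_conf: float = 0.05,
    require_direction_match: bool = True,
    annotation=None,
) -> pd.DataFrame:
    """Intersect discovery and confirmation results at their thresholds.

    Both inputs need columns feature_id, log2fc, fdr (extra columns are
    ignored). Thresholds are strict (<). Features absent from the
    confirmation cohort, or with a missing FDR in either cohort, are not
    confirmed. Returns a ConfirmedHit table: feature_id, symbol,
    direction, log2fc (discovery), fdr_disc, fdr_conf, biotype, novel
    (initialised to True; see :func:`annotate_novelty`).
    """
    for df, what in ((discovery, "discovery"), (confirmation, "confirmation")):
        missing = [c for c in ("feature_id", "log2fc", "fdr") if c not in df.columns]
        if missing:
            raise ValidationError(f"{what} results missing columns: {missing}")
        _check_unique(df, what)

    d = discovery.set_index("feature_id")
    c = confirmation.set_index("feature_id")
    joined = d.join(c, how="inner", lsuffix="_disc", rsuffix="_conf")
    keep = (joined["fdr_disc"] < fdr_disc) & (joined["fdr_conf"] < fdr_conf)
    if require_direction_match:
        keep &= np.sign(joined["log2fc_disc"]) == np.sign(joined["log2fc_conf"])
    hits = joined[keep.fillna(False)]

    out = pd.DataFrame(
        {
            "feature_id": hits.index,
            "direction": np.where(hits["log2fc_disc"] > 0, "up", "down"),
            "log2fc": hits["log2fc_disc"].to_numpy(),
            "fdr_disc": hits["fdr_disc"].to_numpy(),
            "fdr_conf": hits["fdr_conf"].to_numpy(),
        }
    ).reset_index(drop=True)
    if annotation is not None:
        ann = annotation.table.set_index("feature_id")
        out["symbol"] = out["feature_id"].map(ann["symbol"])
        out["biotype"] = out["feature_id"].map(ann["biotype"])
    else:
        out["symbol"] = hits["symbol"].to_numpy() if "symbol" in hits else out["feature_id"]
        out["biotype"] = hits["biotype"].to_numpy() if "biotype" in hits else ""
    out["novel"] = True
    cols = ["feature_id", "symbol", "direction", "log2fc", "fdr_disc", "fdr_conf", "biotype", "novel"]
    return out[cols]


def partition_by_direction(hits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split confirmed hits into (up, down) by the sign of log2fc."""
    if (hits["log2fc"] == 0).any():
        bad = hits.loc[hits["log2fc"] == 0, "feature_id"].tolist()
        raise ValidationError(f"log2fc exactly 0 cannot be a hit: {bad[:5]}")
    up = hits[hits["log2fc"] > 0].reset_index(drop=True)
    down = hits[hits["log2fc"] < 0].reset_index(drop=True)
    return up, down


def annotate_novelty(hits: pd.DataFrame, known_ids: set[str]) -> pd.DataFrame:
    """Set the ``novel`` flag: novel iff symbol not in ``known_ids``.

    Matching is case-sensitive and exact on the symbol column.
    """
    out = hits.copy()
    out["novel"] = ~out["symbol"].isin(set(known_ids))
    return out


# ---------------------------------------------------------------------------
# packaged worked example
# ---------------------------------------------------------------------------


def parse_censored(value) -> float:
    """Parse a printed FDR/p token; '<x' becomes x/2 (interval midpoint).

    The midpoint stands in for comparison and sorting only — any censored
    value is below every threshold used here regardless of this choice.
    """
    s = str(value).strip()
    if s.startswith("<"):
        return float(s[1:]) / 2.0
    return float(s)


def load_table2() -> pd.DataFrame:
    """The packaged 49-row confirmed-transcript table (pre-joined cohorts).

    Columns: transcript_id, gene_id, symbol, log2fc, p_value, fdr,
    biotype, fdr_confirm. Censored '<0.001' entries are parsed per
    :func:`parse_censored`.
    """
    with resources.as_file(
        resources.files("lnckit.data").joinpath("table2.tsv")
    ) as path:
        df = _read_tsv(path, dtype=str)
    df["log2fc"] = df["log2fc"].astype(float)
    for col in ("p_value", "fdr", "fdr_confirm"):
        df[col] = df[col].map(parse_censored)
    return df


def table2_cohorts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The worked example as (discovery, confirmation) DE-result frames.

    The printed table reports only confirmed transcripts and omits the
    confirmation cohort's fold change; since confirmation there means a
    concordant change, the confirmation frame carries the discovery sign.
    """
    t2 = load_table2()
    discovery = pd.DataFrame(
        {
            "feature_id": t2["transcript_id"],
            "symbol": t2["symbol"],
            "biotype": t2["biotype"],
            "log2fc": t2["log2fc"],
            "p_value": t2["p_value"],
            "fdr": t2["fdr"],
        }
    )
    confirmation = pd.DataFrame(
        {
            "feature_id": t2["transcript_id"],
            "log2fc": np.sign(t2["log2fc"]),
            "fdr": t2["fdr_confirm"],
        }
    )
    return discovery, confirmation


def load_known_lncrnas() -> set[str]:
    """The packaged 7-symbol literature-known lncRNA list."""
    with resources.as_file(
        resources.files("lnckit.data").joinpath("known_lncrnas.txt")
    ) as path:
        return read_id_list(path)


def write_confirmed(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format="%.6g")
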