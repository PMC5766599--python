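"""On-disk artifacts: count matrices, sample sheets, annotation, gene sets.

Everything is tab-delimited UTF-8 with '.' as the decimal mark — a single
dialect, no autodetection. Readers validate aggressively and raise
structured errors; they never coerce silently. Writers and readers
round-trip exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import PairingError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Allowed values for the ``condition`` column of a sample sheet.
CONDITIONS = ("tumor", "normal")

#: Tumor-stage vocabulary. "CA" is colorectal adenoma, a pre-malignant
#: stage analysed alongside stage I–IV carcinomas; "NA" marks samples
#: (e.g. normal mucosa) with no stage.
STAGES = ("CA", "I", "II", "III", "IV", "NA")

#: Feature biotype vocabulary: the four lncRNA subtypes seen in practice
#: plus protein-coding and a catch-all.
BIOTYPES = (
    "lincRNA",
    "antisense",
    "retained_intron",
    "sense_intronic",
    "protein_coding",
    "other",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class CountMatrix:
    """Integer feature-by-sample read counts.

    Wraps a pandas DataFrame (rows = features, columns = samples) and
    enforces the invariants every downstream stage relies on: unique ids,
    non-negative integral counts.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be finite integers")
            values = values.astype(np.int64)
        if values.size and values.min() < 0:
            raise ValidationError("counts must be non-negative")
        self._df = pd.DataFrame(
            values.astype(np.int64, copy=False),
            index=counts.index.astype(str),
            columns=counts.columns.astype(str),
        )

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        """(n_features, n_samples) int64 array (a copy-on-write view)."""
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self._df.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return CountMatrix(self._df[ids])

    def subset_features(self, feature_ids: Iterable[str]) -> "CountMatrix":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self._df.index]
        if missing:
            raise ValidationError(f"features not in matrix: {missing[:5]}")
        return CountMatrix(self._df.loc[ids])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self._df.equals(other._df)

    def __repr__(self) -> str:
        f, s = self.shape
        return f"CountMatrix({f} features x {s} samples)"


class SampleSheet:
    """Sample metadata: sample_id, patient_id, condition, stage.

    In *paired mode* every patient contributes exactly one tumor and one
    normal sample; :meth:`pairs` materialises that pairing and raises
    :class:`PairingError` when it does not hold.
    """

    REQUIRED = ("sample_id", "patient_id", "condition", "stage")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = table.loc[:, list(self.REQUIRED)].astype(str).reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups[:5]}")
        bad = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad:
            raise ValidationError(
                f"unknown condition value(s) {bad}; allowed: {list(CONDITIONS)}"
            )
        bad = sorted(set(df["stage"]) - set(STAGES))
        if bad:
            raise ValidationError(
                f"unknown stage value(s) {bad}; allowed: {list(STAGES)}"
            )
        self._df = df

    @property
    def table(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df["sample_id"])

    def condition_of(self) -> pd.Series:
        return self._df.set_index("sample_id")["condition"]

    def samples_where(self, condition: str) -> list[str]:
        return list(self._df.loc[self._df["condition"] == condition, "sample_id"])

    def pairs(self) -> list[tuple[str, str, str]]:
        """Return (patient_id, tumor_sample, normal_sample) triples.

        Raises PairingError unless every patient has exactly one sample of
        each condition.
        """
        out = []
        for patient, grp in self._df.groupby("patient_id", sort=True):
            tumors = grp.loc[grp["condition"] == "tumor", "sample_id"].tolist()
            normals = grp.loc[grp["condition"] == "normal", "sample_id"].tolist()
            if len(tumors) != 1 or len(normals) != 1:
                raise PairingError(
                    f"patient {patient!r} has {len(tumors)} tumor and "
                    f"{len(normals)} normal samples; paired mode needs 1+1"
                )
            out.append((patient, tumors[0], normals[0]))
        return out

    def validate_against(self, counts: CountMatrix) -> None:
        """Cross-check: every sample in the count matrix must be in the sheet."""
        known = set(self._df["sample_id"])
        missing = [s for s in counts.sample_ids if s not in known]
        if missing:
            raise ValidationError(
                f"samples in counts but not in sample sheet: {missing[:5]}"
            )

    def __len__(self) -> int:
        return len(self._df)


class FeatureAnnotation:
    """Feature metadata: feature_id, symbol, biotype, is_lncRNA flag."""

    REQUIRED = ("feature_id", "symbol", "biotype", "is_lncRNA")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        df = table.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        df["feature_id"] = df["feature_id"].astype(str)
        df["symbol"] = df["symbol"].astype(str)
        if df["feature_id"].duplicated().any():
            dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValidationError(f"duplicate feature ids in annotation: {dups[:5]}")
        bad = sorted(set(df["biotype"].astype(str)) - set(BIOTYPES))
        if bad:
            raise ValidationError(
                f"unknown biotype value(s) {bad}; allowed: {list(BIOTYPES)}"
            )
        flags = df["is_lncRNA"]
        if flags.dtype != bool:
            mapping = {"True": True, "False": False, "1": True, "0": False}
            try:
                flags = flags.astype(str).map(lambda v: mapping[v])
            except KeyError as exc:
                raise ValidationError(f"is_lncRNA must be boolean, got {exc}") from exc
        df["is_lncRNA"] = flags.astype(bool)
        self._df = df

    @property
    def table(self) -> pd.DataFrame:
        return self._df.copy()

    def symbols(self) -> pd.Series:
        return self._df.set_index("feature_id")["symbol"]

    def is_lncrna(self) -> pd.Series:
        return self._df.set_index("feature_id")["is_lncRNA"]

    def lncrna_ids(self) -> list[str]:
        return list(self._df.loc[self._df["is_lncRNA"], "feature_id"])

    def protein_coding_ids(self) -> list[str]:
        m = (~self._df["is_lncRNA"]) & (self._df["biotype"] == "protein_coding")
        return list(self._df.loc[m, "feature_id"])


@dataclass
class GeneSetCollection:
    """Named gene sets: set_id -> unique member feature ids."""

    sets: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for set_id, members in self.sets.items():
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(str(m))
            clean[str(set_id)] = tuple(seen)
        self.sets = clean

    def members(self, set_id: str) -> tuple[str, ...]:
        if set_id not in self.sets:
            raise ValidationError(f"unknown gene set {set_id!r}")
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ValidationError(f"empty file: {path}")
    kw.setdefault("sep", "\t")
    kw.setdefault("keep_default_na", False)
    kw.setdefault("na_values", [""])
    try:
        return pd.read_csv(path, **kw)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_counts(path) -> CountMatrix:
    """Read a counts TSV (first column = feature id, header = sample ids).

    Non-integer or negative cells raise :class:`ParseError` naming the
    offending (feature, sample) cell.
    """
    df = _read_tsv(path, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    bad |= numeric.notna() & (numeric != np.floor(numeric.fillna(0)))
    bad |= df.isna()
    bad |= numeric < 0
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: cell (feature {df.index[r]!r}, sample {df.columns[c]!r}) "
            f"= {df.iat[r, c]!r} is not a non-negative integer"
        )
    return CountMatrix(numeric.astype(np.int64))


def write_counts(counts: CountMatrix, path) -> None:
    df = counts.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path, counts: CountMatrix | None = None) -> SampleSheet:
    sheet = SampleSheet(_read_tsv(path, dtype=str))
    if counts is not None:
        sheet.validate_against(counts)
    return sheet


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> FeatureAnnotation:
    return FeatureAnnotation(_read_tsv(path, dtype=str))


def write_annotation(ann: FeatureAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a two-column (feature_id, set_id) membership TSV.

    Duplicated (feature, set) rows are deduplicated with a logged warning.
    """
    df = _read_tsv(path, dtype=str)
    for col in ("feature_id", "set_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: gene-set table missing column {col!r}")
    n_before = len(df)
    df = df.drop_duplicates(subset=["feature_id", "set_id"])
    if len(df) < n_before:
        logger.warning(
            "%s: dropped %d duplicated (feature,set) rows", path, n_before - len(df)
        )
    sets = {
        set_id: tuple(grp["feature_id"])
        for set_id, grp in df.groupby("set_id", sort=True)
    }
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    rows = [
        {"feature_id": fid, "set_id": set_id}
        for set_id in collection
        for fid in collection.members(set_id)
    ]
    pd.DataFrame(rows, columns=["feature_id", "set_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_id_list(path) -> set[str]:
    """Read one id per line; blank lines and '#' comments are ignored."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    ids: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


def write_id_list(ids: Iterable[str], path) -> None:
    Path(path).write_text(
        "".join(f"{i}\n" for i in sorted(set(map(str, ids)))), encoding="utf-8"
    )
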