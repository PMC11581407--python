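"""Focal differential-abundance universe: loading, direction calls, background fractions.

The "universe" of every overlap test in this package is the set of features
(transcripts or proteins) *detected* in the focal dataset.  Each feature carries
a direction call — ``increased`` / ``decreased`` / ``unchanged`` — and the
whole-dataset fraction of increased features is the chance-level background
against which marker-list overlaps are scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIRECTIONS = ("increased", "decreased", "unchanged")

#: canonical internal column names
_COLUMNS = ["gene_id", "log2fc", "pvalue", "adj_pvalue", "direction"]

#: default schema: internal name -> expected file column
DEFAULT_SCHEMA = {
    "feature": "feature_id",
    "gene": "gene_id",
    "log2fc": "log2fc",
    "p": "pvalue",
    "padj": "adj_pvalue",
}


@dataclass
class DEDataset:
    """A detected-feature universe with direction calls.

    Parameters
    ----------
    modality : {"transcript", "protein"}
        Which molecular level the features live at.  Transcript universes are
        joined to marker lists on ``gene_id``; protein universes on the feature
        (protein-isoform) id itself.
    table : pandas.DataFrame
        Indexed by feature id (unique); columns ``gene_id``, ``log2fc``,
        ``pvalue``, ``adj_pvalue``, ``direction``.
    """

    modality: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.modality not in ("transcript", "protein"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DEDataset table missing columns: {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        bad = set(self.table["direction"]) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"invalid direction values: {sorted(bad)}")

    # -- counts ---------------------------------------------------------------

    @property
    def n_detected(self) -> int:
        return len(self.table)

    @property
    def n_increased(self) -> int:
        return int((self.table["direction"] == "increased").sum())

    @property
    def n_decreased(self) -> int:
        return int((self.table["direction"] == "decreased").sum())

    def n_direction(self, direction: str) -> int:
        _check_direction(direction)
        return int((self.table["direction"] == direction).sum())

    # -- joins ----------------------------------------------------------------

    @property
    def join_key(self) -> str:
        """Column on which marker lists are matched: genes for transcripts,
        feature ids (isoforms) for proteins."""
        return "gene_id" if self.modality == "transcript" else "feature_id"

    def detected_keys(self) -> set[str]:
        if self.modality == "transcript":
            return set(self.table["gene_id"])
        return set(self.table.index)

    def direction_keys(self, direction: str) -> set[str]:
        """Join keys of features with the given direction.  For transcript
        universes a gene counts as e.g. increased if *any* of its transcripts
        is increased."""
        _check_direction(direction)
        mask = self.table["direction"] == direction
        if self.modality == "transcript":
            return set(self.table.loc[mask, "gene_id"])
        return set(self.table.index[mask])

    def gene_ids(self, direction: str | None = None) -> set[str]:
        if direction is None:
            return set(self.table["gene_id"])
        _check_direction(direction)
        return set(self.table.loc[self.table["direction"] == direction, "gene_id"])

    # -- output ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def load_de_table(
    path,
    schema: dict[str, str] | None = None,
    modality: str = "transcript",
    sep: str = "\t",
) -> DEDataset:
    """Load a differential-abundance table into a :class:`DEDataset`.

    ``schema`` maps the internal field names (``feature``, ``gene``,
    ``log2fc``, ``p``, ``padj`` and optionally ``direction``) onto the file's
    column names.  Rows with missing statistic values are dropped with a logged
    count; duplicate feature ids are an error.  If the schema maps a
    ``direction`` column its values are taken verbatim ("as-given" mode);
    otherwise every feature starts out ``unchanged`` until
    :func:`call_directions` is applied.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep, dtype={schema["feature"]: str, schema["gene"]: str})
    required = ["feature", "gene", "log2fc", "p", "padj"]
    missing = [schema[k] for k in required if schema[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped column(s): {missing}")

    rename = {schema[k]: v for k, v in zip(required, ["feature_id"] + _COLUMNS[:4])}
    df = df.rename(columns=rename)
    df["feature_id"] = df["feature_id"].str.strip()
    df["gene_id"] = df["gene_id"].str.strip()
    if (df["feature_id"] == "").any():
        raise ValueError(f"{path}: empty feature id")

    stat_cols = ["log2fc", "pvalue", "adj_pvalue"]
    n_before = len(df)
    df = df.dropna(subset=stat_cols)
    if len(df) < n_before:
        logger.warning("%s: dropped %d rows with missing statistics", path, n_before - len(df))

    dup = df["feature_id"][df["feature_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate feature id(s): {list(dup[:5])}")

    for col in ("pvalue", "adj_pvalue"):
        vals = df[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")

    if "direction" in schema and schema["direction"] in df.columns:
        df["direction"] = df[schema["direction"]].str.strip()
    else:
        df["direction"] = "unchanged"

    df = df.set_index("feature_id")[_COLUMNS]
    return DEDataset(modality=modality, table=df)


def call_directions(
    ds: DEDataset, alpha: float = 0.05, min_abs_log2fc: float = 0.0
) -> DEDataset:
    """Flag each feature increased/decreased/unchanged from its statistics.

    A feature is ``increased`` iff adj_p <= ``alpha``, log2fc >= ``min_abs_log2fc``
    and log2fc > 0; symmetric for ``decreased``.  Idempotent: the call depends
    only on the statistic columns, never on previous flags.  Returns a new
    dataset; the input is untouched.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if min_abs_log2fc < 0:
        raise ValueError(f"min_abs_log2fc must be >= 0, got {min_abs_log2fc}")
    table = ds.table.copy()
    sig = table["adj_pvalue"].to_numpy(dtype=float) <= alpha
    lfc = table["log2fc"].to_numpy(dtype=float)
    up = sig & (lfc >= min_abs_log2fc) & (lfc > 0)
    down = sig & (lfc <= -min_abs_log2fc) & (lfc < 0)
    table["direction"] = np.where(up, "increased", np.where(down, "decreased", "unchanged"))
    return DEDataset(modality=ds.modality, table=table)


def background_fraction(ds: DEDataset, direction: str = "increased") -> float:
    """Whole-dataset fraction of features with the given direction call.

    379 increased of 10,903 detected gives 0.03476 — reported as 3.5% (one
    decimal) or 3.48% (two decimals); see :func:`format_percent`.
    """
    if ds.n_detected == 0:
        raise ValueError("background fraction of an empty dataset is undefined")
    return ds.n_direction(direction) / ds.n_detected


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percentage string, e.g. 0.03476 -> '3.5%'."""
    return f"{100.0 * fraction:.{decimals}f}%"
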