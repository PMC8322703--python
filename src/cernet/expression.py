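"""Expression-matrix ingest: reading, probe collapsing, log2 enforcement, outlier screening.

Expression tables are genes (or probes) x samples on the log2 scale, with a
two-level case/control group label per sample.  Probe-level arrays are
collapsed to gene symbols the way microarray meta-analyses conventionally do
it: probes annotated to several symbols are discarded, and symbols measured
by several probes get the per-sample mean.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Separators used by GEO platform annotation files for multi-symbol probes.
MULTI_SYMBOL_SEPARATORS = re.compile(r"///|;|,")

#: Values above this are taken as evidence the matrix is on the raw
#: (unlogged) intensity scale.  Log2 microarray data rarely exceeds ~20.
UNLOGGED_MAX_THRESHOLD = 30.0


class ExpressionError(ValueError):
    """Raised for malformed or unusable expression input."""


@dataclass
class ExpressionMatrix:
    """A genes/probes x samples log2 expression matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (probe or gene symbol) with one
        column per sample.  All entries must be finite floats.
    groups
        Mapping ``sample_id -> "case" | "control"`` covering every column.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionError(f"duplicate feature ids: {list(dupes[:5])}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ExpressionError(f"samples without a group label: {missing}")
        bad = set(self.groups.values()) - {"case", "control"}
        if bad:
            raise ExpressionError(f"group labels must be case/control, got {bad}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ExpressionError("non-finite values in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def drop_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return ExpressionMatrix(
            self.values[keep], {s: self.groups[s] for s in keep}
        )


def read_group_map(path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a dict."""
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", header=None,
                     comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ExpressionError(f"group map {path} needs two columns")
    # Tolerate a header row naming the columns.
    if df.iloc[0, 1].lower() not in {"case", "control"}:
        df = df.iloc[1:]
    return {str(r[0]): str(r[1]).lower() for r in df.itertuples(index=False)}


def read_expression_table(path, group_map) -> ExpressionMatrix:
    """Read a TSV/CSV expression table and attach case/control labels.

    ``group_map`` may be a path to a two-column file or an in-memory dict.
    Samples absent from the group map are dropped with a warning; a
    non-numeric cell raises with its 1-based row/column position.
    """
    groups = group_map if isinstance(group_map, dict) else read_group_map(group_map)
    sep = "," if str(path).removesuffix(".gz").endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & raw.notna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ExpressionError(
            f"non-numeric cell {raw.iat[i, j]!r} at row {i + 1}, column {j + 1}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionError(f"missing value at row {i + 1}, column {j + 1}")
    unlabeled = [s for s in numeric.columns if s not in groups]
    if unlabeled:
        logger.warning("dropping %d samples absent from group map: %s",
                       len(unlabeled), unlabeled)
        numeric = numeric.drop(columns=unlabeled)
    groups = {s: groups[s] for s in numeric.columns}
    for g in ("case", "control"):
        n = sum(1 for v in groups.values() if v == g)
        if n < 2:
            raise ExpressionError(
                f"group {g!r} has {n} samples; need >= 2 for a variance"
            )
    numeric.index = numeric.index.astype(str)
    return ExpressionMatrix(numeric, groups)


def read_probe_annotation(path) -> dict[str, list[str]]:
    """Read a two-column (probe_id, symbol-field) TSV.

    The symbol field may hold several symbols separated by "///", ";" or ","
    (GEO platform dialects), or be empty for unannotated probes.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                     keep_default_na=False)
    ann: dict[str, list[str]] = {}
    for probe, sym in df.itertuples(index=False):
        probe = str(probe)
        if probe in ann:
            raise ExpressionError(f"duplicate probe id {probe!r} in annotation")
        symbols = [s.strip() for s in MULTI_SYMBOL_SEPARATORS.split(str(sym))]
        ann[probe] = [s for s in symbols if s]
    return ann


def collapse_probes(m: ExpressionMatrix,
                    annotation: dict[str, list[str]]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to unique gene symbols.

    Probes mapping to zero or multiple symbols are eliminated; symbols with
    several remaining probes get the per-sample arithmetic mean.
    """
    symbol_of: dict[str, str] = {}
    for probe in m.feature_ids:
        symbols = annotation.get(probe, [])
        if len(symbols) == 1:
            symbol_of[probe] = symbols[0]
    if not symbol_of:
        raise ExpressionError("no probe maps to exactly one gene symbol")
    kept = m.values.loc[list(symbol_of)]
    collapsed = kept.groupby([symbol_of[p] for p in kept.index]).mean()
    collapsed.index = collapsed.index.astype(str)
    return ExpressionMatrix(collapsed, dict(m.groups))


def ensure_log2(m: ExpressionMatrix,
                max_threshold: float = UNLOGGED_MAX_THRESHOLD) -> ExpressionMatrix:
    """Apply log2(x+1) when the matrix looks unlogged (max > threshold).

    Idempotent: data already on the log2 scale is returned unchanged.  Raw
    intensity scales are non-negative, so negative entries alongside a large
    maximum indicate a corrupt table and raise.
    """
    vals = m.values.to_numpy()
    if vals.max(initial=-np.inf) <= max_threshold:
        logger.info("expression values within log2 range; no transform")
        return m
    if (vals < 0).any():
        raise ExpressionError(
            "negative values in apparently unlogged data (max "
            f"{vals.max():.1f} > {max_threshold})"
        )
    logger.info("max value %.1f > %.0f; applying log2(x+1)",
                vals.max(), max_threshold)
    return ExpressionMatrix(np.log2(m.values + 1.0), dict(m.groups))


def detect_outlier_samples(m: ExpressionMatrix, k_mads: float = 3.0) -> list[str]:
    """Flag heterogeneous samples by their mean inter-sample correlation.

    Each sample's mean Pearson correlation with all other samples is
    computed; samples more than ``k_mads`` median-absolute-deviations below
    the median of those means are flagged.  Constant (zero-variance) samples
    are flagged unconditionally.  The caller decides whether to drop them.
    """
    if m.values.shape[1] < 4:
        raise ExpressionError("need >= 4 samples to screen for outliers")
    vals = m.values.to_numpy()
    sds = vals.std(axis=0)
    constant = [s for s, sd in zip(m.sample_ids, sds) if sd == 0]
    for s in constant:
        logger.warning("sample %s is constant; flagged as outlier", s)
    ok = [i for i, sd in enumerate(sds) if sd > 0]
    flagged = list(constant)
    if len(ok) >= 3:
        corr = np.corrcoef(vals[:, ok].T)
        np.fill_diagonal(corr, np.nan)
        mean_corr = np.nanmean(corr, axis=1)
        med = np.median(mean_corr)
        # 1.4826 makes the MAD a consistent sigma estimate, so k_mads is a
        # robust z-score threshold
        mad = 1.4826 * np.median(np.abs(mean_corr - med))
        if mad > 0:
            low = mean_corr < med - k_mads * mad
            flagged += [m.sample_ids[ok[i]] for i in np.nonzero(low)[0]]
    return sorted(set(flagged), key=m.sample_ids.index)
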