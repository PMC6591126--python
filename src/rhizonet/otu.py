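"""OTU table input/output, validation, filtering, and rarefaction.

Tables are plain pandas DataFrames:

* counts: samples x OTUs, non-negative integers, index = sample ids.
* taxonomy: OTUs x ranks (kingdom..genus), index = OTU ids.
* metadata: samples x covariates, index = sample ids; must include a
  ``system`` column with the management-group label.

On disk all three are tab-separated with the index in the first column
(samples as rows for the count table; a transpose flag supports the
OTU-as-rows dialect).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_taxonomy",
    "read_metadata",
    "validate_counts",
    "filter_low_abundance",
    "prevalence_filter",
    "rarefy",
    "relative_abundance",
]

TAXONOMY_RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]


class EmptyTableError(ValueError):
    """A filter removed every OTU (or sample) from the table."""


def validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("duplicate sample or OTU identifiers")
    if (table.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return table


def read_counts(path, transpose: bool = False) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        table = table.T
    return validate_counts(table.astype(np.int64))


def write_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    missing = [r for r in TAXONOMY_RANKS if r not in tax.columns]
    if missing:
        raise ValueError(f"taxonomy table missing ranks: {missing}")
    return tax


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0)
    if "system" not in md.columns:
        raise ValueError("metadata must contain a 'system' column")
    return md


def _check_nonempty(table: pd.DataFrame, what: str) -> pd.DataFrame:
    if table.shape[1] == 0:
        raise EmptyTableError(f"{what} removed every OTU")
    return table


def filter_low_abundance(
    table: pd.DataFrame,
    global_frac: float = 0.001,
    sample_frac: float = 0.005,
    mode: str = "and",
) -> pd.DataFrame:
    """Drop rare OTUs by joint global and within-sample abundance thresholds.

    An OTU is removed iff its fraction of total reads across all samples is
    below ``global_frac`` AND its within-sample fraction is below
    ``sample_frac`` in every sample (``mode="or"`` removes on either
    condition alone). Column order of survivors is preserved.
    """
    if not (0 <= global_frac < 1 and 0 <= sample_frac < 1):
        raise ValueError("thresholds must be in [0, 1)")
    X = table.to_numpy(dtype=float)
    total = X.sum()
    if total == 0:
        raise EmptyTableError("table has no reads")
    global_ok = X.sum(axis=0) / total >= global_frac
    row_sums = X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(row_sums > 0, X / row_sums, 0.0)
    sample_ok = (frac >= sample_frac).any(axis=0)
    if mode == "and":
        keep = global_ok | sample_ok  # removed iff fails both
    elif mode == "or":
        keep = global_ok & sample_ok
    else:
        raise ValueError("mode must be 'and' or 'or'")
    return _check_nonempty(table.loc[:, keep], "abundance filter")


def prevalence_filter(table: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Keep OTUs with nonzero counts in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    keep = (table.to_numpy() > 0).sum(axis=0) >= min_samples
    return _check_nonempty(table.loc[:, keep], "prevalence filter")


def rarefy(table: pd.DataFrame, depth: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Subsample each sample's reads to a common depth without replacement.

    Every rarefied row sums exactly to ``depth``; a sample with fewer reads
    than ``depth`` raises an error naming it, so the caller may drop it.
    """
    rng = np.random.default_rng(seed)
    X = table.to_numpy(dtype=np.int64)
    out = np.zeros_like(X)
    for i, sample in enumerate(table.index):
        total = int(X[i].sum())
        if total < depth:
            raise ValueError(
                f"sample {sample!r} has {total} reads, fewer than depth {depth}"
            )
        if total == depth:
            out[i] = X[i]
            continue
        # multivariate hypergeometric draw
        out[i] = rng.multivariate_hypergeometric(X[i], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to fractions summing to 1 per sample."""
    X = table.to_numpy(dtype=float)
    row_sums = X.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        bad = table.index[row_sums.ravel() == 0].tolist()
        raise ValueError(f"zero-sum sample(s): {bad}")
    return pd.DataFrame(X / row_sums, index=table.index, columns=table.columns)
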