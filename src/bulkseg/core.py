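"""SNP-index, Delta(SNP-index) and the per-locus filters.

The SNP-index of a bulk at one site is the fraction of that bulk's reads
carrying the restorer-parent allele: 0 when every read matches the CMS
parent, 1 when every read matches the restorer parent, ~0.5 at loci
unlinked to the trait.  Delta(SNP-index) subtracts the SM-bulk index from
the FR-bulk index; it drifts toward +1 where the restorer parent's allele
is enriched in the fertile bulk.

Locus filters (defaults follow standard QTL-seq practice): a site is
dropped when either bulk's read depth is below 7, or when the index is
below 0.3 in both bulks, or above 0.7 in both bulks — both-extreme sites
are uninformative (typically mis-called or monomorphic loci), while
contrasting sites are the signal of interest and are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "snp_index",
    "delta_index",
    "compute_indices",
    "apply_locus_filters",
    "LocusFilterCounts",
]


def snp_index(restorer_reads: int, other_reads: int) -> float:
    """Fraction of reads carrying the restorer-parent allele at one site."""
    if restorer_reads < 0 or other_reads < 0:
        raise DataError("negative read counts")
    total = restorer_reads + other_reads
    if total == 0:
        raise DataError("SNP-index undefined at zero depth; filter such sites upstream")
    return restorer_reads / total


def delta_index(fr_index: float, sm_index: float) -> float:
    """Delta(SNP-index): FR-bulk index minus SM-bulk index, in [-1, 1]."""
    return fr_index - sm_index


def compute_indices(sites: pd.DataFrame) -> pd.DataFrame:
    """Add per-bulk depths, SNP-indices and delta to an oriented site table.

    Zero-depth bulks yield NaN indices; such sites must be removed by the
    depth filter before any downstream averaging.
    """
    out = sites.copy()
    fr_depth = out["fr_restorer"].to_numpy() + out["fr_other"].to_numpy()
    sm_depth = out["sm_restorer"].to_numpy() + out["sm_other"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        fr_index = np.where(fr_depth > 0, out["fr_restorer"].to_numpy() / np.maximum(fr_depth, 1), np.nan)
        sm_index = np.where(sm_depth > 0, out["sm_restorer"].to_numpy() / np.maximum(sm_depth, 1), np.nan)
    out["fr_depth"] = fr_depth
    out["sm_depth"] = sm_depth
    out["fr_index"] = fr_index
    out["sm_index"] = sm_index
    out["delta"] = fr_index - sm_index
    return out


@dataclass
class LocusFilterCounts:
    """Accounting of the per-locus filters."""

    retained: int = 0
    low_depth: int = 0
    both_low_index: int = 0
    both_high_index: int = 0

    @property
    def total(self) -> int:
        return self.retained + self.low_depth + self.both_low_index + self.both_high_index


def apply_locus_filters(
    records: pd.DataFrame,
    min_depth: int = 7,
    low: float = 0.3,
    high: float = 0.7,
) -> tuple[pd.DataFrame, LocusFilterCounts]:
    """Drop low-depth and both-extreme sites from an indexed record table.

    A site is removed when (a) either bulk's depth is below `min_depth`
    (strict <, so depth exactly 7 passes the default), or (b) both bulks'
    indices are below `low`, or (c) both are above `high`.  The depth rule
    runs first, so indices of the surviving sites are always defined.
    Returns the retained records and per-rule discard counts.
    """
    if min_depth < 1:
        raise ConfigError("min_depth must be >= 1 (zero-depth sites have no index)")
    if not 0 <= low < high <= 1:
        raise ConfigError(f"index thresholds must satisfy 0 <= low < high <= 1, got {low}, {high}")
    counts = LocusFilterCounts()
    fr_depth = records["fr_depth"].to_numpy()
    sm_depth = records["sm_depth"].to_numpy()
    fr = records["fr_index"].to_numpy()
    sm = records["sm_index"].to_numpy()

    low_depth = (fr_depth < min_depth) | (sm_depth < min_depth)
    both_low = ~low_depth & (fr < low) & (sm < low)
    both_high = ~low_depth & (fr > high) & (sm > high)
    counts.low_depth = int(low_depth.sum())
    counts.both_low_index = int(both_low.sum())
    counts.both_high_index = int(both_high.sum())
    kept = records.loc[~(low_depth | both_low | both_high)].reset_index(drop=True)
    counts.retained = len(kept)
    return kept, counts
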