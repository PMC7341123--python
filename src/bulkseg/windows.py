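"""Sliding-window averaging, Monte-Carlo null bands and region calling.

Window scan
-----------
SNP-index and Delta(SNP-index) are averaged in windows of fixed physical
span (default 5 Mb) advanced by a fixed increment (default 10 kb).
Windows are anchored at 0-based multiples of the step; a site at 1-based
position p belongs to window [s, s + W) iff s <= p - 1 < s + W.  Empty
windows are omitted — nothing can be averaged there.

Null confidence bands
---------------------
Under the no-QTL null each bulk chromosome carries the restorer allele
independently (probability 1/2 in an F2 design), so the bulk allele
frequency is Binomial(2n, 1/2)/(2n) and the observed index at read depth
d is Binomial(d, p)/d.  For each tabulated depth, Delta replicates are
simulated and empirical quantiles form the band.  Because the index at
finite depth is discrete, the replicates receive a per-bulk uniform
continuity correction of width 1/d before the quantiles are taken
(configurable off): bands built this way attain their nominal exceedance
when the same correction is applied to an observed statistic (see
`band_exceedance`), the randomized-test device standard for discrete
statistics.  Window means average many sites and are compared to the
bands directly, without dithering.

Region calling
--------------
Windows whose mean delta exceeds the band at the chosen level are merged
when overlapping or separated by at most `max_gap`; short regions are
discarded; the peak is the member window with the largest |mean delta|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .rng import substream

__all__ = [
    "WindowStat",
    "NullCiTable",
    "CandidateRegion",
    "sliding_windows",
    "null_ci",
    "attach_ci",
    "call_regions",
    "band_exceedance",
    "regions_to_bed",
    "DEFAULT_DEPTH_GRID",
]

#: Depths at which the null band is tabulated; bands change slowly above
#: 100x, so the grid thins out and values are clamped at its ends.
DEFAULT_DEPTH_GRID = tuple(range(7, 101)) + (120, 150, 200)


@dataclass(frozen=True)
class WindowStat:
    """One sliding-window summary (row-object view of the windows table)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_fr: float
    mean_sm: float
    mean_delta: float
    ci95_lo: float = np.nan
    ci95_hi: float = np.nan
    ci99_lo: float = np.nan
    ci99_hi: float = np.nan


def _window_means(
    sites: pd.DataFrame, value_cols: Sequence[str], window: int, step: int
) -> pd.DataFrame:
    """Per-window unweighted means of `value_cols` via prefix sums."""
    frames = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1  # 0-based
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        vals = {c: grp[c].to_numpy()[order] for c in value_cols}
        last = int(pos0[-1])
        starts = np.arange(0, last + 1, step, dtype=np.int64)
        left = np.searchsorted(pos0, starts, side="left")
        right = np.searchsorted(pos0, starts + window, side="left")
        n = right - left
        keep = n > 0
        starts, left, right, n = starts[keep], left[keep], right[keep], n[keep]
        cols = {
            "chrom": np.repeat(chrom, starts.size),
            "start": starts,
            "end": starts + window,
            "n_snps": n,
        }
        for c in value_cols:
            csum = np.concatenate([[0.0], np.cumsum(vals[c])])
            cols[f"mean_{c}"] = (csum[right] - csum[left]) / n
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps"] + [f"mean_{c}" for c in value_cols])
    return pd.concat(frames, ignore_index=True)


def sliding_windows(records: pd.DataFrame, window: int = 5_000_000, step: int = 10_000) -> pd.DataFrame:
    """Average fr_index, sm_index and delta in sliding windows.

    `records` must be filtered, indexed sites sorted by (chrom, pos).
    Returns one row per non-empty window: chrom, start (0-based), end
    (half-open), n_snps, mean_fr, mean_sm, mean_delta.
    """
    if window <= 0:
        raise ConfigError(f"window must be > 0, got {window}")
    if step <= 0:
        raise ConfigError(f"step must be > 0, got {step}")
    df = _window_means(records, ["fr_index", "sm_index", "delta"], window, step)
    return df.rename(
        columns={"mean_fr_index": "mean_fr", "mean_sm_index": "mean_sm", "mean_delta": "mean_delta"}
    )


def _null_freq(design: str, n_bulk: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Bulk restorer-allele frequency under the no-QTL null."""
    if design == "F2":
        # each of the 2n bulk chromosomes is restorer-type w.p. 1/2
        return rng.binomial(2 * n_bulk, 0.5, size=reps) / (2 * n_bulk)
    if design == "BC1":
        # one founder chromosome per plant plus one segregating gamete
        return rng.binomial(n_bulk, 0.5, size=reps) / (2 * n_bulk)
    raise ConfigError(f"unsupported design {design!r} (expected 'F2' or 'BC1')")


@dataclass
class NullCiTable:
    """Depth-indexed quantile bands of Delta(SNP-index) under no QTL.

    `table` is indexed by read depth with columns lo_95/hi_95/lo_99/hi_99
    (one lo/hi pair per confidence level).
    """

    design: str
    n_bulk: int
    levels: tuple[float, ...]
    reps: int
    seed: int
    continuity: bool
    table: pd.DataFrame = field(repr=False)

    def column(self, level: float, side: str) -> str:
        return f"{side}_{round(level * 100):d}"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# null-ci design={self.design} n_bulk={self.n_bulk} reps={self.reps} "
                f"seed={self.seed} continuity={self.continuity} "
                f"levels={','.join(str(l) for l in self.levels)}\n"
            )
            self.table.round(6).to_csv(fh, sep="\t", index=True, index_label="depth")

    @classmethod
    def from_tsv(cls, path) -> "NullCiTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline()
        for tok in header.lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        table = pd.read_csv(path, sep="\t", comment="#", index_col="depth")
        levels = tuple(float(x) for x in meta.get("levels", "0.95,0.99").split(","))
        return cls(
            design=meta.get("design", "F2"),
            n_bulk=int(meta.get("n_bulk", 30)),
            levels=levels,
            reps=int(meta.get("reps", 0)),
            seed=int(meta.get("seed", 0)),
            continuity=meta.get("continuity", "True") == "True",
            table=table,
        )


def null_ci(
    design: str = "F2",
    n_bulk: int = 30,
    depths: Sequence[int] = DEFAULT_DEPTH_GRID,
    levels: Sequence[float] = (0.95, 0.99),
    reps: int = 10_000,
    seed: int = 0,
    continuity: bool = True,
    rng: np.random.Generator | None = None,
) -> NullCiTable:
    """Simulate the no-QTL null band of Delta(SNP-index) per read depth.

    For each depth d, `reps` replicates draw an independent bulk frequency
    p per bulk, an observed index Binomial(d, p)/d per bulk, and record
    empirical quantiles of the difference at each confidence level.
    """
    if reps < 1000:
        raise ConfigError(f"reps must be >= 1000 for stable quantiles, got {reps}")
    if n_bulk < 1:
        raise ConfigError("n_bulk must be >= 1")
    depths = sorted(set(int(d) for d in depths))
    if not depths or depths[0] < 1:
        raise ConfigError("depths must be positive")
    rng = rng if rng is not None else substream(seed, "null-ci")
    rows = {}
    for d in depths:
        deltas = []
        for _bulk in range(2):
            p = _null_freq(design, n_bulk, reps, rng)
            index = rng.binomial(d, p) / d
            if continuity:
                index = index + rng.uniform(-0.5 / d, 0.5 / d, size=reps)
            deltas.append(index)
        delta = deltas[0] - deltas[1]
        row = {}
        for level in levels:
            a = (1 - level) / 2
            lo, hi = np.quantile(delta, [a, 1 - a])
            row[f"lo_{round(level * 100):d}"] = lo
            row[f"hi_{round(level * 100):d}"] = hi
        rows[d] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "depth"
    return NullCiTable(
        design=design,
        n_bulk=n_bulk,
        levels=tuple(levels),
        reps=reps,
        seed=seed,
        continuity=continuity,
        table=table,
    )


def _site_bounds(
    records: pd.DataFrame, ci_table: NullCiTable, depth_rule: str = "min"
) -> pd.DataFrame:
    """Per-site band bounds at each site's effective depth (interpolated)."""
    if ci_table.table.empty:
        raise DataError("empty null-CI table")
    fr = records["fr_depth"].to_numpy(dtype=float)
    sm = records["sm_depth"].to_numpy(dtype=float)
    if depth_rule == "min":
        eff = np.minimum(fr, sm)
    elif depth_rule == "mean":
        eff = (fr + sm) / 2
    else:
        raise ConfigError(f"unknown depth rule {depth_rule!r} (expected 'min' or 'mean')")
    grid = ci_table.table.index.to_numpy(dtype=float)
    eff = np.clip(eff, grid[0], grid[-1])
    out = {}
    for col in ci_table.table.columns:
        out[col] = np.interp(eff, grid, ci_table.table[col].to_numpy())
    return pd.DataFrame(out, index=records.index)


def attach_ci(
    windows: pd.DataFrame,
    records: pd.DataFrame,
    ci_table: NullCiTable,
    window: int = 5_000_000,
    step: int = 10_000,
    depth_rule: str = "min",
) -> pd.DataFrame:
    """Attach null-band bounds to each window.

    Each member site gets bounds at its own effective depth (default the
    smaller of its two bulk depths, clamped to the tabulated range, with
    linear interpolation between tabulated depths); the window's band is
    the mean of its member-site bounds.  `window`/`step` must match the
    values used to build `windows`.
    """
    bounds = _site_bounds(records, ci_table, depth_rule)
    aug = pd.concat(
        [records[["chrom", "pos"]].reset_index(drop=True), bounds.reset_index(drop=True)], axis=1
    )
    wb = _window_means(aug, list(bounds.columns), window, step)
    ren = {f"mean_{c}": c.replace("lo_", "ci_lo_").replace("hi_", "ci_hi_") for c in bounds.columns}
    wb = wb.rename(columns=ren).drop(columns=["n_snps", "end"])
    merged = windows.merge(wb, on=["chrom", "start"], how="left", validate="one_to_one")
    return merged


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of significant windows."""

    chrom: str
    start: int
    end: int
    peak_delta: float
    peak_position: int
    n_windows: int
    level: float


def call_regions(
    windows: pd.DataFrame,
    level: float = 0.95,
    tail: str = "upper",
    min_span: int = 1_000_000,
    max_gap: int = 10_000,
) -> list[CandidateRegion]:
    """Extract candidate regions from band-annotated windows.

    Windows with mean_delta beyond the band at `level` ('upper' tail for a
    restorer-parent QTL; 'lower' for the opposite direction) are merged
    when overlapping or separated by at most `max_gap` bp; merged regions
    shorter than `min_span` are discarded.  Region bounds are the min
    start / max end of member windows; the peak is the member window with
    the largest |mean_delta| (its centre is reported as peak_position).
    """
    lo_col = f"ci_lo_{round(level * 100):d}"
    hi_col = f"ci_hi_{round(level * 100):d}"
    if hi_col not in windows.columns:
        raise ConfigError(f"windows carry no band at level {level} (missing column {hi_col})")
    if tail == "upper":
        sig = windows["mean_delta"].to_numpy() > windows[hi_col].to_numpy()
    elif tail == "lower":
        sig = windows["mean_delta"].to_numpy() < windows[lo_col].to_numpy()
    else:
        raise ConfigError(f"unknown tail {tail!r}")
    hits = windows.loc[sig].sort_values(["chrom", "start"], kind="stable")
    regions: list[CandidateRegion] = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        deltas = grp["mean_delta"].to_numpy()
        i = 0
        while i < len(grp):
            j = i
            cur_end = ends[i]
            while j + 1 < len(grp) and starts[j + 1] <= cur_end + max_gap:
                j += 1
                cur_end = max(cur_end, ends[j])
            block = slice(i, j + 1)
            span_start = int(starts[i])
            span_end = int(cur_end)
            if span_end - span_start >= min_span:
                k = i + int(np.argmax(np.abs(deltas[block])))
                width = int(ends[k] - starts[k])
                regions.append(
                    CandidateRegion(
                        chrom=str(chrom),
                        start=span_start,
                        end=span_end,
                        peak_delta=float(deltas[k]),
                        peak_position=int(starts[k]) + width // 2,
                        n_windows=j - i + 1,
                        level=level,
                    )
                )
            i = j + 1
    return regions


def band_exceedance(
    records: pd.DataFrame,
    ci_table: NullCiTable,
    level: float = 0.95,
    depth_rule: str = "min",
    dither: bool = True,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of sites whose per-SNP delta falls outside the band.

    Calibration diagnostic: on null data the expected value is 1 - level.
    When the table was built with the continuity correction, the observed
    deltas receive the same per-bulk uniform dither here so the discrete
    statistic is compared to the band on equal terms.
    """
    bounds = _site_bounds(records, ci_table, depth_rule)
    delta = records["delta"].to_numpy(dtype=float)
    if dither and ci_table.continuity:
        rng = rng if rng is not None else substream(seed, "exceedance-dither")
        for col in ("fr_depth", "sm_depth"):
            d = records[col].to_numpy(dtype=float)
            delta = delta + rng.uniform(-0.5 / d, 0.5 / d)
    lo = bounds[f"lo_{round(level * 100):d}"].to_numpy()
    hi = bounds[f"hi_{round(level * 100):d}"].to_numpy()
    return float(((delta > hi) | (delta < lo)).mean())


def regions_to_bed(regions: Sequence[CandidateRegion], path) -> None:
    """Write regions as BED (0-based half-open) with the peak delta as score."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t{r.peak_delta:.4f}\n")
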