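"""End-to-end QTL-seq run: variant table -> sites -> windows -> regions.

`run_qtlseq` wires the stages together with the study defaults (parent
depth > 5x, bulk depth >= 7, both-extreme index filter at 0.3/0.7, 5-Mb
window / 10-kb step, Monte-Carlo null bands at 95%/99%, F2 design with
30-plant bulks) and writes a per-SNP TSV, a per-window TSV with band
bounds, a candidate-region BED and, optionally, the three-panel index
plot.  All thresholds live in `RunConfig`, which round-trips to YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import core, variant_io, windows
from .errors import DataError
from .windows import NullCiTable

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "QtlseqResult", "run_qtlseq"]


@dataclass
class RunConfig:
    """All knobs of a QTL-seq run; defaults follow the study design."""

    variants: str = ""
    outdir: str = "qtlseq_out"
    fmt: str | None = None  # 'vcf' | 'tsv' | None (infer)
    sample_map: dict = field(default_factory=lambda: dict(variant_io.DEFAULT_SAMPLE_MAP))

    min_parent_depth: int = 5
    require_pass: bool = True
    snps_only: bool = True

    min_depth: int = 7
    index_low: float = 0.3
    index_high: float = 0.7

    window: int = 5_000_000
    step: int = 10_000

    design: str = "F2"
    bulk_size: int = 30
    ci_levels: tuple[float, ...] = (0.95, 0.99)
    ci_reps: int = 10_000
    depth_rule: str = "min"

    region_level: float = 0.95
    tail: str = "upper"
    min_span: int = 1_000_000
    max_gap: int = 10_000

    seed: int = 0
    make_plots: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["ci_levels"] = list(self.ci_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            from .errors import ConfigError

            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ci_levels" in d:
            d["ci_levels"] = tuple(d["ci_levels"])
        return cls(**d)


@dataclass
class QtlseqResult:
    """In-memory results plus paths of everything written."""

    sites: pd.DataFrame
    records: pd.DataFrame
    selection_counts: variant_io.SelectionCounts
    filter_counts: core.LocusFilterCounts
    window_table: pd.DataFrame
    regions: list
    ci_table: NullCiTable
    paths: dict


def run_qtlseq(config: RunConfig, ci_table: NullCiTable | None = None) -> QtlseqResult:
    """Execute the full scan and write site/window/region outputs.

    A precomputed `ci_table` (e.g. shared across replicate runs) bypasses
    the Monte-Carlo band simulation.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    raw = variant_io.read_variants(config.variants, fmt=config.fmt, sample_map=config.sample_map)
    sites, sel_counts = variant_io.select_informative(
        raw,
        min_parent_depth=config.min_parent_depth,
        require_pass=config.require_pass,
        snps_only=config.snps_only,
    )
    records = core.compute_indices(sites)
    records, flt_counts = core.apply_locus_filters(
        records, min_depth=config.min_depth, low=config.index_low, high=config.index_high
    )
    if records.empty:
        raise DataError(
            "no sites survive the filters: "
            f"selection {sel_counts}, locus filters {flt_counts} "
            f"(check bulk coverage against the depth filter min_depth={config.min_depth})"
        )

    if ci_table is None:
        ci_table = windows.null_ci(
            design=config.design,
            n_bulk=config.bulk_size,
            levels=config.ci_levels,
            reps=config.ci_reps,
            seed=config.seed,
        )
    win = windows.sliding_windows(records, window=config.window, step=config.step)
    win = windows.attach_ci(
        win,
        records,
        ci_table,
        window=config.window,
        step=config.step,
        depth_rule=config.depth_rule,
    )
    regions = windows.call_regions(
        win,
        level=config.region_level,
        tail=config.tail,
        min_span=config.min_span,
        max_gap=config.max_gap,
    )

    paths = {
        "sites": outdir / "sites.tsv",
        "windows": outdir / "windows.tsv",
        "regions": outdir / "regions.bed",
        "ci": outdir / "null_ci.tsv",
    }
    # 1-based inclusive coordinates in TSVs, 0-based half-open in BED
    records.to_csv(paths["sites"], sep="\t", index=False, float_format="%.6f")
    win_out = win.copy()
    win_out["start"] = win_out["start"] + 1
    win_out.to_csv(paths["windows"], sep="\t", index=False, float_format="%.6f")
    windows.regions_to_bed(regions, paths["regions"])
    ci_table.to_tsv(paths["ci"])

    if config.make_plots:
        from .plotting import plot_index_tracks

        paths.update(plot_index_tracks(win, outdir / "index_tracks", levels=config.ci_levels))

    logger.info(
        "qtlseq run: %d raw records, %d informative, %d after locus filters, "
        "%d windows, %d candidate regions",
        sel_counts.total,
        sel_counts.retained,
        flt_counts.retained,
        len(win),
        len(regions),
    )
    return QtlseqResult(
        sites=sites,
        records=records,
        selection_counts=sel_counts,
        filter_counts=flt_counts,
        window_table=win,
        regions=regions,
        ci_table=ci_table,
        paths=paths,
    )
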