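"""Reading the four-sample variant table and selecting informative sites.

The pipeline consumes a variant table with two inbred parents (P1 =
restorer-carrying parent, P2 = CMS/maintainer parent) and two extreme
bulks (FR = fertility restored, SM = sterility maintained), either as a
VCF v4.2 with GT/DP/AD FORMAT fields (the shape a GATK-style caller
produces) or as the flat TSV dialect the simulator emits.

Two stages:

1. `read_variants` parses the file into a raw per-site DataFrame with
   per-sample allele depths, checking (chrom, pos) sort order.
2. `select_informative` keeps sites where both parents are homozygous for
   opposite alleles with depth above a threshold (default: strictly more
   than 5 reads per parent), and orients every retained site to the
   restorer-parent allele.  Counts of discarded sites are reported per
   reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "SITE_COLUMNS",
    "SelectionCounts",
    "read_variants",
    "select_informative",
    "write_sites_tsv",
]

#: Columns of the oriented informative-site table ("VariantSite" records).
SITE_COLUMNS = [
    "chrom",
    "pos",
    "restorer_allele",
    "other_allele",
    "p1_depth",
    "p2_depth",
    "fr_restorer",
    "fr_other",
    "sm_restorer",
    "sm_other",
]

# raw genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing
_RAW_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "p1_gt",
    "p2_gt",
    "p1_depth",
    "p2_depth",
    "fr_ref",
    "fr_alt",
    "sm_ref",
    "sm_alt",
    "filter_pass",
    "is_snp",
]

DEFAULT_SAMPLE_MAP = {"P1": "P1", "P2": "P2", "FR": "FR", "SM": "SM"}


def _check_sorted(df: pd.DataFrame) -> None:
    """Require ascending (chrom, pos) with chromosomes in blocks."""
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    seen: dict[str, int] = {}
    last_chrom = None
    last_pos = -1
    for i in range(len(df)):
        c = chrom[i]
        if c != last_chrom:
            if c in seen:
                raise DataError(
                    f"input not sorted: chromosome {c} reappears at record {i + 1} "
                    f"({c}:{pos[i]})"
                )
            seen[c] = i
            last_chrom = c
            last_pos = -1
        if pos[i] <= last_pos:
            raise DataError(f"input not sorted: out-of-order position {c}:{pos[i]}")
        last_pos = pos[i]


def _gt_code(alleles: list[int]) -> int:
    a = [x for x in alleles[:2] if isinstance(x, (int, np.integer))]
    if len(a) < 2 or any(x < 0 for x in a):
        return -1
    if a[0] == a[1]:
        return 0 if a[0] == 0 else (2 if a[0] == 1 else -1)
    return 1


def _read_vcf(path, sample_map: dict[str, str]) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    try:
        idx = {role: samples.index(sample_map[role]) for role in ("P1", "P2", "FR", "SM")}
    except ValueError as exc:
        raise ConfigError(
            f"sample map {sample_map} does not match VCF samples {samples}: {exc}"
        ) from None

    rows = []
    n_malformed = 0
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            # multi-allelic or monomorphic record: keep as non-SNP so the
            # selection stage counts it
            rows.append(
                (v.CHROM, v.POS, v.REF, v.ALT[0] if v.ALT else ".", -1, -1, 0, 0, 0, 0, 0, 0,
                 v.FILTER is None, False)
            )
            continue
        ad = v.format("AD")
        if ad is None:
            n_malformed += 1
            logger.warning("record %d (%s:%d): missing AD field, skipped", k + 1, v.CHROM, v.POS)
            continue
        ad = np.where(ad < 0, 0, ad)
        gts = v.genotypes
        p1 = idx["P1"]
        p2 = idx["P2"]
        fr = idx["FR"]
        sm = idx["SM"]
        is_snp = len(v.REF) == 1 and len(v.ALT[0]) == 1
        rows.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                v.ALT[0],
                _gt_code(gts[p1]),
                _gt_code(gts[p2]),
                int(ad[p1, 0] + ad[p1, 1]),
                int(ad[p2, 0] + ad[p2, 1]),
                int(ad[fr, 0]),
                int(ad[fr, 1]),
                int(ad[sm, 0]),
                int(ad[sm, 1]),
                v.FILTER is None,
                is_snp,
            )
        )
    if n_malformed:
        logger.warning("%d malformed records skipped", n_malformed)
    df = pd.DataFrame(rows, columns=_RAW_COLUMNS)
    return df


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "chrom",
        "pos",
        "p1_allele",
        "p2_allele",
        "fr_restorer_depth",
        "fr_other_depth",
        "sm_restorer_depth",
        "sm_other_depth",
    }
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"TSV is missing required columns: {sorted(missing)}")
    if "p1_depth" not in df.columns or "p2_depth" not in df.columns:
        # dialect without parent depths: parents taken as deeply covered
        logger.warning("TSV has no parent depth columns; assuming deep parental coverage")
        df["p1_depth"] = np.iinfo(np.int32).max
        df["p2_depth"] = np.iinfo(np.int32).max
    # normalize to the raw schema with REF = restorer-parent allele
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(np.int64),
            "ref": df["p1_allele"].astype(str),
            "alt": df["p2_allele"].astype(str),
            "p1_gt": 0,
            "p2_gt": 2,
            "p1_depth": df["p1_depth"].astype(np.int64),
            "p2_depth": df["p2_depth"].astype(np.int64),
            "fr_ref": df["fr_restorer_depth"].astype(np.int64),
            "fr_alt": df["fr_other_depth"].astype(np.int64),
            "sm_ref": df["sm_restorer_depth"].astype(np.int64),
            "sm_alt": df["sm_other_depth"].astype(np.int64),
            "filter_pass": True,
            "is_snp": (df["p1_allele"].str.len() == 1) & (df["p2_allele"].str.len() == 1),
        }
    )
    return out


def read_variants(path, fmt: str | None = None, sample_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Parse a variant table into raw per-site records.

    `fmt` is 'vcf' or 'tsv'; inferred from the file suffix when None.
    `sample_map` names which VCF sample plays each of P1/P2/FR/SM.
    The result is checked for ascending (chrom, pos) order.
    """
    if fmt is None:
        s = str(path)
        if s.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif s.endswith((".tsv", ".txt", ".tab")):
            fmt = "tsv"
        else:
            raise ConfigError(f"cannot infer format from {s!r}; pass fmt='vcf' or 'tsv'")
    if fmt == "vcf":
        df = _read_vcf(path, dict(DEFAULT_SAMPLE_MAP, **(sample_map or {})))
    elif fmt == "tsv":
        df = _read_tsv(path)
    else:
        raise ConfigError(f"unknown format {fmt!r}")
    _check_sorted(df)
    return df


@dataclass
class SelectionCounts:
    """Accounting of the parental-informativeness selection."""

    retained: int = 0
    not_biallelic_snp: int = 0
    failed_filter: int = 0
    missing_parent_genotype: int = 0
    het_parent: int = 0
    same_allele: int = 0
    low_parent_depth: int = 0

    @property
    def total(self) -> int:
        return (
            self.retained
            + self.not_biallelic_snp
            + self.failed_filter
            + self.missing_parent_genotype
            + self.het_parent
            + self.same_allele
            + self.low_parent_depth
        )


def select_informative(
    raw: pd.DataFrame,
    min_parent_depth: int = 5,
    require_pass: bool = True,
    snps_only: bool = True,
) -> tuple[pd.DataFrame, SelectionCounts]:
    """Keep parent-informative sites and orient them to the restorer allele.

    A site is retained when both parents are called homozygous for
    different alleles and each parent's depth is strictly greater than
    `min_parent_depth` (a site at exactly the threshold is discarded).
    Returns the oriented site table (SITE_COLUMNS) and per-reason discard
    counts; discards are attributed to the first failing rule in the order
    non-SNP, FILTER, missing parent call, het parent, same allele, depth.
    """
    counts = SelectionCounts()
    n = len(raw)
    drop = np.zeros(n, dtype=bool)

    def take(mask: np.ndarray, reason: str) -> None:
        mask = mask & ~drop
        setattr(counts, reason, int(mask.sum()))
        drop[mask] = True

    if snps_only:
        take(~raw["is_snp"].to_numpy(), "not_biallelic_snp")
    if require_pass:
        take(~raw["filter_pass"].to_numpy(), "failed_filter")
    p1 = raw["p1_gt"].to_numpy()
    p2 = raw["p2_gt"].to_numpy()
    take((p1 == -1) | (p2 == -1), "missing_parent_genotype")
    take((p1 == 1) | (p2 == 1), "het_parent")
    take(p1 == p2, "same_allele")
    low = (raw["p1_depth"].to_numpy() <= min_parent_depth) | (
        raw["p2_depth"].to_numpy() <= min_parent_depth
    )
    take(low, "low_parent_depth")

    kept = raw.loc[~drop]
    counts.retained = len(kept)

    # orientation: the restorer allele is whichever allele P1 is homozygous for
    p1_is_ref = kept["p1_gt"].to_numpy() == 0
    sites = pd.DataFrame(
        {
            "chrom": kept["chrom"].to_numpy(),
            "pos": kept["pos"].to_numpy(),
            "restorer_allele": np.where(p1_is_ref, kept["ref"], kept["alt"]),
            "other_allele": np.where(p1_is_ref, kept["alt"], kept["ref"]),
            "p1_depth": kept["p1_depth"].to_numpy(),
            "p2_depth": kept["p2_depth"].to_numpy(),
            "fr_restorer": np.where(p1_is_ref, kept["fr_ref"], kept["fr_alt"]),
            "fr_other": np.where(p1_is_ref, kept["fr_alt"], kept["fr_ref"]),
            "sm_restorer": np.where(p1_is_ref, kept["sm_ref"], kept["sm_alt"]),
            "sm_other": np.where(p1_is_ref, kept["sm_alt"], kept["sm_ref"]),
        }
    ).reset_index(drop=True)
    logger.info(
        "informative-site selection: %d retained of %d (%s)",
        counts.retained,
        counts.total,
        counts,
    )
    return sites, counts


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    """Audit dump of the oriented site table (1-based positions)."""
    sites.to_csv(path, sep="\t", index=False)
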