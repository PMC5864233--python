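"""Copies-per-genome and transcript-fraction profiling.

Gene abundances are normalised to genome equivalents: a gene's coverage
in a sample divided by the arithmetic mean coverage of ten universal
single-copy marker genes (USCGs) in that sample estimates its copies
per genome. Category profiles (taxon, motif label, biosynthesis gene
set) are coverage-weighted sums of member-gene copy numbers; depth
profiles group samples by their exact sampled depth. Transcript
abundance is expressed as the percentage of non-rRNA reads mapping to
rhodopsin genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: the ten universal single-copy marker genes used for normalisation
USCG_IDS = (
    "COG0012", "COG0016", "COG0018", "COG0172", "COG0215",
    "COG0495", "COG0525", "COG0533", "COG0541", "COG0552",
)

COVERAGE_COLUMNS = ["sample_id", "gene_id", "coverage", "is_uscg"]
METADATA_COLUMNS = ["sample_id", "depth_m", "date"]


@dataclass
class CoverageTable:
    """Per-sample gene coverages with designated single-copy markers.

    ``coverage`` holds one row per (sample, gene); ``metadata`` one row
    per sample with at least ``depth_m``. Validation enforces the
    normalisation contract: every sample carries all ten USCGs with
    positive coverage, and no coverage is negative.
    """

    coverage: pd.DataFrame
    metadata: pd.DataFrame
    uscg_ids: tuple[str, ...] = USCG_IDS

    def __post_init__(self) -> None:
        missing = set(COVERAGE_COLUMNS[:3]) - set(self.coverage.columns)
        if missing:
            raise ValueError(f"coverage table missing columns: {sorted(missing)}")
        if "is_uscg" not in self.coverage.columns:
            self.coverage = self.coverage.assign(
                is_uscg=self.coverage["gene_id"].isin(self.uscg_ids)
            )
        if (self.coverage["coverage"] < 0).any():
            bad = self.coverage.loc[self.coverage["coverage"] < 0].iloc[0]
            raise ValueError(
                f"negative coverage for {bad['gene_id']} in {bad['sample_id']}"
            )
        for sample_id, sub in self.coverage.groupby("sample_id"):
            uscg = sub[sub["gene_id"].isin(self.uscg_ids)]
            present = set(uscg["gene_id"])
            absent = sorted(set(self.uscg_ids) - present)
            if absent:
                raise ValueError(
                    f"sample {sample_id}: missing USCG marker(s) {', '.join(absent)}"
                )
            zero = uscg[uscg["coverage"] <= 0]
            if not zero.empty:
                raise ValueError(
                    f"sample {sample_id}: non-positive coverage for USCG "
                    f"{zero.iloc[0]['gene_id']}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.coverage["sample_id"]))

    def uscg_mean(self, sample_id: str, statistic: str = "mean") -> float:
        """Average USCG coverage of a sample (genome equivalents)."""
        sub = self.coverage[
            (self.coverage["sample_id"] == sample_id)
            & (self.coverage["gene_id"].isin(self.uscg_ids))
        ]
        if sub.empty:
            raise ValueError(f"unknown sample {sample_id!r}")
        if statistic == "mean":
            return float(sub["coverage"].mean())
        if statistic == "median":
            return float(sub["coverage"].median())
        raise ValueError(f"unknown statistic {statistic!r}")

    def depth_of(self, sample_id: str) -> float:
        row = self.metadata[self.metadata["sample_id"] == sample_id]
        if row.empty:
            raise ValueError(f"sample {sample_id!r} absent from metadata")
        return float(row["depth_m"].iloc[0])


def copies_per_genome(
    table: CoverageTable,
    sample_id: str,
    gene_ids: Iterable[str],
    statistic: str = "mean",
) -> float:
    """Summed coverage of ``gene_ids`` over the sample's mean USCG coverage.

    Genes absent from the sample's table contribute zero coverage
    (absence from an assembled catalogue is evidence of absence).
    """
    gene_ids = set(gene_ids)
    denom = table.uscg_mean(sample_id, statistic)
    sub = table.coverage[
        (table.coverage["sample_id"] == sample_id)
        & (table.coverage["gene_id"].isin(gene_ids))
    ]
    return float(sub["coverage"].sum()) / denom


def copy_number_profile(
    table: CoverageTable,
    gene_ids: Optional[Iterable[str]] = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Tidy per-(sample, gene) copies-per-genome table.

    Defaults to every non-USCG gene in the table.
    """
    if gene_ids is None:
        gene_ids = [
            g for g in dict.fromkeys(table.coverage["gene_id"])
            if g not in table.uscg_ids
        ]
    else:
        gene_ids = list(dict.fromkeys(gene_ids))
    rows = []
    for sample_id in table.sample_ids:
        denom = table.uscg_mean(sample_id, statistic)
        sub = table.coverage[table.coverage["sample_id"] == sample_id]
        cov = dict(zip(sub["gene_id"], sub["coverage"]))
        for g in gene_ids:
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene_id": g,
                    "copies_per_genome": cov.get(g, 0.0) / denom,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "copies_per_genome"])


def depth_profile(values: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-depth summary (n, mean, median, quartiles, min, max).

    ``values`` must carry ``sample_id`` and a single numeric value column
    (its last column); samples are grouped by exact depth, no binning.
    """
    value_col = values.columns[-1]
    merged = values.merge(metadata[["sample_id", "depth_m"]], on="sample_id")
    if merged.empty:
        raise ValueError("no samples after joining metadata")
    rows = []
    for depth, sub in merged.groupby("depth_m", sort=True):
        v = sub[value_col].to_numpy(dtype=float)
        rows.append(
            {
                "depth_m": float(depth),
                "n": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
        )
    return pd.DataFrame(rows)


def relative_abundance(
    profile: pd.DataFrame,
    categories: Mapping[str, str],
    unassigned: str = "unassigned",
) -> pd.DataFrame:
    """Per-sample category fractions of summed copies-per-genome.

    ``profile`` is a ``copy_number_profile`` output; ``categories`` maps
    gene_id → category (taxon, motif label, ...), genes not in the map
    falling into ``unassigned``. Fractions sum to 1 per sample; a sample
    whose total is zero reports NaN fractions.
    """
    df = profile.assign(
        category=[categories.get(g, unassigned) for g in profile["gene_id"]]
    )
    per_cat = (
        df.groupby(["sample_id", "category"], sort=True)["copies_per_genome"]
        .sum()
        .reset_index()
    )
    totals = per_cat.groupby("sample_id")["copies_per_genome"].transform("sum")
    per_cat["fraction"] = np.where(
        totals > 0, per_cat["copies_per_genome"] / totals, np.nan
    )
    return per_cat[["sample_id", "category", "copies_per_genome", "fraction"]]


def gene_set_profile(
    table: CoverageTable,
    sets: Mapping[str, Iterable[str]],
    statistic: str = "mean",
    allow_overlap: bool = False,
) -> pd.DataFrame:
    """Per-depth copies-per-genome for named gene sets.

    Unknown gene ids are skipped with a count reported in the
    ``n_unknown`` column (constant per set). Sets must be disjoint
    unless ``allow_overlap``.
    """
    sets = {name: list(dict.fromkeys(ids)) for name, ids in sets.items()}
    if not allow_overlap:
        seen: dict[str, str] = {}
        for name, ids in sets.items():
            for g in ids:
                if g in seen:
                    raise ValueError(
                        f"gene {g} in both sets {seen[g]!r} and {name!r}"
                    )
                seen[g] = name
    known = set(table.coverage["gene_id"])
    rows = []
    for name, ids in sets.items():
        usable = [g for g in ids if g in known]
        n_unknown = len(ids) - len(usable)
        values = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "copies_per_genome": [
                    copies_per_genome(table, s, usable, statistic) if usable else 0.0
                    for s in table.sample_ids
                ],
            }
        )
        prof = depth_profile(values, table.metadata)
        prof.insert(0, "gene_set", name)
        prof["n_unknown"] = n_unknown
        rows.append(prof)
    return pd.concat(rows, ignore_index=True)


def transcript_fraction(rhodopsin_reads: int, total_nonrrna_reads: int) -> float:
    """Rhodopsin transcripts as a percentage of total non-rRNA reads."""
    if total_nonrrna_reads < 1:
        raise ValueError("total read count must be >= 1")
    if rhodopsin_reads < 0:
        raise ValueError("negative rhodopsin read count")
    if rhodopsin_reads > total_nonrrna_reads:
        raise ValueError(
            f"rhodopsin reads ({rhodopsin_reads}) exceed total ({total_nonrrna_reads})"
        )
    return 100.0 * rhodopsin_reads / total_nonrrna_reads


def transcript_summary(counts: pd.DataFrame, metadata: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-sample transcript fractions from a read-count table.

    ``counts`` columns: sample_id, rhodopsin_reads, total_nonrrna_reads.
    """
    out = counts.copy()
    out["fraction_percent"] = [
        transcript_fraction(int(r), int(t))
        for r, t in zip(out["rhodopsin_reads"], out["total_nonrrna_reads"])
    ]
    if metadata is not None:
        out = out.merge(metadata[["sample_id", "depth_m"]], on="sample_id", how="left")
        out = out[
            ["sample_id", "depth_m", "rhodopsin_reads", "total_nonrrna_reads", "fraction_percent"]
        ]
    return out
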