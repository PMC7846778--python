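"""Readers and writers for the plain-text formats the pipeline consumes.

Bismark-coverage files are tab-separated
``chrom  start  end  meth_pct  count_meth  count_unmeth`` with 1-based
inclusive positions on disk (``zero_based=True`` switches the dialect);
internally a CpG is a single 1-based position. BED files are 0-based
half-open. The methylation percentage column is always recomputed from
counts on write, so read-then-write round-trips are identity up to float
formatting of that column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .intervals import GenomicInterval

__all__ = [
    "read_bismark_cov",
    "write_bismark_cov",
    "combine_samples",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "export_cpg_bedgraph",
    "read_config",
    "write_json",
]


def read_bismark_cov(path: str | Path, sample: str = "sample",
                     zero_based: bool = False) -> pd.DataFrame:
    """Read one sample's Bismark-coverage file into a CpG count table."""
    cols = ["chrom", "start", "end", "meth_pct", "count_meth", "count_unmeth"]
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=cols,
                          dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int),
             f"{sample}_meth": pd.Series(dtype=int),
             f"{sample}_unmeth": pd.Series(dtype=int)}
        )
    if raw.isna().any().any():
        raise ValueError(f"{path}: expected 6 tab-separated columns")
    if (raw["count_meth"] < 0).any() or (raw["count_unmeth"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    cov = raw["count_meth"] + raw["count_unmeth"]
    if (cov == 0).any():
        raise ValueError(f"{path}: rows with zero coverage")
    pos = raw["start"].astype(int) + (1 if zero_based else 0)
    return pd.DataFrame(
        {"chrom": raw["chrom"], "pos": pos,
         f"{sample}_meth": raw["count_meth"].astype(int),
         f"{sample}_unmeth": raw["count_unmeth"].astype(int)}
    )


def write_bismark_cov(table: pd.DataFrame, path: str | Path, sample: str,
                      zero_based: bool = False) -> None:
    """Write one sample of a CpG count table as Bismark coverage.

    The percentage column is recomputed from the counts.
    """
    meth = table[f"{sample}_meth"]
    unmeth = table[f"{sample}_unmeth"]
    pct = 100.0 * meth / (meth + unmeth)
    start = table["pos"] - (1 if zero_based else 0)
    end = table["pos"]
    out = pd.DataFrame(
        {"chrom": table["chrom"], "start": start, "end": end,
         "meth_pct": pct.round(6), "count_meth": meth, "count_unmeth": unmeth}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def combine_samples(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join single-sample count tables on (chrom, pos).

    CpGs absent from a sample get zero counts there (they then fail any
    coverage filter for that sample, as they should).
    """
    merged: pd.DataFrame | None = None
    for sample, t in tables.items():
        sub = t[["chrom", "pos", f"{sample}_meth", f"{sample}_unmeth"]]
        merged = sub if merged is None else merged.merge(
            sub, on=["chrom", "pos"], how="outer"
        )
    merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
    count_cols = [c for c in merged.columns if c not in ("chrom", "pos")]
    merged[count_cols] = merged[count_cols].fillna(0).astype(int)
    return merged


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else None
            strand = parts[5] if len(parts) > 5 else "."
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                name=name, strand=strand)
            )
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedgraph(rows: Iterable[tuple[str, int, int, float]],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def export_cpg_bedgraph(table: pd.DataFrame, path: str | Path, sample: str,
                        min_coverage: int = 5) -> int:
    """Write per-CpG betas as bedGraph for CpGs at or above a coverage floor.

    Returns the number of CpGs written. (Browser-track export; the default
    floor of 5 reads is looser than the >= 10 analysis filter.)
    """
    meth = table[f"{sample}_meth"]
    cov = meth + table[f"{sample}_unmeth"]
    keep = cov >= min_coverage
    sub = table.loc[keep]
    betas = (meth[keep] / cov[keep]).to_numpy()
    rows = (
        (row.chrom, int(row.pos) - 1, int(row.pos), float(b))
        for row, b in zip(sub.itertuples(), betas)
    )
    write_bedgraph(rows, path)
    return int(keep.sum())


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
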