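"""Readers and writers for per-CpG, region, and signal formats.

Supported dialects
------------------
methcounts
    Six whitespace-separated columns: chrom, pos (0-based), strand, context,
    methylation level, coverage.
bedmethyl
    BED9+2: coverage in column 10, percent methylated in column 11.
array
    Tab-separated beta table (probe_id + one column per sample) combined with a
    three-column probe manifest (probe_id, chrom, pos).  Betas are carried as-is
    with no renormalisation; read counts stay absent.

Plus bedGraph signal tracks and BED3/BED5 region files, and the two
count-preserving transforms: symmetric-dyad merging and sample pooling.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Methylome, Region, ScoredRegion, SignalTrack, make_sites, sort_sites

logger = logging.getLogger(__name__)

DIALECTS = ("methcounts", "bedmethyl", "array")


def _read_table(path, n_min_cols: int, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#", dtype=str, engine="python"
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if df.shape[1] < n_min_cols:
        raise ValueError(
            f"{path}: {what} needs >= {n_min_cols} columns, found {df.shape[1]}"
        )
    return df


def _numeric(col: pd.Series, path, line_offset: int, what: str) -> np.ndarray:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: malformed {what} at line {i + 1 + line_offset}: {col.iloc[i]!r}"
        )
    if out.isna().any():
        i = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ValueError(f"{path}: missing {what} at line {i + 1 + line_offset}")
    return out.to_numpy()


def read_methylome(
    path,
    dialect: str = "methcounts",
    manifest=None,
    sample: str | None = None,
    sample_id: str | None = None,
) -> Methylome:
    """Read a per-CpG methylome.

    For count-based dialects methylated counts are reconstructed as
    ``round(level * coverage)``.  ``dialect='array'`` requires a ``manifest``
    (path or DataFrame with columns probe_id, chrom, pos); probes absent from
    the manifest are skipped and counted in the log.  ``sample`` names the beta
    column to extract (default: the first sample column).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if sample_id is None:
        sample_id = path.stem

    if dialect == "array":
        if manifest is None:
            raise ValueError("array dialect requires a probe-coordinate manifest")
        return _read_array(path, manifest, sample, sample_id)

    if dialect == "methcounts":
        df = _read_table(path, 6, "methcounts")
        if df.empty:
            return Methylome(sample_id, make_sites("chr", np.empty(0, dtype=np.int64), beta=np.empty(0)))
        pos = _numeric(df[1], path, 0, "position").astype(np.int64)
        level = _numeric(df[4], path, 0, "methylation level")
        cov = _numeric(df[5], path, 0, "coverage")
        strand = df[2].to_numpy()
        chrom = df[0].to_numpy()
    else:  # bedmethyl
        df = _read_table(path, 11, "bedMethyl")
        if df.empty:
            return Methylome(sample_id, make_sites("chr", np.empty(0, dtype=np.int64), beta=np.empty(0)))
        pos = _numeric(df[1], path, 0, "start").astype(np.int64)
        cov = _numeric(df[9], path, 0, "coverage")
        level = _numeric(df[10], path, 0, "percent methylated") / 100.0
        strand = df[5].to_numpy()
        chrom = df[0].to_numpy()

    if np.any((level < 0) | (level > 1)):
        i = int(np.flatnonzero((level < 0) | (level > 1))[0])
        raise ValueError(f"{path}: methylation level outside [0,1] at line {i + 1}")
    if np.any(cov < 0):
        raise ValueError(f"{path}: negative coverage")
    meth = np.rint(level * cov)
    sites = make_sites(chrom, pos, strand, meth_count=meth, total_count=cov)
    sites = _sorted_dedup(sites, path)
    return Methylome(sample_id, sites, assay="wgbs")


def _read_array(path, manifest, sample, sample_id) -> Methylome:
    table = pd.read_csv(path, sep="\t")
    probe_col = table.columns[0]
    if sample is None:
        candidates = [c for c in table.columns[1:]]
        if not candidates:
            raise ValueError(f"{path}: no sample columns in array table")
        sample = candidates[0]
    if sample not in table.columns:
        raise ValueError(f"{path}: no sample column {sample!r}")
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    need = {"probe_id", "chrom", "pos"}
    if not need <= set(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(need)}")
    merged = table[[probe_col, sample]].merge(
        manifest[["probe_id", "chrom", "pos"]],
        left_on=probe_col,
        right_on="probe_id",
        how="left",
    )
    missing = merged["chrom"].isna()
    if missing.any():
        logger.warning(
            "%s: %d probes absent from manifest, skipped", path, int(missing.sum())
        )
    merged = merged.loc[~missing]
    beta = pd.to_numeric(merged[sample], errors="coerce").to_numpy()
    sites = make_sites(
        merged["chrom"].to_numpy(),
        merged["pos"].to_numpy(dtype=np.int64),
        ".",
        beta=np.clip(beta, 0.0, 1.0),
    )
    sites = _sorted_dedup(sites, path)
    return Methylome(str(sample) if sample_id is None else sample_id, sites, assay="array")


def _sorted_dedup(sites: pd.DataFrame, path) -> pd.DataFrame:
    sites = sort_sites(sites)
    dup = sites.duplicated(subset=["chrom", "pos"], keep="first")
    if dup.any():
        logger.warning("%s: dropped %d duplicate positions", path, int(dup.sum()))
        sites = sites.loc[~dup].reset_index(drop=True)
    return sites


def merge_symmetric(m: Methylome) -> Methylome:
    """Pool the two strands of each CpG dyad into one forward-anchored record.

    A '-'-strand site at position p+1 is summed into the '+'-strand site at p;
    the merged record sits at p with strand '.'.  A '-' site with no partner is
    kept, repositioned to p-1, and logged — total methylated and total read
    counts are conserved exactly.
    """
    if not m.has_counts:
        raise ValueError("symmetric merge requires a count-based methylome")
    df = m.sites.copy()
    strand = df["strand"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64).copy()
    minus = strand == "-"
    pos[minus] = pos[minus] - 1

    if minus.any():
        partner = pd.MultiIndex.from_arrays(
            [df.loc[~minus, "chrom"], df.loc[~minus, "pos"]]
        )
        anchors = pd.MultiIndex.from_arrays(
            [df.loc[minus, "chrom"], pd.Series(pos[minus])]
        )
        orphan = ~anchors.isin(partner)
        if orphan.any():
            logger.info(
                "%s: %d '-' sites without a '+' partner kept at pos-1",
                m.sample_id,
                int(orphan.sum()),
            )
    df["pos"] = pos
    df["meth_count"] = df["meth_count"].astype(np.int64)
    df["total_count"] = df["total_count"].astype(np.int64)
    pooled = (
        df.groupby(["chrom", "pos"], sort=True, as_index=False)[
            ["meth_count", "total_count"]
        ].sum()
    )
    sites = make_sites(
        pooled["chrom"].to_numpy(),
        pooled["pos"].to_numpy(dtype=np.int64),
        ".",
        meth_count=pooled["meth_count"].to_numpy(),
        total_count=pooled["total_count"].to_numpy(),
    )
    return Methylome(m.sample_id, sort_sites(sites), assay=m.assay)


def pool_methylomes(methylomes: Sequence[Methylome], sample_id: str = "pooled") -> Methylome:
    """Sum read counts across samples (the merge used for group methylomes)."""
    if not methylomes:
        raise ValueError("nothing to pool")
    for m in methylomes:
        if not m.has_counts:
            raise ValueError("pooling requires count-based methylomes")
    df = pd.concat([m.sites for m in methylomes], ignore_index=True)
    pooled = (
        df.groupby(["chrom", "pos"], sort=True, as_index=False)[
            ["meth_count", "total_count"]
        ].sum()
    )
    sites = make_sites(
        pooled["chrom"].to_numpy(),
        pooled["pos"].to_numpy(dtype=np.int64),
        ".",
        meth_count=pooled["meth_count"].to_numpy(),
        total_count=pooled["total_count"].to_numpy(),
    )
    return Methylome(sample_id, sort_sites(sites), assay=methylomes[0].assay)


def write_methcounts(m: Methylome, path) -> None:
    """Write a count-based methylome as methcounts six-column text."""
    if not m.has_counts:
        raise ValueError("methcounts output requires counts")
    df = m.sites
    with open(path, "w") as fh:
        for chrom, pos, strand, meth, total in zip(
            df["chrom"], df["pos"], df["strand"], df["meth_count"], df["total_count"]
        ):
            beta = meth / total if total > 0 else 0.0
            fh.write(f"{chrom}\t{int(pos)}\t{strand}\tCpG\t{beta:.6f}\t{int(total)}\n")


def read_signal_track(path, semantics: str = "fold_change") -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack.

    Zero-value intervals are dropped under fold-change semantics (gaps already
    mean zero); overlapping intervals are an error naming the offending pair.
    """
    df = _read_table(path, 4, "bedGraph")
    if df.empty:
        return SignalTrack({}, semantics=semantics)
    chrom = df[0].to_numpy()
    start = _numeric(df[1], path, 0, "start").astype(np.int64)
    end = _numeric(df[2], path, 0, "end").astype(np.int64)
    value = _numeric(df[3], path, 0, "value")
    if np.any(end <= start):
        i = int(np.flatnonzero(end <= start)[0])
        raise ValueError(f"{path}: start >= end at line {i + 1}")
    if semantics == "fold_change":
        if np.any(value < 0):
            i = int(np.flatnonzero(value < 0)[0])
            raise ValueError(f"{path}: negative fold-change value at line {i + 1}")
        keep = value > 0
        chrom, start, end, value = chrom[keep], start[keep], end[keep], value[keep]
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in pd.unique(chrom):
        mask = chrom == c
        data[str(c)] = (start[mask], end[mask], value[mask])
    return SignalTrack(data, semantics=semantics)


def write_signal_track(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.data:
            s, e, v = track.data[chrom]
            for si, ei, vi in zip(s, e, v):
                fh.write(f"{chrom}\t{int(si)}\t{int(ei)}\t{vi:.6g}\n")


def read_regions_bed(path) -> list[Region]:
    """Read BED3+ regions (half-open, 0-based); start >= end is an error."""
    df = _read_table(path, 3, "BED")
    if df.empty:
        return []
    chrom = df[0].to_numpy()
    start = _numeric(df[1], path, 0, "start").astype(np.int64)
    end = _numeric(df[2], path, 0, "end").astype(np.int64)
    if np.any(start >= end):
        i = int(np.flatnonzero(start >= end)[0])
        raise ValueError(f"{path}: start >= end at line {i + 1}")
    names = df[3].to_numpy() if df.shape[1] > 3 else np.full(len(df), None)
    out = [
        Region(str(c), int(s), int(e), name=None if n is None else str(n))
        for c, s, e, n in zip(chrom, start, end, names)
    ]
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def write_regions_bed(regions: Sequence[Region], path) -> None:
    """Write regions as BED5 (+ rank column for scored regions).

    The score column carries the PRC2 score when present, otherwise
    ``round(mean_level * 1000)``.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            name = r.name if r.name else f"region_{i}"
            if isinstance(r, ScoredRegion) and np.isfinite(r.prc2_score):
                score = f"{r.prc2_score:.6g}"
                extra = f"\t{r.rank}" if r.rank is not None else ""
            else:
                score = (
                    str(int(round(r.mean_level * 1000)))
                    if np.isfinite(r.mean_level)
                    else "0"
                )
                extra = ""
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}{extra}\n")
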