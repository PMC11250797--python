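"""Core containers: per-CpG methylomes, genomic regions, and ChIP signal tracks.

All coordinates are 0-based, half-open, matching BED. A methylome is a sorted
per-CpG table; a signal track is a piecewise-constant non-negative function per
chromosome (bedGraph semantics: gaps are background).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

SITE_COLUMNS = ("chrom", "pos", "strand", "meth_count", "total_count", "beta")
ASSAYS = ("wgbs", "rrbs", "array", "scwgbs")

#: Track semantics: ``fold_change`` — higher is more bound, gaps are 0;
#: ``p_value`` — lower is more bound, gaps are 1.
SEMANTICS = ("fold_change", "p_value")


def make_sites(
    chrom,
    pos,
    strand=None,
    meth_count=None,
    total_count=None,
    beta=None,
) -> pd.DataFrame:
    """Assemble a site table with the canonical columns.

    For count-based sites ``beta`` is derived as ``meth_count / total_count``
    (NaN where coverage is zero).  Array-style sites carry ``beta`` directly and
    leave both count columns NaN — counts are never fabricated.
    """
    pos = np.asarray(pos, dtype=np.int64)
    n = pos.shape[0]
    chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n,))
    if strand is None:
        strand = "."
    strand = np.broadcast_to(np.asarray(strand, dtype=object), (n,))
    if meth_count is not None and total_count is not None:
        meth = np.asarray(meth_count, dtype=np.float64)
        total = np.asarray(total_count, dtype=np.float64)
        if np.any(meth > total):
            raise ValueError("meth_count exceeds total_count")
        if np.any(meth < 0) or np.any(total < 0):
            raise ValueError("negative read counts")
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    elif beta is not None:
        b = np.asarray(beta, dtype=np.float64)
        ok = np.isnan(b) | ((b >= 0.0) & (b <= 1.0))
        if not np.all(ok):
            raise ValueError("beta outside [0, 1]")
        meth = np.full(n, np.nan)
        total = np.full(n, np.nan)
    else:
        raise ValueError("provide counts or beta")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "meth_count": meth,
            "total_count": total,
            "beta": b,
        }
    )


def sort_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Sort a site table by (chrom, pos) with a stable order."""
    return df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


@dataclass
class Methylome:
    """A sample's per-CpG methylation table, sorted by (chrom, pos).

    Parameters
    ----------
    sample_id
        Free-form sample label, propagated into results.
    sites
        DataFrame with columns ``chrom, pos, strand, meth_count, total_count,
        beta``.  Count columns are NaN for array-derived data.
    assay
        One of ``wgbs``, ``rrbs``, ``array``, ``scwgbs``.
    """

    sample_id: str
    sites: pd.DataFrame
    assay: str = "wgbs"

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        missing = set(SITE_COLUMNS) - set(self.sites.columns)
        if missing:
            raise ValueError(f"site table missing columns {sorted(missing)}")
        df = self.sites
        if len(df) > 1:
            c = df["chrom"].to_numpy()
            p = df["pos"].to_numpy()
            same = c[1:] == c[:-1]
            if np.any(same & (p[1:] <= p[:-1])):
                self.sites = sort_sites(df)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def has_counts(self) -> bool:
        return bool(self.sites["total_count"].notna().any())

    def covered_mask(self) -> np.ndarray:
        """Sites with a defined methylation level (coverage > 0, or array beta)."""
        total = self.sites["total_count"].to_numpy()
        beta = self.sites["beta"].to_numpy()
        return np.where(np.isnan(total), ~np.isnan(beta), total > 0)

    def covered_sites(self) -> pd.DataFrame:
        return self.sites.loc[self.covered_mask()].reset_index(drop=True)

    def global_mean_beta(self) -> float:
        """Mean methylation over all covered CpGs (the sample-QC statistic)."""
        cov = self.covered_sites()
        if len(cov) == 0:
            raise ValueError(f"{self.sample_id}: no covered CpGs")
        return float(cov["beta"].mean())

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (the table is sorted)."""
        chrom = self.sites["chrom"].to_numpy()
        out: dict[str, slice] = {}
        if len(chrom) == 0:
            return out
        change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(chrom)]])
        for i in range(len(bounds) - 1):
            out[str(chrom[bounds[i]])] = slice(int(bounds[i]), int(bounds[i + 1]))
        return out


@dataclass
class Region:
    """Half-open genomic interval with CpG summary statistics."""

    chrom: str
    start: int
    end: int
    n_cpgs: int = 0
    mean_level: float = float("nan")
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"degenerate region {self.chrom}:{self.start}-{self.end}"
            )
        if self.n_cpgs < 0:
            raise ValueError("n_cpgs must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ScoredRegion(Region):
    """Region with aggregated PRC2 binding; rank 1 = most bound."""

    prc2_score: float = float("nan")
    factor_scores: tuple[float, ...] = ()
    rank: int | None = None


def regions_by_chrom(regions: Sequence[Region]) -> dict[str, list[Region]]:
    out: dict[str, list[Region]] = {}
    for r in regions:
        out.setdefault(r.chrom, []).append(r)
    for rs in out.values():
        rs.sort(key=lambda r: (r.start, r.end))
    return out


class SignalTrack:
    """Piecewise-constant ChIP signal: sorted, disjoint intervals per chromosome.

    ``semantics`` declares how values order binding strength and what uncovered
    bases mean: fold-change gaps read as 0 (no enrichment), p-value gaps as 1
    (no evidence).
    """

    def __init__(
        self,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        semantics: str = "fold_change",
    ) -> None:
        if semantics not in SEMANTICS:
            raise ValueError(f"unknown semantics {semantics!r}")
        self.semantics = semantics
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in data.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            order = np.argsort(s, kind="mergesort")
            s, e, v = s[order], e[order], v[order]
            if np.any(e <= s):
                raise ValueError(f"{chrom}: empty interval in signal track")
            bad = np.flatnonzero(s[1:] < e[:-1])
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"{chrom}: overlapping intervals "
                    f"({s[i]},{e[i]}) and ({s[i + 1]},{e[i + 1]})"
                )
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative signal value")
            if semantics == "p_value" and np.any((v <= 0) | (v > 1)):
                raise ValueError(f"{chrom}: p-value outside (0, 1]")
            self.data[chrom] = (s, e, v)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int, float]], semantics: str = "fold_change"
    ) -> "SignalTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in intervals:
            per.setdefault(chrom, []).append((s, e, v))
        data = {
            c: tuple(np.array(col) for col in zip(*rows))  # type: ignore[misc]
            for c, rows in per.items()
        }
        return cls(data, semantics=semantics)

    @property
    def gap_value(self) -> float:
        return 0.0 if self.semantics == "fold_change" else 1.0

    def chroms(self) -> list[str]:
        return list(self.data)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at a single base; the gap value where uncovered."""
        if chrom not in self.data:
            return self.gap_value
        s, e, v = self.data[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return float(v[i])
        return self.gap_value

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Base-length-weighted mean over [start, end), gaps at the gap value."""
        if end <= start:
            raise ValueError("empty region")
        total = end - start
        if chrom not in self.data:
            return self.gap_value
        s, e, v = self.data[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if lo >= hi:
            return self.gap_value
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        ov = np.clip(ov, 0, None)
        covered = int(ov.sum())
        acc = float(np.dot(ov, v[lo:hi]))
        return (acc + (total - covered) * self.gap_value) / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.data:
            s, e, v = self.data[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        return pd.concat(rows, ignore_index=True)

    def scaled(self, factor: float) -> "SignalTrack":
        if self.semantics != "fold_change":
            raise ValueError("scaling only defined for fold_change tracks")
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.data.items()},
            semantics=self.semantics,
        )
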