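"""The PRC2-AgeIndex and its companion statistics.

The index of a sample is the average methylation over the high-PRC2 LMR set —
a scalar in [0, 1] that rises with age as Polycomb-bound regulatory islands
gain methylation.  Companions: per-chromosome indices, binding-ranked sliding
window profiles, per-region old-minus-young deltas, the hypermethylated
fraction, and the share of genome-wide methylation gain captured by the set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Methylome, Region, ScoredRegion
from .ranking import HighPRC2Set
from .segment import score_regions

logger = logging.getLogger(__name__)

WEIGHTINGS = ("pooled_cpg", "region_mean")


@dataclass
class AgeIndexResult:
    """The scalar index with coverage diagnostics.

    ``weighting='pooled_cpg'`` averages betas over every covered CpG inside
    the set (robust to region-size variation); ``'region_mean'`` averages the
    per-region means.  Regions with no covered CpG are excluded and counted.
    """

    sample_id: str
    index: float
    n_regions_covered: int
    n_cpgs_used: int
    weighting: str
    per_chromosome: dict[str, float] | None = None


@dataclass
class RankedProfile:
    """Sliding-window mean methylation along the binding-rank axis.

    Regions are ordered from lowest binding (left) to highest binding (right);
    ``centers`` are window midpoints in that rank coordinate.
    """

    centers: np.ndarray
    values: np.ndarray
    window: int
    step: int


@dataclass
class DeltaRecord:
    region: Region
    mean_young: float
    mean_old: float

    @property
    def delta(self) -> float:
        return self.mean_old - self.mean_young


@dataclass
class GainShareResult:
    """Positive methylation gain inside the high-PRC2 set vs genome-wide."""

    gain_in_set: float
    gain_total: float
    share: float
    n_cpgs: int


def _member_indices(
    m: Methylome, regions: Sequence[Region]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-region covered-CpG row indices into the covered-site table."""
    cov = m.covered_sites()
    slices: dict[str, tuple[np.ndarray, int]] = {}
    offset = 0
    for c, grp in cov.groupby("chrom", sort=False):
        slices[str(c)] = (grp["pos"].to_numpy(dtype=np.int64), offset)
        offset += len(grp)
    beta = cov["beta"].to_numpy()
    idx: list[np.ndarray] = []
    for r in regions:
        if r.chrom in slices:
            p, off = slices[r.chrom]
            lo = int(np.searchsorted(p, r.start, side="left"))
            hi = int(np.searchsorted(p, r.end, side="left"))
            idx.append(np.arange(off + lo, off + hi))
        else:
            idx.append(np.empty(0, dtype=np.int64))
    return idx, beta


def compute_index(
    m: Methylome, hp: HighPRC2Set, weighting: str = "pooled_cpg"
) -> AgeIndexResult:
    """Average methylation of a sample within the high-PRC2 set."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    if len(hp) == 0:
        raise ValueError("empty high-PRC2 set")
    idx, beta = _member_indices(m, hp.regions)
    covered = [i for i in idx if i.size > 0]
    if not covered:
        raise ValueError(
            f"{m.sample_id}: no covered CpG inside the high-PRC2 set"
        )
    if weighting == "pooled_cpg":
        pooled = np.unique(np.concatenate(covered))
        value = float(beta[pooled].mean())
        n_used = int(pooled.size)
    else:
        means = np.array([beta[i].mean() for i in covered])
        value = float(means.mean())
        n_used = int(sum(i.size for i in covered))
    return AgeIndexResult(
        sample_id=m.sample_id,
        index=value,
        n_regions_covered=len(covered),
        n_cpgs_used=n_used,
        weighting=weighting,
    )


def per_chromosome_index(
    m: Methylome, hp: HighPRC2Set, weighting: str = "pooled_cpg"
) -> dict[str, float]:
    """The index restricted to each chromosome's members (uncovered omitted)."""
    by_chrom: dict[str, list[ScoredRegion]] = {}
    for r in hp.regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: dict[str, float] = {}
    for chrom, regs in by_chrom.items():
        sub = HighPRC2Set(regs, k=hp.k, semantics=hp.semantics)
        try:
            out[chrom] = compute_index(m, sub, weighting=weighting).index
        except ValueError:
            continue
    return out


def ranked_profile(
    m: Methylome,
    scored: Sequence[ScoredRegion],
    window: int = 100,
    step: int = 10,
) -> RankedProfile:
    """Sliding-window mean methylation over binding-ranked regions.

    A plain moving average: regions are sorted from least to most bound
    (rank N ... rank 1), each window's value is the mean of its member
    regions' mean betas, skipping regions without coverage.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if any(r.rank is None for r in scored):
        raise ValueError("regions must carry ranks (see aggregate_binding)")
    ordered = sorted(scored, key=lambda r: -r.rank)  # least bound first
    if window > len(ordered):
        raise ValueError("window exceeds the number of regions")
    means = np.array(
        [r.mean_level for r in score_regions(ordered, m)], dtype=np.float64
    )
    n_windows = (len(ordered) - window) // step + 1
    centers = np.empty(n_windows)
    values = np.empty(n_windows)
    for w in range(n_windows):
        lo = w * step
        chunk = means[lo : lo + window]
        with np.errstate(invalid="ignore"):
            values[w] = np.nanmean(chunk) if np.any(~np.isnan(chunk)) else np.nan
        centers[w] = lo + (window - 1) / 2.0
    return RankedProfile(centers=centers, values=values, window=window, step=step)


def delta_dnam(
    regions: Sequence[Region], young: Methylome, old: Methylome
) -> list[DeltaRecord]:
    """Per-region methylation difference, old minus young.

    Means are taken over the CpGs covered in each respective sample; regions
    covered in only one sample are dropped (and logged).
    """
    ys = score_regions(regions, young)
    os_ = score_regions(regions, old)
    records = []
    dropped = 0
    for r, y, o in zip(regions, ys, os_):
        if y.n_cpgs == 0 or o.n_cpgs == 0:
            dropped += 1
            continue
        records.append(DeltaRecord(r, y.mean_level, o.mean_level))
    if dropped:
        logger.info("delta_dnam: dropped %d regions lacking coverage", dropped)
    return records


def fraction_hypermethylated(
    deltas: Sequence[DeltaRecord], subset: Sequence[Region] | HighPRC2Set | None = None
) -> float:
    """Proportion of regions with a strictly positive delta."""
    if subset is not None:
        members = list(subset.regions) if isinstance(subset, HighPRC2Set) else list(subset)
        deltas = [
            d for d in deltas if any(d.region.overlaps(s) for s in members)
        ]
    if not deltas:
        raise ValueError("no deltas after subsetting")
    return float(np.mean([d.delta > 0 for d in deltas]))


def gain_share(
    young: Methylome,
    old: Methylome,
    hp: HighPRC2Set,
    all_lmrs: Sequence[Region] | None = None,
) -> GainShareResult:
    """Share of genome-wide positive methylation gain inside the high-PRC2 set.

    The numerator sums max(delta, 0) over CpGs inside the set; the denominator
    sums it over every CpG covered in both samples.  Per-CpG deltas are noisy
    at ordinary sequencing depth, so the intended inputs are deep or
    group-pooled methylomes (see ``io.pool_methylomes``).
    """
    ycov = young.covered_sites()[["chrom", "pos", "beta"]]
    ocov = old.covered_sites()[["chrom", "pos", "beta"]]
    both = ycov.merge(ocov, on=["chrom", "pos"], suffixes=("_young", "_old"))
    if len(both) == 0:
        raise ValueError("no CpG covered in both samples")
    delta = both["beta_old"].to_numpy() - both["beta_young"].to_numpy()
    gain = np.clip(delta, 0.0, None)
    total = float(gain.sum())
    if total == 0.0:
        raise ValueError("no positive methylation gain anywhere")

    in_set = np.zeros(len(both), dtype=bool)
    chrom = both["chrom"].to_numpy()
    pos = both["pos"].to_numpy(dtype=np.int64)
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in hp.regions:
        per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for c, ivs in per_chrom.items():
        mask = chrom == c
        if not mask.any():
            continue
        p = pos[mask]
        hit = np.zeros(p.shape[0], dtype=bool)
        for s, e in ivs:
            lo = np.searchsorted(p, s, side="left")
            hi = np.searchsorted(p, e, side="left")
            hit[lo:hi] = True
        in_set[np.flatnonzero(mask)[hit]] = True
    inside = float(gain[in_set].sum())
    return GainShareResult(
        gain_in_set=inside,
        gain_total=total,
        share=inside / total,
        n_cpgs=int(len(both)),
    )
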