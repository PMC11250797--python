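"""Rank LMRs (or individual low-methylated CpGs) by PRC2 ChIP binding.

Binding is aggregated per region as the base-length-weighted mean of each
factor's signal track (EZH2, SUZ12, ...), then averaged across factors.  Under
fold-change semantics the most-bound elements have the highest scores; under
p-value semantics the lowest average p wins.  Blacklisted regions are removed
before ranking, and the top-K most-bound elements form the high-PRC2 set.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import spearmanr

from .core import Methylome, Region, ScoredRegion, SignalTrack


@dataclass
class SelectionConfig:
    """Top-set size and score semantics; ties break on genomic coordinate."""

    k: int = 1000
    semantics: str = "fold_change"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.semantics not in ("fold_change", "p_value"):
            raise ValueError(f"unknown semantics {self.semantics!r}")


@dataclass
class HighPRC2Set:
    """The top-K most PRC2-bound regions, most extreme first."""

    regions: list[ScoredRegion]
    k: int
    semantics: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


@dataclass
class RankedSites:
    """Low-methylated CpGs (LMCs) with per-site PRC2 signal and rank.

    ``table`` columns: chrom, pos, ref_beta (baseline methylation across the
    reference samples), signal (mean across factors), rank (1 = most bound).
    """

    table: pd.DataFrame
    low_threshold: float
    semantics: str


@dataclass
class ConcordanceResult:
    overlap_fraction: float
    rank_correlation: float
    n_shared: int


def _sort_key(score: np.ndarray, semantics: str) -> np.ndarray:
    return -score if semantics == "fold_change" else score


def aggregate_binding(
    regions: Sequence[Region], tracks: Sequence[SignalTrack] | SignalTrack
) -> list[ScoredRegion]:
    """Score each region by its mean ChIP signal, averaged across factors.

    Uncovered bases contribute the track's gap value (0 for fold change, 1 for
    p-values).  Ranks are assigned over the returned list: rank 1 is the most
    bound under the declared semantics, ties broken by (chrom, start).
    """
    if isinstance(tracks, SignalTrack):
        tracks = [tracks]
    if not tracks:
        raise ValueError("at least one signal track required")
    semantics = tracks[0].semantics
    if any(t.semantics != semantics for t in tracks):
        raise ValueError("mixed track semantics (fold_change vs p_value)")
    scored: list[ScoredRegion] = []
    for r in regions:
        per_factor = tuple(t.region_mean(r.chrom, r.start, r.end) for t in tracks)
        scored.append(
            ScoredRegion(
                r.chrom,
                r.start,
                r.end,
                n_cpgs=r.n_cpgs,
                mean_level=r.mean_level,
                name=r.name,
                prc2_score=float(np.mean(per_factor)),
                factor_scores=per_factor,
            )
        )
    scores = np.array([s.prc2_score for s in scored])
    order = sorted(
        range(len(scored)),
        key=lambda i: (_sort_key(scores, semantics)[i], scored[i].chrom, scored[i].start),
    )
    for rank, i in enumerate(order, start=1):
        scored[i].rank = rank
    return scored


def filter_blacklist(
    regions: Sequence[Region], blacklist: Sequence[Region]
) -> list[Region]:
    """Drop any region overlapping a blacklist interval by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for b in blacklist:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end)
    return [
        r
        for r in regions
        if r.chrom not in trees or not trees[r.chrom].overlap(r.start, r.end)
    ]


def select_top_k(
    scored: Sequence[ScoredRegion], cfg: SelectionConfig | None = None
) -> HighPRC2Set:
    """Select the K most-bound regions (highest fold change / lowest p)."""
    if cfg is None:
        cfg = SelectionConfig()
    if not scored:
        raise ValueError("no scored regions to select from")
    scores = np.array([s.prc2_score for s in scored])
    order = sorted(
        range(len(scored)),
        key=lambda i: (
            _sort_key(scores, cfg.semantics)[i],
            scored[i].chrom,
            scored[i].start,
        ),
    )
    if cfg.k > len(scored):
        import warnings

        warnings.warn(
            f"k={cfg.k} exceeds the {len(scored)} available regions; returning all"
        )
    chosen = [scored[i] for i in order[: cfg.k]]
    chosen = [replace(s, rank=i + 1) for i, s in enumerate(chosen)]
    return HighPRC2Set(chosen, k=cfg.k, semantics=cfg.semantics)


def rank_lmcs(
    references: Methylome | Sequence[Methylome],
    tracks: Sequence[SignalTrack] | SignalTrack,
    low_threshold: float = 0.3,
) -> RankedSites:
    """Rank low-methylated CpGs (LMCs) by single-base PRC2 signal.

    The baseline methylation of each CpG is its mean beta across the reference
    methylome(s); sites below ``low_threshold`` are retained and ranked by the
    across-factor mean of the track value at the site.
    """
    if isinstance(references, Methylome):
        references = [references]
    if isinstance(tracks, SignalTrack):
        tracks = [tracks]
    semantics = tracks[0].semantics
    if any(t.semantics != semantics for t in tracks):
        raise ValueError("mixed track semantics (fold_change vs p_value)")
    frames = [m.covered_sites()[["chrom", "pos", "beta"]] for m in references]
    baseline = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False)["beta"]
        .mean()
        .rename(columns={"beta": "ref_beta"})
    )
    low = baseline[baseline["ref_beta"] < low_threshold].reset_index(drop=True)
    if len(low) == 0:
        raise ValueError(f"no CpG below the low threshold {low_threshold}")
    signal = np.array(
        [
            np.mean([t.value_at(c, int(p)) for t in tracks])
            for c, p in zip(low["chrom"], low["pos"])
        ]
    )
    low["signal"] = signal
    low["_key"] = _sort_key(signal, semantics)
    low = low.sort_values(["_key", "chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    low["rank"] = np.arange(1, len(low) + 1)
    low = (
        low.drop(columns="_key")
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return RankedSites(low, low_threshold=low_threshold, semantics=semantics)


def select_top_sites(
    ranked: RankedSites, cfg: SelectionConfig | None = None
) -> HighPRC2Set:
    """Top-K LMCs as a high-PRC2 set of 2-bp dyad regions."""
    if cfg is None:
        cfg = SelectionConfig()
    tab = ranked.table
    top = tab[tab["rank"] <= cfg.k].sort_values("rank")
    regions = [
        ScoredRegion(
            str(row.chrom),
            int(row.pos),
            int(row.pos) + 2,
            prc2_score=float(row.signal),
            rank=int(row.rank),
        )
        for row in top.itertuples()
    ]
    return HighPRC2Set(regions, k=cfg.k, semantics=ranked.semantics)


def _positions_by_chrom(source) -> dict[str, np.ndarray]:
    if isinstance(source, Methylome):
        df = source.sites
        return {
            str(c): g["pos"].to_numpy(dtype=np.int64)
            for c, g in df.groupby("chrom", sort=False)
        }
    return {c: np.asarray(p, dtype=np.int64) for c, p in source.items()}


def density_filter(
    regions: Sequence[Region],
    cpg_positions,
    min_cpgs_per_kb: float = 10.0,
) -> list[Region]:
    """Keep regions whose CpG density meets ``min_cpgs_per_kb``.

    Density is computed against a reference CpG coordinate set (a Methylome or
    a chrom → sorted positions mapping) — typically the full CpG complement,
    not the sparse coverage of a single cell.
    """
    pos = _positions_by_chrom(cpg_positions)
    out = []
    for r in regions:
        p = pos.get(r.chrom)
        n = 0
        if p is not None:
            n = int(
                np.searchsorted(p, r.end, side="left")
                - np.searchsorted(p, r.start, side="left")
            )
        if n / (r.length / 1000.0) >= min_cpgs_per_kb:
            out.append(r)
    return out


def density_filter_sites(
    ranked: RankedSites,
    cpg_positions,
    min_cpgs_per_kb: float = 10.0,
    window: int = 1000,
) -> RankedSites:
    """Restrict ranked LMCs to high-CpG-density neighbourhoods.

    Counts reference CpGs in a ``window`` bp window centred on each site; used
    for single-cell data, where sparse per-cell coverage makes isolated sites
    unreliable.
    """
    pos = _positions_by_chrom(cpg_positions)
    tab = ranked.table
    keep = np.zeros(len(tab), dtype=bool)
    half = window // 2
    need = min_cpgs_per_kb * window / 1000.0
    for i, (c, p) in enumerate(zip(tab["chrom"], tab["pos"])):
        ref = pos.get(str(c))
        if ref is None:
            continue
        n = np.searchsorted(ref, p + half, side="left") - np.searchsorted(
            ref, p - half, side="left"
        )
        keep[i] = n >= need
    sub = tab.loc[keep].copy()
    # re-rank within the surviving sites, preserving relative order
    sub = sub.sort_values("rank")
    sub["rank"] = np.arange(1, len(sub) + 1)
    return RankedSites(
        sub.reset_index(drop=True), ranked.low_threshold, ranked.semantics
    )


def rank_concordance(a: HighPRC2Set, b: HighPRC2Set) -> ConcordanceResult:
    """Overlap fraction of a's members in b, plus rank agreement of shared ones."""
    trees: dict[str, IntervalTree] = {}
    for r in b.regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    shared_a: list[int] = []
    shared_b: list[int] = []
    n_overlap = 0
    for r in a.regions:
        tree = trees.get(r.chrom)
        hits = tree.overlap(r.start, r.end) if tree is not None else ()
        if hits:
            n_overlap += 1
            partner = min(hits, key=lambda iv: iv.begin).data
            if r.rank is not None and partner.rank is not None:
                shared_a.append(r.rank)
                shared_b.append(partner.rank)
    frac = n_overlap / len(a.regions) if a.regions else 0.0
    if len(shared_a) >= 2 and len(set(shared_a)) > 1 and len(set(shared_b)) > 1:
        rho = float(spearmanr(shared_a, shared_b).statistic)
    elif shared_a:
        rho = 1.0
    else:
        rho = float("nan")
    return ConcordanceResult(frac, rho, len(shared_a))
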