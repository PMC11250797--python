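"""Synthetic methylomes and ChIP tracks with planted ground truth.

The generator emulates the structure the index relies on: hypomethylated
islands (mean length ~3 kb, CpG density ~1/10 bp) in a methylated background
(~1 CpG/100 bp); a linear age-dependent global background loss; a linear
age-dependent gain confined to the PRC2-target subset of islands; correlated
ChIP factor tracks whose enrichment marks the targets; Poisson coverage with
beta-binomial read noise; and array / RRBS / single-cell downsampling.

Effects are linear in age with clamping — the simplest structure consistent
with monotone aging trends — so every planted quantity has a closed form that
tests can check against.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Methylome, Region, SignalTrack, make_sites


@dataclass
class PlantedLMR:
    chrom: str
    start: int
    end: int
    is_target: bool
    strength: float

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end)


@dataclass
class SimLayout:
    """Planted genome architecture: CpG coordinates and LMR intervals."""

    chrom_lengths: dict[str, int]
    cpg_pos: dict[str, np.ndarray]
    lmrs: list[PlantedLMR]

    @property
    def n_targets(self) -> int:
        return sum(l.is_target for l in self.lmrs)

    def target_regions(self) -> list[Region]:
        return [l.as_region() for l in self.lmrs if l.is_target]

    def lmr_regions(self) -> list[Region]:
        return [l.as_region() for l in self.lmrs]

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        return self.cpg_pos


@dataclass
class SimParams:
    """Aging-effect and noise parameters.

    Baselines and rates are on the beta scale per year: the background starts
    at ``m_bg0`` and loses ``loss_rate`` per year; PRC2-target LMRs start at
    ``m_low0`` and gain ``gain_rate`` per year; non-target LMRs stay at
    ``m_low0``.  True betas are clamped to [beta_floor, beta_ceiling].
    Coverage is Poisson(``coverage_mean``); read counts are beta-binomial with
    concentration ``dispersion_conc`` (smaller = more overdispersed).  ChIP
    tracks add N(0, ``chip_noise_sd``) per factor per LMR over a
    ``chip_background`` baseline.
    """

    m_bg0: float = 0.85
    m_low0: float = 0.05
    loss_rate: float = 0.001
    gain_rate: float = 0.004
    beta_floor: float = 0.01
    beta_ceiling: float = 0.99
    coverage_mean: float = 30.0
    dispersion_conc: float = 100.0
    chip_noise_sd: float = 0.5
    chip_background: float = 0.5

    def __post_init__(self) -> None:
        if self.loss_rate < 0 or self.gain_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.beta_floor < self.beta_ceiling <= 1.0:
            raise ValueError("invalid beta clamps")

    def clamp(self, x):
        return np.clip(x, self.beta_floor, self.beta_ceiling)


BG_SPACING = 100.0  # mean inter-CpG distance outside LMRs (bp)
LMR_SPACING = 10.0  # mean inter-CpG distance inside LMRs (bp)


def _spacings(rng: np.random.Generator, span: int, mean: float) -> np.ndarray:
    """Strictly positive integer CpG spacings covering up to ``span`` bp."""
    n_guess = int(span / mean * 1.6) + 16
    gaps = np.maximum(2, np.rint(rng.exponential(mean - 2.0, n_guess) + 2.0))
    while gaps.sum() < span:
        extra = np.maximum(2, np.rint(rng.exponential(mean - 2.0, n_guess) + 2.0))
        gaps = np.concatenate([gaps, extra])
    return gaps.astype(np.int64)


def make_layout(
    n_chroms: int = 1,
    chrom_len: int = 10_000_000,
    n_lmrs: int = 50,
    target_fraction: float = 0.3,
    seed: int = 0,
    mean_length: float = 3000.0,
    length_shape: float = 9.0,
    target_strength: tuple[float, float] = (8.0, 1.5),
    nontarget_strength: tuple[float, float] = (1.0, 0.3),
) -> SimLayout:
    """Plant disjoint LMRs and a CpG landscape on a toy genome.

    Each chromosome is divided into ``n_lmrs`` equal slots and one LMR (length
    Gamma-distributed around ``mean_length``) is placed at a random offset
    within each slot, which guarantees disjointness.  The PRC2-target subset
    gets binding strengths from the high component.  Raises when the slots
    cannot accommodate the requested lengths.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    margin = 1000
    slot = chrom_len // n_lmrs
    if slot < 3 * mean_length + 2 * margin:
        raise ValueError(
            f"infeasible packing: {n_lmrs} LMRs of ~{mean_length:.0f} bp "
            f"do not fit a {chrom_len} bp chromosome"
        )
    chrom_lengths: dict[str, int] = {}
    cpg_pos: dict[str, np.ndarray] = {}
    lmrs: list[PlantedLMR] = []
    n_targets = int(round(target_fraction * n_lmrs * n_chroms))
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        chrom_lengths[chrom] = chrom_len
        lengths = rng.gamma(length_shape, mean_length / length_shape, n_lmrs)
        lengths = np.clip(lengths, 500, slot - 2 * margin).astype(np.int64)
        offsets = rng.integers(margin, slot - lengths - margin + 1)
        starts = np.arange(n_lmrs) * slot + offsets
        positions: list[np.ndarray] = []
        cursor = 0
        bounds: list[tuple[int, int]] = []
        for s, L in zip(starts, lengths):
            # background CpGs up to the island
            gaps = _spacings(rng, int(s - cursor), BG_SPACING)
            bg = cursor + np.cumsum(gaps)
            positions.append(bg[bg < s - 1])
            # dense CpGs inside the island, anchored at its start
            gaps = _spacings(rng, int(L), LMR_SPACING)
            inside = s + np.concatenate([[0], np.cumsum(gaps)])
            inside = inside[inside < s + L]
            positions.append(inside)
            bounds.append((int(s), int(inside[-1]) + 1))
            cursor = int(inside[-1]) + 2
        gaps = _spacings(rng, int(chrom_len - cursor), BG_SPACING)
        tail = cursor + np.cumsum(gaps)
        positions.append(tail[tail < chrom_len])
        cpg_pos[chrom] = np.concatenate(positions).astype(np.int64)
        for s, e in bounds:
            lmrs.append(PlantedLMR(chrom, s, e, False, 0.0))
    if n_targets > 0:
        chosen = rng.choice(len(lmrs), size=n_targets, replace=False)
        for i in chosen:
            lmrs[i].is_target = True
    for l in lmrs:
        mu, sd = target_strength if l.is_target else nontarget_strength
        l.strength = float(max(rng.normal(mu, sd), 0.05))
    return SimLayout(chrom_lengths, cpg_pos, lmrs)


def true_beta(layout: SimLayout, age: float, params: SimParams) -> dict[str, np.ndarray]:
    """Noise-free per-CpG methylation at a given age."""
    out: dict[str, np.ndarray] = {}
    lmrs_by_chrom: dict[str, list[PlantedLMR]] = {}
    for l in layout.lmrs:
        lmrs_by_chrom.setdefault(l.chrom, []).append(l)
    for chrom, pos in layout.cpg_pos.items():
        mu = np.full(pos.shape[0], params.clamp(params.m_bg0 - params.loss_rate * age))
        for l in lmrs_by_chrom.get(chrom, []):
            lo = np.searchsorted(pos, l.start, side="left")
            hi = np.searchsorted(pos, l.end, side="left")
            level = params.m_low0 + (params.gain_rate * age if l.is_target else 0.0)
            mu[lo:hi] = params.clamp(level)
        out[chrom] = mu
    return out


def simulate_methylome(
    layout: SimLayout,
    age: float,
    params: SimParams | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> Methylome:
    """Draw one sample's observed methylome at the given age.

    Coverage per CpG is Poisson; methylated counts are beta-binomial around the
    true beta.  Zero-coverage CpGs are omitted (as in real count files after
    filtering).  The same seed reproduces the sample byte for byte.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if params is None:
        params = SimParams()
    rng = np.random.default_rng(seed)
    truth = true_beta(layout, age, params)
    chroms, poss, meths, totals = [], [], [], []
    for chrom in layout.cpg_pos:
        pos = layout.cpg_pos[chrom]
        mu = truth[chrom]
        n = rng.poisson(params.coverage_mean, pos.shape[0])
        keep = n > 0
        s = params.dispersion_conc
        p = rng.beta(mu[keep] * s, (1.0 - mu[keep]) * s)
        k = rng.binomial(n[keep], p)
        chroms.append(np.full(keep.sum(), chrom, dtype=object))
        poss.append(pos[keep])
        meths.append(k)
        totals.append(n[keep])
    sites = make_sites(
        np.concatenate(chroms),
        np.concatenate(poss),
        ".",
        meth_count=np.concatenate(meths),
        total_count=np.concatenate(totals),
    )
    if sample_id is None:
        sample_id = f"sim-age{age:g}-s{seed}"
    return Methylome(sample_id, sites, assay="wgbs")


def simulate_chip_tracks(
    layout: SimLayout,
    n_factors: int = 2,
    params: SimParams | None = None,
    seed: int = 0,
) -> list[SignalTrack]:
    """Piecewise-constant fold-change tracks for ``n_factors`` PRC2 subunits.

    Each factor reads every LMR at its true binding strength plus independent
    Gaussian noise (floored at 0); bases outside LMRs sit at the background
    level.  Factors share the truth, so they correlate like real EZH2/SUZ12.
    """
    if n_factors < 1:
        raise ValueError("need at least one factor")
    if params is None:
        params = SimParams()
    rng = np.random.default_rng(seed)
    lmrs_by_chrom: dict[str, list[PlantedLMR]] = {}
    for l in layout.lmrs:
        lmrs_by_chrom.setdefault(l.chrom, []).append(l)
    for ls in lmrs_by_chrom.values():
        ls.sort(key=lambda l: l.start)
    tracks = []
    for _ in range(n_factors):
        data = {}
        for chrom, length in layout.chrom_lengths.items():
            s_list, e_list, v_list = [], [], []
            cursor = 0
            for l in lmrs_by_chrom.get(chrom, []):
                if l.start > cursor and params.chip_background > 0:
                    s_list.append(cursor)
                    e_list.append(l.start)
                    v_list.append(params.chip_background)
                s_list.append(l.start)
                e_list.append(l.end)
                v_list.append(max(l.strength + rng.normal(0.0, params.chip_noise_sd), 0.0))
                cursor = l.end
            if cursor < length and params.chip_background > 0:
                s_list.append(cursor)
                e_list.append(length)
                v_list.append(params.chip_background)
            data[chrom] = (np.array(s_list), np.array(e_list), np.array(v_list))
        tracks.append(SignalTrack(data, semantics="fold_change"))
    return tracks


def downsample_array(m: Methylome, probe_fraction: float = 0.015, seed: int = 0) -> Methylome:
    """Keep a random probe-like subset, carrying betas only (no counts)."""
    if not 0.0 < probe_fraction <= 1.0:
        raise ValueError("probe_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(m.n_sites) < probe_fraction
    sub = m.sites.loc[keep]
    sites = make_sites(
        sub["chrom"].to_numpy(),
        sub["pos"].to_numpy(dtype=np.int64),
        ".",
        beta=sub["beta"].to_numpy(),
    )
    return Methylome(m.sample_id, sites, assay="array")


def downsample_rrbs(
    m: Methylome,
    layout: SimLayout | None = None,
    seed: int = 0,
    dense_keep: float = 0.9,
    sparse_keep: float = 0.05,
    density_window: int = 1000,
    min_cpgs_in_window: int = 20,
) -> Methylome:
    """Keep CpG-dense neighbourhoods preferentially (enzyme-free RRBS stand-in).

    Local density is measured on the reference CpG landscape (the layout when
    given, otherwise the sample itself): sites in windows with at least
    ``min_cpgs_in_window`` CpGs are kept with probability ``dense_keep``,
    others with ``sparse_keep``.
    """
    if not m.has_counts:
        raise ValueError("RRBS downsampling requires a count-based methylome")
    rng = np.random.default_rng(seed)
    ref = (
        layout.cpg_pos
        if layout is not None
        else {
            str(c): g["pos"].to_numpy(dtype=np.int64)
            for c, g in m.sites.groupby("chrom", sort=False)
        }
    )
    half = density_window // 2
    keep = np.zeros(m.n_sites, dtype=bool)
    u = rng.random(m.n_sites)
    row = 0
    for c, g in m.sites.groupby("chrom", sort=False):
        pos = g["pos"].to_numpy(dtype=np.int64)
        refpos = ref.get(str(c), pos)
        counts = np.searchsorted(refpos, pos + half, side="left") - np.searchsorted(
            refpos, pos - half, side="left"
        )
        p = np.where(counts >= min_cpgs_in_window, dense_keep, sparse_keep)
        keep[row : row + len(g)] = u[row : row + len(g)] < p
        row += len(g)
    sub = m.sites.loc[keep]
    sites = make_sites(
        sub["chrom"].to_numpy(),
        sub["pos"].to_numpy(dtype=np.int64),
        ".",
        meth_count=sub["meth_count"].to_numpy(),
        total_count=sub["total_count"].to_numpy(),
    )
    return Methylome(m.sample_id, sites, assay="rrbs")


def downsample_single_cell(
    m: Methylome, site_fraction: float = 0.05, seed: int = 0
) -> Methylome:
    """Keep a sparse site subset and binarise each kept CpG (coverage 1)."""
    if not 0.0 < site_fraction <= 1.0:
        raise ValueError("site_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(m.n_sites) < site_fraction
    sub = m.sites.loc[keep]
    beta = sub["beta"].to_numpy()
    ok = ~np.isnan(beta)
    sub = sub.loc[ok]
    k = rng.binomial(1, beta[ok])
    sites = make_sites(
        sub["chrom"].to_numpy(),
        sub["pos"].to_numpy(dtype=np.int64),
        ".",
        meth_count=k,
        total_count=np.ones(k.shape[0], dtype=np.int64),
    )
    return Methylome(m.sample_id, sites, assay="scwgbs")
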