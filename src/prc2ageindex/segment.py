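"""Two-state HMM segmentation of low-methylated regions (LMRs).

The genome-wide methylation landscape is modelled as a hidden two-state chain
over consecutive CpGs: a hypomethylated state (regulatory islands) embedded in
a hypermethylated background.  Emissions are beta-binomial on the per-CpG
(methylated, total) read counts, capturing the overdispersion of bisulfite
data relative to a plain binomial.  Parameters are fitted by Baum–Welch EM;
chains are broken at CpG deserts (large gaps) so distant loci do not share
transition information.  Decoding reports maximal runs of CpGs whose posterior
probability of the low state exceeds a cut, subject to a minimum CpG count.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .core import Methylome, Region


@dataclass
class HmmParams:
    """Segmentation model parameters.

    Emissions per state are beta-binomial with mean ``mu`` and concentration
    ``conc`` (alpha = mu*conc, beta = (1-mu)*conc); the low state must have the
    smaller mean.  ``p_stay`` initialises both self-transition probabilities.
    ``desert_size`` (bp) splits chains at large inter-CpG gaps; ``min_cpgs``
    filters reported regions; ``tol`` is the absolute log-likelihood change at
    which EM stops.  When the fitted low-state mean is not below
    ``max_low_mean`` the two states have collapsed onto a uniformly methylated
    genome and no hypomethylated compartment exists, so nothing is reported.
    """

    p_stay: float = 0.95
    mu_low: float = 0.1
    mu_high: float = 0.8
    conc_low: float = 10.0
    conc_high: float = 10.0
    desert_size: int = 1000
    min_cpgs: int = 10
    max_iter: int = 100
    tol: float = 1e-4
    posterior_cut: float = 0.5
    max_low_mean: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_stay < 1.0:
            raise ValueError("p_stay must lie in (0, 1)")
        if not self.mu_low < self.mu_high:
            raise ValueError("low-state emission mean must be below high-state mean")
        for mu in (self.mu_low, self.mu_high):
            if not 0.0 < mu < 1.0:
                raise ValueError("emission means must lie in (0, 1)")
        if self.conc_low <= 0 or self.conc_high <= 0:
            raise ValueError("concentrations must be positive")
        if not 0.0 < self.posterior_cut < 1.0:
            raise ValueError("posterior_cut must lie in (0, 1)")

    @property
    def alpha_low(self) -> float:
        return self.mu_low * self.conc_low

    @property
    def beta_low(self) -> float:
        return (1.0 - self.mu_low) * self.conc_low

    @property
    def alpha_high(self) -> float:
        return self.mu_high * self.conc_high

    @property
    def beta_high(self) -> float:
        return (1.0 - self.mu_high) * self.conc_high


@dataclass
class SegmentationResult:
    """Called LMRs plus the fitted model and the EM log-likelihood trace."""

    regions: list[Region]
    params: HmmParams
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _forward_backward(e, chain_starts, T, pi):  # pragma: no cover - numba
    """Scaled forward-backward for a 2-state chain set.

    ``e`` holds max-normalised emission likelihoods; returns the posterior
    ``gamma``, summed transition counts ``xi``, summed chain-start posteriors,
    and the sum of log scaling factors.
    """
    N = e.shape[0]
    gamma = np.empty((N, 2))
    alpha = np.empty((N, 2))
    c = np.empty(N)
    xi = np.zeros((2, 2))
    sg = np.zeros(2)
    ll = 0.0
    for ci in range(chain_starts.shape[0] - 1):
        s = chain_starts[ci]
        t_end = chain_starts[ci + 1]
        a0 = pi[0] * e[s, 0]
        a1 = pi[1] * e[s, 1]
        cc = a0 + a1
        alpha[s, 0] = a0 / cc
        alpha[s, 1] = a1 / cc
        c[s] = cc
        for t in range(s + 1, t_end):
            a0 = (alpha[t - 1, 0] * T[0, 0] + alpha[t - 1, 1] * T[1, 0]) * e[t, 0]
            a1 = (alpha[t - 1, 0] * T[0, 1] + alpha[t - 1, 1] * T[1, 1]) * e[t, 1]
            cc = a0 + a1
            alpha[t, 0] = a0 / cc
            alpha[t, 1] = a1 / cc
            c[t] = cc
        b0 = 1.0
        b1 = 1.0
        gamma[t_end - 1, 0] = alpha[t_end - 1, 0]
        gamma[t_end - 1, 1] = alpha[t_end - 1, 1]
        for t in range(t_end - 2, s - 1, -1):
            f0 = e[t + 1, 0] * b0 / c[t + 1]
            f1 = e[t + 1, 1] * b1 / c[t + 1]
            xi[0, 0] += alpha[t, 0] * T[0, 0] * f0
            xi[0, 1] += alpha[t, 0] * T[0, 1] * f1
            xi[1, 0] += alpha[t, 1] * T[1, 0] * f0
            xi[1, 1] += alpha[t, 1] * T[1, 1] * f1
            b0n = T[0, 0] * f0 + T[0, 1] * f1
            b1n = T[1, 0] * f0 + T[1, 1] * f1
            b0 = b0n
            b1 = b1n
            g0 = alpha[t, 0] * b0
            g1 = alpha[t, 1] * b1
            gs = g0 + g1
            gamma[t, 0] = g0 / gs
            gamma[t, 1] = g1 / gs
        sg[0] += gamma[s, 0]
        sg[1] += gamma[s, 1]
        for t in range(s, t_end):
            ll += np.log(c[t])
    return gamma, xi, sg, ll


@njit(cache=True)
def _viterbi(loge, chain_starts, logT, logpi):  # pragma: no cover - numba
    N = loge.shape[0]
    state = np.empty(N, dtype=np.int8)
    for ci in range(chain_starts.shape[0] - 1):
        s = chain_starts[ci]
        t_end = chain_starts[ci + 1]
        n = t_end - s
        d0 = logpi[0] + loge[s, 0]
        d1 = logpi[1] + loge[s, 1]
        back = np.empty((n, 2), dtype=np.int8)
        for t in range(1, n):
            c00 = d0 + logT[0, 0]
            c10 = d1 + logT[1, 0]
            c01 = d0 + logT[0, 1]
            c11 = d1 + logT[1, 1]
            if c00 >= c10:
                n0 = c00 + loge[s + t, 0]
                back[t, 0] = 0
            else:
                n0 = c10 + loge[s + t, 0]
                back[t, 0] = 1
            if c11 >= c01:
                n1 = c11 + loge[s + t, 1]
                back[t, 1] = 1
            else:
                n1 = c01 + loge[s + t, 1]
                back[t, 1] = 0
            d0 = n0
            d1 = n1
        k = 0 if d0 >= d1 else 1
        state[t_end - 1] = k
        for t in range(n - 1, 0, -1):
            k = back[t, k]
            state[s + t - 1] = k
    return state


# ---------------------------------------------------------------------------
# beta-binomial emissions on the unique (coverage, meth) pairs


def _pair_table(k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse sites to unique (k, n) pairs; emissions depend on counts only."""
    nmax = int(n.max())
    codes = n.astype(np.int64) * (nmax + 2) + k.astype(np.int64)
    uniq, inverse = np.unique(codes, return_inverse=True)
    un = uniq // (nmax + 2)
    uk = uniq % (nmax + 2)
    return uk.astype(np.float64), un.astype(np.float64), inverse


def _bb_loglik(uk: np.ndarray, un: np.ndarray, mu: float, conc: float) -> np.ndarray:
    a = mu * conc
    b = (1.0 - mu) * conc
    return (
        gammaln(un + 1)
        - gammaln(uk + 1)
        - gammaln(un - uk + 1)
        + gammaln(uk + a)
        + gammaln(un - uk + b)
        - gammaln(un + a + b)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )


_MU_EPS = 1e-4
_CONC_LO, _CONC_HI = np.log(1.5), np.log(1e5)


def _clamp_emission(x: np.ndarray) -> tuple[float, float]:
    mu = float(expit(np.clip(x[0], logit(_MU_EPS), logit(1 - _MU_EPS))))
    conc = float(np.exp(np.clip(x[1], _CONC_LO, _CONC_HI)))
    return mu, conc


def _optimise_emission(
    w: np.ndarray, uk: np.ndarray, un: np.ndarray, mu0: float, conc0: float
) -> tuple[float, float]:
    """Maximise the expected complete-data emission likelihood for one state.

    Nelder-Mead from the previous parameters: the returned point is never worse
    than the start, so each EM step is a generalised EM step and the total
    log-likelihood is non-decreasing.
    """
    if w.sum() < 1e-9:
        return mu0, conc0

    def nll(x):
        mu, conc = _clamp_emission(x)
        return -float(w @ _bb_loglik(uk, un, mu, conc))

    x0 = np.array([logit(np.clip(mu0, _MU_EPS, 1 - _MU_EPS)), np.log(conc0)])
    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-9},
    )
    if res.fun <= nll(x0):
        return _clamp_emission(res.x)
    return mu0, conc0


# ---------------------------------------------------------------------------


def _chain_starts(chrom: np.ndarray, pos: np.ndarray, desert_size: int) -> np.ndarray:
    """Chain boundaries: chromosome changes and gaps > desert_size bp."""
    n = pos.shape[0]
    if n == 0:
        return np.array([0], dtype=np.int64)
    breaks = (chrom[1:] != chrom[:-1]) | ((pos[1:] - pos[:-1]) > desert_size)
    starts = np.concatenate([[0], np.flatnonzero(breaks) + 1, [n]])
    return starts.astype(np.int64)


def call_lmrs(
    m: Methylome,
    params: HmmParams | None = None,
    decoding: str = "posterior",
) -> SegmentationResult:
    """Segment a count-based methylome into low-methylated regions.

    Chromosomes with fewer than ``min_cpgs`` covered CpGs are skipped.  Returns
    regions anchored on CpG positions (end = last member CpG + 1) with
    ``n_cpgs`` and ``mean_level`` filled, sorted and disjoint.

    Array and single-cell methylomes are rejected: without read counts (or with
    binarised singleton coverage) the emission model is meaningless — the
    site-level LMC ranking path serves those assays.
    """
    if params is None:
        params = HmmParams()
    if m.assay in ("array", "scwgbs"):
        raise ValueError(
            f"assay {m.assay!r} is not segmentable; use the LMC site-level path"
        )
    if m.n_sites == 0:
        return SegmentationResult([], params, [], converged=True)
    if not m.has_counts:
        raise ValueError("segmentation requires read counts")

    cov = m.covered_sites()
    # restrict to chromosomes with enough covered CpGs to inform the model
    counts = cov.groupby("chrom")["pos"].size()
    keep = counts[counts >= params.min_cpgs].index
    cov = cov[cov["chrom"].isin(keep)].reset_index(drop=True)
    if len(cov) == 0:
        return SegmentationResult([], params, [], converged=True)

    chrom = cov["chrom"].to_numpy()
    pos = cov["pos"].to_numpy(dtype=np.int64)
    k = cov["meth_count"].to_numpy(dtype=np.float64)
    n = cov["total_count"].to_numpy(dtype=np.float64)
    starts = _chain_starts(chrom, pos, params.desert_size)

    uk, un, inverse = _pair_table(k, n)
    T = np.array(
        [
            [params.p_stay, 1.0 - params.p_stay],
            [1.0 - params.p_stay, params.p_stay],
        ]
    )
    pi = np.array([0.5, 0.5])
    mus = [params.mu_low, params.mu_high]
    concs = [params.conc_low, params.conc_high]

    trace: list[float] = []
    gamma = None
    converged = False
    for _ in range(params.max_iter):
        table = np.stack(
            [_bb_loglik(uk, un, mus[j], concs[j]) for j in range(2)], axis=1
        )
        loge = table[inverse]
        offset = loge.max(axis=1)
        e = np.exp(loge - offset[:, None])
        gamma, xi, sg, ll_scaled = _forward_backward(e, starts, T, pi)
        ll = float(ll_scaled + offset.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < params.tol:
            converged = True
            break
        # M-step: exact for transitions/start, generalised (ascent) for emissions
        rows = xi.sum(axis=1)
        if np.all(rows > 0):
            T = xi / rows[:, None]
            T = np.clip(T, 1e-6, 1 - 1e-6)
            T /= T.sum(axis=1, keepdims=True)
        if sg.sum() > 0:
            pi = np.clip(sg / sg.sum(), 1e-6, 1 - 1e-6)
            pi /= pi.sum()
        for j in range(2):
            w = np.bincount(inverse, weights=gamma[:, j], minlength=uk.shape[0])
            mus[j], concs[j] = _optimise_emission(w, uk, un, mus[j], concs[j])
    if not converged:
        warnings.warn(
            "EM did not converge within max_iter; using best-iterate parameters",
            RuntimeWarning,
        )

    # resolve label symmetry: the low state is the one with the smaller mean
    low = int(np.argmin(mus))
    high = 1 - low
    fitted = replace(
        params,
        p_stay=float((T[0, 0] + T[1, 1]) / 2.0),
        mu_low=float(mus[low]),
        mu_high=float(mus[high]),
        conc_low=float(concs[low]),
        conc_high=float(concs[high]),
    )

    if mus[low] >= params.max_low_mean:
        # no genuinely hypomethylated state: the model collapsed
        return SegmentationResult([], fitted, trace, converged=converged)

    if decoding == "posterior":
        in_low = gamma[:, low] >= params.posterior_cut
    elif decoding == "viterbi":
        table = np.stack(
            [_bb_loglik(uk, un, mus[j], concs[j]) for j in range(2)], axis=1
        )
        state = _viterbi(
            table[inverse], starts, np.log(T), np.log(np.clip(pi, 1e-12, None))
        )
        in_low = state == low
    else:
        raise ValueError(f"unknown decoding {decoding!r}")

    beta = cov["beta"].to_numpy()
    regions = _runs_to_regions(chrom, pos, beta, in_low, starts, params.min_cpgs)
    return SegmentationResult(regions, fitted, trace, converged=converged)


def _runs_to_regions(
    chrom: np.ndarray,
    pos: np.ndarray,
    beta: np.ndarray,
    in_low: np.ndarray,
    chain_starts: np.ndarray,
    min_cpgs: int,
) -> list[Region]:
    regions: list[Region] = []
    for ci in range(chain_starts.shape[0] - 1):
        s, t_end = int(chain_starts[ci]), int(chain_starts[ci + 1])
        flags = in_low[s:t_end]
        if not flags.any():
            continue
        padded = np.concatenate([[False], flags, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a < min_cpgs:
                continue
            lo, hi = s + int(a), s + int(b)
            regions.append(
                Region(
                    str(chrom[lo]),
                    int(pos[lo]),
                    int(pos[hi - 1]) + 1,
                    n_cpgs=hi - lo,
                    mean_level=float(beta[lo:hi].mean()),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def score_regions(regions: Sequence[Region], m: Methylome) -> list[Region]:
    """Fill ``n_cpgs`` and ``mean_level`` for regions from a methylome.

    ``n_cpgs`` counts covered CpGs inside [start, end); ``mean_level`` is their
    unweighted mean beta (NaN when no CpG is covered).
    """
    cov = m.covered_sites()
    slices: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, grp in cov.groupby("chrom", sort=False):
        slices[str(c)] = (
            grp["pos"].to_numpy(dtype=np.int64),
            grp["beta"].to_numpy(),
        )
    out: list[Region] = []
    for r in regions:
        if r.chrom in slices:
            p, b = slices[r.chrom]
            lo = int(np.searchsorted(p, r.start, side="left"))
            hi = int(np.searchsorted(p, r.end, side="left"))
        else:
            lo = hi = 0
        n = hi - lo
        mean = float(b[lo:hi].mean()) if n > 0 else float("nan")
        out.append(replace(r, n_cpgs=n, mean_level=mean))
    return out


def base_jaccard(a: Sequence[Region], b: Sequence[Region]) -> float:
    """Base-level Jaccard index between two region sets (0 when both empty)."""

    def merged(regions: Sequence[Region]) -> dict[str, np.ndarray]:
        per: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            per.setdefault(r.chrom, []).append((r.start, r.end))
        out = {}
        for c, ivs in per.items():
            ivs.sort()
            merged_ivs: list[list[int]] = []
            for s, e in ivs:
                if merged_ivs and s <= merged_ivs[-1][1]:
                    merged_ivs[-1][1] = max(merged_ivs[-1][1], e)
                else:
                    merged_ivs.append([s, e])
            out[c] = np.array(merged_ivs, dtype=np.int64)
        return out

    A, B = merged(a), merged(b)
    inter = 0
    len_a = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in A.values())
    len_b = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in B.values())
    for c in set(A) & set(B):
        ia, ib = A[c], B[c]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if e > s:
                inter += int(e - s)
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
    union = len_a + len_b - inter
    return inter / union if union > 0 else 0.0
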