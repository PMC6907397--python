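"""Significant peaks in Ks distributions and WGD calling.

Peak significance follows the SiZer approach (SIgnificant ZERo crossings
of derivatives): the density derivative is estimated over a grid of
positions x bandwidths with a Gaussian kernel, and each cell is coded
significantly increasing / decreasing / flat / sparse using simultaneous
confidence intervals with the effective-independent-blocks adjustment. A
peak is a significant rise followed by a significant fall that persists
across at least two adjacent bandwidths — a feature of the data, not of
one smoothing choice.

Peak ages come from maximum-likelihood normal mixtures: 1-D EM from many
random and k-means starts, model selection by BIC with p = 3k - 1
parameters. Only mixture components that coincide with a SiZer peak are
reported as WGD candidates; components younger than a recency threshold
are flagged as likely background duplication rather than WGD. Shared WGDs
across genomes are grouped by single linkage on component means, and each
call is placed before/after a speciation by comparing its Ks to the mode
of an ortholog Ks distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.stats import norm

NOT_SIG, SIG_INCREASE, SIG_DECREASE, SPARSE = 0, 1, -1, 2

DEFAULT_BINS = 401
DEFAULT_ALPHA = 0.05
RECENCY_THRESHOLD = 0.25  # components younger than this are flagged non-WGD


def _as_values(sample) -> np.ndarray:
    values = np.asarray(getattr(sample, "values", sample), dtype=float)
    return values[np.isfinite(values)]


def silverman_bandwidth(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def kde(sample, bandwidth: float, bins: int = DEFAULT_BINS,
        ks_range: tuple[float, float] = (0.0, 3.0)) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate on a fixed grid.

    Returns (grid, density). The density integrates to ~1 over the real
    line; over the grid it loses only the tail mass outside ``ks_range``.
    """
    values = _as_values(sample)
    if len(values) == 0:
        raise ValueError("empty sample")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(ks_range[0], ks_range[1], bins)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = norm.pdf(z).mean(axis=1) / bandwidth
    return grid, density


@dataclass
class SiZerMap:
    grid: np.ndarray        # positions (bins,)
    bandwidths: np.ndarray  # (n_bw,) log-spaced
    codes: np.ndarray       # (n_bw, bins) over {NOT_SIG, SIG_INCREASE, ...}
    alpha: float


def sizer_map(
    sample,
    bandwidths: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    bins: int = DEFAULT_BINS,
    ks_range: tuple[float, float] = (0.0, 3.0),
    min_ess: float = 5.0,
) -> SiZerMap:
    """SiZer significance map of the density derivative.

    Per (position, bandwidth) cell the derivative f'(x; h) and its
    standard error are estimated from the Gaussian derivative kernel; the
    simultaneous level comes from adjusting alpha for the effective number
    of independent blocks (grid width / 2h). Cells whose effective local
    sample size is below ``min_ess`` are coded sparse.
    """
    values = _as_values(sample)
    n = len(values)
    grid = np.linspace(ks_range[0], ks_range[1], bins)
    if bandwidths is None:
        h0 = silverman_bandwidth(values) if n >= 2 else 0.1
        bandwidths = np.geomspace(0.5 * h0, 4.0 * h0, 15)
    codes = np.full((len(bandwidths), bins), SPARSE, dtype=np.int8)
    if n < 20:
        return SiZerMap(grid=grid, bandwidths=np.asarray(bandwidths),
                        codes=codes, alpha=alpha)
    span = ks_range[1] - ks_range[0]
    for bi, h in enumerate(bandwidths):
        z = (grid[:, None] - values[None, :]) / h
        phi = norm.pdf(z)
        # derivative kernel values per (position, observation)
        dk = -z * phi / h**2
        deriv = dk.mean(axis=1)
        se = dk.std(axis=1, ddof=1) / math.sqrt(n)
        ess = phi.sum(axis=1) / norm.pdf(0.0)
        m = max(span / (2.0 * h), 1.0)  # effective independent blocks
        q = norm.ppf(0.5 * (1.0 + (1.0 - alpha) ** (1.0 / m)))
        row = np.full(bins, NOT_SIG, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            row[deriv - q * se > 0] = SIG_INCREASE
            row[deriv + q * se < 0] = SIG_DECREASE
        row[ess < min_ess] = SPARSE
        codes[bi] = row
    return SiZerMap(grid=grid, bandwidths=np.asarray(bandwidths),
                    codes=codes, alpha=alpha)


def _row_features(row: np.ndarray, grid: np.ndarray) -> list[tuple[float, float]]:
    """Peak intervals in one bandwidth row: +run followed by -run."""
    runs = []  # (code, start_idx, end_idx) over significant codes only
    for i, code in enumerate(row):
        if code not in (SIG_INCREASE, SIG_DECREASE):
            continue
        if runs and runs[-1][0] == code and i - runs[-1][2] <= 1:
            runs[-1] = (code, runs[-1][1], i)
        elif runs and runs[-1][0] == code:
            runs.append((code, i, i))
        elif not runs or runs[-1][0] != code:
            runs.append((code, i, i))
    features = []
    for (c1, s1, _), (c2, _, e2) in zip(runs, runs[1:]):
        if c1 == SIG_INCREASE and c2 == SIG_DECREASE:
            features.append((float(grid[s1]), float(grid[e2])))
    return features


def count_significant_peaks(map_: SiZerMap) -> tuple[int, list[tuple[float, float]]]:
    """Number of SiZer-significant peaks and their position intervals.

    A peak is a significant-increase run followed by a significant-
    decrease run at some bandwidth, persisting (by interval overlap)
    across at least two adjacent bandwidths. The count is the maximum over
    bandwidths of persistent features; intervals come from the first row
    attaining that count.
    """
    per_row = [_row_features(row, map_.grid) for row in map_.codes]
    best_count, best_intervals = 0, []
    for r, feats in enumerate(per_row):
        persistent = []
        for lo, hi in feats:
            neighbors = []
            if r > 0:
                neighbors.extend(per_row[r - 1])
            if r < len(per_row) - 1:
                neighbors.extend(per_row[r + 1])
            if any(lo <= nhi and hi >= nlo for nlo, nhi in neighbors):
                persistent.append((lo, hi))
        if len(persistent) > best_count:
            best_count = len(persistent)
            best_intervals = persistent
    return best_count, best_intervals


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n: int

    def sorted(self) -> "MixtureFit":
        order = np.argsort(self.means)
        return MixtureFit(self.k, self.weights[order], self.means[order],
                          self.sds[order], self.loglik, self.bic, self.n)


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _em_1d(
    values: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
    min_sd: float = 1e-4,
    min_weight: float = 1e-3,
) -> MixtureFit | None:
    """EM for a 1-D Gaussian mixture; None when a component degenerates.

    The observed-data log-likelihood is checked to be non-decreasing at
    every iteration (a property of EM; a violation means a numerical
    fault).
    """
    n = len(values)
    k = len(means)
    prev_ll = -np.inf
    x = values[:, None]
    sqrt_2pi = math.sqrt(2.0 * math.pi)
    for _ in range(max_iter):
        z = (x - means[None, :]) / sds[None, :]
        comp = (weights / (sds * sqrt_2pi))[None, :] * np.exp(-0.5 * z * z)
        mix = np.maximum(comp.sum(axis=1), 1e-300)
        ll = float(np.log(mix).sum())
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise AssertionError("EM log-likelihood decreased")
        resp = comp / mix[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk / n < min_weight):
            return None
        weights = nk / n
        means = (resp * x).sum(axis=0) / nk
        var = (resp * (x - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < min_sd):
            return None
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    p = 3 * k - 1
    bic = -2.0 * prev_ll + p * math.log(n)
    return MixtureFit(k=k, weights=weights, means=means, sds=sds,
                      loglik=prev_ll, bic=bic, n=n).sorted()


def fit_gaussian_mixture(
    sample,
    k_range: range = range(1, 6),
    n_random_starts: int = 20,
    n_kmeans_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[list[MixtureFit], MixtureFit]:
    """Fit normal mixtures for each k, select the minimum-BIC model.

    Each k runs a short EM burn-in from ``n_random_starts`` random starts
    (means drawn from the data) plus ``n_kmeans_starts`` k-means starts,
    then continues the best burn-in fit to full convergence (standard
    multi-start practice). Raises when the sample is smaller than
    10 x max(k_range).
    """
    values = _as_values(sample)
    k_max = max(k_range)
    if len(values) < 10 * k_max:
        raise ValueError(f"need >= {10 * k_max} values to fit up to k={k_max}")
    rng = np.random.default_rng(seed)
    fits: list[MixtureFit] = []
    global_sd = values.std(ddof=1)
    for k in k_range:
        starts = []
        for _ in range(n_random_starts):
            starts.append(rng.choice(values, size=k, replace=False))
        for s in range(n_kmeans_starts):
            centroids, _ = kmeans2(values, k, seed=int(rng.integers(2**31)),
                                   minit="++")
            starts.append(np.sort(centroids))
        burn: MixtureFit | None = None
        for means0 in starts:
            fit = _em_1d(
                values,
                weights=np.full(k, 1.0 / k),
                means=np.asarray(means0, dtype=float),
                sds=np.full(k, max(global_sd / k, 1e-3)),
                tol=tol, max_iter=100,
            )
            if fit is not None and (burn is None or fit.loglik > burn.loglik):
                burn = fit
        if burn is None:
            continue
        best = _em_1d(values, weights=burn.weights, means=burn.means,
                      sds=burn.sds, tol=tol, max_iter=max_iter)
        fits.append(best if best is not None else burn)
    if not fits:
        raise RuntimeError("every EM start degenerated for every k")
    selected = min(fits, key=lambda f: f.bic)
    return fits, selected


def match_components_to_sizer(
    fit: MixtureFit, peak_intervals: list[tuple[float, float]]
) -> list[int]:
    """Indices of mixture components whose mean lies inside a SiZer peak."""
    return [
        i for i, mean in enumerate(fit.means)
        if any(lo <= mean <= hi for lo, hi in peak_intervals)
    ]


@dataclass
class WGDCall:
    ks_mean: float
    genomes: tuple[str, ...]
    component_means: dict[str, float] = field(default_factory=dict)
    is_wgd: bool = True
    placements: dict[str, str] = field(default_factory=dict)


def match_peaks_across_genomes(
    component_means: dict[str, list[float]],
    tolerance: float = 0.25,
    recency_threshold: float = RECENCY_THRESHOLD,
) -> list[WGDCall]:
    """Group reported component means across genomes into shared WGD calls.

    Single-linkage in one dimension: means are chained while adjacent
    values lie within ``tolerance``. Calls with pooled mean below
    ``recency_threshold`` are flagged as likely background duplication
    (``is_wgd=False``) rather than WGD.
    """
    items = sorted(
        (mean, genome)
        for genome, means in component_means.items()
        for mean in means
    )
    calls: list[WGDCall] = []
    group: list[tuple[float, str]] = []

    def flush() -> None:
        if not group:
            return
        pooled = float(np.mean([m for m, _ in group]))
        genomes = tuple(sorted({g for _, g in group}))
        calls.append(WGDCall(
            ks_mean=pooled, genomes=genomes,
            component_means={g: m for m, g in group},
            is_wgd=pooled >= recency_threshold,
        ))

    for mean, genome in items:
        if group and mean - group[-1][0] > tolerance:
            flush()
            group = []
        group.append((mean, genome))
    flush()
    return calls


def _kde_mode_and_halfwidth(values: np.ndarray) -> tuple[float, float]:
    grid, dens = kde(values, silverman_bandwidth(values),
                     ks_range=(0.0, float(values.max()) * 1.1 + 0.1))
    peak = int(np.argmax(dens))
    half = dens[peak] / 2.0
    lo = peak
    while lo > 0 and dens[lo] > half:
        lo -= 1
    hi = peak
    while hi < len(dens) - 1 and dens[hi] > half:
        hi += 1
    halfwidth = (grid[hi] - grid[lo]) / 2.0
    return float(grid[peak]), float(halfwidth)


def place_wgd_relative_to_speciation(
    wgd: WGDCall,
    ortholog_sample,
    label: str,
    wgd_sd: float | None = None,
) -> str:
    """Place a WGD before/after the speciation an ortholog sample dates.

    The speciation Ks is the mode of the ortholog Ks density. The WGD is
    ``before_speciation`` when its Ks exceeds the mode by more than delta,
    ``after_speciation`` when smaller by more than delta, else
    ``indistinguishable``; delta is half the larger of the two peak
    half-widths (ortholog KDE half-width at half maximum; WGD component
    half-width from its sd when known).
    """
    values = _as_values(ortholog_sample)
    if len(values) == 0:
        raise ValueError("empty ortholog sample")
    mode, hw_orth = _kde_mode_and_halfwidth(values)
    hw_wgd = 1.1774 * wgd_sd if wgd_sd is not None else hw_orth  # FWHM/2 of N(0, sd)
    delta = 0.5 * max(hw_orth, hw_wgd)
    if wgd.ks_mean > mode + delta:
        placement = "before_speciation"
    elif wgd.ks_mean < mode - delta:
        placement = "after_speciation"
    else:
        placement = "indistinguishable"
    wgd.placements[label] = placement
    return placement


@dataclass
class GenomePeakReport:
    genome: str
    sizer: SiZerMap
    n_peaks: int
    peak_intervals: list[tuple[float, float]]
    fits: list[MixtureFit]
    selected: MixtureFit
    reported_components: list[int]


def analyze_genome_ks(sample, genome: str = "genome", seed: int = 0,
                      k_range: range = range(1, 6)) -> GenomePeakReport:
    """SiZer + mixture analysis of one genome's paranome Ks sample."""
    smap = sizer_map(sample)
    n_peaks, intervals = count_significant_peaks(smap)
    fits, selected = fit_gaussian_mixture(sample, k_range=k_range, seed=seed)
    reported = match_components_to_sizer(selected, intervals)
    return GenomePeakReport(genome=genome, sizer=smap, n_peaks=n_peaks,
                            peak_intervals=intervals, fits=fits,
                            selected=selected, reported_components=reported)


def shared_wgd_calls(
    reports: list[GenomePeakReport], tolerance: float = 0.25
) -> list[WGDCall]:
    """Cross-genome WGD calls from per-genome peak reports."""
    means = {
        rep.genome: [float(rep.selected.means[i])
                     for i in rep.reported_components]
        for rep in reports
    }
    return match_peaks_across_genomes(means, tolerance=tolerance)
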