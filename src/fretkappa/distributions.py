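"""Empirical distributions, FWHH summaries, and the isotropic kappa^2 density.

This module provides the statistical layer of the pipeline: histograms of
R_DA, kappa^2 and efficiency samples; the closed-form probability density of
kappa^2 under isotropic, independently re-orienting dipoles (the theoretical
reference curve with mean 2/3); reconstruction of the "apparent" distance
distribution obtained by pushing efficiencies through the unique-R0 inverse
map; and the true-vs-apparent width comparison that quantifies how the
unique-R0 assumption inflates the width of the inferred distance
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fret_model import apparent_distance

DEFAULT_BIN_WIDTH_DISTANCE = 1.0  # Angstrom
DEFAULT_BIN_WIDTH_EFFICIENCY = 0.02
DEFAULT_BIN_WIDTH_KAPPA2 = 0.05


@dataclass(frozen=True)
class Histogram:
    """Binned empirical distribution with unit-area density."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "density", density)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending with >= 2 entries")
        if counts.shape != (edges.size - 1,) or density.shape != counts.shape:
            raise ValueError("counts/density must have one entry per bin")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: bin_left bin_right count density."""
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "density": self.density,
            }
        )


@dataclass(frozen=True)
class DistributionSummary:
    """Mean, standard deviation and full width at half height of a sample."""

    mean: float
    standard_deviation: float
    fwhh: float
    n_samples: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.standard_deviation,
            "fwhh": self.fwhh,
            "n": self.n_samples,
            "n_excluded": self.n_excluded,
        }


def make_histogram(samples, bin_width) -> Histogram:
    """Histogram with unit-area density and edges aligned to bin_width multiples.

    ``bin_width`` is a positive float, or the string ``"auto"`` to delegate
    bin selection to numpy's automatic rule (edges then unaligned).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample collection")
    if isinstance(bin_width, str):
        if bin_width != "auto":
            raise ValueError(f"unknown bin rule {bin_width!r}")
        edges = np.histogram_bin_edges(x, bins="auto")
        if edges.size < 2 or edges[0] == edges[-1]:
            edges = np.array([x[0] - 0.5, x[0] + 0.5])
    else:
        w = float(bin_width)
        if w <= 0:
            raise ValueError("bin_width must be positive")
        lo = math.floor(x.min() / w)
        hi = math.ceil(x.max() / w)
        if hi <= lo:
            hi = lo + 1
        edges = (np.arange(lo, hi + 1)) * w
    counts, edges = np.histogram(x, bins=edges)
    total = counts.sum()
    density = counts / (total * np.diff(edges))
    return Histogram(bin_edges=edges, counts=counts, density=density)


def fwhh(histogram: Histogram) -> float:
    """Full width at half height of the histogram's global peak.

    The peak is the leftmost maximal-density bin; the width is measured
    between the outermost crossings of half the peak density, linearly
    interpolated between bin centers.  A histogram whose mass sits in a
    single bin has FWHH equal to that bin's width by convention.
    """
    d = histogram.density
    occupied = np.flatnonzero(histogram.counts)
    if occupied.size == 1:
        return float(histogram.widths[occupied[0]])
    if np.all(d == d[0]):
        raise ValueError("flat histogram: no defined peak")
    peak = int(np.argmax(d))
    half = d[peak] / 2.0
    c = histogram.centers

    # outermost left crossing: first bin from the left at/above half height
    i = int(np.argmax(d >= half))
    if i == 0:
        left = histogram.bin_edges[0]
    else:
        left = c[i - 1] + (half - d[i - 1]) / (d[i] - d[i - 1]) * (c[i] - c[i - 1])

    # outermost right crossing: last bin at/above half height
    j = len(d) - 1 - int(np.argmax(d[::-1] >= half))
    if j == len(d) - 1:
        right = histogram.bin_edges[-1]
    else:
        right = c[j] + (half - d[j]) / (d[j + 1] - d[j]) * (c[j + 1] - c[j])
    return float(right - left)


def summarize(samples, bin_width, n_excluded: int = 0) -> DistributionSummary:
    """Moment summary plus histogram-based FWHH of a sample collection."""
    x = np.asarray(samples, dtype=float).ravel()
    hist = make_histogram(x, bin_width)
    try:
        width = fwhh(hist)
    except ValueError:
        width = float(np.ptp(hist.bin_edges))
    return DistributionSummary(
        mean=float(x.mean()),
        standard_deviation=float(x.std(ddof=0)),
        fwhh=width,
        n_samples=int(x.size),
        n_excluded=n_excluded,
    )


def isotropic_kappa2_pdf(kappa2):
    """Closed-form density of kappa^2 for isotropic, independent dipoles.

    p(k) = ln(2 + sqrt(3)) / (2 sqrt(3 k))                       for 0 < k <= 1
    p(k) = ln[(2 + sqrt(3)) / (sqrt(k) + sqrt(k - 1))] / (2 sqrt(3 k))
                                                                  for 1 < k <= 4
    and 0 for k > 4.  The density has an integrable inverse-square-root
    singularity at k = 0, integrates to 1 and has mean 2/3.
    """
    k = np.asarray(kappa2, dtype=float)
    if np.any(k <= 0):
        raise ValueError("kappa2 must be positive (singularity at 0; density 0 for k <= 0)")
    ln_c = math.log(2.0 + math.sqrt(3.0))
    with np.errstate(invalid="ignore"):
        base = 1.0 / (2.0 * np.sqrt(3.0 * k))
        low = ln_c * base
        sqrt_k = np.sqrt(k)
        high = base * (ln_c - np.log(np.where(k > 1, sqrt_k + np.sqrt(np.abs(k - 1.0)), 1.0)))
    p = np.where(k <= 1.0, low, np.where(k <= 4.0, high, 0.0))
    return float(p) if np.isscalar(kappa2) else p


@dataclass(frozen=True)
class ApparentReconstruction:
    """Apparent-distance histogram with its summary and exclusion count."""

    histogram: Histogram
    summary: DistributionSummary
    distances: np.ndarray
    n_excluded: int


def reconstruct_apparent_distribution(
    efficiencies, r0: float, bin_width: float = DEFAULT_BIN_WIDTH_DISTANCE
) -> ApparentReconstruction:
    """Apparent donor-acceptor distance distribution under a unique R0.

    Each efficiency strictly inside (0, 1) is mapped to
    R_app = R0 (1/E - 1)^(1/6); efficiencies at or outside the open
    interval (e.g. E = 0 frames with kappa^2 = 0) cannot be inverted and
    are excluded with a reported count.
    """
    e = np.asarray(efficiencies, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("empty efficiency collection")
    keep = (e > 0.0) & (e < 1.0)
    n_excluded = int(e.size - keep.sum())
    if not keep.any():
        raise ValueError("all efficiencies outside (0, 1); nothing to reconstruct")
    r_app = apparent_distance(e[keep], r0)
    hist = make_histogram(r_app, bin_width)
    summary = summarize(r_app, bin_width, n_excluded=n_excluded)
    return ApparentReconstruction(
        histogram=hist, summary=summary, distances=r_app, n_excluded=n_excluded
    )


@dataclass(frozen=True)
class TrueApparentComparison:
    """Width comparison of the true vs unique-R0 apparent distance distributions."""

    true_summary: DistributionSummary
    apparent_summary: DistributionSummary
    width_ratio: float


def _histogram_summary(hist: Histogram, n_excluded: int = 0) -> DistributionSummary:
    w = hist.counts / max(hist.n_samples, 1)
    mean = float(np.sum(w * hist.centers))
    var = float(np.sum(w * (hist.centers - mean) ** 2))
    try:
        width = fwhh(hist)
    except ValueError:
        width = float(np.ptp(hist.bin_edges))
    return DistributionSummary(
        mean=mean,
        standard_deviation=math.sqrt(var),
        fwhh=width,
        n_samples=hist.n_samples,
        n_excluded=n_excluded,
    )


def compare_true_vs_apparent(
    true_distances,
    apparent: Histogram,
    bin_width: float = DEFAULT_BIN_WIDTH_DISTANCE,
    n_excluded_apparent: int = 0,
) -> TrueApparentComparison:
    """Summaries of both distributions and FWHH(apparent)/FWHH(true).

    When the true distances occupy a single histogram bin (a degenerate,
    effectively zero-width distribution) the ratio is reported as +inf.
    """
    x = np.asarray(true_distances, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty true-distance collection")
    true_hist = make_histogram(x, bin_width)
    true_summary = summarize(x, bin_width)
    apparent_summary = _histogram_summary(apparent, n_excluded=n_excluded_apparent)
    if int(np.count_nonzero(true_hist.counts)) <= 1:
        ratio = math.inf
    else:
        ratio = apparent_summary.fwhh / true_summary.fwhh
    return TrueApparentComparison(
        true_summary=true_summary,
        apparent_summary=apparent_summary,
        width_ratio=float(ratio),
    )


@dataclass(frozen=True)
class SeriesSummary:
    """Running-mean convergence diagnostic of a distance time series."""

    table: pd.DataFrame  # columns: frame, r_da, running_mean
    overall_mean: float
    tail_mean: float
    tail_fraction: float


def distance_series_summary(
    series, window: int, tail_fraction: float = 1.0 / 3.0
) -> SeriesSummary:
    """Trailing running mean of an R_DA series plus overall and tail means.

    ``series`` is a DataFrame with columns ``frame`` and ``r_da`` (as
    produced by the kappa^2 series or the relaxation generator) or a plain
    1-D array of distances.  The tail mean — the mean over the final
    ``tail_fraction`` of frames — operationalizes the plateau value of a
    converging trajectory.
    """
    if isinstance(series, pd.DataFrame):
        if "r_da" not in series.columns:
            raise ValueError("series DataFrame must have an 'r_da' column")
        r = series["r_da"].to_numpy(dtype=float)
        idx = (
            series["frame"].to_numpy()
            if "frame" in series.columns
            else np.arange(len(r))
        )
    else:
        r = np.asarray(series, dtype=float).ravel()
        idx = np.arange(r.size)
    if r.size == 0:
        raise ValueError("empty series")
    if not (1 <= window <= r.size):
        raise ValueError(f"window must lie in [1, {r.size}]")
    if not (0 < tail_fraction <= 1):
        raise ValueError("tail_fraction must lie in (0, 1]")
    running = pd.Series(r).rolling(window, min_periods=1).mean().to_numpy()
    n_tail = max(1, int(round(tail_fraction * r.size)))
    table = pd.DataFrame({"frame": idx, "r_da": r, "running_mean": running})
    return SeriesSummary(
        table=table,
        overall_mean=float(r.mean()),
        tail_mean=float(r[-n_tail:].mean()),
        tail_fraction=tail_fraction,
    )
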