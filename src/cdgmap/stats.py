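"""Density estimation, distribution comparison, and count/ratio statistics.

Positions live on the circular 0-100% ori-anchored scale. The kernel
density estimate respects that circularity by replicating the sample at
-100/0/+100 and renormalizing over one period; the two-sample
Kolmogorov-Smirnov test, in contrast, is computed linearly on the
ori-anchored scale (the scale is already anchored at a biologically fixed
point, so the usual rotation-invariance objection to linear KS on circular
data does not bite); a Kuiper variant is available for the cautious.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CDG_CLASSES, CdgmapError, EnzymeClass, NormalizedPosition

PositionLike = Union[float, NormalizedPosition]

KDE_GRID_POINTS = 512
EXACT_KS_MAX_N = 16

RATIO_PAIRS = (
    ("GGDEF", "EAL"),
    ("GGDEF", "GGDEF_EAL"),
    ("GGDEF", "HD-GYP"),
)


def _as_array(positions: Iterable[PositionLike]) -> np.ndarray:
    return np.asarray([float(p) for p in positions], dtype=float)


# ---------------------------------------------------------------------------
# circular KDE


@dataclass
class DensityEstimate:
    """Gaussian-kernel density on a regular grid over [0, 100), normalized so
    the trapezoidal integral over one full period is 1."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        # close the circle with the wrap point density(100) = density(0)
        x = np.append(self.grid, 100.0)
        y = np.append(self.density, self.density[0])
        return float(np.trapezoid(y, x))

    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])

    def modes(self, min_height_fraction: float = 0.1) -> list[float]:
        """Circular local maxima above ``min_height_fraction`` of the peak."""
        d = self.density
        is_max = (d > np.roll(d, 1)) & (d >= np.roll(d, -1))
        floor = min_height_fraction * d.max()
        return [float(g) for g, m, v in zip(self.grid, is_max, d) if m and v >= floor]


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 min(sd, IQR/1.34) n^(-1/5), on the
    unwrapped data."""
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1.0)
    return 0.9 * scale * n ** (-0.2)


def kde_circular(
    positions: Iterable[PositionLike],
    bandwidth: Optional[float] = None,
    grid_points: int = KDE_GRID_POINTS,
) -> DensityEstimate:
    """Kernel density of positions on the 0-100% circle.

    Circular wrap is handled by tripling the data at -100/0/+100 offsets,
    evaluating a Gaussian kernel sum on a ``grid_points``-point grid over
    [0, 100), and renormalizing over one period. The default bandwidth is
    Silverman's rule computed on the unwrapped sample.
    """
    x = _as_array(positions)
    if x.size < 2:
        raise CdgmapError("kernel density estimation needs at least 2 positions")
    if np.any((x < 0) | (x >= 100)):
        raise CdgmapError("positions must lie in [0, 100)")
    h = float(bandwidth) if bandwidth is not None else silverman_bandwidth(x)
    if h <= 0:
        raise CdgmapError("bandwidth must be positive")
    grid = np.linspace(0.0, 100.0, grid_points, endpoint=False)
    tripled = np.concatenate([x - 100.0, x, x + 100.0])
    z = (grid[:, None] - tripled[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    est = DensityEstimate(grid=grid, density=density, bandwidth=h)
    est.density = est.density / est.integral()
    return est


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "asymptotic" | "exact_permutation"


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """sup over all sample points of |ECDF_x - ECDF_y|."""
    pts = np.concatenate([x, y])
    fx = np.searchsorted(np.sort(x), pts, side="right") / x.size
    fy = np.searchsorted(np.sort(y), pts, side="right") / y.size
    return float(np.abs(fx - fy).max())


def ks_two_sample(
    x: Iterable[PositionLike],
    y: Iterable[PositionLike],
    method: str = "asymptotic",
) -> KSResult:
    """Two-sample KS test on the linear ori-anchored scale.

    ``method="asymptotic"``: p from the limiting Kolmogorov distribution at
    sqrt(en) D with effective size en = n_x n_y / (n_x + n_y).
    ``method="exact_permutation"``: full enumeration of all C(n_x+n_y, n_x)
    label assignments (allowed up to n_x + n_y = 16); p is the fraction of
    assignments with D at least the observed D.
    """
    xa, ya = _as_array(x), _as_array(y)
    if xa.size < 1 or ya.size < 1:
        raise CdgmapError("both samples must be non-empty")
    d = _ks_d(xa, ya)
    if method == "asymptotic":
        en = xa.size * ya.size / (xa.size + ya.size)
        p = float(sps.kstwobign.sf(np.sqrt(en) * d))
    elif method == "exact_permutation":
        n = xa.size + ya.size
        if n > EXACT_KS_MAX_N:
            raise CdgmapError(
                f"exact permutation limited to n_x + n_y <= {EXACT_KS_MAX_N}, got {n}"
            )
        pooled = np.concatenate([xa, ya])
        idx = np.arange(n)
        count = 0
        total = 0
        eps = 1e-12
        for combo in combinations(idx, xa.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            dd = _ks_d(pooled[mask], pooled[~mask])
            count += dd >= d - eps
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return KSResult(d_statistic=d, p_value=p, n_x=xa.size, n_y=ya.size, method=method)


def kuiper_two_sample(x: Iterable[PositionLike], y: Iterable[PositionLike]) -> KSResult:
    """Rotation-invariant circular alternative: V = D+ + D- with an
    asymptotic p-value. Provided as an option; not the default."""
    xa, ya = _as_array(x), _as_array(y)
    if xa.size < 1 or ya.size < 1:
        raise CdgmapError("both samples must be non-empty")
    pts = np.concatenate([xa, ya])
    fx = np.searchsorted(np.sort(xa), pts, side="right") / xa.size
    fy = np.searchsorted(np.sort(ya), pts, side="right") / ya.size
    diff = fx - fy
    v = float(diff.max() - diff.min())
    en = xa.size * ya.size / (xa.size + ya.size)
    lam = (np.sqrt(en) + 0.155 + 0.24 / np.sqrt(en)) * v
    k = np.arange(1, 101)
    p = float(2 * np.sum((4 * k**2 * lam**2 - 1) * np.exp(-2 * k**2 * lam**2)))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return KSResult(d_statistic=v, p_value=p, n_x=xa.size, n_y=ya.size, method="kuiper")


# ---------------------------------------------------------------------------
# count and ratio statistics


def per_genus_mean_counts(
    genome_counts: Mapping[str, int], taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Mean c-di-GMP gene count per genus: total genes across the genus's
    genomes divided by the number of genomes. Returns columns
    order, genus, n_genomes, mean_count."""
    tax = taxonomy.set_index("genome_id")
    rows = []
    for gid, count in genome_counts.items():
        if gid not in tax.index:
            raise CdgmapError(f"genome {gid!r} missing from taxonomy table")
        rows.append({"order": tax.at[gid, "order"], "genus": tax.at[gid, "genus"],
                     "count": count})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["order", "genus"], as_index=False)
        .agg(n_genomes=("count", "size"), mean_count=("count", "mean"))
        .sort_values(["order", "genus"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def order_quartiles(genus_means: pd.DataFrame) -> pd.DataFrame:
    """Box-plot summary (quartiles) of genus means per order."""
    return (
        genus_means.groupby("order")["mean_count"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
        .reset_index()
    )


def class_ratios(counts: Mapping[EnzymeClass, int]) -> dict[str, Optional[float]]:
    """Per-genome GGDEF:EAL, GGDEF:GGDEF_EAL and GGDEF:HD-GYP ratios.

    A ratio with a zero denominator is undefined (``None``) and is excluded
    from any genus-level mean rather than imputed.
    """
    by_name = {cls.value: counts.get(cls, 0) for cls in CDG_CLASSES}
    out: dict[str, Optional[float]] = {}
    for num, den in RATIO_PAIRS:
        key = f"{num}:{den}"
        out[key] = by_name[num] / by_name[den] if by_name[den] > 0 else None
    return out


def genus_mean_ratios(
    genome_class_counts: Mapping[str, Mapping[EnzymeClass, int]],
    taxonomy: pd.DataFrame,
) -> pd.DataFrame:
    """Ratios computed per genome, then averaged per genus over the genomes
    where the ratio is defined. Columns: order, genus, ratio, mean, n_defined."""
    tax = taxonomy.set_index("genome_id")
    rows = []
    for gid, counts in genome_class_counts.items():
        ratios = class_ratios(counts)
        for key, val in ratios.items():
            if val is not None:
                rows.append({"order": tax.at[gid, "order"], "genus": tax.at[gid, "genus"],
                             "ratio": key, "value": val})
    if not rows:
        return pd.DataFrame(columns=["order", "genus", "ratio", "mean", "n_defined"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["order", "genus", "ratio"], as_index=False)
        .agg(mean=("value", "mean"), n_defined=("value", "size"))
        .sort_values(["order", "genus", "ratio"], kind="mergesort")
        .reset_index(drop=True)
    )


def median_counts(counts: Sequence[int]) -> float:
    """50% quantile of per-genome counts, linear interpolation at even n."""
    if len(counts) == 0:
        raise CdgmapError("median of an empty count list")
    return float(np.median(np.asarray(counts, dtype=float)))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    defined: bool


def size_count_correlation(
    lengths: Sequence[float], counts: Sequence[float]
) -> CorrelationResult:
    """Spearman rank correlation between largest-replicon length and
    c-di-GMP gene count, tie-corrected, p from the t-approximation.
    A constant input vector leaves rho undefined (``defined=False``)."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CdgmapError("correlation needs >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=float("nan"), p_value=float("nan"),
                                 n=x.size, defined=False)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=x.size, defined=True)
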