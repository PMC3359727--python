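"""Size-exclusion chromatography: fraction mapping, Gaussian peaks, purity.

A chromatogram arrives as a paired ASCII export: an absorbance trace
(time-or-volume vs mAU) and a run log supplying flow rate, fraction size and
collection start time.  The x axis is converted to collector fraction
coordinates, a Gaussian mixture

    A(f) = sum_i h_i * exp(-(f - c_i)^2 / (2 w_i^2))

is fitted by least squares, and two statistics are derived:

* pooled purity -- the percent of the absorbance integral inside the pooled
  fraction window contributed by the pool's dominant component;
* ``r_sec`` -- the residual after fitting a single Gaussian, normalized by
  the total sum of squares (1 - R^2 form), in [0, 1].  A monodisperse,
  symmetric elution profile gives r_sec near 0; shoulders, aggregates and
  multiple species push it up.  This is the SEC value used by the predictor.

Fraction boundaries are half-open [start, end) in eluted volume and fraction
indices are 1-based; points eluting before collection start map to fraction 0.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special


@dataclass
class SecChromatogram:
    fraction_axis: np.ndarray   # fraction coordinate (possibly fractional)
    absorbance: np.ndarray      # mAU
    flow_rate: float = 1.0      # mL/min
    fraction_size: float = 1.0  # mL
    collection_start: float = 0.0  # min

    def __post_init__(self) -> None:
        self.fraction_axis = np.asarray(self.fraction_axis, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.fraction_axis.shape != self.absorbance.shape:
            raise ValueError("fraction axis and absorbance must have equal length")
        if np.any(np.diff(self.fraction_axis) < 0):
            raise ValueError("fraction axis must be nondecreasing")
        if self.flow_rate <= 0 or self.fraction_size <= 0:
            raise ValueError("flow rate and fraction size must be positive")


@dataclass
class SecFit:
    """Gaussian mixture fit of a chromatogram with derived purity statistics."""

    components: list[tuple[float, float, float]]  # (height mAU, center, sigma) by center
    rss: float
    pool_range: tuple[float, float] | None = None
    purity_pool: float | None = None   # percent
    r_sec: float | None = None         # RSS1/TSS of the single-Gaussian fit

    def __call__(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        out = np.zeros_like(f)
        for h, c, w in self.components:
            out += h * np.exp(-((f - c) ** 2) / (2 * w**2))
        return out


def time_to_fraction(t: float, flow_rate: float, fraction_size: float,
                     collection_start: float) -> int:
    """Collector fraction (1-based) holding the eluate at run time ``t`` min.

    Volume intervals are half-open [start, end); pre-collection points are
    fraction 0.
    """
    if t < collection_start:
        return 0
    vol = (t - collection_start) * flow_rate
    return int(math.floor(vol / fraction_size)) + 1


_KEY_PATTERNS = {
    "flow_rate": re.compile(r"flow\s*rate", re.I),
    "fraction_size": re.compile(r"fraction\s*(size|volume)", re.I),
    "collection_start": re.compile(r"(collection|frac(tionation)?)\s*start", re.I),
}
_NUM = re.compile(r"[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?")


def _parse_doc_asc(doc_path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(doc_path) as fh:
        for line in fh:
            for key, pat in _KEY_PATTERNS.items():
                if key not in meta and pat.search(line):
                    m = _NUM.search(line.split(":", 1)[-1] if ":" in line else line[pat.search(line).end():])
                    if m:
                        meta[key] = float(m.group())
    missing = [k for k in _KEY_PATTERNS if k not in meta]
    if missing:
        raise ValueError(f"run log {doc_path} is missing metadata: {', '.join(missing)}")
    return meta


def parse_sec_ascii(curve_path, doc_path) -> SecChromatogram:
    """Parse paired curve/run-log ASCII exports into fraction coordinates.

    The curve file holds (time [min], absorbance [mAU]) pairs, whitespace or
    comma delimited, with optional non-numeric header lines.  The run log is
    scanned for flow rate (mL/min), fraction size (mL) and collection start
    (min).  The continuous fraction coordinate for each point is
    ``(t - start) * flow / size`` shifted to the 1-based convention; integer
    truncation of that coordinate recovers the collector fraction number.
    """
    meta = _parse_doc_asc(doc_path)
    times: list[float] = []
    absorb: list[float] = []
    with open(curve_path) as fh:
        for lineno, line in enumerate(fh, 1):
            raw = line.strip()
            if not raw:
                continue
            parts = [p for p in raw.replace(",", " ").replace("\t", " ").split() if p]
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if times:
                    raise ValueError(f"{curve_path}: line {lineno}: malformed data row {raw!r}")
                continue
            if len(vals) < 2:
                raise ValueError(f"{curve_path}: line {lineno}: expected (time, absorbance) pair")
            times.append(vals[0])
            absorb.append(vals[1])
    if not times:
        raise ValueError(f"no data points found in {curve_path}")
    t = np.asarray(times)
    # continuous coordinate; fraction n spans [n, n+1) so floor() gives the bin
    frac = np.where(
        t < meta["collection_start"],
        0.0,
        (t - meta["collection_start"]) * meta["flow_rate"] / meta["fraction_size"] + 1.0,
    )
    return SecChromatogram(
        fraction_axis=frac,
        absorbance=np.asarray(absorb),
        flow_rate=meta["flow_rate"],
        fraction_size=meta["fraction_size"],
        collection_start=meta["collection_start"],
    )


def _smooth(y: np.ndarray, w: int = 5) -> np.ndarray:
    w = min(w, len(y))
    if w < 2:
        return y.astype(float)
    kernel = np.ones(w) / w
    pad = np.r_[np.full(w // 2, y[0]), y, np.full(w - 1 - w // 2, y[-1])]
    return np.convolve(pad, kernel, mode="valid")


def initial_peak_estimates(
    chrom: SecChromatogram, noise_mad_factor: float = 3.0, smooth_window: int = 5
) -> list[tuple[float, float]]:
    """(height, center) seeds: smoothed local maxima above the noise floor.

    The noise floor is median + ``noise_mad_factor`` * MAD of the smoothed
    trace; candidates are returned in descending height order.
    """
    if len(chrom.absorbance) < 10:
        raise ValueError("need at least 10 points for peak estimation")
    y = _smooth(chrom.absorbance, smooth_window)
    # noise floor from the raw trace: smoothing shrinks noise spread and
    # would let baseline wiggles above a floor computed on the smoothed data
    med = np.median(chrom.absorbance)
    mad = np.median(np.abs(chrom.absorbance - med))
    floor = med + noise_mad_factor * max(mad, 1e-12)
    peaks = []
    for i in range(1, len(y) - 1):
        if y[i] > floor and y[i] >= y[i - 1] and y[i] > y[i + 1]:
            peaks.append((float(chrom.absorbance[i]), float(chrom.fraction_axis[i])))
    peaks.sort(key=lambda hc: -hc[0])
    return peaks


def _mixture(f: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    for h, c, w in params.reshape(-1, 3):
        out = out + h * np.exp(-((f - c) ** 2) / (2 * w**2))
    return out


class GaussianPeakModel:
    """Gaussian-mixture peak model of a chromatogram.

    Parameters
    ----------
    chrom : SecChromatogram
    k : int or None
        Number of Gaussian components; defaults to the number of candidate
        peaks found by :func:`initial_peak_estimates` (minimum 1).
    """

    def __init__(self, chrom: SecChromatogram, k: int | None = None):
        self.chrom = chrom
        if k is None:
            try:
                k = max(1, len(initial_peak_estimates(chrom)))
            except ValueError:
                k = 1
        if k < 1:
            raise ValueError("k must be >= 1")
        if len(chrom.absorbance) < 3 * k + 2:
            raise ValueError(
                f"{len(chrom.absorbance)} points cannot support {k} Gaussian components"
            )
        self.k = k

    def _initial_params(self) -> np.ndarray:
        f, y = self.chrom.fraction_axis, self.chrom.absorbance
        try:
            seeds = initial_peak_estimates(self.chrom)
        except ValueError:
            seeds = []
        span = max(f[-1] - f[0], 1.0)
        params = []
        for j in range(self.k):
            if j < len(seeds):
                h, c = seeds[j]
            else:  # spread extra components across the axis
                h = max(float(np.max(y)), 1e-6)
                c = f[0] + span * (j + 0.5) / self.k
            params.extend([max(h, 1e-6), c, span / (4 * self.k)])
        return np.asarray(params)

    def fit(self, pool_range: tuple[float, float] | None = None,
            compute_r_sec: bool = True) -> SecFit:
        """Least-squares fit; optionally also computes pooled purity and r_sec."""
        fit = self._fit_core()
        fit.pool_range = pool_range
        if pool_range is not None:
            fit.purity_pool = pool_purity(fit, pool_range)
        if compute_r_sec:
            fit.r_sec = single_gaussian_residual(self.chrom)
        return fit

    def _fit_core(self) -> SecFit:
        f, y = self.chrom.fraction_axis, self.chrom.absorbance
        p0 = self._initial_params()
        lo = np.tile([0.0, f[0] - 1.0, 1e-6], self.k)
        hi = np.tile([np.inf, f[-1] + 1.0, (f[-1] - f[0]) + 1.0], self.k)
        sol = optimize.least_squares(
            lambda p: _mixture(f, p) - y, p0, bounds=(lo, hi), method="trf",
            max_nfev=20000,
        )
        if not sol.success and sol.cost > 1e-6 * float(np.sum(y**2)):
            raise RuntimeError(
                f"Gaussian mixture fit did not converge (best RSS {2 * sol.cost:.4g})"
            )
        comps = sorted(
            [tuple(map(float, c)) for c in sol.x.reshape(-1, 3)], key=lambda c: c[1]
        )
        rss = float(np.sum((_mixture(f, sol.x) - y) ** 2))
        return SecFit(components=comps, rss=rss)


def fit_gaussians(chrom: SecChromatogram, k: int,
                  pool_range: tuple[float, float] | None = None) -> SecFit:
    """Fit a k-component Gaussian mixture (functional wrapper)."""
    return GaussianPeakModel(chrom, k=k).fit(pool_range=pool_range)


def _gauss_integral(h: float, c: float, w: float, a: float, b: float) -> float:
    """Integral of h*exp(-(x-c)^2/(2w^2)) over [a, b]."""
    s = w * math.sqrt(2.0)
    return h * w * math.sqrt(2 * math.pi) * 0.5 * (
        special.erf((b - c) / s) - special.erf((a - c) / s)
    )


def pool_purity(fit: SecFit, pool_range: tuple[float, float]) -> float | None:
    """Percent of the pooled absorbance contributed by the pool's main species.

    The main component is the one with the largest integral inside the pool
    window (what was actually pooled), not the globally tallest peak.
    Returns None (missing) when the mixture has no mass in the pool.
    """
    a, b = float(pool_range[0]), float(pool_range[1])
    if b < a:
        a, b = b, a
    integrals = [_gauss_integral(h, c, w, a, b) for h, c, w in fit.components]
    total = sum(integrals)
    if total <= 0:
        return None
    return 100.0 * max(integrals) / total


def single_gaussian_residual(chrom: SecChromatogram) -> float | None:
    """r_sec = RSS1 / TSS for the best single-Gaussian fit, clamped to [0, 1].

    RSS1 is the residual sum of squares of a one-component fit and TSS the
    total sum of squares about the mean.  Returns None for a constant trace
    (TSS = 0, statistic undefined).
    """
    y = chrom.absorbance
    tss = float(np.sum((y - np.mean(y)) ** 2))
    if tss <= 0:
        return None
    fit = GaussianPeakModel(chrom, k=1)._fit_core()
    return float(min(max(fit.rss / tss, 0.0), 1.0))
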