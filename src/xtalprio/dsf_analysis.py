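"""Differential scanning fluorimetry: melt-curve parsing and Boltzmann fits.

A DSF (thermofluor) experiment follows a hydrophobicity-sensitive dye's
fluorescence while the sample is heated; unfolding exposes hydrophobic
surface and produces a sigmoidal rise.  Each unfolding transition is modelled
as a Boltzmann sigmoid, so a curve with ``k`` transitions is

    F(T) = baseline + sum_j dF_j / (1 + exp((Tm_j - T) / s_j))

with midpoint ``Tm_j`` (K), slope parameter ``s_j`` (K) and amplitude
``dF_j``.  Derived per transition: maximum slope dF/dT = dF/(4s) and the
FWHM of dF/dT, 2*ln(3 + 2*sqrt(2))*s.  Fitting is restricted to the region
up to the fluorescence maximum after the highest-temperature transition
(beyond it, dye-aggregate dissociation makes the signal decay).

The steepest transition is taken as the major one (user-overridable).  The
predictor value is the fluorescence ratio r_dsf = F(303.15 K) / F(Tm_major)
evaluated from the fitted model: already-unfolded or dye-binding samples show
high fluorescence at 30 C and hence high r_dsf.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.signal import argrelmax

#: FWHM of the derivative of a Boltzmann sigmoid, in units of s
FWHM_FACTOR = 2.0 * math.log(3.0 + 2.0 * math.sqrt(2.0))

F30_KELVIN = 303.15  # 30 C, the low-temperature evaluation point for r_dsf


@dataclass
class DsfCurve:
    """One well's melt curve; temperature in Kelvin, strictly increasing."""

    well_label: str
    temperature: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence arrays must have equal length")
        if len(self.temperature) < 10:
            raise ValueError("a melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        # Celsius input is detected by magnitude and converted
        if self.temperature.max() < 150.0:
            self.temperature = self.temperature + 273.15


@dataclass
class BoltzmannTransition:
    tm: float       # K
    s: float        # K, slope parameter (> 0)
    delta_f: float  # fluorescence amplitude

    @property
    def max_slope(self) -> float:
        """Maximum of dF/dT for this transition: delta_f / (4 s)."""
        return self.delta_f / (4.0 * self.s)

    @property
    def fwhm(self) -> float:
        """FWHM of dF/dT: 2 ln(3 + 2 sqrt(2)) * s."""
        return FWHM_FACTOR * self.s


@dataclass
class DsfFit:
    """Fitted multi-transition Boltzmann model of one melt curve."""

    baseline: float
    transitions: list[BoltzmannTransition]  # sorted by tm
    major_index: int
    fit_region: tuple[int, int]  # [start, end) indices of the truncated region
    rss: float
    well_label: str = ""

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.baseline)
        for tr in self.transitions:
            out = out + tr.delta_f / (1.0 + np.exp((tr.tm - t) / tr.s))
        return out if out.shape else float(out)

    @property
    def major(self) -> BoltzmannTransition:
        return self.transitions[self.major_index]

    @property
    def f30(self) -> float:
        return float(self(F30_KELVIN))

    @property
    def f_tm(self) -> float:
        return float(self(self.major.tm))

    @property
    def r_dsf(self) -> float:
        """F(303.15 K) / F(Tm_major) from the fitted model."""
        return self.f30 / self.f_tm

    def set_major(self, index: int) -> None:
        """Persist a user override of the major-transition choice."""
        if not 0 <= index < len(self.transitions):
            raise ValueError("major transition index out of range")
        self.major_index = index

    def summary(self) -> str:
        lines = [
            f"DSF Boltzmann fit{' — well ' + self.well_label if self.well_label else ''}",
            f"  baseline {self.baseline:.4g}   transitions {len(self.transitions)}   RSS {self.rss:.4g}",
            "  #   Tm (K)     s (K)    dF        dF/dT max   FWHM (K)",
        ]
        for i, tr in enumerate(self.transitions):
            tag = " *" if i == self.major_index else "  "
            lines.append(
                f"  {i}{tag}{tr.tm:9.3f} {tr.s:8.3f} {tr.delta_f:10.4g} "
                f"{tr.max_slope:10.4g} {tr.fwhm:9.4f}"
            )
        lines.append(
            f"  F(303.15 K) {self.f30:.4g}   F(Tm) {self.f_tm:.4g}   r_dsf {self.r_dsf:.4f}"
        )
        return "\n".join(lines)


def parse_dsf_csv(path) -> list[DsfCurve]:
    """Parse a melt-curve table: temperature column then one column per well.

    Comma, semicolon, tab or whitespace delimited; a header row supplies well
    labels, otherwise plate-order labels (A1..H12, then numeric) are assigned.
    Ragged rows and non-monotone temperature are rejected.
    """
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty DSF file {path}")
    sep = None
    for cand in (",", ";", "\t"):
        if cand in lines[0]:
            sep = cand
            break
    try:
        df = pd.read_csv(
            io.StringIO(text),
            sep=sep if sep else r"\s+",
            engine="python",
            header=None,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as e:
        raise ValueError(f"ragged or malformed rows in {path}: {e}") from e
    # header detection: first row non-numeric
    first = df.iloc[0]
    if pd.to_numeric(first, errors="coerce").isna().any():
        labels = [str(x).strip() for x in first[1:]]
        df = df.iloc[1:]
    else:
        labels = _plate_labels(df.shape[1] - 1)
    data = df.apply(pd.to_numeric, errors="coerce")
    if data.isna().any().any():
        bad = int(np.where(data.isna().any(axis=1))[0][0])
        raise ValueError(f"non-numeric or ragged data row {bad + 1} in {path}")
    arr = data.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: need a temperature column plus >= 1 intensity column")
    temp = arr[:, 0]
    if np.any(np.diff(temp) <= 0):
        raise ValueError(f"{path}: temperature column must be strictly increasing")
    return [
        DsfCurve(well_label=labels[j], temperature=temp, fluorescence=arr[:, j + 1])
        for j in range(arr.shape[1] - 1)
    ]


def _plate_labels(n: int) -> list[str]:
    labels = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    if n <= len(labels):
        return labels[:n]
    return labels + [f"W{i}" for i in range(len(labels) + 1, n + 1)]


def _smooth3(y: np.ndarray) -> np.ndarray:
    pad = np.r_[y[0], y, y[-1]]
    return np.convolve(pad, np.ones(3) / 3, mode="valid")


def truncate_curve(curve: DsfCurve) -> tuple[int, int]:
    """Fit region [0, end): up to the smoothed global fluorescence maximum.

    Ties break to the latest index, so flat or monotonically rising curves
    keep the full range.
    """
    sm = _smooth3(curve.fluorescence)
    # latest-index argmax
    imax = len(sm) - 1 - int(np.argmax(sm[::-1]))
    if imax >= len(sm) - 1:
        return (0, len(sm))
    return (0, imax + 1)


def _model(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    base = params[0]
    out = np.full_like(t, base)
    for tm, s, df in params[1:].reshape(-1, 3):
        out = out + df / (1.0 + np.exp(np.clip((tm - t) / s, -500, 500)))
    return out


class BoltzmannMeltModel:
    """Multi-transition Boltzmann melt model for one DSF curve.

    Parameters
    ----------
    curve : DsfCurve
    k : int
        Number of Boltzmann transitions to fit (>= 1).
    seed : int
        RNG seed for jittered restart initial values (reproducibility).
    """

    def __init__(self, curve: DsfCurve, k: int = 1, seed: int = 0):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.curve = curve
        self.k = k
        self.seed = seed
        self.region = truncate_curve(curve)
        if self.region[1] - self.region[0] < 4 * k + 2:
            raise ValueError(
                f"fit region of {self.region[1] - self.region[0]} points cannot "
                f"support {k} transitions"
            )

    def _initial_params(self, rng: np.random.Generator | None = None) -> np.ndarray:
        lo, hi = self.region
        t = self.curve.temperature[lo:hi]
        y = self.curve.fluorescence[lo:hi]
        sm = _smooth3(y)
        dy = np.gradient(sm, t)
        # seed tm at the k largest local maxima of the smoothed derivative
        cand = list(argrelmax(dy)[0])
        cand.sort(key=lambda i: -dy[i])
        tms = [t[i] for i in cand[: self.k]]
        while len(tms) < self.k:
            tms.append(t[0] + (t[-1] - t[0]) * (len(tms) + 1) / (self.k + 1))
        tms.sort()
        base = float(np.min(y))
        amp = max(float(np.max(y) - np.min(y)), 1e-6) / self.k
        params = [base]
        for tm in tms:
            params.extend([tm, 2.0, amp])
        p = np.asarray(params)
        if rng is not None:
            span = t[-1] - t[0]
            jit = np.zeros_like(p)
            jit[1::3] = rng.normal(0, 0.05 * span, self.k)  # tm
            jit[2::3] = rng.normal(0, 0.5, self.k)          # s
            jit[3::3] = rng.normal(0, 0.1 * amp, self.k)    # dF
            p = p + np.r_[0.0, jit[1:]]
            p[2::3] = np.maximum(p[2::3], 0.1)
        return p

    def fit(self, max_restarts: int = 5) -> DsfFit:
        """Damped least-squares fit with bounded jittered restarts."""
        lo, hi = self.region
        t = self.curve.temperature[lo:hi]
        y = self.curve.fluorescence[lo:hi]
        scale = float(np.sum(y**2))
        lb = np.r_[-np.inf, np.tile([t[0] - 20.0, 0.05, -np.inf], self.k)]
        ub = np.r_[np.inf, np.tile([t[-1] + 20.0, 50.0, np.inf], self.k)]
        rng = np.random.default_rng(self.seed)
        best = None
        for attempt in range(max_restarts + 1):
            p0 = self._initial_params(rng if attempt else None)
            try:
                sol = optimize.least_squares(
                    lambda p: _model(t, p) - y, p0, bounds=(lb, ub), method="trf",
                    max_nfev=10000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
            if best.cost <= 1e-4 * scale:
                break
        if best is None:
            raise RuntimeError("Boltzmann fit failed on every restart")
        rss = 2.0 * float(best.cost)
        if not best.success and rss > 0.5 * scale:
            raise RuntimeError(
                f"Boltzmann fit did not converge after {max_restarts} restarts "
                f"(best RSS {rss:.4g})"
            )
        trs = sorted(
            (BoltzmannTransition(tm, s, df) for tm, s, df in best.x[1:].reshape(-1, 3)),
            key=lambda tr: tr.tm,
        )
        major = int(np.argmax([tr.max_slope for tr in trs]))
        return DsfFit(
            baseline=float(best.x[0]),
            transitions=trs,
            major_index=major,
            fit_region=self.region,
            rss=rss,
            well_label=self.curve.well_label,
        )


def fit_boltzmann(curve: DsfCurve, k: int = 1, seed: int = 0) -> DsfFit:
    """Fit k Boltzmann transitions to a melt curve (functional wrapper)."""
    return BoltzmannMeltModel(curve, k=k, seed=seed).fit()


def select_transition_count(
    curve: DsfCurve, k_max: int = 3, bic_threshold: float = 10.0, seed: int = 0
) -> tuple[int, DsfFit]:
    """Smallest k whose BIC is not beaten by more than ``bic_threshold`` at k+1.

    Returns (k, fit at k).  Gaussian-error BIC: n*ln(RSS/n) + p*ln(n).
    """
    lo, hi = truncate_curve(curve)
    n = hi - lo
    fits: dict[int, DsfFit] = {}

    def bic(k: int) -> float:
        if k not in fits:
            fits[k] = fit_boltzmann(curve, k=k, seed=seed)
        rss = max(fits[k].rss, 1e-300)
        return n * math.log(rss / n) + (3 * k + 1) * math.log(n)

    k = 1
    while k < k_max and n >= 4 * (k + 1) + 2:
        try:
            if bic(k) - bic(k + 1) > bic_threshold:
                k += 1
            else:
                break
        except (RuntimeError, ValueError):
            break
    return k, fits[k] if k in fits else fit_boltzmann(curve, k=k, seed=seed)
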