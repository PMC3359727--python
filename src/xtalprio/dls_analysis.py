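"""Dynamic light scattering: peak tables, radius-derived MW, Pmaj, DLS score.

The module starts from vendor-style text exports of regularized DLS peak
tables (one row per particle population: mean hydrodynamic radius,
polydispersity, percent polydispersity, percent intensity, percent mass) and
an optional intensity-versus-radius histogram.

Derived quantities:

* ``mw_from_radius`` -- empirical globular-protein calibration
  MW[kDa] = (1.68 * Rh[nm]) ** 2.3398 (constants configurable);
* major peak -- highest-intensity peak with Rh in the 2--10 nm window
  (proteins; smaller peaks are solvent, larger are aggregates), with a
  flagged global fallback and persistent user override;
* oligomer ratio n_olig = MW(Rh_major) / monomer MW from sequence;
* Pmaj -- intensity fraction of the major peak among all peaks at least as
  large as it (smaller particles excluded from the denominator);
* an ordinal 1-4 DLS quality score from peak count and %Pd (display only;
  the default predictor uses Pmaj).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: globular-protein Rh -> MW calibration constants, MW[kDa] = (A * Rh)**B
RH_TO_MW_A = 1.68
RH_TO_MW_B = 2.3398

MAJOR_RH_RANGE = (2.0, 10.0)  # nm

#: DLS quality rubric (editable): %Pd monodispersity cutoff and the
#: major-peak intensity share separating scores 2 and 1.
DLS_SCORE_RUBRIC = {"pd_pct_mono": 15.0, "major_intensity_min": 50.0}


@dataclass
class DlsPeak:
    rh: float            # nm, mean hydrodynamic radius
    pd: float = 0.0      # nm, polydispersity
    pd_pct: float = 0.0  # percent polydispersity
    intensity_pct: float = 0.0
    mass_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.rh <= 0:
            raise ValueError("hydrodynamic radius must be positive")
        for name in ("pd_pct", "intensity_pct", "mass_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    @property
    def mw_r(self) -> float:
        """Estimated particle MW in kDa from the radius calibration."""
        return mw_from_radius(self.rh)


@dataclass
class DlsResult:
    peaks: list[DlsPeak]
    histogram: tuple[np.ndarray, np.ndarray] | None = None
    major_index: int | None = None        # user override persists here
    major_fallback_warning: bool = False

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a DLS result needs at least one peak")
        total = sum(p.intensity_pct for p in self.peaks)
        if total and abs(total - 100.0) > 1.0:
            raise ValueError(f"peak intensity percentages sum to {total:.2f}, not ~100")
        if self.major_index is None:
            self.major_index, self.major_fallback_warning = select_major_peak(self.peaks)
        elif not 0 <= self.major_index < len(self.peaks):
            raise ValueError("major_index out of range")

    @property
    def major(self) -> DlsPeak:
        return self.peaks[self.major_index]

    @property
    def p_maj(self) -> float:
        return pmaj(self.peaks, self.major_index)

    def n_olig(self, mw_mono_da: float) -> float:
        """Oligomer ratio: DLS-estimated MW over the sequence monomer MW (Da)."""
        return self.major.mw_r * 1000.0 / mw_mono_da

    @property
    def dls_score(self) -> int:
        return dls_score(self.peaks, self.major_index)


def mw_from_radius(rh: float, a: float = RH_TO_MW_A, b: float = RH_TO_MW_B) -> float:
    """Estimated MW (kDa) of a globular protein with hydrodynamic radius rh (nm)."""
    if rh <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    return (a * rh) ** b


def select_major_peak(
    peaks: list[DlsPeak], rh_range: tuple[float, float] = MAJOR_RH_RANGE
) -> tuple[int, bool]:
    """Index of the major peak and a fallback-warning flag.

    The major peak is the highest-intensity peak with Rh inside ``rh_range``
    (inclusive).  When no peak qualifies the global intensity maximum is used
    and the warning flag is set.  Intensity ties break toward smaller Rh
    (monomer-favoring).
    """
    if not peaks:
        raise ValueError("no peaks")
    lo, hi = rh_range
    candidates = [i for i, p in enumerate(peaks) if lo <= p.rh <= hi]
    fallback = not candidates
    if fallback:
        candidates = list(range(len(peaks)))
    best = min(candidates, key=lambda i: (-peaks[i].intensity_pct, peaks[i].rh))
    return best, fallback


def pmaj(peaks: list[DlsPeak], major_index: int) -> float:
    """Intensity fraction of the major peak among peaks at least as large.

    p_maj = I_major / sum{ I_j : Rh_j >= Rh_major }.  Particles smaller than
    the major peak (salts, buffer components) are excluded from the total.
    """
    major = peaks[major_index]
    denom = sum(p.intensity_pct for p in peaks if p.rh >= major.rh)
    if denom == 0:
        raise ValueError("major peak has zero intensity")
    return major.intensity_pct / denom


def dls_score(peaks: list[DlsPeak], major_index: int | None = None,
              rubric: dict | None = None) -> int:
    """Ordinal 1-4 DLS quality score from peak count and %Pd (4 = best).

    4: single peak, monodisperse (%Pd below the rubric cutoff);
    3: single peak, polydisperse;
    2: multiple peaks but the major peak carries >= half the intensity;
    1: otherwise.  Display-only; not a predictor input.
    """
    r = dict(DLS_SCORE_RUBRIC)
    if rubric:
        r.update(rubric)
    if major_index is None:
        major_index, _ = select_major_peak(peaks)
    if len(peaks) == 1:
        return 4 if peaks[0].pd_pct < r["pd_pct_mono"] else 3
    if peaks[major_index].intensity_pct >= r["major_intensity_min"]:
        return 2
    return 1


def parse_dls_export(path) -> DlsResult:
    """Parse a vendor-style DLS text export: a peak table plus optional histogram.

    The peak table has one row per peak with columns Rh (nm), Pd (nm), %Pd,
    %intensity and %mass, delimited by tabs or commas, optionally preceded by
    header/metadata lines.  A section starting with a line containing
    "histogram" is read as (radius, intensity) pairs.
    """
    peaks: list[DlsPeak] = []
    hist_r: list[float] = []
    hist_i: list[float] = []
    in_hist = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            raw = line.strip()
            if not raw or raw.startswith("#"):
                continue
            if "histogram" in raw.lower():
                in_hist = True
                continue
            parts = [p.strip() for p in raw.replace(",", "\t").split("\t") if p.strip()]
            # drop a leading peak-number column if present
            if not in_hist and len(parts) >= 6:
                parts = parts[1:]
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if peaks or in_hist:
                    raise ValueError(f"line {lineno}: malformed numeric field in {raw!r}")
                continue  # header line before the table
            if in_hist:
                if len(vals) < 2:
                    raise ValueError(f"line {lineno}: histogram rows need (radius, intensity)")
                hist_r.append(vals[0])
                hist_i.append(vals[1])
            else:
                if len(vals) < 5:
                    raise ValueError(f"line {lineno}: peak rows need 5 columns, got {len(vals)}")
                rh, pd, pd_pct, int_pct, mass_pct = vals[:5]
                if not (0 <= pd_pct <= 100 and 0 <= int_pct <= 100 and 0 <= mass_pct <= 100):
                    raise ValueError(f"line {lineno}: percent column out of [0, 100]")
                peaks.append(DlsPeak(rh, pd, pd_pct, int_pct, mass_pct))
    if not peaks:
        raise ValueError(f"no DLS peaks found in {path}")
    hist = (np.asarray(hist_r), np.asarray(hist_i)) if hist_r else None
    return DlsResult(peaks=peaks, histogram=hist)


def analyze_dls(result: DlsResult, mw_mono_da: float | None = None) -> dict:
    """Summary values for storage/prediction from a parsed DLS result."""
    out = {
        "rh_major": result.major.rh,
        "pd_pct_major": result.major.pd_pct,
        "mw_r": result.major.mw_r,
        "p_maj": result.p_maj,
        "dls_score": float(result.dls_score),
    }
    if mw_mono_da is not None:
        out["n_olig"] = result.n_olig(mw_mono_da)
    return out
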