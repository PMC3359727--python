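"""Synthetic raw-data generators for every experiment type and for cohorts.

Each generator emits files in exactly the dialect the corresponding parser
accepts, together with a JSON ground-truth record of the generative
parameters, so loop-closure tests (parse -> fit -> compare to truth) never
re-derive the truth.  Identical seed + spec give byte-identical output.

Defaults emulate routine protein-characterization runs: DSF over 25--90 C at
0.5 C steps with ~1% multiplicative noise and an optional post-transition
decay; SEC over 40 fractions with mAU-scale Gaussian peaks; DLS peak tables
whose intensity percentages sum to 100; training cohorts with features drawn
from documented distributions and scores from a planted split rule plus
clipped Gaussian noise.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class DsfSpec:
    baseline: float = 200.0
    transitions: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(323.0, 1.5, 1000.0)]
    )  # (tm K, s K, delta_f)
    noise: float = 0.01            # multiplicative Gaussian noise fraction
    t_start: float = 298.15        # K
    t_stop: float = 363.15         # K
    t_step: float = 0.5            # K
    decay_slope: float = 0.0       # units/K after onset (0 disables decay)
    well_label: str = "A1"
    celsius: bool = False          # write the temperature column in Celsius


def dsf_model(t: np.ndarray, spec: DsfSpec) -> np.ndarray:
    """Noiseless multi-Boltzmann curve with optional post-transition decay."""
    y = np.full_like(t, spec.baseline, dtype=float)
    for tm, s, df in spec.transitions:
        y = y + df / (1.0 + np.exp((tm - t) / s))
    if spec.decay_slope > 0:
        tm_last, s_last, _ = max(spec.transitions, key=lambda tr: tr[0])
        onset = tm_last + 3.0 * s_last
        y = y - np.where(t > onset, (t - onset) * spec.decay_slope, 0.0)
    return y


def gen_dsf_curve(spec: DsfSpec, out_dir, seed: int = 0) -> tuple[str, str]:
    """Write a melt-curve CSV plus ground-truth JSON; returns (csv, truth) paths."""
    rng = np.random.default_rng(seed)
    t = np.arange(spec.t_start, spec.t_stop + spec.t_step / 2, spec.t_step)
    y = dsf_model(t, spec)
    if spec.noise > 0:
        y = y * (1.0 + rng.normal(0.0, spec.noise, size=t.shape))
    os.makedirs(out_dir, exist_ok=True)
    csv_path = os.path.join(out_dir, "dsf_curve.csv")
    t_col = t - 273.15 if spec.celsius else t
    with open(csv_path, "w") as fh:
        fh.write(f"Temp,{spec.well_label}\n")
        for ti, yi in zip(t_col, y):
            fh.write(f"{ti:.3f},{yi:.6f}\n")
    truth_path = os.path.join(out_dir, "dsf_truth.json")
    truth = asdict(spec) | {"seed": seed, "n_points": len(t)}
    if spec.decay_slope > 0:
        tm_last, s_last, _ = max(spec.transitions, key=lambda tr: tr[0])
        truth["decay_onset"] = tm_last + 3.0 * s_last
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return csv_path, truth_path


@dataclass
class SecSpec:
    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(100.0, 20.0, 2.0)]
    )  # (height mAU, center fraction, sigma fractions)
    noise: float = 0.0             # additive noise, fraction of max height
    flow_rate: float = 1.0         # mL/min
    fraction_size: float = 1.0     # mL
    collection_start: float = 5.0  # min
    n_fractions: int = 40
    points_per_fraction: int = 10


def sec_model(frac: np.ndarray, spec: SecSpec) -> np.ndarray:
    y = np.zeros_like(frac, dtype=float)
    for h, c, w in spec.components:
        y = y + h * np.exp(-((frac - c) ** 2) / (2 * w**2))
    return y


def gen_sec_chromatogram(spec: SecSpec, out_dir, seed: int = 0) -> tuple[str, str, str]:
    """Write paired curve/doc ASCII files plus truth JSON."""
    rng = np.random.default_rng(seed)
    n = spec.n_fractions * spec.points_per_fraction
    frac = 1.0 + np.arange(n) * (spec.n_fractions / n)  # continuous coordinate
    y = sec_model(frac, spec)
    if spec.noise > 0:
        hmax = max(h for h, _, _ in spec.components)
        y = y + rng.normal(0.0, spec.noise * hmax, size=y.shape)
    # time for continuous fraction coordinate f: t = start + (f-1)*size/flow
    t = spec.collection_start + (frac - 1.0) * spec.fraction_size / spec.flow_rate
    os.makedirs(out_dir, exist_ok=True)
    curve_path = os.path.join(out_dir, "curve.asc")
    with open(curve_path, "w") as fh:
        fh.write("min\tmAU\n")
        for ti, yi in zip(t, y):
            fh.write(f"{ti:.5f}\t{yi:.6f}\n")
    doc_path = os.path.join(out_dir, "doc.asc")
    with open(doc_path, "w") as fh:
        fh.write("Method run log\n")
        fh.write(f"Flow rate: {spec.flow_rate:.3f} ml/min\n")
        fh.write(f"Fraction size: {spec.fraction_size:.3f} ml\n")
        fh.write(f"Collection start: {spec.collection_start:.3f} min\n")
    truth_path = os.path.join(out_dir, "sec_truth.json")
    with open(truth_path, "w") as fh:
        json.dump(asdict(spec) | {"seed": seed}, fh, indent=1)
    return curve_path, doc_path, truth_path


@dataclass
class DlsSpec:
    peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(3.0, 12.0, 80.0), (30.0, 40.0, 20.0)]
    )  # (rh nm, pd_pct, intensity_pct); intensities must sum to ~100
    with_histogram: bool = True


def gen_dls_export(spec: DlsSpec, out_dir, seed: int = 0) -> tuple[str, str]:
    """Write a vendor-style DLS peak-table export plus truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "dls_export.txt")
    total_int = sum(i for _, _, i in spec.peaks)
    with open(path, "w") as fh:
        fh.write("Peak\tRh (nm)\tPd (nm)\t%Pd\t%Int\t%Mass\n")
        for i, (rh, pd_pct, int_pct) in enumerate(spec.peaks, 1):
            pd_nm = rh * pd_pct / 100.0
            mass_pct = 100.0 * int_pct / total_int  # simplistic mass model
            fh.write(
                f"{i}\t{rh:.3f}\t{pd_nm:.3f}\t{pd_pct:.2f}\t{int_pct:.2f}\t{mass_pct:.2f}\n"
            )
        if spec.with_histogram:
            fh.write("Histogram (intensity vs radius)\n")
            for rh, pd_pct, int_pct in spec.peaks:
                sigma = max(rh * pd_pct / 100.0, 1e-3)
                for r in np.geomspace(max(rh - 3 * sigma, 0.1), rh + 3 * sigma, 7):
                    inten = int_pct * np.exp(-((r - rh) ** 2) / (2 * sigma**2))
                    fh.write(f"{r:.4f}\t{inten:.4f}\n")
    truth_path = os.path.join(out_dir, "dls_truth.json")
    with open(truth_path, "w") as fh:
        json.dump(asdict(spec) | {"seed": seed}, fh, indent=1)
    return path, truth_path


@dataclass
class CohortSpec:
    n: int = 100
    rule_feature: str = "l_dis"
    rule_threshold: float = 40.0
    score_below: float = 5.0       # planted mean score when feature <= threshold
    score_above: float = 0.0
    noise_sigma: float = 0.5       # outcome noise before clipping to 0..6
    missing_rate: float = 0.0      # per-feature missingness (mw_mono always kept)


def _draw_features(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "r_dsf": rng.beta(2.0, 5.0, n) * 2.0,           # mostly < 1, tail above
        "yield_score": rng.integers(0, 6, n).astype(float),
        "r_sec": rng.beta(1.5, 6.0, n),                 # mostly clean profiles
        "p_maj": rng.beta(6.0, 2.0, n),                 # mostly near 1
        "mw_mono": np.exp(rng.normal(np.log(35000.0), 0.5, n)),  # lognormal Da
        "l_dis": np.minimum(rng.geometric(0.03, n).astype(float), 300.0),
    }


def gen_cohort(spec: CohortSpec, out_dir=None, seed: int = 0):
    """Planted-rule training cohort.

    Returns (cohort, truth) where cohort is a list of (feature dict, score)
    pairs; when ``out_dir`` is given, also writes cohort.csv (six feature
    columns + score, empty cells for missing) and cohort_truth.json.
    """
    if spec.n < 10:
        raise ValueError("cohort size must be >= 10")
    rng = np.random.default_rng(seed)
    feats = _draw_features(rng, spec.n)
    base = np.where(
        feats[spec.rule_feature] <= spec.rule_threshold,
        spec.score_below, spec.score_above,
    )
    scores = base + (rng.normal(0.0, spec.noise_sigma, spec.n)
                     if spec.noise_sigma > 0 else 0.0)
    scores = np.clip(np.rint(scores), 0, 6).astype(int)
    cohort = []
    names = list(feats)
    for i in range(spec.n):
        fv = {}
        for name in names:
            if (
                spec.missing_rate > 0 and name != "mw_mono"
                and rng.random() < spec.missing_rate
            ):
                fv[name] = None
            else:
                fv[name] = float(feats[name][i])
        cohort.append((fv, int(scores[i])))
    truth = asdict(spec) | {"seed": seed}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        csv_path = os.path.join(out_dir, "cohort.csv")
        with open(csv_path, "w") as fh:
            fh.write(",".join(names + ["score"]) + "\n")
            for fv, sc in cohort:
                cells = ["" if fv[n] is None else f"{fv[n]:.9g}" for n in names]
                fh.write(",".join(cells + [str(sc)]) + "\n")
        with open(os.path.join(out_dir, "cohort_truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)
    return cohort, truth


def load_cohort_csv(path) -> list[tuple[dict, int]]:
    """Read a cohort CSV (feature columns + 'score') into (features, score) pairs."""
    import pandas as pd
    df = pd.read_csv(path)
    if "score" not in df.columns:
        raise ValueError("cohort CSV needs a 'score' column")
    names = [c for c in df.columns if c != "score"]
    cohort = []
    for _, row in df.iterrows():
        fv = {n: (None if pd.isna(row[n]) else float(row[n])) for n in names}
        cohort.append((fv, int(row["score"])))
    return cohort
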