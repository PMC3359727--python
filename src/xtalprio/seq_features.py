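"""Sequence-derived features: monomer MW, hydropathy, longest disorder stretch.

Three numbers are extracted from each protein sequence. The monomer molecular
weight and the longest contiguous stretch of disordered residues feed the
diffraction-score predictor; the grand average of hydropathy (GRAVY, Kyte &
Doolittle residue scale) is reported for display.

Disorder calls are an injection point: per-residue boolean calls from any
external predictor can be attached to a :class:`SequenceRecord`.  When no
calls are supplied a clearly labelled in-package heuristic
(:func:`fallback_disorder`) is used instead; it is a smoothed
charge/hydropathy score, not a trained disorder predictor, and results that
rely on it are flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

WATER_MW = 18.0153  # average mass of H2O, Da

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# average residue masses = free amino-acid average weight minus one water
_RESIDUE_MW = {aa: protein_weights[aa] - WATER_MW for aa in STANDARD_AA}
_MEAN_RESIDUE_MW = sum(_RESIDUE_MW.values()) / len(_RESIDUE_MW)

_CHARGED = set("DEKR")


@dataclass
class SequenceRecord:
    """A protein sequence with optional externally supplied disorder calls."""

    id: str
    residues: str
    disorder_calls: list[bool] | None = None
    disorder_source: str = "none"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace(" ", "").replace("\n", "")
        bad = [
            (i, c) for i, c in enumerate(self.residues)
            if c not in STANDARD_AA and c != "X"
        ]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"illegal residue character {c!r} at position {i + 1} in sequence {self.id!r}"
            )
        if self.disorder_calls is not None:
            if len(self.disorder_calls) != len(self.residues):
                raise ValueError(
                    f"disorder_calls length {len(self.disorder_calls)} does not match "
                    f"sequence length {len(self.residues)}"
                )
            self.disorder_source = self.disorder_source if self.disorder_source != "none" else "external"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SeqFeatures:
    """Summary features of one sequence.

    mw_mono   -- monomer molecular weight, Da (average isotopic masses)
    gravy     -- grand average of hydropathy, dimensionless, in [-4.5, 4.5]
    l_dis     -- longest contiguous disordered stretch, residues
    disorder_source -- provenance of the disorder calls used for ``l_dis``
    """

    mw_mono: float
    gravy: float
    l_dis: int
    disorder_source: str = "none"


def monomer_mw(seq: SequenceRecord | str) -> float:
    """Monomer molecular weight in Da from average residue masses plus one water.

    ``X`` residues contribute the mean of the 20 standard residue masses.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("_", seq).residues
    if not residues:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    total = WATER_MW
    for c in residues:
        total += _RESIDUE_MW.get(c, _MEAN_RESIDUE_MW)
    return total


def avg_hydropathy(seq: SequenceRecord | str) -> float:
    """GRAVY: mean Kyte-Doolittle hydropathy over the sequence (no window).

    ``X`` residues are excluded from the mean; an all-``X`` sequence is an error.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("_", seq).residues
    if not residues:
        raise ValueError("cannot compute hydropathy of an empty sequence")
    vals = [KYTE_DOOLITTLE[c] for c in residues if c != "X"]
    if not vals:
        raise ValueError("sequence contains only X residues; hydropathy undefined")
    return float(np.mean(vals))


def longest_disorder_stretch(calls: list[bool] | np.ndarray) -> int:
    """Length of the maximal run of consecutive True values."""
    best = run = 0
    for c in calls:
        run = run + 1 if c else 0
        best = max(best, run)
    return best


def fallback_disorder(
    seq: SequenceRecord | str,
    threshold: float = 0.5,
    window: int = 15,
) -> list[bool]:
    """Heuristic per-residue disorder calls (fallback, not a trained predictor).

    Score per residue: 0.5 + 0.5*(charge_frac - hydropathy/4.5) smoothed over a
    ``window``-residue moving average; positions with smoothed score above
    ``threshold`` are called disordered.  Charged, low-hydropathy stretches
    (e.g. poly-E) score high; hydrophobic globular-like stretches score low.
    Deterministic; user-supplied calls always take precedence upstream.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("_", seq).residues
    if not residues:
        raise ValueError("cannot predict disorder for an empty sequence")
    charge = np.array([1.0 if c in _CHARGED else 0.0 for c in residues])
    hyd = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in residues])
    raw = 0.5 + 0.5 * (charge - hyd / 4.5)
    w = min(window, len(residues))
    kernel = np.ones(w) / w
    smooth = np.convolve(raw, kernel, mode="same")
    return [bool(s > threshold) for s in smooth]


def sequence_features(seq: SequenceRecord, disorder_threshold: float = 0.5) -> SeqFeatures:
    """Compute all sequence features, preferring user-supplied disorder calls."""
    if seq.disorder_calls is not None:
        calls = seq.disorder_calls
        source = seq.disorder_source
    else:
        calls = fallback_disorder(seq, threshold=disorder_threshold)
        source = "fallback-heuristic (not an external disorder predictor)"
    return SeqFeatures(
        mw_mono=monomer_mw(seq),
        gravy=avg_hydropathy(seq),
        l_dis=longest_disorder_stretch(calls),
        disorder_source=source,
    )


def read_disorder_csv(path) -> list[bool]:
    """Read per-residue disorder calls from two-column CSV (position, call/prob).

    The call column accepts 0/1, true/false, or a probability (>= 0.5 is
    disordered).  Positions are 1-based and must be contiguous from 1.
    """
    calls: list[tuple[int, bool]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected two columns (position, call)")
            try:
                pos = int(parts[0])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"line {lineno}: bad position {parts[0]!r}")
            tok = parts[1].lower()
            if tok in ("true", "t", "yes"):
                call = True
            elif tok in ("false", "f", "no"):
                call = False
            else:
                call = float(tok) >= 0.5
            calls.append((pos, call))
    calls.sort()
    if [p for p, _ in calls] != list(range(1, len(calls) + 1)):
        raise ValueError("disorder positions must be contiguous starting at 1")
    return [c for _, c in calls]
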