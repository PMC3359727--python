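"""Gel-based scores: expression yield, SDS--PAGE purity, limited proteolysis.

Yield enters the predictor as the visual gel score when one was recorded, or
as purified milligrams per liter of culture otherwise.  The visual scale has
six levels, 0 ("none") to 5 ("extremely high", equivalent to roughly 100 mg
per liter of culture).

Limited proteolysis (Lp) probes conformational stability: the major gel band
is followed through 1 h and 24 h protease digests and each protease is scored
on a 1 (unstable) to 5 (extremely stable) ordinal; the sample's stability is
the unrounded mean over proteases.  The SDS purity score and the Lp stability
score are stored and serialized but do not enter the default predictor
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: mg/L equivalents anchoring the 6-level visual yield scale; level 5
#: ("extremely high") is pinned at ~100 mg per liter of culture.
VISUAL_YIELD_MG_PER_L = {0: 0.0, 1: 5.0, 2: 15.0, 3: 35.0, 4: 65.0, 5: 100.0}

#: Lp rubric thresholds (intensity retention fractions and MW-change fraction).
LP_RUBRIC = {
    "intact_retention": 0.90,   # "unchanged" band
    "partial_retention": 0.50,
    "degraded_retention": 0.10,
    "mw_change_max": 0.05,
}


@dataclass
class YieldResult:
    """Expression yield: visual 0-5 score and/or purified mass per culture volume."""

    visual_score: int | None = None
    mass_mg: float | None = None
    culture_l: float | None = None

    def __post_init__(self) -> None:
        if self.visual_score is not None and self.visual_score not in range(6):
            raise ValueError("visual yield score must be an integer 0-5")
        has_numeric = self.mass_mg is not None and self.culture_l is not None
        if self.visual_score is None and not has_numeric:
            raise ValueError("need a visual score or (mass_mg, culture_l)")
        if has_numeric and self.culture_l <= 0:
            raise ValueError("culture volume must be positive")

    @property
    def mg_per_l(self) -> float | None:
        if self.mass_mg is not None and self.culture_l is not None:
            return self.mass_mg / self.culture_l
        return None


def visual_yield_to_mg_per_l(visual_score: int) -> float:
    """Approximate mg/L equivalent of a visual yield level (5 -> ~100 mg/L)."""
    return VISUAL_YIELD_MG_PER_L[int(visual_score)]


def effective_yield(y: YieldResult | None) -> tuple[float, str] | None:
    """Yield value for the predictor: (value, kind).

    The visual gel score takes precedence when recorded; otherwise the
    calculated mg per liter of culture is used.  Returns None when neither
    is available (missing marker).
    """
    if y is None:
        return None
    if y.visual_score is not None:
        return float(y.visual_score), "visual"
    if y.mg_per_l is not None:
        return y.mg_per_l, "mg_per_l"
    return None


@dataclass
class BandObservation:
    """Major-band change after digestion by one protease.

    mw_change         -- |MW shift| as a fraction of the undigested band MW
    retention_1h/24h  -- band intensity retained after 1 h / 24 h, fraction of
                         the undigested intensity (None if not observed)
    """

    mw_change: float = 0.0
    retention_1h: float | None = None
    retention_24h: float | None = None

    def __post_init__(self) -> None:
        if self.retention_1h is None and self.retention_24h is None:
            raise ValueError("need a band observation at 1 h or 24 h")


def lp_protease_score(obs: BandObservation, rubric: dict | None = None) -> int:
    """Ordinal 1-5 stability score for one protease digest.

    5: band essentially unchanged at 24 h (<=5% MW change, >=90% intensity);
    4: intact (>=90%) at 1 h and >=50% retained at 24 h;
    3: intact at 1 h but <50% at 24 h (or no 24 h observation);
    2: partial digestion at 1 h (10-90% retained);
    1: band essentially gone (<10%) within 1 h.
    """
    r = dict(LP_RUBRIC)
    if rubric:
        r.update(rubric)
    i1 = obs.retention_1h
    i24 = obs.retention_24h
    if (
        i24 is not None
        and i24 >= r["intact_retention"]
        and obs.mw_change <= r["mw_change_max"]
        and (i1 is None or i1 >= r["intact_retention"])
    ):
        return 5
    # treat a missing 1 h point as at least as intact as the 24 h one
    eff1 = i1 if i1 is not None else (i24 if i24 is not None else 0.0)
    if eff1 >= r["intact_retention"]:
        if i24 is not None and i24 >= r["partial_retention"]:
            return 4
        return 3
    if eff1 >= r["degraded_retention"]:
        return 2
    return 1


@dataclass
class LpResult:
    """Per-protease Lp scores and their mean stability."""

    per_protease: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, s in self.per_protease:
            if s not in (1, 2, 3, 4, 5):
                raise ValueError(f"Lp score for {name!r} must be in 1..5, got {s}")

    @property
    def stability(self) -> float:
        return lp_stability([s for _, s in self.per_protease])


def lp_stability(scores: list[int]) -> float:
    """Unrounded arithmetic mean of per-protease Lp scores."""
    if not scores:
        raise ValueError("need at least one protease score")
    return sum(scores) / len(scores)


def sds_purity_score(visual_score: int) -> int:
    """SDS-PAGE visual purity score (0-5), stored for display only.

    Not used by the default predictor: the training outcomes lacked samples
    with poor gels (those were dropped before crystallization trials).
    """
    if visual_score not in range(6):
        raise ValueError("SDS purity score must be an integer 0-5")
    return int(visual_score)
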