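"""Samples, result selection/aggregation, feature assembly and XML interchange.

A sample groups one or more sequences with results from up to seven
experiment types ({seq, dsf, sec, dls, yield, sds, lp}).  Several results of
one type may be stored; the user selects which ones count, and selected
results are aggregated by the arithmetic mean of their summary values.
Sequence features are taken as the maximum over the sample's sequences
(multi-protein samples), and the six predictor inputs are assembled into a
:class:`FeatureVector` with an explicit missing-mask — nothing is imputed at
this layer.

Every parsed or fitted result can be serialized to the package's
standardized XML: ``<xtalprio_result type=... version=...>`` with
``<metadata>``, ``<series>`` (raw x/y arrays) and ``<analysis>`` (summary
values); numbers carry 12 significant digits so round-trips are lossless at
display precision.  Projects are a thin JSON manifest on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .seq_features import SequenceRecord, sequence_features

EXPERIMENT_TAGS = ("seq", "dsf", "sec", "dls", "yield", "sds", "lp")

XML_VERSION = "1"
_NUM_FMT = "{:.12g}"  # >= 9 significant digits for lossless round-trips

#: summary-value keys accepted per experiment type
SUMMARY_SCHEMAS = {
    "seq": {"mw_mono", "gravy", "l_dis"},
    "dsf": {"tm", "s", "delta_f", "max_slope", "fwhm", "f30", "f_tm", "r_dsf"},
    "sec": {"purity_pool", "r_sec"},
    "dls": {"rh_major", "pd_pct_major", "mw_r", "n_olig", "p_maj", "dls_score"},
    "yield": {"visual_score", "mg_per_l", "yield_score"},
    "sds": {"purity_score"},
    "lp": {"stability"},
}


@dataclass
class ExperimentSummary:
    """Summary values for one experiment, parsed from raw data or entered manually."""

    type_tag: str
    summary_values: dict[str, float] = field(default_factory=dict)
    provenance: str = "parsed"  # "parsed" | "manual"
    payload: object | None = None  # full fit object for parsed results
    series: tuple[np.ndarray, np.ndarray] | None = None  # raw (x, y)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type_tag not in EXPERIMENT_TAGS:
            raise ValueError(
                f"unknown experiment type {self.type_tag!r}; expected one of {EXPERIMENT_TAGS}"
            )
        if self.provenance not in ("parsed", "manual"):
            raise ValueError("provenance must be 'parsed' or 'manual'")
        if self.provenance == "manual" and self.payload is not None:
            raise ValueError("manually entered summaries cannot carry a fit payload")
        schema = SUMMARY_SCHEMAS[self.type_tag]
        unknown = set(self.summary_values) - schema
        if unknown:
            raise ValueError(
                f"summary keys {sorted(unknown)} not in the {self.type_tag!r} schema "
                f"{sorted(schema)}"
            )


@dataclass
class FeatureVector:
    """The six predictor inputs for one sample; None marks a missing value."""

    r_dsf: float | None = None
    yield_score: float | None = None
    r_sec: float | None = None
    p_maj: float | None = None
    mw_mono: float | None = None
    l_dis: float | None = None

    def __post_init__(self) -> None:
        if self.p_maj is not None and not 0 <= self.p_maj <= 1:
            raise ValueError("p_maj must lie in [0, 1]")
        if self.r_sec is not None and not 0 <= self.r_sec <= 1:
            raise ValueError("r_sec must lie in [0, 1]")
        if self.mw_mono is not None and self.mw_mono <= 0:
            raise ValueError("mw_mono must be positive")
        if self.l_dis is not None and self.l_dis < 0:
            raise ValueError("l_dis must be >= 0")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "r_dsf": self.r_dsf, "yield_score": self.yield_score,
            "r_sec": self.r_sec, "p_maj": self.p_maj,
            "mw_mono": self.mw_mono, "l_dis": self.l_dis,
        }

    @property
    def missing_mask(self) -> dict[str, bool]:
        return {k: v is None for k, v in self.as_dict().items()}


@dataclass
class Sample:
    """A protein sample: sequences plus per-experiment result lists and selections."""

    name: str
    description: str = ""
    sequences: list[SequenceRecord] = field(default_factory=list)
    results: dict[str, list[ExperimentSummary]] = field(default_factory=dict)
    selection: dict[str, set[int]] = field(default_factory=dict)

    def add_result(self, result: ExperimentSummary, selected: bool = True) -> int:
        lst = self.results.setdefault(result.type_tag, [])
        lst.append(result)
        idx = len(lst) - 1
        if selected:
            self.selection.setdefault(result.type_tag, set()).add(idx)
        return idx

    def selected(self, tag: str) -> list[ExperimentSummary]:
        lst = self.results.get(tag, [])
        sel = self.selection.get(tag, set())
        bad = [i for i in sel if not 0 <= i < len(lst)]
        if bad:
            raise IndexError(f"selection indices {bad} out of range for {tag!r}")
        return [lst[i] for i in sorted(sel)]

    def data_status(self) -> dict[str, str]:
        """'present'/'missing' per experiment tag (display aid)."""
        return {
            tag: "present" if self.results.get(tag) else "missing"
            for tag in EXPERIMENT_TAGS
        }


def aggregate_selected(
    results: list[ExperimentSummary], selection: set[int] | list[int]
) -> ExperimentSummary | None:
    """Mean of the summary values over the selected results.

    Returns None (a missing marker, never zero) for an empty selection.
    Mixed experiment types are rejected.  Keys carried by only some selected
    results are averaged over the results that have them.
    """
    sel = sorted(set(selection))
    bad = [i for i in sel if not 0 <= i < len(results)]
    if bad:
        raise IndexError(f"selection indices {bad} out of range")
    chosen = [results[i] for i in sel]
    if not chosen:
        return None
    tags = {r.type_tag for r in chosen}
    if len(tags) > 1:
        raise ValueError(f"cannot aggregate mixed experiment types {sorted(tags)}")
    keys = sorted({k for r in chosen for k in r.summary_values})
    values = {
        k: float(np.mean([r.summary_values[k] for r in chosen if k in r.summary_values]))
        for k in keys
    }
    return ExperimentSummary(
        type_tag=chosen[0].type_tag,
        summary_values=values,
        provenance="parsed" if any(r.provenance == "parsed" for r in chosen) else "manual",
        metadata={"aggregated_from": str(len(chosen))},
    )


#: which aggregated summary key feeds each predictor feature
_FEATURE_SOURCES = {
    "r_dsf": ("dsf", "r_dsf"),
    "yield_score": ("yield", "yield_score"),
    "r_sec": ("sec", "r_sec"),
    "p_maj": ("dls", "p_maj"),
}


def assemble_feature_vector(sample: Sample) -> FeatureVector:
    """Build the six predictor inputs from a sample's selected results.

    Sequence features (MW, disorder stretch) are the maximum over sequences;
    experimental features come from the mean of the selected results per
    type.  Absent experiments stay None (flagged in ``missing_mask``).  A
    sample without sequences is rejected: monomer MW is mandatory.
    """
    if not sample.sequences:
        raise ValueError(f"sample {sample.name!r} has no sequence; MW is mandatory")
    feats = [sequence_features(s) for s in sample.sequences]
    fv = {
        "mw_mono": max(f.mw_mono for f in feats),
        "l_dis": float(max(f.l_dis for f in feats)),
    }
    for feature, (tag, key) in _FEATURE_SOURCES.items():
        agg = aggregate_selected(
            sample.results.get(tag, []), sample.selection.get(tag, set())
        )
        if agg is not None and key in agg.summary_values:
            fv[feature] = agg.summary_values[key]
        elif agg is not None and feature == "yield_score":
            # yield stores either the visual score or mg/L, visual preferred
            sv = agg.summary_values
            fv[feature] = sv.get("visual_score", sv.get("mg_per_l"))
    return FeatureVector(**fv)


# ---------------------------------------------------------------------------
# standardized XML interchange
# ---------------------------------------------------------------------------

def write_standard_xml(result: ExperimentSummary) -> bytes:
    """Serialize one experiment result to the standardized XML document."""
    root = etree.Element(
        "xtalprio_result", type=result.type_tag, version=XML_VERSION,
        provenance=result.provenance,
    )
    meta = etree.SubElement(root, "metadata")
    for k, v in sorted(result.metadata.items()):
        etree.SubElement(meta, "entry", key=k).text = str(v)
    if result.series is not None:
        x, y = result.series
        series = etree.SubElement(root, "series")
        etree.SubElement(series, "x").text = " ".join(_NUM_FMT.format(v) for v in x)
        etree.SubElement(series, "y").text = " ".join(_NUM_FMT.format(v) for v in y)
    analysis = etree.SubElement(root, "analysis")
    for k in sorted(result.summary_values):
        etree.SubElement(analysis, "value", name=k).text = _NUM_FMT.format(
            result.summary_values[k]
        )
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def read_standard_xml(doc: bytes | str) -> ExperimentSummary:
    """Parse a standardized XML document back into an ExperimentSummary.

    Schema violations are rejected with the offending element named.
    """
    if isinstance(doc, str) and doc.lstrip().startswith("<"):
        root = etree.fromstring(doc.encode())
    elif isinstance(doc, bytes):
        root = etree.fromstring(doc)
    else:
        root = etree.parse(str(doc)).getroot()
    if root.tag != "xtalprio_result":
        raise ValueError(f"schema error: unexpected root element <{root.tag}>")
    tag = root.get("type")
    if tag not in EXPERIMENT_TAGS:
        raise ValueError(f"schema error: unknown experiment type attribute {tag!r}")
    provenance = root.get("provenance", "parsed")
    metadata = {}
    meta = root.find("metadata")
    if meta is not None:
        for entry in meta.findall("entry"):
            if entry.get("key") is None:
                raise ValueError("schema error: <entry> without key attribute")
            metadata[entry.get("key")] = entry.text or ""
    series = None
    ser = root.find("series")
    if ser is not None:
        xel, yel = ser.find("x"), ser.find("y")
        if xel is None or yel is None:
            raise ValueError("schema error: <series> needs <x> and <y>")
        x = np.array([float(t) for t in (xel.text or "").split()])
        y = np.array([float(t) for t in (yel.text or "").split()])
        if len(x) != len(y):
            raise ValueError("schema error: <series> x/y length mismatch")
        series = (x, y)
    values = {}
    analysis = root.find("analysis")
    if analysis is None:
        raise ValueError("schema error: missing <analysis> element")
    for val in analysis.findall("value"):
        name = val.get("name")
        if name is None:
            raise ValueError("schema error: <value> without name attribute")
        try:
            values[name] = float(val.text)
        except (TypeError, ValueError):
            raise ValueError(f"schema error: non-numeric <value name={name!r}>")
    return ExperimentSummary(
        type_tag=tag, summary_values=values, provenance=provenance,
        series=series, metadata=metadata,
    )


# ---------------------------------------------------------------------------
# project manifest
# ---------------------------------------------------------------------------

def write_project_manifest(path, projects: dict[str, list[str]]) -> None:
    """Thin JSON manifest: project name -> list of sample XML/JSON file names."""
    import json
    with open(path, "w") as fh:
        json.dump({"format": "xtalprio-project", "projects": projects}, fh, indent=1)


def read_project_manifest(path) -> dict[str, list[str]]:
    import json
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "xtalprio-project":
        raise ValueError("not an xtalprio project manifest")
    return doc["projects"]
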