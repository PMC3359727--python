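"""Sample organization, result aggregation, feature assembly and XML round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from xtalprio.sample_model import (
    ExperimentSummary,
    FeatureVector,
    Sample,
    aggregate_selected,
    assemble_feature_vector,
    read_project_manifest,
    read_standard_xml,
    write_project_manifest,
    write_standard_xml,
)
from xtalprio.seq_features import SequenceRecord


def _dsf(tm, r=0.3):
    return ExperimentSummary("dsf", {"tm": tm, "r_dsf": r})


def test_aggregate_mean_of_selected():
    agg = aggregate_selected([_dsf(50.0), _dsf(54.0)], {0, 1})
    assert agg.summary_values["tm"] == pytest.approx(52.0)


def test_aggregate_single_selection_is_identity():
    agg = aggregate_selected([_dsf(50.0, 0.25), _dsf(54.0)], {0})
    assert agg.summary_values == {"tm": 50.0, "r_dsf": 0.25}


def test_aggregate_empty_selection_is_missing_not_zero():
    assert aggregate_selected([_dsf(50.0)], set()) is None


def test_aggregate_rejects_mixed_types():
    with pytest.raises(ValueError):
        aggregate_selected([_dsf(50.0), ExperimentSummary("sec", {"r_sec": 0.1})],
                           {0, 1})


def test_aggregate_rejects_bad_indices():
    with pytest.raises(IndexError):
        aggregate_selected([_dsf(50.0)], {3})


@given(st.lists(st.floats(0, 100), min_size=1, max_size=8))
def test_aggregation_permutation_invariant(tms):
    results = [_dsf(tm) for tm in tms]
    sel = set(range(len(tms)))
    a = aggregate_selected(results, sel).summary_values["tm"]
    b = aggregate_selected(results[::-1], sel).summary_values["tm"]
    assert a == pytest.approx(b, rel=1e-12)


def _sample_with(sequences, **results):
    s = Sample("s1", sequences=sequences)
    for tag_values in results.values():
        for tv in tag_values:
            s.add_result(tv)
    return s


def test_feature_vector_max_over_sequences():
    # MWs ~30 kDa and ~50 kDa via polyG lengths; explicit disorder calls
    s1 = SequenceRecord("a", "G" * 100, disorder_calls=[True] * 12 + [False] * 88)
    s2 = SequenceRecord("b", "W" * 100, disorder_calls=[True] * 25 + [False] * 75)
    sample = _sample_with([s1, s2])
    fv = assemble_feature_vector(sample)
    from xtalprio.seq_features import monomer_mw
    assert fv.mw_mono == pytest.approx(max(monomer_mw(s1), monomer_mw(s2)))
    assert fv.l_dis == 25


def test_feature_vector_missing_mask_flags_absent_experiments():
    seq = SequenceRecord("a", "MKTAYIAK", disorder_calls=[False] * 8)
    sample = _sample_with([seq])
    sample.add_result(_dsf(50.0, 0.3))
    sample.add_result(ExperimentSummary("yield", {"yield_score": 4.0},
                                        provenance="manual"))
    fv = assemble_feature_vector(sample)
    mask = fv.missing_mask
    assert not mask["mw_mono"] and not mask["r_dsf"] and not mask["yield_score"]
    assert mask["p_maj"] and mask["r_sec"]
    assert fv.r_dsf == pytest.approx(0.3)


def test_feature_vector_all_experiments_present_mask_all_false():
    seq = SequenceRecord("a", "MKTAYIAK", disorder_calls=[False] * 8)
    sample = _sample_with([seq])
    sample.add_result(_dsf(50.0))
    sample.add_result(ExperimentSummary("sec", {"r_sec": 0.1}))
    sample.add_result(ExperimentSummary("dls", {"p_maj": 0.9}))
    sample.add_result(ExperimentSummary("yield", {"yield_score": 3.0},
                                        provenance="manual"))
    fv = assemble_feature_vector(sample)
    assert not any(fv.missing_mask.values())


def test_feature_assembly_requires_sequence():
    with pytest.raises(ValueError):
        assemble_feature_vector(Sample("empty"))


def test_feature_assembly_deterministic():
    seq = SequenceRecord("a", "MKTAYIAKQR", disorder_calls=[False] * 10)
    sample = _sample_with([seq])
    sample.add_result(_dsf(50.0))
    assert assemble_feature_vector(sample) == assemble_feature_vector(sample)


def test_feature_vector_invariants_enforced():
    with pytest.raises(ValueError):
        FeatureVector(p_maj=1.5, mw_mono=1000.0)
    with pytest.raises(ValueError):
        FeatureVector(mw_mono=-5.0)


def test_sample_data_status():
    s = Sample("s", sequences=[SequenceRecord("a", "MK")])
    s.add_result(_dsf(50.0))
    status = s.data_status()
    assert status["dsf"] == "present" and status["sec"] == "missing"


def test_xml_roundtrip_with_series_payload():
    x = np.linspace(293.0, 363.0, 30)
    y = 200.0 + 1000.0 / (1.0 + np.exp((323.123456789 - x) / 1.5))
    es = ExperimentSummary(
        "dsf",
        {"tm": 323.123456789, "s": 1.5, "delta_f": 1000.0, "r_dsf": 0.2857142857},
        series=(x, y),
        metadata={"well": "B3"},
    )
    back = read_standard_xml(write_standard_xml(es))
    assert back.type_tag == "dsf"
    assert back.metadata["well"] == "B3"
    # >= 9 significant digits survive the round trip
    for k, v in es.summary_values.items():
        assert back.summary_values[k] == pytest.approx(v, rel=1e-9)
    np.testing.assert_allclose(back.series[0], x, rtol=1e-9)
    np.testing.assert_allclose(back.series[1], y, rtol=1e-9)


def test_xml_manual_entry_has_analysis_only():
    es = ExperimentSummary("sec", {"r_sec": 0.12}, provenance="manual")
    doc = write_standard_xml(es)
    assert b"<series>" not in doc
    back = read_standard_xml(doc)
    assert back.provenance == "manual"
    assert back.summary_values == {"r_sec": 0.12}


def test_xml_unknown_experiment_tag_rejected():
    doc = b'<xtalprio_result type="nmr" version="1"><analysis/></xtalprio_result>'
    with pytest.raises(ValueError, match="nmr"):
        read_standard_xml(doc)


def test_xml_schema_violations_name_offender():
    with pytest.raises(ValueError, match="analysis"):
        read_standard_xml(b'<xtalprio_result type="dsf" version="1"/>')
    bad = (b'<xtalprio_result type="dsf" version="1">'
           b'<analysis><value name="tm">abc</value></analysis></xtalprio_result>')
    with pytest.raises(ValueError, match="tm"):
        read_standard_xml(bad)


def test_manual_provenance_rejects_payload():
    with pytest.raises(ValueError):
        ExperimentSummary("dsf", {"tm": 50.0}, provenance="manual", payload=object())


def test_summary_keys_must_match_schema():
    with pytest.raises(ValueError, match="schema"):
        ExperimentSummary("dsf", {"nonsense": 1.0})


def test_project_manifest_roundtrip(tmp_path):
    p = tmp_path / "proj.json"
    projects = {"kinases": ["s1.xml", "s2.xml"], "phosphatases": []}
    write_project_manifest(p, projects)
    assert read_project_manifest(p) == projects
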