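"""Claims loading, validation, filtering, and design assembly."""

import numpy as np
import pandas as pd
import pytest

from qbill import claims_io
from qbill.claims_io import (
    ANALYSIS_COLUMNS,
    ClaimLine,
    SchemaError,
    assemble_design,
    compute_aggressiveness,
    filter_study_population,
    load_claims,
    provider_type_aggregates,
)
from qbill.synthetic_data import emit_raw_files, simulate_study

_CANON_ROW = {
    "provider_id": "NPI1", "procedure_code": "77055", "place_of_service": "F",
    "entity_type": "I", "provider_type": "Diagnostic Radiology", "state": "TX",
    "zip": "78701", "line_service_count": 20, "unique_beneficiary_count": 15,
    "avg_submitted_charge": 100.0, "avg_allowed_payment": 25.0,
    "avg_medicare_payment": 20.0, "avg_standardized_payment": 24.0,
}


def _claims_csv(tmp_path, rows, name="claims.csv", columns=None):
    df = pd.DataFrame(rows)
    if columns:
        df = df.rename(columns=columns)
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def _row(**overrides):
    return {**_CANON_ROW, **overrides}


def _claim(**overrides):
    rec = _row(**overrides)
    rec["place_of_service"] = {"F": "facility", "O": "non_facility"}[rec["place_of_service"]]
    rec["entity_type"] = {"I": "individual", "O": "organization"}[rec["entity_type"]]
    return ClaimLine(**rec)


def test_load_rejects_invalid_rows_with_reasons(tmp_path):
    path = _claims_csv(tmp_path, [
        _row(),
        _row(provider_id="NPI2", avg_submitted_charge=0.0),
        _row(provider_id="NPI3"),
    ])
    claims, report = load_claims(path)
    assert len(claims) == 2
    assert report["rejections"] == {"nonpositive_currency": 1}


def test_load_counts_other_rejection_reasons(tmp_path):
    path = _claims_csv(tmp_path, [
        _row(),
        _row(provider_id="NPI2", place_of_service="Q"),
        _row(provider_id="NPI3", unique_beneficiary_count=25),  # exceeds services
        _row(provider_id="NPI4", state=""),
    ])
    claims, report = load_claims(path)
    assert len(claims) == 1
    assert report["rejections"] == {
        "unknown_enum": 1, "beneficiaries_exceed_services": 1, "missing_field": 1}


def test_schema_config_rename_is_equivalent(tmp_path):
    p1 = _claims_csv(tmp_path, [_row()], "a.csv")
    p2 = _claims_csv(tmp_path, [_row()], "b.csv",
                     columns={"provider_id": "the_npi", "avg_submitted_charge": "chg"})
    c1, _ = load_claims(p1)
    c2, _ = load_claims(p2, schema_config={"provider_id": "the_npi",
                                           "avg_submitted_charge": "chg"})
    assert c1 == c2


def test_missing_column_is_fatal_and_named(tmp_path):
    rows = [{k: v for k, v in _CANON_ROW.items() if k != "state"}]
    path = _claims_csv(tmp_path, rows)
    with pytest.raises(SchemaError, match="state"):
        load_claims(path)


def test_empty_file_is_fatal(tmp_path):
    path = tmp_path / "empty.csv"
    pd.DataFrame(columns=list(_CANON_ROW)).to_csv(path, index=False)
    with pytest.raises(ValueError, match="no data rows"):
        load_claims(path)


def test_generated_claims_roundtrip(tmp_path):
    """Writing then loading the generator's claims file is the identity on
    the validated fields."""
    sim = simulate_study(200, 7)
    paths = emit_raw_files(sim.X, sim.meta, sim.y, tmp_path)
    written = pd.read_csv(paths["claims"], dtype={"nppes_provider_zip": str},
                          float_precision="round_trip")
    claims, report = load_claims(paths["claims"])
    assert report["n_valid"] == len(written) == 200
    by_id = {c.provider_id: c for c in claims}
    for rec in written.itertuples(index=False):
        c = by_id[rec.npi]
        assert c.line_service_count == rec.line_srvc_cnt
        assert c.avg_submitted_charge == rec.average_submitted_chrg_amt
        assert c.zip == rec.nppes_provider_zip
        assert c.place_of_service == "facility" and c.entity_type == "individual"


def test_filter_study_population_rules():
    claims = [
        _claim(),
        _claim(provider_id="NPI2", place_of_service="O"),
        _claim(provider_id="NPI3", entity_type="O"),
        _claim(provider_id="NPI4", procedure_code="99213"),
    ]
    out = filter_study_population(claims, "77055")
    assert [c.provider_id for c in out] == ["NPI1"]
    with pytest.raises(ValueError, match="filter"):
        filter_study_population(claims, "00000")


def test_filter_aggregates_multiple_rows_per_provider():
    claims = [
        _claim(line_service_count=10, avg_submitted_charge=100.0),
        _claim(line_service_count=30, avg_submitted_charge=200.0,
               unique_beneficiary_count=25),
    ]
    out = filter_study_population(claims, "77055")
    assert len(out) == 1
    assert out[0].avg_submitted_charge == pytest.approx(175.0)
    assert out[0].line_service_count == 40
    assert out[0].unique_beneficiary_count == 40


def test_filter_keeps_every_qualifying_synthetic_provider():
    sim = simulate_study(150, 3)
    claims = [
        ClaimLine(provider_id=pid, procedure_code="77055", place_of_service="facility",
                  entity_type="individual", provider_type=pt, state=st, zip=z,
                  line_service_count=20, unique_beneficiary_count=10,
                  avg_submitted_charge=100.0, avg_allowed_payment=25.0,
                  avg_medicare_payment=20.0, avg_standardized_payment=24.0)
        for pid, pt, st, z in sim.meta.itertuples(index=False)
    ]
    assert len(filter_study_population(claims, "77055")) == 150


def test_compute_aggressiveness():
    assert compute_aggressiveness(_claim()) == pytest.approx(4.0)
    assert compute_aggressiveness(_claim(avg_submitted_charge=25.0)) == pytest.approx(1.0)
    assert compute_aggressiveness(_claim(), "standardized") == pytest.approx(100.0 / 24.0)
    with pytest.raises(ValueError, match="denominator"):
        compute_aggressiveness(_claim(), "bogus")


def test_generated_aggressiveness_is_right_skewed():
    from scipy.stats import skew

    from qbill.synthetic_data import heavy_tail_truth

    sim = simulate_study(2000, 7, truth_factory=heavy_tail_truth)
    assert skew(np.maximum(sim.y, 0.01)) > 2.0


def test_provider_type_aggregates():
    df = pd.DataFrame({
        "provider_type": ["A", "A", "A", "B"],
        "aggressiveness": [2.0, 4.0, 6.0, 5.5],
    })
    agg = provider_type_aggregates(df)
    assert agg["A"] == (pytest.approx(4.0), pytest.approx(2.0))  # sample sd, ddof=1
    assert agg["B"] == (pytest.approx(5.5), 0.0)  # singleton type


def test_provider_type_aggregates_recover_population_means():
    rng = np.random.default_rng(15)
    df = pd.DataFrame({
        "provider_type": ["A"] * 1000 + ["B"] * 1000,
        "aggressiveness": np.concatenate([
            rng.normal(3.0, 1.0, 1000), rng.normal(6.0, 1.0, 1000)]),
    })
    agg = provider_type_aggregates(df)
    se = 1.0 / np.sqrt(1000)
    assert abs(agg["A"][0] - 3.0) <= 3 * se
    assert abs(agg["B"][0] - 6.0) <= 3 * se


def _lookup_tables():
    states = pd.DataFrame({
        "state": ["TX", "CA"],
        "ma_participation_rate": [0.3, 0.45],
        "average_age": [71.0, 72.0],
        "percent_female": [0.55, 0.54],
        "percent_nonhispanic_white": [0.6, 0.5],
        "percent_medicaid_eligible": [0.2, 0.25],
        "average_hcc_score": [1.0, 1.1],
        "std_risk_adjusted_per_capita_cost": [9500.0, 9800.0],
    })
    locality = pd.DataFrame({"state": ["TX", "CA"],
                             "locality_id": ["L00", "L01"],
                             "gpci_work": [1.0, 1.05]})
    return states, locality


def test_assemble_design_completeness():
    states, locality = _lookup_tables()
    claims = [_claim(), _claim(provider_id="NPI2", state="CA", provider_type="General Surgery")]
    table, report = assemble_design(claims, states, locality)
    assert list(table.columns) == ANALYSIS_COLUMNS
    assert len(table) == 2
    assert report["n_dropped_unmatched"] == 0
    assert not table.isna().any().any()


def test_assemble_drops_and_counts_unmatched_states():
    states, locality = _lookup_tables()
    claims = [_claim(), _claim(provider_id="NPI2", state="CA"),
              _claim(provider_id="NPI3", state="ZZ")]
    table, report = assemble_design(claims, states, locality)
    assert len(table) == 2
    assert report["n_dropped_unmatched"] == 1
    assert report["unmatched_state"] == 1


def test_assemble_fatal_when_most_rows_unmatched():
    states, locality = _lookup_tables()
    claims = [_claim(provider_id=f"NPI{i}", state="ZZ") for i in range(3)] + [_claim()]
    with pytest.raises(ValueError, match="half"):
        assemble_design(claims, states, locality)


def test_percent_scale_detection():
    states, locality = _lookup_tables()
    states = states.copy()
    states["percent_female"] = states["percent_female"] * 100  # 0-100 input
    claims = [_claim(), _claim(provider_id="NPI2", state="CA")]
    table, _ = assemble_design(claims, states, locality)
    assert table["percent_female"].between(0, 1).all()


def test_assemble_permutation_invariance():
    states, locality = _lookup_tables()
    claims = [_claim(provider_id=f"NPI{i}", state=("TX" if i % 2 else "CA"),
                     avg_submitted_charge=50.0 + i) for i in range(8)]
    t1, _ = assemble_design(claims, states, locality)
    t2, _ = assemble_design(claims[::-1], states, locality)
    t1 = t1.sort_values("provider_id").reset_index(drop=True)
    t2 = t2.sort_values("provider_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(t1, t2)


def test_mean_agg_self_consistency():
    """Each row's provider-type mean covariate equals the mean response
    over all rows sharing its type, recomputed from the final table."""
    sim = simulate_study(250, 5)
    from qbill.claims_io import attach_provider_type_aggregates

    table = attach_provider_type_aggregates(pd.concat([
        sim.meta[["provider_id", "provider_type"]],
        pd.Series(np.maximum(sim.y, 0.01), name="aggressiveness"),
    ], axis=1))
    for ptype, grp in table.groupby("provider_type"):
        np.testing.assert_allclose(grp["mean_agg_provider_type"],
                                   grp["aggressiveness"].mean(), atol=1e-12)


def test_locality_zip_prefix_join():
    states, _ = _lookup_tables()
    locality = pd.DataFrame({"zip_prefix": ["787", "900"], "gpci_work": [1.0, 1.06]})
    claims = [_claim(), _claim(provider_id="NPI2", state="CA", zip="90001")]
    table, report = assemble_design(claims, states, locality)
    assert len(table) == 2
    assert set(table["gpci_work"]) == {1.0, 1.06}
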