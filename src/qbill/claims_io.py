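"""Claims ingest, validation, filtering and design-table assembly.

Reads provider-procedure claim summary CSVs (schema modeled on the CMS
physician/supplier public-use file), state-level covariate tables and a
simplified locality/GPCI lookup; computes the billing-aggressiveness
response (average submitted charge over average payment) and the
provider-type aggregate covariates; and emits the analysis-ready design
table with the 14 reference covariates.

Rows failing validation or joins are never silently dropped: every load
and assembly step logs counts by reason and returns a report dictionary
suitable for JSON serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import COVARIATE_NAMES

__all__ = [
    "ClaimLine",
    "SchemaError",
    "DEFAULT_SCHEMA",
    "ANALYSIS_COLUMNS",
    "load_claims",
    "filter_study_population",
    "compute_aggressiveness",
    "provider_type_aggregates",
    "attach_provider_type_aggregates",
    "assemble_design",
    "read_state_covariates",
    "read_locality",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Fatal configuration problem: a required column is missing."""


@dataclass(frozen=True)
class ClaimLine:
    """One provider x procedure x place-of-service billing summary row."""

    provider_id: str
    procedure_code: str
    place_of_service: str  # "facility" | "non_facility"
    entity_type: str  # "individual" | "organization"
    provider_type: str
    state: str
    zip: str
    line_service_count: int
    unique_beneficiary_count: int
    avg_submitted_charge: float
    avg_allowed_payment: float
    avg_medicare_payment: float
    avg_standardized_payment: float


#: Canonical column name -> public-use-file style header.
DEFAULT_SCHEMA = {
    "provider_id": "npi",
    "procedure_code": "hcpcs_code",
    "place_of_service": "place_of_service",
    "entity_type": "nppes_entity_code",
    "provider_type": "provider_type",
    "state": "nppes_provider_state",
    "zip": "nppes_provider_zip",
    "line_service_count": "line_srvc_cnt",
    "unique_beneficiary_count": "bene_unique_cnt",
    "avg_submitted_charge": "average_submitted_chrg_amt",
    "avg_allowed_payment": "average_medicare_allowed_amt",
    "avg_medicare_payment": "average_medicare_payment_amt",
    "avg_standardized_payment": "average_medicare_standard_amt",
}

_CURRENCY_FIELDS = [
    "avg_submitted_charge",
    "avg_allowed_payment",
    "avg_medicare_payment",
    "avg_standardized_payment",
]

_PLACE_CODES = {"f": "facility", "facility": "facility",
                "o": "non_facility", "non_facility": "non_facility"}
_ENTITY_CODES = {"i": "individual", "individual": "individual",
                 "o": "organization", "organization": "organization"}

#: Fixed column order of the analysis table.
ANALYSIS_COLUMNS = ["provider_id", "provider_type", "aggressiveness"] + COVARIATE_NAMES

#: Aggressiveness denominator -> claim field.
_DENOMINATORS = {
    "allowed": "avg_allowed_payment",
    "medicare_payment": "avg_medicare_payment",
    "standardized": "avg_standardized_payment",
}


def load_claims(
    path, schema_config: dict[str, str] | None = None
) -> tuple[list[ClaimLine], dict]:
    """Read and validate a claims CSV.

    ``schema_config`` maps canonical field names (the keys of
    :data:`DEFAULT_SCHEMA`) to the column headers actually present; a
    file already using canonical headers needs no config.  Returns the
    validated rows plus a report with rejection counts by reason.

    Raises
    ------
    SchemaError
        If a required column is absent (named in the message).
    ValueError
        If the file is empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(DEFAULT_SCHEMA)
    schema.update(schema_config or {})
    # read everything as text; typed parsing happens during validation so
    # zip codes keep leading zeros and bad numbers are counted, not fatal
    dtype = {c: str for c in set(schema.values()) | set(schema)}
    df = pd.read_csv(path, dtype=dtype, comment="#")
    if df.empty:
        raise ValueError(f"claims file {path} contains no data rows")
    rename = {}
    for canonical, actual in schema.items():
        if actual in df.columns:
            rename[actual] = canonical
        elif canonical in df.columns:
            pass  # already canonical
        else:
            raise SchemaError(
                f"claims file {path} is missing required column "
                f"{actual!r} (canonical name {canonical!r})"
            )
    df = df.rename(columns=rename)

    claims: list[ClaimLine] = []
    rejects: dict[str, int] = {}

    def reject(reason: str) -> None:
        rejects[reason] = rejects.get(reason, 0) + 1

    for row in df.itertuples(index=False):
        rec = {k: getattr(row, k) for k in DEFAULT_SCHEMA}
        if any(v is None or (isinstance(v, float) and np.isnan(v)) or
               (isinstance(v, str) and v.strip() == "") for v in rec.values()):
            reject("missing_field")
            continue
        place = _PLACE_CODES.get(str(rec["place_of_service"]).strip().lower())
        entity = _ENTITY_CODES.get(str(rec["entity_type"]).strip().lower())
        if place is None or entity is None:
            reject("unknown_enum")
            continue
        try:
            services = int(float(rec["line_service_count"]))
            benes = int(float(rec["unique_beneficiary_count"]))
            money = {f: float(rec[f]) for f in _CURRENCY_FIELDS}
        except (TypeError, ValueError):
            reject("unparseable_number")
            continue
        if services < 0 or benes < 0:
            reject("negative_count")
            continue
        if services > 0 and benes > 0 and benes > services:
            reject("beneficiaries_exceed_services")
            continue
        if any(v <= 0 for v in money.values()):
            reject("nonpositive_currency")
            continue
        claims.append(
            ClaimLine(
                provider_id=str(rec["provider_id"]).strip(),
                procedure_code=str(rec["procedure_code"]).strip(),
                place_of_service=place,
                entity_type=entity,
                provider_type=str(rec["provider_type"]).strip(),
                state=str(rec["state"]).strip().upper(),
                zip=str(rec["zip"]).strip(),
                line_service_count=services,
                unique_beneficiary_count=benes,
                **money,
            )
        )
    report = {"n_read": int(len(df)), "n_valid": len(claims), "rejections": rejects}
    if rejects:
        logger.info("load_claims(%s): rejected rows by reason: %s", path.name, rejects)
    return claims, report


def filter_study_population(
    claims: list[ClaimLine], procedure_code: str
) -> list[ClaimLine]:
    """Restrict to the study population and collapse to one row per provider.

    Keeps rows for the requested procedure billed by *individual* entities
    at a *facility* place of service.  A provider with several qualifying
    rows is collapsed by service-count-weighted means of the currency
    fields (the averages are per-service means, so this recovers the
    pooled mean) and sums of the counts.

    Raises
    ------
    ValueError
        If no rows survive, with per-filter diagnostic counts.
    """
    counts = {"total": len(claims), "procedure": 0, "individual": 0, "facility": 0}
    kept: dict[str, list[ClaimLine]] = {}
    for c in claims:
        if c.procedure_code != procedure_code:
            continue
        counts["procedure"] += 1
        if c.entity_type != "individual":
            continue
        counts["individual"] += 1
        if c.place_of_service != "facility":
            continue
        counts["facility"] += 1
        kept.setdefault(c.provider_id, []).append(c)
    if not kept:
        raise ValueError(
            f"no claims survive the study filters for procedure {procedure_code!r}; "
            f"rows passing each successive filter: {counts}"
        )
    out = []
    for pid, rows in kept.items():
        if len(rows) == 1:
            out.append(rows[0])
            continue
        w = np.array([r.line_service_count for r in rows], dtype=float)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        money = {
            f: float(np.dot(w, [getattr(r, f) for r in rows])) for f in _CURRENCY_FIELDS
        }
        out.append(
            replace(
                rows[0],
                line_service_count=sum(r.line_service_count for r in rows),
                unique_beneficiary_count=sum(r.unique_beneficiary_count for r in rows),
                **money,
            )
        )
    return out


def compute_aggressiveness(row: ClaimLine, denominator: str = "allowed") -> float:
    """Billing aggressiveness: average submitted charge over the chosen
    average payment field (default: the allowed amount)."""
    try:
        den_field = _DENOMINATORS[denominator]
    except KeyError:
        raise ValueError(
            f"unknown denominator {denominator!r}; choose from {sorted(_DENOMINATORS)}"
        ) from None
    den = getattr(row, den_field)
    if den <= 0:
        raise ValueError(f"nonpositive denominator {den_field}={den} for {row.provider_id}")
    return row.avg_submitted_charge / den


def provider_type_aggregates(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-provider-type mean and sample sd (ddof=1) of aggressiveness.

    Types with a single provider get sd = 0 (the n=1 sample sd is
    undefined; zero keeps the design matrix complete).  The focal
    provider is included in its own type's aggregate — a known leakage
    caveat of this engineered covariate.
    """
    out = {}
    for ptype, grp in table.groupby("provider_type"):
        vals = grp["aggressiveness"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[str(ptype)] = (float(vals.mean()), sd)
    return out


def attach_provider_type_aggregates(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``mean_agg_provider_type`` / ``sd_agg_provider_type`` columns
    computed from the table's own (provider_type, aggressiveness) pairs."""
    agg = provider_type_aggregates(df)
    df = df.copy()
    df["mean_agg_provider_type"] = [agg[t][0] for t in df["provider_type"]]
    df["sd_agg_provider_type"] = [agg[t][1] for t in df["provider_type"]]
    return df


_PROPORTION_COLUMNS = [
    "ma_participation_rate",
    "percent_female",
    "percent_nonhispanic_white",
    "percent_medicaid_eligible",
]

_STATE_COLUMNS = _PROPORTION_COLUMNS + [
    "average_age",
    "average_hcc_score",
    "std_risk_adjusted_per_capita_cost",
]


def _rescale_percent_columns(df: pd.DataFrame, where: str) -> pd.DataFrame:
    """Proportions are stored in [0, 1]; inputs on a 0-100 scale are
    detected by range and rescaled with a warning."""
    df = df.copy()
    for col in _PROPORTION_COLUMNS:
        if col in df.columns and df[col].max() > 1.5:
            logger.warning("%s: column %s looks like 0-100 percent; rescaling to [0,1]", where, col)
            df[col] = df[col] / 100.0
    return df


def read_state_covariates(path) -> pd.DataFrame:
    """Read and validate the state-level covariate table."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ["state"] + _STATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"state covariate file {path} missing columns {missing}")
    if df["state"].duplicated().any():
        dupes = sorted(df.loc[df["state"].duplicated(), "state"].unique())
        raise ValueError(f"state covariate table has duplicate states: {dupes}")
    df = _rescale_percent_columns(df, f"state covariates {path}")
    for col in _PROPORTION_COLUMNS:
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise ValueError(f"{col} outside [0,1] for states {bad['state'].tolist()}")
    df["state"] = df["state"].str.strip().str.upper()
    return df


def read_locality(path) -> pd.DataFrame:
    """Read the simplified locality/GPCI lookup (keyed by state or
    zip_prefix; two-column crosswalk in place of the full fee-schedule
    locality structure)."""
    df = pd.read_csv(path, comment="#", dtype={"zip_prefix": str})
    key = "state" if "state" in df.columns else "zip_prefix" if "zip_prefix" in df.columns else None
    if key is None or "gpci_work" not in df.columns:
        raise SchemaError(f"locality file {path} needs a 'state' or 'zip_prefix' key and 'gpci_work'")
    if (df["gpci_work"] <= 0).any():
        raise ValueError("gpci_work must be strictly positive")
    if df[key].duplicated().any():
        raise ValueError(f"locality table has duplicate {key} keys")
    if key == "state":
        df["state"] = df["state"].str.strip().str.upper()
    return df


def assemble_design(
    claims: list[ClaimLine],
    state_cov: pd.DataFrame,
    locality: pd.DataFrame,
    denominator: str = "allowed",
) -> tuple[pd.DataFrame, dict]:
    """Join filtered claims with the lookup tables into the analysis table.

    Computes the aggressiveness response, joins state covariates and the
    locality GPCI, recomputes the provider-type aggregate covariates, and
    returns the table in the fixed :data:`ANALYSIS_COLUMNS` order plus a
    join report.  Rows with unmatched joins are dropped and counted; more
    than 50% unmatched is fatal (it signals a schema mismatch, not noise).
    """
    if not claims:
        raise ValueError("no claims to assemble")
    rows = pd.DataFrame(
        {
            "provider_id": [c.provider_id for c in claims],
            "provider_type": [c.provider_type for c in claims],
            "state": [c.state for c in claims],
            "zip": [c.zip for c in claims],
            "aggressiveness": [compute_aggressiveness(c, denominator) for c in claims],
            "line_service_count": [float(c.line_service_count) for c in claims],
            "unique_beneficiary_count": [float(c.unique_beneficiary_count) for c in claims],
            "avg_allowed_payment": [c.avg_allowed_payment for c in claims],
            "avg_standardized_payment": [c.avg_standardized_payment for c in claims],
        }
    )
    n0 = len(rows)

    state_cov = _rescale_percent_columns(state_cov, "state covariates")
    merged = rows.merge(state_cov[["state"] + _STATE_COLUMNS], on="state", how="left")
    unmatched_state = int(merged[_STATE_COLUMNS[0]].isna().sum())

    if "state" in locality.columns:
        merged = merged.merge(locality[["state", "gpci_work"]], on="state", how="left")
    else:
        plen = locality["zip_prefix"].str.len().iloc[0]
        merged["zip_prefix"] = merged["zip"].str[: int(plen)]
        merged = merged.merge(locality[["zip_prefix", "gpci_work"]], on="zip_prefix", how="left")
        merged = merged.drop(columns=["zip_prefix"])
    unmatched_locality = int(merged["gpci_work"].isna().sum())

    complete = merged.dropna(subset=_STATE_COLUMNS + ["gpci_work"]).reset_index(drop=True)
    n_dropped = n0 - len(complete)
    if n_dropped:
        logger.warning(
            "assemble_design: dropped %d/%d rows with unmatched joins "
            "(state: %d, locality: %d)", n_dropped, n0, unmatched_state, unmatched_locality,
        )
    if len(complete) < 0.5 * n0:
        raise ValueError(
            f"more than half of the rows ({n_dropped}/{n0}) failed the lookup joins; "
            "this usually means the state/locality tables use a different key scheme"
        )

    table = attach_provider_type_aggregates(complete)[ANALYSIS_COLUMNS]
    assert not table.isna().any().any()
    report = {
        "n_providers_in": n0,
        "n_providers_out": int(len(table)),
        "n_dropped_unmatched": n_dropped,
        "unmatched_state": unmatched_state,
        "unmatched_locality": unmatched_locality,
        "denominator": denominator,
    }
    return table, report
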