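"""Reading, validation, and canonicalization of claims tables and provider registries.

A claim is the atomic event of the whole pipeline: one patient seeing one
provider (who bills under one organization) on one calendar day.  Everything
downstream — network construction, censoring, metric panels — consumes the
per-patient, time-ordered visit sequences produced here.

Identifiers follow the NPI convention: 10 decimal digits whose Luhn check is
computed over the string prefixed with the card-issuer code ``"80840"``.
Validation is advisory by default (counted and reported, not rejected),
mirroring its role as a quality-control step on administrative data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "ClaimsDataset",
    "ParseReport",
    "ProviderRegistry",
    "SchemaError",
    "luhn_checksum",
    "prepare_patient_sequences",
    "read_claims",
    "read_registry",
    "validate_npi",
    "write_claims",
    "write_registry",
]

#: Canonical column names used internally and by :func:`write_claims`.
CANONICAL_COLUMNS = ("patient_id", "provider_id", "organization_id", "service_date")

#: Default role -> source-column mapping, following DE-SynPUF outpatient naming:
#: the beneficiary id, attending-physician NPI, institutional provider (organization)
#: number, and claim start date.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "patient": "DESYNPUF_ID",
    "provider": "AT_PHYSN_NPI",
    "organization": "PRVDR_NUM",
    "date": "CLM_FROM_DT",
}

_ID_RE = re.compile(r"^\d{10}$")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def luhn_checksum(digits: str) -> int:
    """Luhn mod-10 checksum of a digit string (0 means the string validates)."""
    total = 0
    for i, ch in enumerate(reversed(digits)):
        d = int(ch)
        if i % 2 == 1:
            d *= 2
            if d > 9:
                d -= 9
        total += d
    return total % 10


def validate_npi(identifier: str) -> bool:
    """True iff *identifier* is a structurally valid NPI.

    The check digit is verified with the Luhn algorithm over the identifier
    prefixed with the issuer code ``80840``, as prescribed for NPIs.
    Non-string or non-10-digit inputs return False (never raise).
    """
    if not isinstance(identifier, str) or not _ID_RE.match(identifier):
        return False
    return luhn_checksum("80840" + identifier) == 0


@dataclass
class ParseReport:
    """Row-quality tallies from :func:`read_claims`."""

    n_rows: int = 0
    n_bad_dates: int = 0
    n_bad_provider_ids: int = 0
    n_bad_organization_ids: int = 0
    n_luhn_failures: int = 0
    n_dropped: int = 0

    def summary(self) -> str:
        return (
            f"{self.n_rows} rows; {self.n_bad_dates} unparseable dates, "
            f"{self.n_bad_provider_ids} malformed provider ids, "
            f"{self.n_bad_organization_ids} malformed organization ids, "
            f"{self.n_luhn_failures} Luhn-check failures, "
            f"{self.n_dropped} rows dropped"
        )


@dataclass
class ClaimsDataset:
    """A collection of claims with one row per claim event.

    ``frame`` holds the canonical columns ``patient_id``, ``provider_id``,
    ``organization_id`` (strings) and ``service_date`` (datetime64, day
    resolution).  Duplicate (patient, provider, date) rows are legitimate
    distinct claims and are kept unless explicitly deduplicated.
    """

    frame: pd.DataFrame
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"claims frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_claims(self) -> int:
        return len(self.frame)

    @property
    def patients(self) -> set[str]:
        return set(self.frame["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def span_days(self) -> int:
        if self.frame.empty:
            return 0
        dates = self.frame["service_date"]
        return int((dates.max() - dates.min()).days)

    def deduplicate(self) -> "ClaimsDataset":
        """Drop exact (patient, provider, organization, date) duplicates."""
        return ClaimsDataset(
            self.frame.drop_duplicates(subset=list(CANONICAL_COLUMNS)).reset_index(drop=True),
            self.report,
        )


def read_claims(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = ",",
    drop_invalid: bool = False,
) -> ClaimsDataset:
    """Read a delimited claims table into a :class:`ClaimsDataset`.

    Parameters
    ----------
    path
        Delimited text file with one row per claim.
    column_map
        Mapping of roles ``patient``, ``provider``, ``organization``, ``date``
        to column names in the file; defaults to DE-SynPUF naming
        (:data:`DEFAULT_COLUMN_MAP`).
    drop_invalid
        When True, rows with unparseable dates or ids that are not 10 decimal
        digits are dropped (and counted in the report).  When False (default)
        every row is kept and problems are only reported.  Luhn-check failures
        are always advisory: counted, never dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for role in ("patient", "provider", "organization", "date"):
        col = cmap[role]
        if col not in raw.columns:
            raise SchemaError(f"{role} column not found: {col!r}")
    frame = pd.DataFrame(
        {
            "patient_id": raw[cmap["patient"]].astype(str),
            "provider_id": raw[cmap["provider"]].astype(str),
            "organization_id": raw[cmap["organization"]].astype(str),
        }
    )
    dates = pd.to_datetime(raw[cmap["date"]], errors="coerce", format="mixed")
    frame["service_date"] = dates

    report = ParseReport(n_rows=len(frame))
    bad_date = dates.isna()
    bad_prov = ~frame["provider_id"].str.fullmatch(r"\d{10}")
    bad_org = ~frame["organization_id"].str.fullmatch(r"\d{10}")
    report.n_bad_dates = int(bad_date.sum())
    report.n_bad_provider_ids = int(bad_prov.sum())
    report.n_bad_organization_ids = int(bad_org.sum())
    ok_prov = frame.loc[~bad_prov, "provider_id"]
    report.n_luhn_failures = int((~ok_prov.map(validate_npi)).sum())

    if drop_invalid:
        bad = bad_date | bad_prov | bad_org
        report.n_dropped = int(bad.sum())
        frame = frame.loc[~bad].reset_index(drop=True)
    return ClaimsDataset(frame, report)


def write_claims(dataset: ClaimsDataset, path) -> None:
    """Write the canonical columns as CSV (dates as ISO ``YYYY-MM-DD``)."""
    out = dataset.frame.copy()
    out["service_date"] = out["service_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


@dataclass
class ProviderRegistry:
    """Geocoded provider registry: id -> (latitude, longitude, state)."""

    frame: pd.DataFrame  # columns: id, lat, lon, state

    def __post_init__(self) -> None:
        missing = [c for c in ("id", "lat", "lon") if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"registry missing columns: {missing}")
        if "state" not in self.frame.columns:
            self.frame = self.frame.assign(state=pd.NA)
        lat = self.frame["lat"].astype(float)
        lon = self.frame["lon"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
        self._coords = {
            str(r.id): (float(r.lat), float(r.lon)) for r in self.frame.itertuples()
        }
        self._state = {
            str(r.id): (None if pd.isna(r.state) else str(r.state))
            for r in self.frame.itertuples()
        }

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._coords

    def __len__(self) -> int:
        return len(self._coords)

    def coords(self, identifier: str) -> tuple[float, float] | None:
        return self._coords.get(identifier)

    def state(self, identifier: str) -> str | None:
        return self._state.get(identifier)

    @property
    def ids(self) -> set[str]:
        return set(self._coords)


def read_registry(path, *, sep: str = ",") -> ProviderRegistry:
    frame = pd.read_csv(path, sep=sep, dtype={"id": str})
    return ProviderRegistry(frame)


def write_registry(registry: ProviderRegistry, path) -> None:
    registry.frame.to_csv(path, index=False)


def prepare_patient_sequences(
    dataset: ClaimsDataset, level: str = "provider"
) -> dict[str, list[tuple[str, int]]]:
    """Group claims by patient and sort each group ascending by service date.

    Returns a mapping patient_id -> list of ``(vertex_id, day)`` where *day*
    is an integer day number (proleptic-Gregorian ordinal), so consumers can
    take plain integer differences for the frame test Δt ≤ τ.

    Same-day tie-break: the sort is stable, so claims on the same day keep
    their input-file order.  This is a deliberate, documented convention —
    claims carry no time of day — and it is what makes the sequential
    (trace-route) construction deterministic for a fixed input ordering.
    """
    if level == "provider":
        vcol = "provider_id"
    elif level == "organization":
        vcol = "organization_id"
    else:
        raise ValueError(f"unknown level {level!r}: expected 'provider' or 'organization'")
    if dataset.frame.empty:
        return {}
    frame = dataset.frame.assign(
        _day=dataset.frame["service_date"].values.astype("datetime64[D]").astype(np.int64)
    )
    sequences: dict[str, list[tuple[str, int]]] = {}
    # stable mergesort preserves input order within a day (the tie-break rule)
    for pid, grp in frame.sort_values("_day", kind="stable").groupby("patient_id", sort=True):
        sequences[str(pid)] = list(zip(grp[vcol].tolist(), grp["_day"].tolist()))
    return sequences
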