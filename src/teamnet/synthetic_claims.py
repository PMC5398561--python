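"""Synthetic claims-stream generator with planted geographic community structure.

The generator emulates the structural features of outpatient claims files
that the rest of the package consumes: one row per claim, several claims
per patient per year, every claim carrying both a provider and an
organization identifier, providers geocoded to roughly 1 km resolution,
and an optional migratory ("snowbird") patient fraction that splits its
time between two distant regions and thereby plants long-distance edges.

Structure planted (and returned as ground truth for recovery tests):

* providers are partitioned into ``n_communities`` geographic clusters,
  Gaussian-scattered around region centers;
* each provider belongs to exactly one organization, and organizations
  never span communities;
* each patient has a home community; each visit stays inside it with
  probability ``p_within_community``, else picks a provider uniformly
  from the rest of the country;
* snowbird patients draw their winter-month visits from a second,
  distant home region.

Visit dates are i.i.d. uniform over the simulated span — the simplest
model sufficient for exercising frame logic; there is no weekday or
seasonal structure beyond the snowbird mechanism.  All identifiers are
valid NPIs (10 digits passing the 80840-prefixed Luhn check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_io import ClaimsDataset, ProviderRegistry, luhn_checksum

__all__ = ["SimConfig", "GroundTruth", "generate_synthetic_claims", "make_npi"]

#: Default region centers: Rochester NY, NYC, Miami FL, Chicago IL.
DEFAULT_REGION_CENTERS = (
    (43.16, -77.61),
    (40.75, -74.00),
    (25.77, -80.19),
    (41.88, -87.63),
)

#: Months (1-12) counted as "winter" for snowbird visit relocation.
WINTER_MONTHS = (12, 1, 2)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic claims stream.

    Defaults describe a desk-scale Medicare-like year: a few hundred
    patients averaging ~10 outpatient claims each across a provider
    population an order of magnitude smaller than the patient panel,
    with strong geographic locality of care.
    """

    n_patients: int = 500
    n_providers: int = 100
    n_organizations: int = 20
    n_communities: int = 4
    days: int = 365
    visits_per_patient: float = 10.0
    p_within_community: float = 0.9
    snowbird_fraction: float = 0.0
    region_centers: tuple[tuple[float, float], ...] = DEFAULT_REGION_CENTERS
    community_scatter_deg: float = 0.25
    powerlaw_community_sizes: bool = False
    start_date: str = "2013-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_providers, self.n_organizations, self.days) <= 0:
            raise ValueError("counts and span must be positive")
        if self.n_communities <= 0 or self.n_communities > self.n_providers:
            raise ValueError("n_communities must be in [1, n_providers]")
        if self.n_communities > self.n_organizations:
            raise ValueError("need at least one organization per community")
        for p in (self.p_within_community, self.snowbird_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.visits_per_patient <= 0:
            raise ValueError("visits_per_patient must be positive")


@dataclass
class GroundTruth:
    """Planted structure returned alongside the generated data."""

    provider_community: dict[str, int]
    organization_community: dict[str, int]
    patient_home: dict[str, int]
    patient_winter: dict[str, int | None] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "provider_community": pd.DataFrame(
                sorted(self.provider_community.items()), columns=["provider_id", "community"]
            ),
            "organization_community": pd.DataFrame(
                sorted(self.organization_community.items()),
                columns=["organization_id", "community"],
            ),
            "patient_home": pd.DataFrame(
                [
                    (p, self.patient_home[p], self.patient_winter.get(p))
                    for p in sorted(self.patient_home)
                ],
                columns=["patient_id", "home_community", "winter_community"],
            ),
        }


def make_npi(rng: np.random.Generator, used: set[str]) -> str:
    """Draw a fresh, structurally valid NPI (Luhn check digit appended)."""
    while True:
        base = "1" + "".join(str(d) for d in rng.integers(0, 10, size=8))
        # choose the 10th digit so that Luhn("80840" + id) == 0
        check = (10 - luhn_checksum("80840" + base + "0")) % 10
        npi = base + str(check)
        if npi not in used:
            used.add(npi)
            return npi


def _community_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Provider counts per community: balanced, or power-law when requested."""
    k = cfg.n_communities
    if not cfg.powerlaw_community_sizes:
        sizes = np.full(k, cfg.n_providers // k, dtype=int)
        sizes[: cfg.n_providers % k] += 1
        return sizes
    # Zipf-ish raw sizes renormalized to the provider total, min 1 each
    raw = (np.arange(1, k + 1, dtype=float)) ** -1.5
    sizes = np.maximum(1, np.round(raw / raw.sum() * cfg.n_providers).astype(int))
    while sizes.sum() > cfg.n_providers:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < cfg.n_providers:
        sizes[np.argmin(sizes)] += 1
    return sizes


def generate_synthetic_claims(
    config: SimConfig,
) -> tuple[ClaimsDataset, ProviderRegistry, GroundTruth]:
    """Generate a claims stream, its provider registry, and the ground truth.

    Reproducible: the same config (including seed) yields byte-identical
    output frames.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    used_ids: set[str] = set()

    # --- providers and organizations, partitioned into communities ---------
    sizes = _community_sizes(cfg, rng)
    centers = [cfg.region_centers[c % len(cfg.region_centers)] for c in range(cfg.n_communities)]

    provider_ids: list[str] = []
    provider_comm: dict[str, int] = {}
    rows = []
    for comm, size in enumerate(sizes):
        lat0, lon0 = centers[comm]
        lats = np.round(lat0 + rng.normal(0, cfg.community_scatter_deg, size), 2)
        lons = np.round(lon0 + rng.normal(0, cfg.community_scatter_deg, size), 2)
        for i in range(size):
            pid = make_npi(rng, used_ids)
            provider_ids.append(pid)
            provider_comm[pid] = comm
            rows.append((pid, float(np.clip(lats[i], -90, 90)), float(np.clip(lons[i], -180, 180)),
                         f"S{comm % 50:02d}"))
    registry = ProviderRegistry(pd.DataFrame(rows, columns=["id", "lat", "lon", "state"]))

    # organizations: allocated per community proportionally (>= 1 each), then
    # each provider joins an organization of its own community
    org_counts = np.maximum(1, np.round(sizes / sizes.sum() * cfg.n_organizations).astype(int))
    while org_counts.sum() > cfg.n_organizations:
        org_counts[np.argmax(org_counts)] -= 1
    while org_counts.sum() < cfg.n_organizations:
        org_counts[np.argmin(org_counts)] += 1
    org_ids_by_comm: list[list[str]] = []
    org_comm: dict[str, int] = {}
    for comm, cnt in enumerate(org_counts):
        ids = [make_npi(rng, used_ids) for _ in range(cnt)]
        org_ids_by_comm.append(ids)
        for oid in ids:
            org_comm[oid] = comm
    provider_org = {
        pid: org_ids_by_comm[comm][int(rng.integers(len(org_ids_by_comm[comm])))]
        for pid, comm in provider_comm.items()
    }

    providers_by_comm: list[np.ndarray] = [
        np.array([p for p in provider_ids if provider_comm[p] == c])
        for c in range(cfg.n_communities)
    ]
    all_providers = np.array(provider_ids)
    outside_by_comm: list[np.ndarray] = []
    for c in range(cfg.n_communities):
        outside = np.array([p for p in provider_ids if provider_comm[p] != c])
        outside_by_comm.append(outside if len(outside) else all_providers)

    # --- patients -----------------------------------------------------------
    patient_ids = [f"P{i:07d}" for i in range(cfg.n_patients)]
    home = rng.integers(0, cfg.n_communities, size=cfg.n_patients)
    is_snowbird = rng.random(cfg.n_patients) < cfg.snowbird_fraction

    # a snowbird's winter region: the geographically most distant center
    def farthest(comm: int) -> int:
        lat0, lon0 = centers[comm]
        d = [
            (centers[c][0] - lat0) ** 2 + (centers[c][1] - lon0) ** 2
            for c in range(cfg.n_communities)
        ]
        return int(np.argmax(d))

    start = np.datetime64(cfg.start_date)
    dates_all = start + np.arange(cfg.days)
    months = pd.DatetimeIndex(dates_all).month.values
    winter_mask = np.isin(months, WINTER_MONTHS)

    patient_home: dict[str, int] = {}
    patient_winter: dict[str, int | None] = {}
    rec_pat: list[str] = []
    rec_prov: list[str] = []
    rec_org: list[str] = []
    rec_date: list[np.datetime64] = []

    n_visits = rng.poisson(cfg.visits_per_patient, size=cfg.n_patients)
    for idx, patient in enumerate(patient_ids):
        comm = int(home[idx])
        patient_home[patient] = comm
        winter_comm: int | None = farthest(comm) if is_snowbird[idx] else None
        patient_winter[patient] = winter_comm
        k = int(n_visits[idx])
        if k == 0:
            continue
        day_idx = np.sort(rng.integers(0, cfg.days, size=k))
        for d in day_idx:
            if winter_comm is not None and winter_mask[d]:
                pool = providers_by_comm[winter_comm]
            elif rng.random() < cfg.p_within_community:
                pool = providers_by_comm[comm]
            else:
                pool = outside_by_comm[comm]
            prov = str(pool[int(rng.integers(len(pool)))])
            rec_pat.append(patient)
            rec_prov.append(prov)
            rec_org.append(provider_org[prov])
            rec_date.append(dates_all[d])

    frame = pd.DataFrame(
        {
            "patient_id": rec_pat,
            "provider_id": rec_prov,
            "organization_id": rec_org,
            "service_date": pd.to_datetime(np.array(rec_date, dtype="datetime64[D]")),
        }
    )
    dataset = ClaimsDataset(frame)
    truth = GroundTruth(
        provider_community=provider_comm,
        organization_community=org_comm,
        patient_home=patient_home,
        patient_winter=patient_winter,
    )
    return dataset, registry, truth
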