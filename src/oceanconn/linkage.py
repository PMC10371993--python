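"""Linking community dissimilarity to connectivity and physical distance.

The linkage procedure: keep only samples from below a depth cutoff
(deep samples sit in the subsurface chlorophyll maximum where the
communities are structured), attach each sample to the subdomain whose
mask contains it (snapping near-misses to the nearest subdomain
centroid), average sample-pair distances in the community NMDS space
per domain pair, and regress those averages, per focal domain, against
(a) the distance between the domains in the connectivity NMDS space and
(b) the mean great-circle distance between the samples.  Comparing the
two R² columns answers whether water-mass connectivity or plain
geographic proximity better explains community similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_stats import (
    Ordination2D,
    RegressionResult,
    SampleTable,
    linreg,
)
from .grid_flow import Grid2D, LonLatGeoref, Subdomain

__all__ = [
    "DomainAssignment",
    "LinkageTable",
    "EARTH_RADIUS_KM",
    "filter_by_depth",
    "assign_domains",
    "domain_pair_distance",
    "connectivity_distance",
    "physical_distance",
    "explainers_table",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class DomainAssignment:
    """sample_id → subdomain label, with a snapped flag for out-of-mask fixes."""

    domain_of: dict[str, str]
    snapped: dict[str, bool]

    def samples_in(self, label: str) -> list[str]:
        return [s for s, d in self.domain_of.items() if d == label]

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for d in self.domain_of.values():
            if d not in seen:
                seen.append(d)
        return seen


@dataclass(frozen=True)
class LinkageTable:
    """Per-focal-domain regression summary (Table-style output).

    One row per focal domain: sample count N and R²/p for the
    connectivity-distance and physical-distance regressions.
    """

    df: pd.DataFrame

    @staticmethod
    def _stars(p: float) -> str:
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    def with_significance(self) -> pd.DataFrame:
        out = self.df.copy()
        out["sig_connectivity"] = out["p_connectivity"].map(self._stars)
        out["sig_physical"] = out["p_physical"].map(self._stars)
        return out


def filter_by_depth(table: SampleTable, min_depth: float) -> SampleTable:
    """Keep samples strictly deeper than ``min_depth`` metres.

    "Below 20 m" is interpreted strictly: a sample at exactly the cutoff
    depth is excluded.
    """
    if min_depth < 0:
        raise ValueError(f"min_depth must be non-negative, got {min_depth}")
    kept = table.data[table.data["depth_m"] > min_depth]
    if kept.empty:
        import warnings

        warnings.warn(
            f"depth filter > {min_depth} m retained no samples", stacklevel=2
        )
    return SampleTable(data=kept.reset_index(drop=True))


def assign_domains(
    table: SampleTable,
    subdomains: list[Subdomain],
    grid: Grid2D,
    georef: LonLatGeoref,
    snap: bool = True,
) -> DomainAssignment:
    """Attach each sample to the subdomain containing its position.

    Positions are lon/lat, mapped through the georeference onto the
    grid; a sample whose position falls outside every mask is snapped
    to the subdomain with the nearest centroid and flagged (stations
    just outside a domain boundary are a normal occurrence in field
    data).  With ``snap=False`` such samples raise instead.
    """
    x, y = georef.to_xy(table.data["lon"].to_numpy(), table.data["lat"].to_numpy())
    ii = np.floor((x - grid.origin[0]) / grid.dx).astype(int)
    jj = np.floor((y - grid.origin[1]) / grid.dy).astype(int)
    centroids = np.array([d.centroid(grid) for d in subdomains])

    domain_of: dict[str, str] = {}
    snapped: dict[str, bool] = {}
    unassigned: list[str] = []
    for k, sid in enumerate(table.sample_ids):
        label = None
        if 0 <= ii[k] < grid.nx and 0 <= jj[k] < grid.ny:
            for dom in subdomains:
                if dom.mask[jj[k], ii[k]]:
                    label = dom.label
                    break
        if label is None:
            if not snap:
                unassigned.append(sid)
                continue
            d2 = (centroids[:, 0] - x[k]) ** 2 + (centroids[:, 1] - y[k]) ** 2
            label = subdomains[int(np.argmin(d2))].label
            snapped[sid] = True
        else:
            snapped[sid] = False
        domain_of[sid] = label
    if unassigned:
        raise ValueError(
            f"samples outside all subdomain masks with snapping disabled: {unassigned}"
        )
    return DomainAssignment(domain_of=domain_of, snapped=snapped)


def domain_pair_distance(
    ordination: Ordination2D,
    assign: DomainAssignment,
    a: str,
    b: str,
) -> tuple[float, float | None, int]:
    """Mean Euclidean ordination distance over all cross sample pairs.

    Every sample assigned to domain ``a`` is paired with every sample of
    ``b``; returns (mean, standard error over pairs, number of pairs).
    The SE is None when only one pair exists.
    """
    ids_a = [s for s in assign.samples_in(a) if s in ordination.labels]
    ids_b = [s for s in assign.samples_in(b) if s in ordination.labels]
    if not ids_a or not ids_b:
        empty = a if not ids_a else b
        raise ValueError(f"domain {empty!r} has no samples in the ordination")
    A = np.array([ordination.coords_for(s) for s in ids_a])
    B = np.array([ordination.coords_for(s) for s in ids_b])
    diff = A[:, None, :] - B[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=2)).ravel()
    mean = float(dists.mean())
    se = float(dists.std(ddof=1) / np.sqrt(len(dists))) if len(dists) > 1 else None
    return mean, se, len(dists)


def connectivity_distance(conn_ord: Ordination2D, a: str, b: str) -> float:
    """Euclidean distance between two domains in the connectivity NMDS."""
    pa = conn_ord.coords_for(a)
    pb = conn_ord.coords_for(b)
    return float(np.linalg.norm(pa - pb))


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371.0 km)."""
    lat1, lat2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dlat = lat2 - lat1
    dlon = np.deg2rad(lon2) - np.deg2rad(lon1)
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def physical_distance(
    table: SampleTable, assign: DomainAssignment, a: str, b: str
) -> float:
    """Mean great-circle distance (km) over all cross sample pairs of a and b."""
    df = table.data.set_index(table.data["sample_id"].astype(str))
    ids_a = [s for s in assign.samples_in(a) if s in df.index]
    ids_b = [s for s in assign.samples_in(b) if s in df.index]
    if not ids_a or not ids_b:
        empty = a if not ids_a else b
        raise ValueError(f"domain {empty!r} has no samples in the table")
    lo_a = df.loc[ids_a, "lon"].to_numpy(float)
    la_a = df.loc[ids_a, "lat"].to_numpy(float)
    lo_b = df.loc[ids_b, "lon"].to_numpy(float)
    la_b = df.loc[ids_b, "lat"].to_numpy(float)
    if (np.abs(la_a) > 90).any() or (np.abs(la_b) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    d = haversine_km(
        lo_a[:, None], la_a[:, None], lo_b[None, :], la_b[None, :]
    )
    return float(d.mean())


def explainers_table(
    eco_ord: Ordination2D,
    conn_ord: Ordination2D,
    table: SampleTable,
    assign: DomainAssignment,
) -> LinkageTable:
    """Per-domain regressions of community distance on connectivity and
    physical distance.

    For each focal domain with samples, the mean community-NMDS distance
    to every other sampled domain is regressed (unweighted OLS) on the
    connectivity-NMDS distance and, separately, on the mean great-circle
    distance between the samples.  Rows report N (samples in the focal
    domain) and both R²/p pairs.
    """
    sampled = [
        d
        for d in assign.domains
        if any(s in eco_ord.labels for s in assign.samples_in(d))
        and d in conn_ord.labels
    ]
    if len(sampled) < 4:
        raise ValueError(
            f"need >= 4 sampled domains (>=3 comparison points per focal "
            f"domain), got {len(sampled)}"
        )
    rows = []
    for a in sampled:
        others = [b for b in sampled if b != a]
        y = []
        x_conn = []
        x_phys = []
        for b in others:
            mean_eco, _, _ = domain_pair_distance(eco_ord, assign, a, b)
            y.append(mean_eco)
            x_conn.append(connectivity_distance(conn_ord, a, b))
            x_phys.append(physical_distance(table, assign, a, b))
        reg_c: RegressionResult = linreg(x_conn, y)
        reg_p: RegressionResult = linreg(x_phys, y)
        n_samples = sum(1 for s in assign.samples_in(a) if s in eco_ord.labels)
        rows.append(
            {
                "domain": a,
                "N": n_samples,
                "r_squared_connectivity": reg_c.r_squared,
                "p_connectivity": reg_c.p,
                "r_squared_physical": reg_p.r_squared,
                "p_physical": reg_p.p,
            }
        )
    return LinkageTable(df=pd.DataFrame(rows))
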