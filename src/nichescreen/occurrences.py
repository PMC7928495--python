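"""Presence records: ingestion, exact deduplication, and spatial thinning.

Thinning keeps only records whose great-circle distance to every previously
kept record is at least a buffer radius (default 16 km), a standard guard
against sampling bias and double-counted individuals. The pass is greedy in
record order, which makes it deterministic and auditable; the retained
count therefore depends on input order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSet", "read_occurrences", "deduplicate", "thin",
           "haversine_km", "EARTH_RADIUS_KM"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class OccurrenceSet:
    """Georeferenced presence records in input order."""

    lon: np.ndarray
    lat: np.ndarray
    ids: list | None = None
    dates: list | None = None
    skipped: int = 0                       # malformed rows dropped at read time
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon/lat length mismatch")
        if self.lon.size and (np.abs(self.lon) > 180).any():
            raise ValueError("longitude outside [-180, 180]")
        if self.lat.size and (np.abs(self.lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")

    def __len__(self) -> int:
        return self.lon.size

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return np.column_stack([self.lon, self.lat])

    def subset(self, index: np.ndarray) -> "OccurrenceSet":
        idx = np.asarray(index)
        return OccurrenceSet(
            self.lon[idx], self.lat[idx],
            [self.ids[i] for i in idx] if self.ids is not None else None,
            [self.dates[i] for i in idx] if self.dates is not None else None,
            self.skipped, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"longitude": self.lon, "latitude": self.lat})
        if self.ids is not None:
            out["id"] = self.ids
        if self.dates is not None:
            out["date"] = self.dates
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_occurrences(path: str | Path, lon_field: str = "longitude",
                     lat_field: str = "latitude",
                     id_field: str | None = None,
                     date_field: str | None = None) -> OccurrenceSet:
    """Parse a CSV of presence records.

    Rows with unparsable or out-of-range coordinates are skipped and counted
    in ``OccurrenceSet.skipped``. Missing coordinate columns raise KeyError.
    """
    df = pd.read_csv(path)
    for f in (lon_field, lat_field):
        if f not in df.columns:
            raise KeyError(f"column {f!r} not found in {path}")
    lon = pd.to_numeric(df[lon_field], errors="coerce")
    lat = pd.to_numeric(df[lat_field], errors="coerce")
    ok = lon.notna() & lat.notna() & (lon.abs() <= 180) & (lat.abs() <= 90)
    skipped = int((~ok).sum())
    if skipped:
        warnings.warn(f"skipped {skipped} malformed occurrence row(s)", stacklevel=2)
    if ok.sum() == 0:
        warnings.warn("no valid occurrence records", stacklevel=2)
    kept = df[ok]
    return OccurrenceSet(
        lon[ok].to_numpy(), lat[ok].to_numpy(),
        ids=kept[id_field].tolist() if id_field else None,
        dates=kept[date_field].tolist() if date_field else None,
        skipped=skipped)


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop exact coordinate duplicates, keeping the first of each."""
    seen: set[tuple[float, float]] = set()
    keep = []
    for i, (x, y) in enumerate(zip(occ.lon, occ.lat)):
        key = (float(x), float(y))
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return occ.subset(np.array(keep, dtype=int))


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def thin(occ: OccurrenceSet, radius_km: float = 16.0,
         report_path: str | Path | None = None) -> OccurrenceSet:
    """Greedy keep-first spatial thinning at a minimum separation.

    A record is kept iff its haversine distance to every previously kept
    record is >= ``radius_km``. Idempotent; output is a subset of input.
    Optionally writes a JSON report of kept/dropped counts and the
    nearest-neighbour distance summary of the retained set.
    """
    if not radius_km > 0:
        raise ValueError("radius_km must be > 0")
    kept: list[int] = []
    klon = np.empty(len(occ))
    klat = np.empty(len(occ))
    for i in range(len(occ)):
        if kept:
            d = haversine_km(occ.lon[i], occ.lat[i],
                             klon[:len(kept)], klat[:len(kept)])
            if d.min() < radius_km:
                continue
        klon[len(kept)] = occ.lon[i]
        klat[len(kept)] = occ.lat[i]
        kept.append(i)
    out = occ.subset(np.array(kept, dtype=int))
    if report_path is not None:
        nn = []
        for i in range(len(out)):
            d = haversine_km(out.lon[i], out.lat[i], out.lon, out.lat)
            d[i] = np.inf
            if len(out) > 1:
                nn.append(float(d.min()))
        report = {"input_records": len(occ), "kept": len(out),
                  "dropped": len(occ) - len(out), "radius_km": radius_km,
                  "nn_min_km": min(nn) if nn else None,
                  "nn_mean_km": float(np.mean(nn)) if nn else None}
        Path(report_path).write_text(json.dumps(report, indent=2))
    return out
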