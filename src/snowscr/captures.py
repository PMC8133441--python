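"""Detectors, detection events and count-detector capture histories.

Camera-trap photographs of identified individuals become *independent
encounters* only when separated by a minimum gap (4 h by default) from the
previous retained encounter of the same individual at the same station —
this guards the Poisson count model against overdispersed bursts of
photographs.  Independent encounters are then tallied into the count
detector format: a non-negative integer matrix y[i, k] of encounters of
individual i at detector k over the (closed) session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorArray",
    "DetectionEvent",
    "CaptureHistory",
    "deduplicate_events",
    "build_capture_history",
    "mcp_area",
    "read_detectors_tsv",
    "read_events_csv",
    "write_events_csv",
]

TOPOGRAPHY_LEVELS = ("cliff", "gully bed", "ridgeline")


@dataclass
class DetectorArray:
    """Camera-trap stations with effort and trap-level covariates.

    ``table`` columns: id, x, y (m), effort_days, n_cameras ({1, 2}),
    topography ({'ridgeline', 'cliff', 'gully bed'}).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "x", "y", "effort_days", "n_cameras", "topography"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"detector table missing columns: {sorted(missing)}")
        t = self.table.reset_index(drop=True).copy()
        t["id"] = t["id"].astype(str)
        if t["id"].duplicated().any():
            raise ValueError("detector ids must be unique")
        if not np.all(np.isfinite(t[["x", "y"]].to_numpy(float))):
            raise ValueError("detector coordinates must be finite")
        if (t["effort_days"] <= 0).any():
            raise ValueError("effort_days must be > 0")
        if not t["n_cameras"].isin([1, 2]).all():
            raise ValueError("n_cameras must be 1 or 2")
        bad = set(t["topography"]) - set(TOPOGRAPHY_LEVELS)
        if bad:
            raise ValueError(f"unknown topography levels: {sorted(bad)}")
        self.table = t

    @classmethod
    def from_arrays(cls, ids, x, y, effort_days, n_cameras, topography) -> "DetectorArray":
        return cls(pd.DataFrame({
            "id": ids, "x": x, "y": y, "effort_days": effort_days,
            "n_cameras": n_cameras, "topography": topography,
        }))

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    @property
    def effort(self) -> np.ndarray:
        return self.table["effort_days"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_detectors_tsv(path) -> DetectorArray:
    return DetectorArray(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class DetectionEvent:
    """One time-stamped detection of an individual at a detector.

    ``individual`` is None for encounters whose photographs could not be
    identified to an individual; such events are dropped (with a logged
    count) when the capture history is built.
    """

    individual: str | None
    detector: str
    timestamp: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))


def read_events_csv(path) -> list[DetectionEvent]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        ind = row["individual"]
        if pd.isna(ind) or str(ind).strip() == "":
            ind = None
        out.append(DetectionEvent(ind, str(row["detector"]), pd.Timestamp(row["timestamp"])))
    return out


def write_events_csv(events: Sequence[DetectionEvent], path) -> None:
    pd.DataFrame({
        "individual": [e.individual if e.individual is not None else "" for e in events],
        "detector": [e.detector for e in events],
        "timestamp": [e.timestamp.isoformat() for e in events],
    }).to_csv(path, index=False)


def deduplicate_events(
    events: Iterable[DetectionEvent],
    window_hours: float = 4.0,
    rule: str = "greedy",
) -> list[DetectionEvent]:
    """Reduce raw detections to independent encounters.

    Within each (individual, detector) pair, events are sorted by time and
    an event is retained iff it is the first or at least ``window_hours``
    after the last *retained* event ("greedy", the default).  The
    alternative rule "consecutive" compares to the immediately preceding raw
    event instead.  Duplicate timestamps collapse to one event.  The greedy
    rule is idempotent.
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be > 0")
    if rule not in {"greedy", "consecutive"}:
        raise ValueError("rule must be 'greedy' or 'consecutive'")
    groups: dict[tuple, list[DetectionEvent]] = {}
    for ev in events:
        groups.setdefault((ev.individual, ev.detector), []).append(ev)
    kept: list[DetectionEvent] = []
    window = pd.Timedelta(hours=window_hours)
    for key in sorted(groups, key=lambda k: (str(k[0]), k[1])):
        evs = sorted(groups[key], key=lambda e: e.timestamp)
        anchor = None  # last retained ("greedy") or last seen ("consecutive")
        last_ts = None
        for ev in evs:
            if last_ts is not None and ev.timestamp == last_ts:
                continue  # duplicate timestamp
            ref = anchor
            if ref is None or (ev.timestamp - ref) >= window:
                kept.append(ev)
                anchor = ev.timestamp
            elif rule == "consecutive":
                anchor = ev.timestamp
            last_ts = ev.timestamp
    kept.sort(key=lambda e: (str(e.individual), e.detector, e.timestamp))
    return kept


@dataclass
class CaptureHistory:
    """Count-detector capture history: y[i, k] encounters over the session.

    Rows are identified individuals (each detected at least once); columns
    are detector ids in the detector-array order.
    """

    y: pd.DataFrame
    session_days: float

    def __post_init__(self) -> None:
        if self.session_days <= 0:
            raise ValueError("session_days must be > 0")
        y = self.y.astype(int)
        if (y.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if len(y) and (y.sum(axis=1) < 1).any():
            raise ValueError("every listed individual must have at least one encounter")
        self.y = y

    @property
    def n_individuals(self) -> int:
        return len(self.y)

    @property
    def total_encounters(self) -> int:
        return int(self.y.to_numpy().sum())

    @property
    def checksum(self) -> str:
        import hashlib
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.y.to_numpy(int)).tobytes())
        h.update(",".join(map(str, self.y.columns)).encode())
        h.update(repr(self.session_days).encode())
        return h.hexdigest()


def build_capture_history(
    encounters: Sequence[DetectionEvent],
    detectors: DetectorArray,
    session_days: float,
) -> CaptureHistory:
    """Tally independent encounters into the count-detector matrix.

    Events with a null individual id (unidentifiable photographs) are
    dropped with a logged count; an unknown detector id is an error.
    """
    known = set(detectors.ids)
    unknown = {e.detector for e in encounters} - known
    if unknown:
        raise ValueError(f"unknown detector id(s): {sorted(unknown)}")
    identified = [e for e in encounters if e.individual is not None]
    discarded = len(encounters) - len(identified)
    if discarded:
        logger.info("discarded %d encounters with unidentifiable individuals", discarded)
    individuals = sorted({e.individual for e in identified})
    y = pd.DataFrame(0, index=individuals, columns=detectors.ids, dtype=int)
    for e in identified:
        y.loc[e.individual, e.detector] += 1
    return CaptureHistory(y=y, session_days=session_days)


def mcp_area(detectors: DetectorArray | np.ndarray) -> float:
    """Minimum convex polygon area (km²) of the detector locations."""
    xy = detectors.xy if isinstance(detectors, DetectorArray) else np.asarray(detectors, float)
    if len(xy) < 3:
        raise ValueError("minimum convex polygon needs at least 3 detectors")
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise ValueError("detector locations are collinear or degenerate") from exc
    return hull.volume / 1e6  # 2-D ConvexHull.volume is the enclosed area
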