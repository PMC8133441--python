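"""Double-observer mark-recapture estimation of wild-prey abundance.

Two observers independently record ungulate groups; treating the two
observers as the two samples of a Lincoln–Petersen experiment on groups,
with n1 = C + S1 groups seen by observer 1, n2 = C + S2 by observer 2, and
m = C seen by both, the bias-corrected Chapman estimator gives the number
of groups,

    G_hat = (n1 + 1)(n2 + 1)/(m + 1) − 1,
    SE(G_hat) = sqrt[(n1+1)(n2+1)(n1−m)(n2−m) / ((m+1)²(m+2))].

Abundance is N_hat = G_hat × U_hat where U_hat is the mean observed group
size; observer detection probabilities are P1 = C/(C+S2), P2 = C/(C+S1).
Per-block densities divide the pooled animal count by block area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupRecord",
    "DoubleObserverEstimate",
    "tally",
    "chapman_groups",
    "abundance",
    "detection_probs",
    "block_density",
    "estimate",
    "read_records_csv",
    "write_records_csv",
    "read_block_areas_csv",
]


@dataclass(frozen=True)
class GroupRecord:
    """One observed ungulate group: who saw it, where, and how many animals."""

    species: str
    block: str
    group_size: int
    seen1: bool
    seen2: bool

    def __post_init__(self):
        if self.group_size < 1:
            raise ValueError("group size must be >= 1")
        if not (self.seen1 or self.seen2):
            raise ValueError("a recorded group must have been seen by at least one observer")


@dataclass
class DoubleObserverEstimate:
    """All derived quantities of a double-observer analysis (one species or
    pooled): tallies, Chapman group estimate, mean group size, abundance
    with SE/CI, and per-observer detection probabilities."""

    c: int
    s1: int
    s2: int
    naive_groups: int
    naive_n: int
    g_hat: float
    se_g: float
    u_hat: float
    n_hat: int
    se_n: float
    ci_n: tuple[float, float]
    p1: float
    p2: float

    def table_row(self) -> dict:
        """Display-precision summary: probabilities truncated at 2 decimals,
        G/U rounded to 2 decimals, N to an integer."""
        return {
            "C": self.c, "S1": self.s1, "S2": self.s2,
            "G_hat": round(self.g_hat, 2), "SE_G": round(self.se_g, 2),
            "U_hat": round(self.u_hat, 2),
            "N": self.naive_n, "N_hat": self.n_hat,
            "SE_N": round(self.se_n, 2),
            "CI": f"{self.ci_n[0]:.0f}-{self.ci_n[1]:.0f}",
            "P1": math.floor(self.p1 * 100) / 100,
            "P2": math.floor(self.p2 * 100) / 100,
        }


def read_records_csv(path) -> list[GroupRecord]:
    df = pd.read_csv(path)
    truthy = {"1", "true", "yes", "y", "t"}
    def as_bool(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return str(v).strip().lower() in truthy
    return [
        GroupRecord(str(r["species"]), str(r["block"]), int(r["group_size"]),
                    as_bool(r["seen1"]), as_bool(r["seen2"]))
        for _, r in df.iterrows()
    ]


def write_records_csv(records: Sequence[GroupRecord], path) -> None:
    pd.DataFrame([{
        "species": r.species, "block": r.block, "group_size": r.group_size,
        "seen1": int(r.seen1), "seen2": int(r.seen2),
    } for r in records]).to_csv(path, index=False)


def read_block_areas_csv(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return dict(zip(df["block"].astype(str), df["area_km2"].astype(float)))


def tally(records: Sequence[GroupRecord]) -> tuple[int, int, int, int, int]:
    """(C, S1, S2, naive G, naive N): groups seen by both / only observer 1 /
    only observer 2, total distinct groups, and pooled animal count."""
    c = sum(1 for r in records if r.seen1 and r.seen2)
    s1 = sum(1 for r in records if r.seen1 and not r.seen2)
    s2 = sum(1 for r in records if r.seen2 and not r.seen1)
    naive_g = c + s1 + s2
    naive_n = sum(r.group_size for r in records)
    return c, s1, s2, naive_g, naive_n


def chapman_groups(c: int, s1: int, s2: int) -> tuple[float, float]:
    """Chapman bias-corrected group estimate and its SE from the tallies."""
    if c < 1:
        raise ValueError("Chapman estimator undefined with no groups seen by both observers")
    n1 = c + s1
    n2 = c + s2
    m = c
    g_hat = (n1 + 1) * (n2 + 1) / (m + 1) - 1
    var = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))
    return float(g_hat), math.sqrt(var)


def detection_probs(c: int, s1: int, s2: int) -> tuple[float, float]:
    """Per-observer detection probabilities P1 = C/(C+S2), P2 = C/(C+S1)."""
    if c < 1:
        raise ValueError("detection probabilities undefined with C = 0")
    return c / (c + s2), c / (c + s1)


def abundance(
    g_hat: float,
    records: Sequence[GroupRecord],
    se_g: float = 0.0,
) -> tuple[float, int, float, tuple[float, float]]:
    """(U_hat, N_hat, SE, 95% CI) from the group estimate and the records.

    U_hat is the mean observed group size (naive N / naive G); N_hat is
    round(G_hat * U_hat); the SE combines SE(G_hat) and the sample SE of
    group sizes by the delta method; the CI is normal-based (symmetric).
    """
    sizes = np.array([r.group_size for r in records], dtype=float)
    naive_g = len(sizes)
    if g_hat == 0:
        return 0.0, 0, 0.0, (0.0, 0.0)
    if naive_g < 1:
        raise ValueError("need at least one recorded group")
    u_hat = float(sizes.sum() / naive_g)
    n_float = g_hat * u_hat
    var_u = float(sizes.var(ddof=1) / naive_g) if naive_g > 1 else 0.0
    var_n = u_hat**2 * se_g**2 + g_hat**2 * var_u
    se_n = math.sqrt(var_n)
    ci = (n_float - 1.96 * se_n, n_float + 1.96 * se_n)
    return u_hat, int(round(n_float)), se_n, ci


def estimate(records: Sequence[GroupRecord]) -> DoubleObserverEstimate:
    """End-to-end double-observer estimate for a set of records."""
    c, s1, s2, naive_g, naive_n = tally(records)
    g_hat, se_g = chapman_groups(c, s1, s2)
    u_hat, n_hat, se_n, ci = abundance(g_hat, records, se_g)
    p1, p2 = detection_probs(c, s1, s2)
    return DoubleObserverEstimate(
        c=c, s1=s1, s2=s2, naive_groups=naive_g, naive_n=naive_n,
        g_hat=g_hat, se_g=se_g, u_hat=u_hat, n_hat=n_hat, se_n=se_n,
        ci_n=ci, p1=p1, p2=p2,
    )


def block_density(
    records: Sequence[GroupRecord],
    block_areas: Mapping[str, float],
) -> pd.DataFrame:
    """Per-block wild-prey density: pooled animal count / block area (km²).

    Every block named in ``block_areas`` appears in the output (density 0 if
    no groups); a record in a block without an area is an error.
    """
    missing = {r.block for r in records} - set(block_areas)
    if missing:
        raise ValueError(f"no area given for block(s): {sorted(missing)}")
    totals = {b: 0 for b in block_areas}
    for r in records:
        totals[r.block] += r.group_size
    rows = [
        {"block": b, "area_km2": a, "animals": totals[b], "density_per_km2": totals[b] / a}
        for b, a in block_areas.items()
    ]
    return pd.DataFrame(rows)
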