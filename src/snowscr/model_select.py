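"""AIC model comparison and model-averaged density surfaces.

Candidate SCR fits on identical data are ranked by AIC = 2k − 2 logL;
Akaike weights exp(−ΔAIC/2), normalized over the full candidate set, give
each model's relative support.  Density surfaces (not coefficients) are
model-averaged: per-pixel D̄(s) = Σ_m w̃_m D̂_m(s), where w̃ are the weights
renormalized over the chosen subset (top-k models or all models within a
ΔAIC cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geomask import MaskGrid
from .scr_core import DensitySurface, ScrFit, derived_density

__all__ = ["AicTable", "aic_table", "model_average_density", "cumulative_covariate_weight"]


@dataclass
class AicTable:
    """Ranked model-comparison table: model, npar, logLik, AIC, dAIC, weight
    (full candidate-set Akaike weights, ascending AIC; ties broken by
    label)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if abs(float(t["weight"].sum()) - 1.0) > 1e-9:
            raise ValueError("AIC weights must sum to 1 over the candidate set")
        if abs(float(t["dAIC"].iloc[0])) > 1e-12:
            raise ValueError("first row must have dAIC 0")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)


def _check_same_data(fits: Sequence[ScrFit]) -> None:
    checksums = {f.data_checksum for f in fits}
    if len(checksums) > 1:
        raise ValueError("fits were made on differing data (capture-history checksum mismatch)")


def aic_table(fits: Sequence[ScrFit], labels: Sequence[str] | None = None) -> AicTable:
    """Build the AIC comparison table for a candidate set of fits."""
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    _check_same_data(fits)
    if labels is None:
        labels = [f.spec.label for f in fits]
    df = pd.DataFrame({
        "model": list(labels),
        "npar": [f.npar for f in fits],
        "logLik": [f.log_lik for f in fits],
        "AIC": [f.aic for f in fits],
    })
    df = df.sort_values(["AIC", "model"], kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    rel = np.exp(-df["dAIC"].to_numpy() / 2.0)
    df["weight"] = rel / rel.sum()
    return AicTable(table=df)


def model_average_density(
    fits: Sequence[ScrFit],
    mask: MaskGrid | None = None,
    rule: str = "delta",
    k: int = 5,
    cutoff: float = 5.0,
) -> DensitySurface:
    """Model-averaged density surface over a subset of the candidate set.

    ``rule="top"`` keeps the ``k`` lowest-AIC models; ``rule="delta"`` keeps
    models with AIC within ``cutoff`` of the best.  Weights are renormalized
    over the chosen subset.  All chosen fits must have converged.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    _check_same_data(fits)
    order = np.argsort([f.aic for f in fits], kind="stable")
    aics = np.array([fits[i].aic for i in order])
    if rule == "top":
        chosen = [fits[i] for i in order[: max(k, 0)]]
    elif rule == "delta":
        chosen = [fits[i] for i in order[aics - aics[0] <= cutoff]]
    else:
        raise ValueError("rule must be 'top' or 'delta'")
    if not chosen:
        raise ValueError(f"no models selected under rule {rule!r}")
    for f in chosen:
        if not f.converged:
            raise ValueError(f"model {f.spec.label!r} did not converge; cannot average")
    rel = np.exp(-(np.array([f.aic for f in chosen]) - min(f.aic for f in chosen)) / 2.0)
    w = rel / rel.sum()
    surfaces = [derived_density(f, mask) for f in chosen]
    dens = np.sum([wi * s.density for wi, s in zip(w, surfaces)], axis=0)
    out_mask = surfaces[0].mask
    n_bar = float(dens.sum() * out_mask.area_per_pixel)
    return DensitySurface(mask=out_mask, density=dens, n_hat=n_bar)


def cumulative_covariate_weight(
    fits: Sequence[ScrFit],
    covariate: str,
    clause: str = "density",
) -> float:
    """Sum of full-candidate-set AIC weights of models whose ``clause``
    ('density', 'lambda0', 'sigma' or 'noneuc') contains ``covariate`` —
    the usual cumulative-importance summary."""
    table = aic_table(fits)
    weights = dict(zip(table.table["model"], table.table["weight"]))
    total = 0.0
    for f in fits:
        if clause == "noneuc":
            terms = (f.spec.noneuc,) if f.spec.noneuc else ()
        else:
            terms = getattr(f.spec, clause)
        bases = {t[:-2] if t.endswith("^2") else t for t in terms}
        if covariate in terms or covariate in bases:
            total += weights[f.spec.label]
    return total
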