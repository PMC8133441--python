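"""Formula parsing, run configuration and the end-to-end pipeline.

Model formulas follow the four-clause notation used throughout the
package's outputs:

    D~WildPrey; lambda0~Topo+Cameras; sigma~1; noneuc~Altitude

where ``~1`` is intercept-only, terms are joined with ``+``, a quadratic
term is written ``x^2``, and the optional ``noneuc`` clause names the
conductance covariate (omit it for Euclidean distance).  Unknown covariate
names are flagged when a model meets its data (validation), not at parse
time.
"""

from __future__ import annotations

import configparser
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import captures, double_observer, geomask, model_select, scr_core

logger = logging.getLogger(__name__)

__all__ = ["parse_formula", "RunConfig", "run_pipeline", "PipelineError"]

_CLAUSE_RE = re.compile(r"^(D|lambda0|sigma|noneuc)\s*~\s*(.+)$")
_TERM_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_ ]*(\^2)?$")


def parse_formula(text: str) -> scr_core.ScrModelSpec:
    """Parse a four-clause model formula into a model specification.

    Missing D/lambda0/sigma clauses default to intercept-only; ``noneuc``
    is optional and must name a single covariate.  Malformed clauses raise
    ValueError naming the clause position.
    """
    clauses = [c.strip() for c in text.split(";") if c.strip()]
    if not clauses:
        raise ValueError("empty model formula")
    parsed: dict[str, list[str]] = {}
    for pos, clause in enumerate(clauses, start=1):
        m = _CLAUSE_RE.match(clause)
        if not m:
            raise ValueError(f"malformed clause {pos} ({clause!r}): expected 'D~...', "
                             "'lambda0~...', 'sigma~...' or 'noneuc~...'")
        lhs, rhs = m.group(1), m.group(2).strip()
        if lhs in parsed:
            raise ValueError(f"clause {pos}: duplicate {lhs!r} clause")
        terms: list[str] = []
        if rhs != "1":
            for raw in rhs.split("+"):
                term = raw.strip()
                if not _TERM_RE.match(term):
                    raise ValueError(f"clause {pos} ({lhs!r}): bad term {raw.strip()!r}")
                terms.append(term)
        parsed[lhs] = terms
    noneuc_terms = parsed.get("noneuc", [])
    if len(noneuc_terms) > 1:
        raise ValueError("noneuc clause must name exactly one covariate")
    if any(t.endswith("^2") for t in noneuc_terms):
        raise ValueError("noneuc covariate cannot be a squared term")
    return scr_core.ScrModelSpec(
        density=parsed.get("D", []),
        lambda0=parsed.get("lambda0", []),
        sigma=parsed.get("sigma", []),
        noneuc=noneuc_terms[0] if noneuc_terms else None,
    )


@dataclass
class RunConfig:
    """Paths and parameters for one full analysis run."""

    detectors_path: str
    events_path: str
    raster_paths: dict[str, str]
    buffer_m: float
    spacing_m: float
    models: list[str]
    out_dir: str
    exclusion: str | None = None
    window_hours: float = 4.0
    session_days: float = 80.0
    average_rule: str = "delta"     # or "top"
    average_k: int = 5
    average_cutoff: float = 5.0
    records_path: str | None = None
    block_areas_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.buffer_m <= 0 or self.spacing_m <= 0:
            raise ValueError("buffer and spacing must be positive")
        for f in self.models:
            parse_formula(f)  # fail fast on grammar errors

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.optionxform = str  # raster/covariate names are case-sensitive
        with open(path) as fh:
            cp.read_file(fh)
        inputs = cp["inputs"]
        mask = cp["mask"]
        rasters = dict(cp["rasters"]) if cp.has_section("rasters") else {}
        models = [v for _, v in sorted(cp["models"].items())]
        avg = cp["average"] if cp.has_section("average") else {}
        out = cp["output"]
        return cls(
            detectors_path=inputs["detectors"],
            events_path=inputs["events"],
            records_path=inputs.get("records"),
            block_areas_path=inputs.get("block_areas"),
            raster_paths=rasters,
            buffer_m=float(mask["buffer_m"]),
            spacing_m=float(mask["spacing_m"]),
            exclusion=mask.get("exclusion") or None,
            window_hours=float(inputs.get("window_hours", 4.0)),
            session_days=float(inputs.get("session_days", 80.0)),
            models=models,
            average_rule=avg.get("rule", "delta") if avg else "delta",
            average_k=int(avg.get("k", 5)) if avg else 5,
            average_cutoff=float(avg.get("cutoff", 5.0)) if avg else 5.0,
            out_dir=out["dir"],
            seed=int(out.get("seed", 0)),
        )


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("pipeline stage: %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run dedup → capture history → mask → candidate fits → AIC table →
    model-averaged surface, writing CSV/JSON/.asc outputs to the output
    directory.  Deterministic given the config; any stage failure raises a
    stage-named :class:`PipelineError` (outputs written so far remain)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    @_stage("read inputs")
    def _read():
        detectors = captures.read_detectors_tsv(config.detectors_path)
        events = captures.read_events_csv(config.events_path)
        rasters = {name: geomask.read_asc(p) for name, p in config.raster_paths.items()}
        return detectors, events, rasters

    detectors, events, rasters = _read()

    @_stage("independent encounters")
    def _dedup():
        enc = captures.deduplicate_events(events, window_hours=config.window_hours)
        logger.info("kept %d of %d events as independent encounters", len(enc), len(events))
        return enc

    encounters = _dedup()

    @_stage("capture history")
    def _history():
        return captures.build_capture_history(encounters, detectors, config.session_days)

    history = _history()

    @_stage("habitat mask")
    def _mask():
        m = geomask.build_mask(detectors, config.buffer_m, config.spacing_m,
                               exclusion=config.exclusion, rasters=rasters)
        logger.info("mask: %d pixels, %.1f km²", m.n_pixels, m.total_area)
        m.to_csv(out_dir / "mask.csv")
        return m

    mask = _mask()

    @_stage("model fits")
    def _fits():
        fits = []
        for formula in config.models:
            spec = parse_formula(formula)
            f = scr_core.fit(spec, history, mask, detectors)
            f.to_json(out_dir / f"fit_{len(fits):02d}.json")
            fits.append(f)
        return fits

    fits = _fits()

    @_stage("AIC table")
    def _aic():
        table = model_select.aic_table(fits)
        table.to_csv(out_dir / "aic_table.csv")
        return table

    table = _aic()

    @_stage("model-averaged density surface")
    def _avg():
        surface = model_select.model_average_density(
            fits, rule=config.average_rule, k=config.average_k, cutoff=config.average_cutoff)
        surface.to_csv(out_dir / "density_surface.csv")
        surface.to_asc(out_dir / "density_surface.asc")
        return surface

    surface = _avg()

    best = max(fits, key=lambda f: -f.aic)
    best_surface = scr_core.derived_density(best)
    bundle.update(history=history, mask=mask, fits=fits, aic_table=table,
                  averaged_surface=surface, best_fit=best, best_surface=best_surface)

    if config.records_path and config.block_areas_path:
        @_stage("double-observer survey")
        def _dobs():
            records = double_observer.read_records_csv(config.records_path)
            areas = double_observer.read_block_areas_csv(config.block_areas_path)
            est = double_observer.estimate(records)
            dens = double_observer.block_density(records, areas)
            dens.to_csv(out_dir / "block_density.csv", index=False)
            with open(out_dir / "double_observer.json", "w") as fh:
                json.dump(est.table_row(), fh, indent=2)
            return est, dens

        bundle["double_observer"], bundle["block_density"] = _dobs()

    summary = {
        "n_individuals": history.n_individuals,
        "total_encounters": history.total_encounters,
        "mask_pixels": mask.n_pixels,
        "mask_area_km2": mask.total_area,
        "best_model": best.spec.label,
        "best_N_hat": best_surface.n_hat,
        "best_N_ci": list(best_surface.ci),
        "best_mean_density_per_100km2": best_surface.mean_density_per_100km2,
        "averaged_N_hat": surface.n_hat,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    bundle["summary"] = summary
    return bundle
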