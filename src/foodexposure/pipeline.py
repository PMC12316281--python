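"""End-to-end orchestration: generate → delineate → indicators → rake →
screen → model → compare, with a JSON run manifest.

Every stage writes plain-text artifacts (GeoJSON/CSV) into the output
directory; the manifest records the seed, a parameter hash and the SHA-256 of
every output so a rerun with the same config and seed is bit-identical.  A
stage failure removes partial outputs and raises
:class:`~foodexposure.errors.PipelineStageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from . import io as fio
from .errors import (
    ConvergenceError,
    PipelineStageError,
    SeparationError,
    SeparationWarning,
)
from .exposure import (
    ACTIVITY_SPACE,
    HOME_BUFFER,
    BufferParams,
    area_km2,
    home_buffer,
    household_activity_space,
)
from .indicators import code_profiles, profile_area, profiles_to_frame
from .models import (
    COVARIATES,
    OUTCOME_ORDERS,
    ExposureModel,
    compare_measures,
    fit_linear_area,
    screen_covariates,
)
from .reporting import plot_effects, summarize_sample
from .synthetic import (
    CityConfig,
    generate_households,
    generate_network,
    generate_outlets,
    true_margins,
)
from .weights import rake

CODED_OUTCOMES = tuple(OUTCOME_ORDERS)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    city: CityConfig = field(default_factory=CityConfig)
    buffer_params: BufferParams = field(default_factory=BufferParams)
    screening_alpha: float = 0.2
    significance_alpha: float = 0.05
    seed: int = 0
    out_dir: str = "runs/out"
    make_plots: bool = False

    def __post_init__(self):
        for a in (self.screening_alpha, self.significance_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")

    def parameter_hash(self) -> str:
        """Hash of every parameter that can influence the run's outputs.

        The output directory is a run location, not a parameter, and is
        excluded so reruns elsewhere compare equal.
        """
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    city = dataclasses.replace(config.city, seed=config.seed)
    written: list[Path] = []
    stage = "generate"
    try:
        network = generate_network(city)
        outlets = generate_outlets(city, network)
        households = generate_households(city, network)
        margins = true_margins(city)
        network.to_geojson(out / "network.geojson")
        fio.write_outlets_geojson(outlets, out / "outlets.geojson")
        fio.write_households_csv(households, out / "households.csv")
        fio.write_margins_csv(margins, out / "margins.csv")
        written += [
            out / n
            for n in (
                "network.geojson",
                "outlets.geojson",
                "households.csv",
                "margins.csv",
            )
        ]

        stage = "delineate"
        areas = []
        for h in households:
            areas.append(home_buffer(h, network, config.buffer_params))
            areas.append(
                household_activity_space(h, network, config.buffer_params)
            )
        fio.write_areas_geojson(areas, out / "areas.geojson")
        written.append(out / "areas.geojson")

        stage = "indicators"
        tree = STRtree([Point(o.location) for o in outlets]) if outlets else None
        profiles = [
            profile_area(a.household_id, a, outlets, tree) for a in areas
        ]
        raw = profiles_to_frame(profiles)
        coded = code_profiles(raw)
        hh_frame = fio.households_to_frame(households)
        area_sizes = pd.DataFrame(
            {
                "household_id": [a.household_id for a in areas],
                "area_kind": [a.kind for a in areas],
                "area_km2": [area_km2(a) for a in areas],
            }
        )
        coded = coded.merge(area_sizes, on=["household_id", "area_kind"])
        coded = coded.merge(hh_frame, on="household_id")
        coded.to_csv(out / "profiles.csv", index=False)
        written.append(out / "profiles.csv")

        stage = "rake"
        wv = rake(hh_frame, margins, tol=1e-6, max_iter=200)
        wframe = wv.weights.rename_axis("household_id").reset_index()
        wframe.to_csv(out / "weights.csv", index=False)
        written.append(out / "weights.csv")
        summary = summarize_sample(hh_frame, wv)
        summary.to_csv(out / "sample_summary.csv", index=False)
        written.append(out / "sample_summary.csv")

        stage = "screen"
        screens = []
        per_outcome_covs: dict[tuple[str, str], list[str]] = {}
        for kind in (HOME_BUFFER, ACTIVITY_SPACE):
            sub = coded[coded["area_kind"] == kind].reset_index(drop=True)
            w = wv.reindex(sub["household_id"])
            for outcome in CODED_OUTCOMES:
                results = screen_covariates(
                    sub, outcome, [c for c in COVARIATES if c in sub.columns],
                    w, config.screening_alpha,
                )
                kept = [r.covariate for r in results if r.keep]
                per_outcome_covs[(kind, outcome)] = kept
                for r in results:
                    screens.append(
                        {
                            "area_kind": kind,
                            "outcome": outcome,
                            "covariate": r.covariate,
                            "p_value": r.p_value,
                            "keep": r.keep,
                            "flag": r.flag,
                        }
                    )
        pd.DataFrame(screens).to_csv(out / "screening.csv", index=False)
        written.append(out / "screening.csv")

        stage = "model"
        est_frames = []
        gvif_frames = []
        for kind in (HOME_BUFFER, ACTIVITY_SPACE):
            sub = coded[coded["area_kind"] == kind].reset_index(drop=True)
            w = wv.reindex(sub["household_id"])
            for outcome in CODED_OUTCOMES:
                covs = per_outcome_covs[(kind, outcome)]
                if not covs:
                    continue
                model = ExposureModel(
                    sub, outcome, covs, weights=w, area_kind=kind
                )
                try:
                    res = model.fit()
                except (SeparationError, ConvergenceError) as exc:
                    warnings.warn(
                        f"{outcome}/{kind}: {exc}; penalized refit",
                        SeparationWarning,
                    )
                    res = model.fit(ridge=1e-4)
                est_frames.append(res.estimates)
                g = res.gvif()
                g.insert(0, "outcome", outcome)
                g.insert(1, "area_kind", kind)
                gvif_frames.append(g)
            lin = fit_linear_area(
                sub, "area_km2", [c for c in COVARIATES if c in sub.columns],
                weights=w, area_kind=kind,
            )
            est_frames.append(lin.estimates)
        estimates = pd.concat(est_frames, ignore_index=True)
        estimates.to_csv(out / "estimates.csv", index=False)
        written.append(out / "estimates.csv")
        if gvif_frames:
            pd.concat(gvif_frames, ignore_index=True).to_csv(
                out / "gvif.csv", index=False
            )
            written.append(out / "gvif.csv")

        stage = "compare"
        home_est = estimates[estimates["area_kind"] == HOME_BUFFER]
        act_est = estimates[estimates["area_kind"] == ACTIVITY_SPACE]
        comparison = compare_measures(
            home_est, act_est, config.significance_alpha
        )
        comparison.to_csv(out / "comparison.csv", index=False)
        written.append(out / "comparison.csv")

        if config.make_plots:
            stage = "plot"
            for outcome in estimates["outcome"].unique():
                sub = estimates[estimates["outcome"] == outcome]
                plot_effects(
                    sub, out / f"forest_{outcome}.png", title=str(outcome)
                )
    except Exception as exc:
        for p in written:
            if p.exists():
                p.unlink()
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "n_households": city.n_households,
        "n_outlets": len(outlets),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {p.name: _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
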