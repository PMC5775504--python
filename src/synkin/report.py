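"""Group comparisons, end-to-end pipeline orchestration, and summaries."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import confinement, shape_metrics, spot_survival, synthetic, trackcore

__all__ = [
    "GroupComparison",
    "star_code",
    "compare_groups",
    "arrest_coefficient",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def star_code(p: float) -> str:
    """Significance stars: *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Two-group comparison with the test matched to the unit of replication.

    Donor-paired means use a paired t test; independent cell-level values use
    the two-tailed Mann-Whitney U test.
    """

    metric: str
    labels: tuple[str, str]
    values_a: np.ndarray
    values_b: np.ndarray
    test: str  # "paired_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    star: str


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    metric: str = "",
    labels: tuple[str, str] = ("a", "b"),
    method: str = "auto",
) -> GroupComparison:
    """Paired t test (paired=True) or two-tailed Mann-Whitney U test.

    ``method`` is passed to :func:`scipy.stats.mannwhitneyu` ("auto",
    "exact", "asymptotic").  Refuses n < 3 and degenerate paired data with
    zero-variance differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        if np.allclose(a - b, (a - b)[0]):
            raise ValueError("degenerate paired data: zero variance of differences")
        res = stats.ttest_rel(a, b)
        test = "paired_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney_u"
    p = float(res.pvalue)
    return GroupComparison(
        metric=metric,
        labels=labels,
        values_a=a,
        values_b=b,
        test=test,
        statistic=float(res.statistic),
        p_value=p,
        star=star_code(p),
    )


def arrest_coefficient(track: trackcore.Track, speed_threshold: float = 2.0) -> float:
    """Optional extra: fraction of frames with smoothed speed below threshold."""
    return float(np.mean(trackcore.smoothed_speed(track) < speed_threshold))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "grid": {"diameter_um": 10.0, "spacing_um": 30.0, "extent_um": [0.0, 0.0, 90.0, 90.0]},
    "confinement": {
        "windows": list(confinement.DEFAULT_WINDOWS),
        "l_threshold": confinement.DEFAULT_L_THRESHOLD,
        "min_duration": confinement.DEFAULT_MIN_DURATION,
        "spread_threshold": confinement.DEFAULT_SPREAD_THRESHOLD,
    },
    "survival": {"bin_min": 15.0, "horizon_h": 8.0, "n_cells": 100},
    "shape": {
        "n_steps": shape_metrics.DEFAULT_N_STEPS,
        "cell_radius_um": 5.0,
        "pixel_size_um": 0.5,
        "n_mask_cells": 6,
        "n_mask_frames": 60,
    },
}

DEMO_COHORTS: dict = {
    "naive_like": {
        "n_tracks": 12,
        "dwell_synapse": 1000.0,
        "dwell_kinapse": 3000.0,
        "speed_kinapse": 8.0,
        "half_life_h": 3.6,
    },
    "memory_like": {
        "n_tracks": 12,
        "dwell_synapse": 3000.0,
        "dwell_kinapse": 1000.0,
        "speed_kinapse": 5.0,
        "half_life_h": 1.1,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results") -> dict:
    """Run the synthetic demo pipeline end to end.

    Per cohort: simulate two-state tracks and score their positional
    stability index; simulate exponential spot-residence times at the
    planted half-life and fit the survival curve; render mask movies for a
    subset of tracks pinned near a spot and compute sampling efficiency and
    protrusion index.  Cohorts are then compared metric by metric
    (cell-level Mann-Whitney U).  Writes ``psi.csv``, ``survival.csv``,
    ``shape.csv``, ``comparisons.csv``, and ``manifest.json``; returns the
    manifest.  Identical config + seed gives identical outputs.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    cohorts = cfg.get("cohorts") or DEMO_COHORTS
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    grid_cfg = cfg["grid"]
    grid = trackcore.build_spot_grid(
        grid_cfg["diameter_um"], grid_cfg["spacing_um"], tuple(grid_cfg["extent_um"])
    )
    ss = np.random.SeedSequence(cfg["seed"])
    cohort_seeds = {name: s for name, s in zip(sorted(cohorts), ss.spawn(len(cohorts)))}

    psi_rows, surv_rows, shape_rows = [], [], []
    per_cohort: dict[str, dict[str, list[float]]] = {}
    conf_cfg = cfg["confinement"]
    shp = cfg["shape"]

    for name in sorted(cohorts):
        spec = cohorts[name]
        seeds = cohort_seeds[name].generate_state(3)
        logger.info("cohort %s: tracks", name)
        values: dict[str, list[float]] = {"psi_index": [], "sampling_efficiency": [],
                                          "protrusion_index": []}
        tracks = []
        for k in range(int(spec.get("n_tracks", 12))):
            params = synthetic.TwoStateParams(
                speed_kinapse=spec.get("speed_kinapse", 8.0),
                dwell_synapse=spec.get("dwell_synapse", 600.0),
                dwell_kinapse=spec.get("dwell_kinapse", 600.0),
                n_frames=int(spec.get("n_frames", 240)),
                seed=int(seeds[0]) + k,
            )
            track, _ = synthetic.simulate_two_state_track(params)
            tracks.append(track)
            res = confinement.analyze_track(
                track,
                windows=conf_cfg["windows"],
                l_threshold=conf_cfg["l_threshold"],
                min_duration=conf_cfg["min_duration"],
                spread_threshold=conf_cfg["spread_threshold"],
            )
            total_confined_min = sum(p.t for p in res.periods) * track.frame_interval / 60.0
            psi_rows.append(
                {
                    "cohort": name,
                    "cell_id": track.cell_id,
                    "psi_index": res.psi_index,
                    "n_stable_periods": len(res.stable_periods),
                    "total_confined_min": total_confined_min,
                }
            )
            values["psi_index"].append(res.psi_index)

        logger.info("cohort %s: survival", name)
        records = synthetic.simulate_residence_times(
            half_life_h=spec.get("half_life_h", 2.0),
            n_cells=int(cfg["survival"]["n_cells"]),
            horizon_h=cfg["survival"]["horizon_h"],
            seed=int(seeds[1]),
        )
        fit = spot_survival.fit_survival(
            records, bin_h=cfg["survival"]["bin_min"] / 60.0, horizon_h=cfg["survival"]["horizon_h"]
        )
        surv_rows.append(
            {
                "cohort": name,
                "half_life_h": fit.half_life,
                "slope_per_h": fit.slope,
                "r_squared": fit.r_squared,
                "n_records": fit.n_records,
                "planted_half_life_h": spec.get("half_life_h", 2.0),
            }
        )

        logger.info("cohort %s: masks", name)
        spot_id = grid.n_spots // 2
        pad = 3 * shp["cell_radius_um"]
        cx, cy = grid.centers[spot_id]
        extent = (cx - pad, cy - pad, cx + pad, cy + pad)
        for k in range(int(shp["n_mask_cells"])):
            params = synthetic.TwoStateParams(
                speed_kinapse=spec.get("speed_kinapse", 8.0),
                dwell_synapse=spec.get("dwell_synapse", 600.0),
                dwell_kinapse=spec.get("dwell_kinapse", 600.0),
                n_frames=int(shp["n_mask_frames"]),
                seed=int(seeds[2]) + k,
            )
            track, _ = synthetic.simulate_two_state_track(params)
            # pin the wandering track near the spot so overlap is informative
            centered = track.positions - track.positions.mean(axis=0) + grid.centers[spot_id]
            radius_cap = min(pad - shp["cell_radius_um"] - shp["pixel_size_um"],
                             grid.radius + 1.0)
            off = centered - grid.centers[spot_id]
            r = np.linalg.norm(off, axis=1)
            scale = np.where(r > radius_cap, radius_cap / np.maximum(r, 1e-12), 1.0)
            pinned = grid.centers[spot_id] + off * scale[:, None]
            track = trackcore.Track(
                cell_id=f"{name}-mask-{k}",
                frames=track.frames,
                times=track.times,
                positions=pinned,
                frame_interval=track.frame_interval,
            )
            masks = synthetic.render_mask_movie(
                track, shp["cell_radius_um"], shp["pixel_size_um"], extent
            )
            se = shape_metrics.mean_sampling_efficiency(masks, n_steps=shp["n_steps"])
            om = shape_metrics.protrusion_index(masks, grid, spot_id)
            pi = float(om.protrusion_index.mean())
            shape_rows.append(
                {
                    "cohort": name,
                    "cell_id": track.cell_id,
                    "mean_sampling_efficiency": se,
                    "mean_protrusion_index": pi,
                }
            )
            values["sampling_efficiency"].append(se)
            values["protrusion_index"].append(pi)
        per_cohort[name] = values

    psi_df = pd.DataFrame(psi_rows)
    surv_df = pd.DataFrame(surv_rows)
    shape_df = pd.DataFrame(shape_rows)
    psi_df.to_csv(out / "psi.csv", index=False)
    surv_df.to_csv(out / "survival.csv", index=False)
    shape_df.to_csv(out / "shape.csv", index=False)

    comp_rows = []
    names = sorted(cohorts)
    if len(names) == 2:
        a, b = names
        for metric in ("psi_index", "sampling_efficiency", "protrusion_index"):
            try:
                cmp_res = compare_groups(
                    per_cohort[a][metric], per_cohort[b][metric],
                    paired=False, metric=metric, labels=(a, b),
                )
            except ValueError as err:
                logger.warning("comparison %s skipped: %s", metric, err)
                continue
            comp_rows.append(
                {
                    "metric": metric,
                    "group_a": a,
                    "group_b": b,
                    "mean_a": float(np.mean(per_cohort[a][metric])),
                    "mean_b": float(np.mean(per_cohort[b][metric])),
                    "test": cmp_res.test,
                    "statistic": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    "star": cmp_res.star,
                }
            )
    pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)

    manifest = {
        "config": cfg,
        "cohorts": {n: dict(cohorts[n]) for n in names},
        "outputs": ["psi.csv", "survival.csv", "shape.csv", "comparisons.csv"],
        "half_life_h": {r["cohort"]: r["half_life_h"] for r in surv_rows},
        "mean_psi_index": {n: float(np.mean(per_cohort[n]["psi_index"])) for n in names},
        "mean_sampling_efficiency": {
            n: float(np.mean(per_cohort[n]["sampling_efficiency"])) for n in names
        },
        "mean_protrusion_index": {
            n: float(np.mean(per_cohort[n]["protrusion_index"])) for n in names
        },
        "elapsed_s": time.time() - t0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline done in %.1f s", manifest["elapsed_s"])
    return manifest
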