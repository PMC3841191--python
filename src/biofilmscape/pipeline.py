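"""End-to-end orchestration: simulate -> features -> ordination -> dynamics.

The pipeline ties the stages into the full landscape analysis: morphology
images -> SGLDM feature table -> scaled PCA -> PC1 series; electropherograms
-> alignment/normalization -> diversity, peak binning -> quantitative
Jaccard -> PCoA and moving-window Raup-Crick series; then windowed
morphology-community regressions, recovery metrics and the dominant
oscillation period.  All intermediate tables are CSV; a config snapshot and
the master seed are written next to the outputs so every run is
reproducible.  Stochastic stages draw per-stage seeds derived from the
single master seed by stable hashing of the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, fingerprints, ordination, synthetic, texture

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "simulate_experiment", "run_pipeline"]

GRID_LO, GRID_HI = 50.0, 500.0  # common aligned coordinate (ladder span)

#: Offset menu for simulated 512x384 images: 15 distances like the full-frame
#: menu, but capped so the largest diagonal offset fits the smaller image.
SIM_OFFSETS_PX = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 200, 250, 300, 350)


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    data_dir: str = "data"
    out_dir: str = "results"
    seed: int = 0
    pixel_size_um: float = texture.DEFAULT_PIXEL_SIZE_UM
    offsets_px: tuple[int, ...] = SIM_OFFSETS_PX
    angles_deg: tuple[int, ...] = texture.ANGLES_DEG
    n_grid: int = 1000
    baseline_window: int = 101
    peak_min_height_frac: float = 0.05
    peak_min_separation: float = 6.0  # size units
    bin_tolerance: float = 3.0  # size units
    rc_reps: int = fingerprints.DEFAULT_N_REPS
    rc_weighting: str = "occupancy"
    recovery_epsilon: float = 0.2
    # simulation block (used by `simulate_experiment`)
    reactors: dict = field(default_factory=lambda: {
        "control": {"frequency": "none"},
        "weekly": {"frequency": "weekly", "start": 21.0, "n_pulses": 5},
        "daily": {"frequency": "daily", "start": 21.0, "n_pulses": 15},
    })
    n_days: float = 56.0
    tau: float = 2.0
    rho: float = 0.6
    image_dims: tuple[int, int] = (512, 384)
    n_locations: int = 2
    render_images: bool = True

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if self.bin_tolerance <= 0 or self.rc_reps < 1:
            raise ValueError("invalid binning tolerance or RC replicate count")
        if self.rc_weighting not in ("occupancy", "uniform"):
            raise ValueError("rc_weighting must be 'occupancy' or 'uniform'")
        max_off = max(self.offsets_px)
        if 45 in self.angles_deg and max_off >= min(self.image_dims):
            raise ValueError(
                f"offset {max_off}px exceeds simulated image extent {self.image_dims}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("offsets_px", "angles_deg", "image_dims"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def snapshot(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _schedule_for(cfg: PipelineConfig, sched_cfg: dict) -> dynamics.DisturbanceSchedule:
    freq = sched_cfg.get("frequency", "none")
    if freq == "weekly":
        return synthetic.weekly_schedule(sched_cfg.get("start", 21.0),
                                         sched_cfg.get("n_pulses", 5))
    if freq == "daily":
        return synthetic.daily_schedule(sched_cfg.get("start", 21.0),
                                        sched_cfg.get("n_pulses", 15))
    return dynamics.DisturbanceSchedule(pulse_days=np.array([]),
                                        window=(0.0, cfg.n_days),
                                        frequency="none")


def _phase(day: float, sched: dynamics.DisturbanceSchedule) -> str:
    if sched.frequency == "none" or sched.pulse_days.size == 0:
        return "pre"
    if day < sched.pulse_days[0]:
        return "pre"
    if day <= sched.window[1]:
        return "treatment"
    return "post"


def simulate_experiment(cfg: PipelineConfig) -> Path:
    """Write a complete synthetic experiment into ``cfg.data_dir``.

    Layout: ``samples.csv`` (sample metadata), ``manifest.csv`` (image files,
    one row per location x illumination), ``profiles/<sample>.csv``
    (scan position, intensity, standard channel) and ``truth.json`` (latent
    states, schedules, seed).
    """
    import tifffile

    cfg.validate()
    data = Path(cfg.data_dir)
    (data / "profiles").mkdir(parents=True, exist_ok=True)
    (data / "images").mkdir(parents=True, exist_ok=True)

    sample_rows, manifest_rows, truth = [], [], {"seed": cfg.seed, "reactors": {}}
    for reactor, sched_cfg in cfg.reactors.items():
        sched = _schedule_for(cfg, sched_cfg)
        days = np.arange(0.0, cfg.n_days + 0.5)
        days = days[days <= max(cfg.n_days, sched.window[1])]
        cp = synthetic.CommunityParams(seed=synthetic.derive_seed(cfg.seed, "cp", reactor))
        sp = synthetic.SimSeriesParams(schedule=sched, rho=cfg.rho, tau=cfg.tau,
                                       sampling_days=days,
                                       seed=synthetic.derive_seed(cfg.seed, "sim", reactor))
        lp = synthetic.LandscapeParams(dims=cfg.image_dims,
                                       pixel_size_um=cfg.pixel_size_um)
        samples = synthetic.simulate_disturbance_series(
            sp, cp, lp, render_images=cfg.render_images,
            n_locations=cfg.n_locations, reactor=reactor)
        truth["reactors"][reactor] = {
            "pulse_days": sched.pulse_days.tolist(),
            "window": list(sched.window),
            "frequency": sched.frequency,
            "tau": cfg.tau, "rho": cfg.rho,
            "latent": [{"day": s.day,
                        "dominant_fraction": s.true_dominant_fraction,
                        "complexity": s.true_complexity} for s in samples],
        }
        for s in samples:
            sid = s.raw_profile.sample_id
            sample_rows.append({"sample_id": sid, "day": s.day, "reactor": reactor,
                                "phase": _phase(s.day, sched)})
            prof = pd.DataFrame({
                "position": np.arange(s.raw_profile.intensity.size),
                "intensity": s.raw_profile.intensity,
                "standard": s.raw_profile.standard_intensity})
            prof.to_csv(data / "profiles" / f"{sid}.csv", index=False)
            if s.images is not None:
                for loc, pair in s.images.items():
                    for il, img in pair.items():
                        rel = f"images/{sid}_loc{loc}_{il}.tif"
                        tifffile.imwrite(data / rel, img.pixels)
                        manifest_rows.append({"sample_id": sid, "day": s.day,
                                              "reactor": reactor, "location": loc,
                                              "illumination": il, "path": rel})
    pd.DataFrame(sample_rows).to_csv(data / "samples.csv", index=False)
    pd.DataFrame(manifest_rows).to_csv(data / "manifest.csv", index=False)
    with open(data / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    logger.info("simulated %d samples into %s", len(sample_rows), data)
    return data


# ---------------------------------------------------------------------------
# analysis stages


def features_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Image manifest -> per-sample 900-variable morphology feature table."""
    data = Path(cfg.data_dir)
    manifest = pd.read_csv(data / "manifest.csv")
    menu = texture.default_offset_menu(cfg.pixel_size_um, cfg.offsets_px,
                                       cfg.angles_deg)
    rows, ids, header = [], [], None
    for sid, grp in manifest.groupby("sample_id", sort=False):
        vectors = []
        for loc, lgrp in grp.groupby("location"):
            imgs = {}
            for _, r in lgrp.iterrows():
                imgs[r["illumination"]] = texture.GrayImage(
                    texture.read_gray_tiff(data / r["path"]), r["illumination"],
                    cfg.pixel_size_um, sid, int(loc))
            if set(imgs) != set(texture.ILLUMINATIONS):
                raise ValueError(
                    f"manifest rows for sample {sid} location {loc} miss an "
                    f"illumination (have {sorted(imgs)})")
            vectors.append(texture.extract_features(imgs, menu=menu))
        agg = texture.aggregate_locations(vectors)
        rows.append(agg.values)
        ids.append(sid)
        if header is None:
            header = agg.key_strings()
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=header)


def fingerprints_stage(cfg: PipelineConfig, samples: pd.DataFrame):
    """Profiles -> aligned profiles, diversity table, community table."""
    data = Path(cfg.data_dir)
    grid = np.linspace(GRID_LO, GRID_HI, cfg.n_grid)
    diversity_rows, peak_tables = [], []
    for _, r in samples.iterrows():
        prof = pd.read_csv(data / "profiles" / f"{r.sample_id}.csv")
        raw = fingerprints.RawProfile(prof["intensity"].to_numpy(),
                                      prof["standard"].to_numpy(),
                                      sample_id=r.sample_id, day=r.day,
                                      reactor=r.reactor)
        std = synthetic.detect_standard(raw, synthetic.LADDER_SIZES)
        fp = fingerprints.process_profile(raw, std, grid=grid,
                                          baseline_window=cfg.baseline_window)
        div = fingerprints.simpson_diversity(fp)
        diversity_rows.append({"sample_id": r.sample_id, "day": r.day,
                               "reactor": r.reactor, "phase": r.phase,
                               "neg_log_simpson": div.d, "lambda": div.lam})
        peak_tables.append(fingerprints.detect_peaks(
            fp, cfg.peak_min_height_frac, cfg.peak_min_separation))
    diversity = pd.DataFrame(diversity_rows)
    community = fingerprints.bin_peaks(peak_tables, cfg.bin_tolerance)
    return diversity, community


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write artifacts into ``cfg.out_dir``.

    Returns the result bundle (tables and scalar summaries) also written to
    disk.  Deterministic given the config seed.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.snapshot(out / "config.yaml")
    data = Path(cfg.data_dir)
    samples = pd.read_csv(data / "samples.csv")
    bundle: dict = {"seed": cfg.seed}

    # morphology: features -> scaled PCA -> oriented PC1 series
    features = features_stage(cfg)
    features.to_csv(out / "features.csv")
    pca = ordination.pca_scaled(features)
    ref = next((c for c in features.columns
                if c.startswith("transmitted|") and c.endswith("|f9")), None)
    if ref is not None and ref in pca.loadings.index:
        pca = ordination.orient_axis(pca, "PC1", ref, -1)
    pca.scores.to_csv(out / "pca_scores.csv")
    pca.loadings.to_csv(out / "pca_loadings.csv")
    bundle["pca"] = pca
    bundle["pc1_variance_fraction"] = float(pca.variance_fraction[0])

    # community: profiles -> diversity + binned table -> PCoA + RC series
    diversity, community = fingerprints_stage(cfg, samples)
    diversity.to_csv(out / "diversity.csv", index=False)
    community.abundance.to_csv(out / "community.csv")
    dm = ordination.quantitative_jaccard(community)
    pcoa_res = ordination.pcoa(dm)
    top = diversity.loc[diversity["neg_log_simpson"].idxmax(), "sample_id"]
    if top in pcoa_res.scores.index:
        pcoa_res = ordination.orient_axis(pcoa_res, "PCoA1", top, +1)
    pcoa_res.scores.to_csv(out / "pcoa_scores.csv")
    bundle["pcoa"] = pcoa_res
    bundle["pcoa1_variance_fraction"] = float(pcoa_res.variance_fraction[0])
    rc = fingerprints.raup_crick_series(
        community, n_reps=cfg.rc_reps, weighting=cfg.rc_weighting,
        seed=synthetic.derive_seed(cfg.seed, "raup_crick"))
    rc.to_csv(out / "rc.csv", index=False)
    bundle["diversity"] = diversity
    bundle["community"] = community
    bundle["rc"] = rc

    # dynamics: per-reactor series analyses
    regress_rows, period_rows, recovery_rows = [], [], []
    for reactor, sched_cfg in cfg.reactors.items():
        sched = _schedule_for(cfg, sched_cfg)
        rsamp = samples[samples.reactor == reactor].sort_values("day")
        sid_by_day = dict(zip(rsamp.day, rsamp.sample_id))
        days = np.array(sorted(sid_by_day))
        pc1 = dynamics.SampleSeries(
            days, np.array([pca.scores.loc[sid_by_day[d], "PC1"] for d in days]),
            reactor=reactor)
        pcoa1 = dynamics.SampleSeries(
            days, np.array([pcoa_res.scores.loc[sid_by_day[d], "PCoA1"]
                            for d in days]), reactor=reactor)
        dvr = diversity[diversity.reactor == reactor].sort_values("day")
        div_series = dynamics.SampleSeries(dvr.day.to_numpy(),
                                           dvr.neg_log_simpson.to_numpy(),
                                           reactor=reactor)
        window = (sched.pulse_days[0], sched.window[1]) if sched.pulse_days.size \
            else sched.window
        try:
            reg = dynamics.windowed_regression(pc1, pcoa1, window)
            regress_rows.append({"reactor": reactor, **dataclasses.asdict(reg)})
        except ValueError as exc:
            logger.warning("regression skipped for %s: %s", reactor, exc)
        if sched.frequency != "none":
            in_win = (div_series.days >= window[0]) & (div_series.days <= window[1])
            if in_win.sum() >= 4:
                per = dynamics.dominant_period(dynamics.SampleSeries(
                    div_series.days[in_win], div_series.values[in_win],
                    reactor=reactor))
                period_rows.append({"reactor": reactor,
                                    "period_days": per.period_days,
                                    "p_value": per.p_value,
                                    "flagged": per.flagged})
            eps = cfg.recovery_epsilon * np.ptp(div_series.values)
            for pr in dynamics.recovery_metrics(div_series, sched, eps):
                recovery_rows.append({"reactor": reactor,
                                      **dataclasses.asdict(pr)})
    for name, rows in (("regressions", regress_rows), ("periods", period_rows),
                       ("recovery", recovery_rows)):
        df = pd.DataFrame(rows)
        df.to_csv(out / f"{name}.csv", index=False)
        bundle[name] = df
    logger.info("pipeline complete; artifacts in %s", out)
    return bundle
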