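"""Orchestration: simulate -> preprocess -> classify -> summarize, with
replicates, seed management, and structured provenance."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .network import StimulationProtocol, evolve_network
from .params import NetworkParams, preset
from .preprocess import analytic_signal, detect_bursts_movie, spectral_summary
from .waves import classify_frames, extract_episodes, transition_statistics

__all__ = ["PipelineConfig", "run_pipeline", "events_table"]

log = logging.getLogger("betawaves.pipeline")


@dataclass
class PipelineConfig:
    preset: str = "SN"
    overrides: dict = field(default_factory=dict)
    n_replicates: int = 20
    duration_ms: float = 10_000.0
    burn_in_ms: float = 500.0
    dt_ms: float = 0.01
    seed: int = 0
    scaled_down: bool = False      # coarse integration step (dt = 0.05 ms)
    stim_amplitude: float = 0.0    # shared-input units; 0 disables
    stim_period_ms: float = 200.0
    stim_duration_ms: float = 50.0
    band_hz: tuple = (13.0, 30.0)
    out_dir: str | None = None

    def params(self) -> NetworkParams:
        p = preset(self.preset)
        bad = set(self.overrides) - set(p.to_dict())
        if bad:
            raise KeyError(f"unknown parameter overrides: {sorted(bad)}")
        return p.with_overrides(**self.overrides)

    @property
    def effective_dt_ms(self) -> float:
        return 0.05 if self.scaled_down else self.dt_ms


def events_table(events) -> pd.DataFrame:
    cols = ["kind", "onset_ms", "offset_ms", "duration_ms", "speed_cm_s",
            "direction_rad", "freq_hz", "mean_sigma_g", "mean_sigma_p",
            "preceding", "following"]
    return pd.DataFrame([{c: getattr(ev, c) for c in cols} for ev in events],
                        columns=cols)


def _run_replicate(params, cfg, rep_seed):
    protocol = None
    if cfg.stim_amplitude != 0.0:
        protocol = StimulationProtocol.periodic(
            cfg.stim_amplitude, period_ms=cfg.stim_period_ms,
            duration_ms=cfg.stim_duration_ms,
            t_start_ms=cfg.burn_in_ms, t_stop_ms=cfg.burn_in_ms + cfg.duration_ms)
    rec = evolve_network(params, cfg.burn_in_ms + cfg.duration_ms,
                         dt_ms=cfg.effective_dt_ms, seed=rep_seed,
                         protocol=protocol)
    burn = int(round(cfg.burn_in_ms * rec.frame_rate_hz / 1000.0))
    movie_arr = rec.measurement_movie("ie")[..., burn:]
    movie = analytic_signal(movie_arr, rec.frame_rate_hz, band_hz=cfg.band_hz,
                            pitch_um=400.0)
    cls = classify_frames(movie)
    events = extract_episodes(cls)
    bursts = detect_bursts_movie(movie)
    spec = spectral_summary(movie_arr.reshape(-1, movie_arr.shape[-1]),
                            rec.frame_rate_hz, band_hz=cfg.band_hz)
    return {
        "events": events, "events_df": events_table(events),
        "bursts": bursts, "proportions": cls.proportions(),
        "peak_hz": spec["peak_hz_mean"], "seed": rep_seed,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested replicates and aggregate wave and burst statistics.

    Replicate seeds are spawned deterministically from the master seed;
    identical configs produce identical bundles.  A failing replicate is
    logged, excluded, and reported in the bundle.
    """
    params = config.params()
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in np.random.SeedSequence(config.seed).spawn(
                       max(config.n_replicates, 0))]
    replicates, failures = [], []
    for i, rep_seed in enumerate(child_seeds):
        t0 = time.time()
        try:
            out = _run_replicate(params, config, rep_seed)
            replicates.append(out)
            log.info(json.dumps({"stage": "replicate", "index": i,
                                 "seed": rep_seed,
                                 "elapsed_s": round(time.time() - t0, 2)}))
        except Exception as exc:  # partial-failure policy: log and continue
            failures.append({"index": i, "seed": rep_seed, "error": str(exc)})
            log.error(json.dumps({"stage": "replicate", "index": i,
                                  "seed": rep_seed, "error": str(exc)}))
    all_events = [ev for r in replicates for ev in r["events"]]
    events_df = (pd.concat([r["events_df"] for r in replicates],
                           ignore_index=True)
                 if replicates else events_table([]))
    bursts_df = (pd.concat([r["bursts"] for r in replicates],
                           ignore_index=True)
                 if replicates else pd.DataFrame())
    planar = events_df[events_df.kind == "planar"]
    prop_keys = ["planar", "radial", "synchronized", "random"]
    proportions = {
        k: float(np.mean([r["proportions"][k] for r in replicates]))
        if replicates else np.nan for k in prop_keys}
    trans = transition_statistics(all_events) if all_events else {}
    summary = {
        "n_replicates": len(replicates),
        "n_failures": len(failures),
        "duration_s_per_replicate": config.duration_ms / 1000.0,
        "wave_type_frame_proportions": proportions,
        "planar_events_per_replicate": (len(planar) / len(replicates)
                                        if replicates else np.nan),
        "planar_mean_duration_ms": float(planar.duration_ms.mean())
        if len(planar) else np.nan,
        "planar_median_speed_cm_s": float(planar.speed_cm_s.median())
        if len(planar) else np.nan,
        "burst_mean_duration_ms": float(bursts_df.duration_ms.mean())
        if len(bursts_df) else np.nan,
        "peak_hz_mean": float(np.mean([r["peak_hz"] for r in replicates]))
        if replicates else np.nan,
    }
    bundle = {
        "summary": summary,
        "events": events_df,
        "bursts": bursts_df,
        "transitions": trans,
        "failures": failures,
        "provenance": {
            "package_version": __version__,
            "config": asdict(config),
            "params": params.to_dict(),
            "replicate_seeds": child_seeds,
        },
    }
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        events_df.to_csv(out_dir / "events.csv", index=False)
        bursts_df.to_csv(out_dir / "bursts.csv", index=False)
        with open(out_dir / "summary.json", "w") as f:
            json.dump({"summary": summary,
                       "provenance": bundle["provenance"],
                       "failures": failures}, f, indent=2, default=str)
    return bundle
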