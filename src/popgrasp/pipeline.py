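"""End-to-end orchestration: synth -> rates -> cbpt -> dpca -> shared -> decode.

A single YAML/dict config drives all stages; per-stage seeds are derived
from one master seed, every output file is listed in a JSON run manifest
together with the config hash and per-stage wall-clock, and re-running the
same config reproduces the outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cbpt import run_population_cbpt, tuning_fraction
from .decode import decode_factor
from .dpca import DemixedPCA, variance_summary
from .rates import build_rate_tensor, default_alignments, exclude_unstable
from .shared import backproject, select_shared, threshold_tuning
from .synth import SynthConfig, build_ground_truth, simulate_dataset, write_ground_truth

DEFAULT_CONFIG = {
    "seed": 0,
    "synth": {},
    "rates": {"step_ms": 10.0, "kernel_sd_ms": 57.0},
    "cbpt": {"enabled": True, "n_perm": 1000, "alpha": 0.05, "cluster_p": 0.05},
    "dpca": {"n_components": 30, "reg": 1e-6},
    "shared": {"threshold": 0.6},
    "decode": {"enabled": True, "factors": ["hand", "grip", "orientation"],
               "n_iter": 100, "n_shuffles": 100},
}


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _stage_seed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def run_pipeline(config, out_dir: str | Path) -> RunManifest:
    """Run every enabled stage and write tables, tensors and a manifest."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(blob).hexdigest(),
        version=__version__,
        seed=int(cfg["seed"]),
    )

    def _record(stage: str, t0: float, files: list) -> None:
        manifest.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
        manifest.outputs[stage] = [str(f) for f in files]

    # ------------------------------------------------------------- synth
    t0 = time.perf_counter()
    synth_seed = _stage_seed(cfg["seed"], "synth")
    manifest.stage_seeds["synth"] = synth_seed
    scfg = SynthConfig(**{**cfg["synth"], "seed": synth_seed})
    comps = build_ground_truth(scfg)
    files = [out / "ground_truth.json"]
    write_ground_truth(comps, files[0])
    datasets = []
    for d in range(scfg.n_datasets):
        ds = simulate_dataset(scfg, d, comps)
        ds = exclude_unstable(ds)
        ds.write(out, prefix=f"dataset{d}")
        datasets.append(ds)
        files += [out / f"dataset{d}_{s}.csv" for s in ("spikes", "trials", "units")]
    _record("synth", t0, files)

    # ------------------------------------------------------------- rates
    t0 = time.perf_counter()
    aligns = default_alignments(cfg["rates"]["step_ms"])
    sd = cfg["rates"]["kernel_sd_ms"]
    single, avg = [], []
    files = []
    for d, ds in enumerate(datasets):
        st = build_rate_tensor(ds, aligns, "single_trial", sd)
        av = st.average_conditions()
        st.to_hdf5(out / f"rates{d}_single.h5")
        av.to_hdf5(out / f"rates{d}_avg.h5")
        single.append(st)
        avg.append(av)
        files += [out / f"rates{d}_single.h5", out / f"rates{d}_avg.h5"]
    _record("rates", t0, files)
    time_ms = avg[0].time_ms
    segments = avg[0].segments

    # -------------------------------------------------------------- cbpt
    cbpt_results = None
    if cfg["cbpt"]["enabled"]:
        t0 = time.perf_counter()
        cbpt_seed = _stage_seed(cfg["seed"], "cbpt")
        manifest.stage_seeds["cbpt"] = cbpt_seed
        files = []
        cbpt_results = []
        for d, ds in enumerate(datasets):
            res = run_population_cbpt(
                ds, aligns,
                alpha=cfg["cbpt"]["alpha"],
                cluster_p=cfg["cbpt"]["cluster_p"],
                n_perm=cfg["cbpt"]["n_perm"],
                kernel_sd_ms=sd,
                seed=cbpt_seed + d,
            )
            cbpt_results.append(res)
            rows = []
            for u, unit_res in enumerate(res):
                for factor, r in unit_res.items():
                    for c in r.significant_clusters:
                        rows.append(
                            (ds.unit_ids[u], factor, c.start_ms, c.stop_ms,
                             c.mass, c.p_value)
                        )
            pd.DataFrame(
                rows,
                columns=["unit_id", "factor", "start_ms", "stop_ms", "mass", "p"],
            ).to_csv(out / f"cbpt{d}_clusters.csv", index=False)
            frac = pd.DataFrame({"time_ms": time_ms})
            for factor in ("hand", "grip", "orientation"):
                frac[factor] = tuning_fraction(res, factor, len(time_ms))
            frac.to_csv(out / f"cbpt{d}_fraction.csv", index=False)
            files += [out / f"cbpt{d}_clusters.csv", out / f"cbpt{d}_fraction.csv"]
        _record("cbpt", t0, files)

    # -------------------------------------------------------------- dpca
    t0 = time.perf_counter()
    ncomp = cfg["dpca"]["n_components"]
    reg = cfg["dpca"]["reg"]
    per_ds_res = []
    for av_t in avg:
        k = min(ncomp, av_t.values.shape[0])
        per_ds_res.append(DemixedPCA(av_t).fit(n_components=k, reg=reg))
    pooled_X = np.concatenate([a.condition_tensor() for a in avg], axis=0)
    pooled_res = DemixedPCA(pooled_X).fit(
        n_components=min(ncomp, pooled_X.shape[0]), reg=reg
    )
    vs = variance_summary(pooled_res, pooled_X)
    vs.to_csv(out / "dpca_pooled_variance.csv", index=False)
    _record("dpca", t0, [out / "dpca_pooled_variance.csv"])

    # ------------------------------------------------------------ shared
    t0 = time.perf_counter()
    selection = select_shared(
        pooled_res, per_ds_res, threshold=cfg["shared"]["threshold"]
    )
    selection.summary().to_csv(out / "shared_components.csv", index=False)
    files = [out / "shared_components.csv"]
    baseline = time_ms < -50.0  # pre-cue samples of the cue alignment
    baseline[len(avg[0].time_grids[0]):] = False
    for d, av_t in enumerate(avg):
        recon = backproject(selection, d, av_t.as_matrix())
        tuned, thr = threshold_tuning(recon, baseline, "hand")
        pd.DataFrame(
            {"time_ms": time_ms, "hand_tuned_pct": 100.0 * tuned.mean(axis=0)}
        ).to_csv(out / f"shared{d}_hand_tuning.csv", index=False)
        files.append(out / f"shared{d}_hand_tuning.csv")
    _record("shared", t0, files)

    # ------------------------------------------------------------ decode
    if cfg["decode"]["enabled"]:
        t0 = time.perf_counter()
        dec_seed = _stage_seed(cfg["seed"], "decode")
        manifest.stage_seeds["decode"] = dec_seed
        files = []
        rows = []
        for factor in cfg["decode"]["factors"]:
            run = decode_factor(
                single[0], factor,
                n_iter=cfg["decode"]["n_iter"],
                n_shuffles=cfg["decode"]["n_shuffles"],
                reg=reg, seed=dec_seed,
            )
            pd.DataFrame(
                {"time_ms": time_ms,
                 "accuracy": run.mean_accuracy,
                 "null_max": run.null.max(axis=0)}
            ).to_csv(out / f"decode_{factor}.csv", index=False)
            files.append(out / f"decode_{factor}.csv")
            for a, b in run.intervals:
                rows.append((factor, a, b))
        pd.DataFrame(rows, columns=["factor", "start_ms", "stop_ms"]).to_csv(
            out / "decode_intervals.csv", index=False
        )
        files.append(out / "decode_intervals.csv")
        _record("decode", t0, files)

    manifest.to_json(out / "manifest.json")
    return manifest
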