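"""Readers, writers, run manifests, and the end-to-end pipeline.

Tables are plain CSV with documented headers; configuration is YAML or
JSON; every simulated dataset and pipeline run carries a JSON manifest
recording the generating seed, the configuration snapshot, and input file
digests, so any result can be traced to exactly one reproducible run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, information, normalization, population
from .synthetic import GenerativeConfig, gen_experiment, make_neurons
from .task import (
    DomainError,
    SpikeTable,
    SpikeTrain,
    TrialRecord,
    frame_to_trials,
    trials_to_frame,
)

logger = logging.getLogger("wmcap")

SPIKE_COLUMNS = ["neuron_id", "trial_id", "t"]


def write_trials(trials: list[TrialRecord], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trial table; violations report the row number."""
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("loc1", "loc2", "loc3", "loc4", "loc5", "loc6", "outcome"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return frame_to_trials(df)


def write_spikes(spikes: SpikeTable | list[SpikeTrain],
                 path: str | Path) -> None:
    if not isinstance(spikes, SpikeTable):
        spikes = SpikeTable(spikes)
    spikes.to_frame().to_csv(path, index=False)


def read_spikes(path: str | Path,
                known_trials: set[int] | None = None) -> SpikeTable:
    """Read long-format spike data (neuron_id, trial_id, t in seconds).

    Unsorted timestamps are sorted with a warning; spikes referencing a
    trial outside ``known_trials`` (when given) raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"spike table missing columns: {missing}")
    if known_trials is not None:
        bad = set(df["trial_id"].unique()) - set(known_trials)
        if bad:
            raise DomainError(
                f"spikes reference unknown trials: {sorted(bad)[:5]}"
            )
    trains = []
    for (nid, tid), g in df.groupby(["neuron_id", "trial_id"]):
        ts = g["t"].to_numpy(dtype=float)
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            warnings.warn(
                f"unsorted spike timestamps for neuron {nid} trial {tid}; "
                "sorting"
            )
            ts = np.sort(ts)
        trains.append(SpikeTrain(int(nid), int(tid), ts))
    return SpikeTable(trains)


def load_config(path: str | Path) -> GenerativeConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(GenerativeConfig)}
    unknown = set(data) - known
    if unknown:
        raise DomainError(f"unknown config keys: {sorted(unknown)}")
    if "p_correct" in data:
        data["p_correct"] = tuple(data["p_correct"])
    cfg = GenerativeConfig(**data)
    cfg.validate()
    return cfg


def save_config(config: GenerativeConfig, path: str | Path) -> None:
    data = asdict(config)
    data["p_correct"] = list(data["p_correct"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one simulation or analysis run."""

    master_seed: int
    config: dict
    stage_seeds: dict[str, int]
    software_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    created: str = ""

    def write(self, path: str | Path) -> None:
        data = asdict(self)
        data["created"] = data["created"] or datetime.now(
            timezone.utc
        ).isoformat()
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Fixed per-stage seeds derived from the master seed."""
    names = ["simulate", "pev", "classify", "population", "subsample",
             "normalize"]
    states = np.random.SeedSequence(master_seed).generate_state(len(names))
    return {name: int(s % (2 ** 31)) for name, s in zip(names, states)}


def run_pipeline(config: GenerativeConfig, outdir: str | Path,
                 seed: int | None = None, n_neurons: int = 24,
                 n_perm: int = 200, cluster_k: int = 7,
                 strict: bool = False) -> dict:
    """Simulate a dataset and run every analysis stage, writing results.

    Produces trials.csv, spikes.csv, behavior_report.json, pev.csv,
    groups.csv, population_report.json, clusters.csv, dnr.json and
    manifest.json under ``outdir``.  Any stage failure aborts with the
    stage name.  Returns the report bundle as a dict.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    seeds = derive_stage_seeds(seed)
    bundle: dict = {}
    stage = "simulate"
    try:
        neurons = (
            make_neurons(config, n_neurons - n_neurons // 3, "carrying")
            + make_neurons(config, n_neurons // 3, "gaining",
                           first_id=n_neurons - n_neurons // 3)
        )
        trials, spike_trains = gen_experiment(config, neurons,
                                              seed=seeds["simulate"])
        spikes = SpikeTable(spike_trains)
        write_trials(trials, outdir / "trials.csv")
        write_spikes(spikes, outdir / "spikes.csv")

        stage = "behavior"
        perf = behavior.performance_by_load(trials)
        chi2, fried_p = behavior.friedman_load_test(perf.dropna())
        full, reduced, dllr = behavior.fit_load_glm(trials)
        per_k, k_summary = behavior.capacity_by_total_load(trials)
        bundle["behavior"] = {
            "median_by_load": {
                int(c): float(perf[c].median()) for c in perf.columns
            },
            "matrix": behavior.performance_matrix(trials).values.tolist(),
            "friedman": {"chi2": chi2, "p": fried_p},
            "glm_full": asdict(full),
            "glm_reduced": asdict(reduced),
            "abs_delta_llr": dllr,
            "cowan_k_mean": {
                int(n): float(r["mean"]) for n, r in k_summary.iterrows()
            },
        }
        (outdir / "behavior_report.json").write_text(
            json.dumps(bundle["behavior"], indent=2)
        )

        stage = "pev"
        fav = {
            n.neuron_id: information.favorite_location(
                spikes, trials, n.neuron_id
            )
            for n in neurons
        }
        pev_rows = []
        tcs: dict[int, dict[int, information.PevTimecourse]] = {}
        for nid, floc in fav.items():
            tcs[nid] = {}
            for load in (1, 2, 3):
                tc = information.pev_timecourse(
                    spikes, trials, nid, floc, load,
                    n_perm=n_perm, seed=seeds["pev"],
                )
                tcs[nid][load] = tc
                for b in range(len(tc.omega2)):
                    pev_rows.append(
                        (nid, load, tc.edges[b], tc.edges[b + 1],
                         tc.omega2[b], tc.p[b], bool(tc.p[b] < information.ALPHA))
                    )
        pev_df = pd.DataFrame(
            pev_rows,
            columns=["neuron_id", "load", "bin_start", "bin_end",
                     "omega2", "p", "significant"],
        )
        pev_df.to_csv(outdir / "pev.csv", index=False)

        stage = "classify"
        classifications = {
            nid: information.classify_significance(
                nid, fav[nid], tcs[nid], strict=strict
            )
            for nid in fav
        }
        cls_rows = []
        for nid, c in sorted(classifications.items()):
            cls_rows.append({
                "neuron_id": nid,
                "favorite_location": c.favorite_location,
                **{f"sample_load{g}": c.sample_sig.get(g) for g in (1, 2, 3)},
                **{f"delay_load{g}": c.delay_sig.get(g) for g in (1, 2, 3)},
                "sample_group": c.group("sample") or "",
                "delay_group": c.group("delay") or "",
            })
        pd.DataFrame(cls_rows).to_csv(outdir / "groups.csv", index=False)
        n_total = len(classifications)
        k_sample = sum(c.in_sample_population for c in classifications.values())
        k_delay = sum(c.in_delay_population for c in classifications.values())
        bundle["classification"] = {
            "n_neurons": n_total,
            "n_sample_population": k_sample,
            "n_delay_population": k_delay,
            "binomial_p_sample": information.binomial_proportion_test(
                k_sample, n_total
            ),
            "binomial_p_delay": information.binomial_proportion_test(
                k_delay, n_total
            ),
        }

        stage = "population"
        wt = population.window_pev(spikes, trials, fav)
        anovas = {}
        for w in population.WINDOWS:
            try:
                a = population.load_effect_anova(wt, w)
                anovas[w] = {
                    "f": a.f, "df": [a.df_between, a.df_within], "p": a.p,
                    "omega_squared": a.omega_squared,
                    "pairwise_p": {f"{i}v{j}": p
                                   for (i, j), p in a.pairwise_p.items()},
                }
            except DomainError as exc:
                anovas[w] = {"error": str(exc)}
        bundle["population"] = {"window_anovas": anovas}
        (outdir / "population_report.json").write_text(
            json.dumps({"classification": bundle["classification"],
                        "population": bundle["population"]}, indent=2)
        )

        stage = "cluster"
        load1 = {nid: tcs[nid][1] for nid in fav}
        ids = sorted(load1)
        traces = np.array([load1[nid].omega2 for nid in ids])
        try:
            cl = population.cluster_timecourses(traces, ids, k=cluster_k)
            pd.DataFrame({
                "neuron_id": cl.neuron_ids, "cluster": cl.labels
            }).to_csv(outdir / "clusters.csv", index=False)
            pd.DataFrame({
                "k": list(cl.wcss), "wcss": list(cl.wcss.values())
            }).to_csv(outdir / "cluster_elbow.csv", index=False)
            bundle["clusters"] = {"k": cl.k,
                                  "sizes": np.bincount(cl.labels).tolist()}
        except DomainError as exc:
            bundle["clusters"] = {"error": str(exc)}

        stage = "normalize"
        dnr = {}
        for phase in ("sample", "delay"):
            fits = normalization.dnr_analysis(
                spikes, trials, fav, phase,
                n_perm=n_perm, seed=seeds["normalize"],
            )
            dnr[phase] = {
                g: (asdict(f) if f is not None else None)
                for g, f in fits.items()
            }
        bundle["dnr"] = dnr
        (outdir / "dnr.json").write_text(json.dumps(dnr, indent=2))

        manifest = RunManifest(
            master_seed=seed,
            config={**asdict(config), "p_correct": list(config.p_correct)},
            stage_seeds=seeds,
            software_version=__version__,
            input_digests={
                p.name: _sha256(p)
                for p in (outdir / "trials.csv", outdir / "spikes.csv")
            },
        )
        manifest.write(outdir / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
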