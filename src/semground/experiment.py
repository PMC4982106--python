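"""End-to-end experiment driver: build -> train -> probe -> analyse.

A "condition" is a (semantic fraction, mask on/off) pair; every condition
trains fresh, independently seeded network instances, each with its own
word-pattern set, mirroring the multi-instance replication design.
Randomness is organised as named substreams of a single run-level seed
(network build, patterns, schedule, training noise, probe noise), so any
stage of any instance can be reproduced in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .ca import CATable, ca_count_table, category_means
from .config import ExperimentConfig
from .connectivity import Network, build_network
from .io import config_hash, save_ca_table, save_network
from .stats import (FOUR_WAY, THREE_WAY, bonferroni_threshold,
                    planned_comparisons, rm_anova, topography_dataset)
from .stimuli import make_schedule, make_word_patterns
from .training import train

__all__ = ["Condition", "InstanceResult", "instance_streams", "run_instance",
           "run_condition", "run_experiment"]

_STREAMS = ("network", "patterns", "schedule", "training", "probe")


@dataclass(frozen=True)
class Condition:
    semantic_fraction: Fraction = Fraction(1)
    mask_enabled: bool = True

    @property
    def label(self) -> str:
        pct = float(self.semantic_fraction) * 100
        tag = "" if self.mask_enabled else "-nomask"
        return f"sem{pct:g}{tag}"

    @property
    def code(self) -> int:
        return int(float(self.semantic_fraction) * 1000) \
            + (0 if self.mask_enabled else 100_000)


@dataclass
class InstanceResult:
    instance: int
    condition: Condition
    table: CATable
    means: pd.DataFrame     # area x {object, action} mean CA counts
    network: Network | None = None


def instance_streams(seed: int, instance: int, condition: Condition
                     ) -> dict[str, np.random.Generator]:
    """Named, independent RNG substreams for one instance of one condition."""
    root = np.random.SeedSequence([int(seed), int(condition.code),
                                   int(instance)])
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


def network_seed(seed: int, instance: int, condition: Condition) -> int:
    root = np.random.SeedSequence([int(seed), int(condition.code),
                                   int(instance), 7])
    return int(root.generate_state(1)[0] % (2**31))


def run_instance(config: ExperimentConfig, instance: int,
                 condition: Condition | None = None, *,
                 keep_network: bool = False, progress_every=None
                 ) -> InstanceResult:
    """Train and probe one network instance under one condition."""
    condition = condition if condition is not None else Condition(
        Fraction(config.semantic_fractions[0]), config.mask_enabled)
    rngs = instance_streams(config.seed, instance, condition)
    network = build_network(kernel=config.kernel, side=config.side,
                            w_init_max=config.w_init_max, w_max=config.w_max,
                            seed=network_seed(config.seed, instance,
                                              condition))
    patterns = make_word_patterns(config.n_object, config.n_action,
                                  config.cells_per_area, config.side,
                                  rngs["patterns"])
    schedule = make_schedule(patterns, config.reps_per_word,
                             condition.semantic_fraction, rngs["schedule"],
                             mask_enabled=condition.mask_enabled,
                             side=config.side,
                             cells_per_area=config.cells_per_area)
    train(network, schedule, config.dyn, config.plast, rngs["training"],
          steps_per_trial=config.steps_per_trial, drive=config.drive,
          progress_every=progress_every)
    table = ca_count_table(network, patterns, config.dyn, rngs["probe"],
                           params=config.ca, window=config.probe_window,
                           stim_steps=config.probe_stim_steps,
                           drive=config.drive)
    return InstanceResult(instance=instance, condition=condition, table=table,
                          means=category_means(table),
                          network=network if keep_network else None)


def run_condition(config: ExperimentConfig, condition: Condition,
                  n_instances: int | None = None, *, progress=False,
                  keep_networks: bool = False) -> list[InstanceResult]:
    n = n_instances if n_instances is not None else config.n_instances
    results = []
    for i in range(n):
        results.append(run_instance(config, i, condition,
                                    keep_network=keep_networks))
        if progress:
            print(f"[{condition.label}] instance {i + 1}/{n} done",
                  flush=True)
    return results


def condition_stats(results: list[InstanceResult]) -> dict:
    """The full topography analysis for one condition's instance fleet."""
    data = topography_dataset({r.instance: r.means for r in results})
    peri = data[data.ExtraPeri == "peri"]
    extra = data[data.ExtraPeri == "extra"]
    return {
        "anova_all12": {k: vars(v) for k, v in
                        rm_anova(data, FOUR_WAY).items()},
        "anova_perisylvian": {k: vars(v) for k, v in
                              rm_anova(peri, THREE_WAY).items()},
        "anova_extrasylvian": {k: vars(v) for k, v in
                               rm_anova(extra, THREE_WAY).items()},
        "planned_comparisons": planned_comparisons(data).to_dict("records"),
        "bonferroni_12": bonferroni_threshold(0.05, 12),
    }


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Run every (instance x condition), write all artifacts, return out dir.

    A failing instance is logged and skipped; the experiment continues.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    run_hash = config_hash({k: str(v) for k, v in cfg_dict.items()})
    provenance = {"config": {k: str(v) for k, v in cfg_dict.items()},
                  "config_hash": run_hash, "seed": config.seed}
    (out / "run.json").write_text(json.dumps(provenance, indent=1))

    conditions = [Condition(Fraction(f), config.mask_enabled)
                  for f in config.semantic_fractions]
    all_counts, log_lines = [], []
    for cond in conditions:
        results = []
        for i in range(config.n_instances):
            try:
                res = run_instance(config, i, cond, keep_network=True)
            except Exception as err:   # noqa: BLE001 - isolate instances
                log_lines.append(f"FAILED {cond.label} instance {i}: {err}")
                continue
            results.append(res)
            save_network(out / f"network_{cond.label}_i{i}.npz", res.network)
            df = res.table.counts.copy()
            df.insert(0, "network_id", i)
            df.insert(1, "condition", cond.label)
            df["config_hash"] = run_hash
            all_counts.append(df)
            log_lines.append(f"ok {cond.label} instance {i}")
        if len(results) >= 2:
            stats = condition_stats(results)
            stats["config_hash"] = run_hash
            (out / f"stats_{cond.label}.json").write_text(
                json.dumps(stats, indent=1))
    if all_counts:
        pd.concat(all_counts, ignore_index=True).to_csv(
            out / "ca_counts.csv", index=False)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
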