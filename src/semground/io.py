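"""Persistence: portable network containers, pattern JSON, tabular CSV.

Networks are stored as NumPy ``.npz`` archives holding the CSR weight
arrays plus a metadata record with the build configuration and a SHA-256
configuration hash; the hash is re-derived and verified on load so that a
state file can never be silently paired with a different configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .areas import Area, build_area_graph
from .ca import CATable
from .connectivity import KernelParams, Network
from .dynamics import NetworkState
from .stimuli import COMPONENT_AREAS, TrainingSchedule, WordPattern

__all__ = ["config_hash", "save_network", "load_network",
           "patterns_to_json", "patterns_from_json",
           "schedule_to_csv", "save_ca_table", "load_ca_counts"]


def _network_config(network: Network) -> dict:
    k = network.kernel
    return {"side": network.side, "w_max": network.w_max,
            "w_init_max": network.w_init_max, "seed": network.seed,
            "kernel": {"within_extent": k.within_extent,
                       "between_extent": k.between_extent,
                       "inhib_extent": k.inhib_extent,
                       "amplitude": k.amplitude,
                       "between_amplitude": k.between_amplitude,
                       "sigma": k.sigma,
                       "inhib_gain": k.inhib_gain}}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()


def save_network(path, network: Network,
                 state: NetworkState | None = None) -> None:
    cfg = _network_config(network)
    arrays = {
        "indptr": network.weights.indptr,
        "indices": network.weights.indices,
        "data": network.weights.data,
        "meta": np.frombuffer(
            json.dumps({"config": cfg, "hash": config_hash(cfg)}).encode(),
            dtype=np.uint8),
    }
    if state is not None:
        arrays.update(state_V_e=state.V_e, state_V_i=state.V_i,
                      state_omega=state.omega, state_O=state.O,
                      state_G=state.G)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)


def load_network(path) -> tuple[Network, NetworkState | None]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        cfg = meta["config"]
        if config_hash(cfg) != meta["hash"]:
            raise ValueError(f"{path}: configuration hash mismatch - "
                             "file metadata was altered or corrupted")
        n = len(Area) * cfg["side"] ** 2
        weights = sp.csr_matrix(
            (z["data"], z["indices"], z["indptr"]), shape=(n, n))
        network = Network(side=cfg["side"],
                          kernel=KernelParams(**cfg["kernel"]),
                          w_max=cfg["w_max"], w_init_max=cfg["w_init_max"],
                          seed=cfg["seed"], graph=build_area_graph(),
                          weights=weights)
        state = None
        if "state_V_e" in z:
            state = NetworkState(z["state_V_e"].copy(), z["state_V_i"].copy(),
                                 z["state_omega"].copy(), z["state_O"].copy(),
                                 z["state_G"].copy())
    return network, state


def patterns_to_json(patterns: list[WordPattern], path=None) -> str:
    payload = [{"word_id": p.word_id, "category": p.category,
                "components": {a.name: np.asarray(c).tolist()
                               for a, c in p.components.items()}}
               for p in patterns]
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def patterns_from_json(source) -> list[WordPattern]:
    s = str(source)
    text = s if s.lstrip().startswith("[") else Path(source).read_text()
    out = []
    for item in json.loads(text):
        comps = {Area[name]: np.asarray(cells, dtype=np.int64)
                 for name, cells in item["components"].items()}
        if tuple(sorted(comps)) != tuple(sorted(
                COMPONENT_AREAS[item["category"]])):
            raise ValueError(f"word {item['word_id']}: component areas do "
                             f"not match category {item['category']!r}")
        out.append(WordPattern(word_id=int(item["word_id"]),
                               category=item["category"], components=comps))
    return out


def schedule_to_csv(schedule: TrainingSchedule, path) -> None:
    rows = [{"trial_index": i, "word_id": t.word_id,
             "semantic_present": t.semantic_present}
            for i, t in enumerate(schedule.trials)]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_ca_table(path, table: CATable) -> None:
    df = table.counts.copy()
    df["gamma"] = table.gamma
    df["probe_mode"] = table.probe_mode
    df["network_seed"] = table.network_seed
    df.to_csv(path, index=False)


def load_ca_counts(path) -> pd.DataFrame:
    return pd.read_csv(path)
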