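"""Experiment configuration: dataclass bundle with YAML round-trip.

Keys follow a dotted naming scheme (``kernel.sigma``, ``dyn.tau_e``,
``plast.delta_w`` ...) so a flat YAML mapping fully describes a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from fractions import Fraction
from pathlib import Path

import yaml

from .ca import CAParams
from .connectivity import KernelParams
from .dynamics import DynamicsParams
from .plasticity import PlasticityParams

__all__ = ["ExperimentConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a full multi-instance experiment.

    ``reps_per_word`` defaults to the full 3000-presentation protocol;
    ``scaled()`` returns the reduced profile used for desk-scale runs.
    """

    side: int = 25
    cells_per_area: int = 19
    n_object: int = 6
    n_action: int = 6
    w_init_max: float = 0.3
    w_max: float = 1.2
    kernel: KernelParams = field(default_factory=KernelParams)
    dyn: DynamicsParams = field(default_factory=DynamicsParams)
    plast: PlasticityParams = field(default_factory=PlasticityParams)
    ca: CAParams = field(default_factory=CAParams)
    drive: float = 4.0
    steps_per_trial: int = 16
    probe_window: int = 15
    probe_stim_steps: int = 15
    n_instances: int = 13
    reps_per_word: int = 3000
    semantic_fractions: tuple = (1,)
    mask_enabled: bool = True
    seed: int = 0

    def scaled(self, *, n_instances: int = 6,
               reps_per_word: int = 300) -> "ExperimentConfig":
        return replace(self, n_instances=n_instances,
                       reps_per_word=reps_per_word)

    @property
    def n_words(self) -> int:
        return self.n_object + self.n_action

    def to_dict(self) -> dict:
        flat: dict = {}
        for name, obj in (("kernel", self.kernel), ("dyn", self.dyn),
                          ("plast", self.plast), ("ca", self.ca)):
            for f in fields(obj):
                flat[f"{name}.{f.name}"] = getattr(obj, f.name)
        for f in fields(self):
            if f.name in ("kernel", "dyn", "plast", "ca"):
                continue
            v = getattr(self, f.name)
            if f.name == "semantic_fractions":
                v = [str(Fraction(x)) for x in v]
            flat[f.name] = v
        return flat


def _group(flat: dict, prefix: str, cls):
    kw = {k.split(".", 1)[1]: v for k, v in flat.items()
          if k.startswith(prefix + ".")}
    return cls(**kw)


def load_config(source) -> ExperimentConfig:
    """Build a config from a YAML file path, YAML text, or a dict."""
    if isinstance(source, dict):
        flat = dict(source)
    else:
        s = str(source)
        text = Path(source).read_text() if Path(s).suffix in (".yml", ".yaml") \
            else s
        flat = yaml.safe_load(text) or {}
    kernel = _group(flat, "kernel", KernelParams)
    dyn = _group(flat, "dyn", DynamicsParams)
    plast = _group(flat, "plast", PlasticityParams)
    ca = _group(flat, "ca", CAParams)
    top = {k: v for k, v in flat.items() if "." not in k}
    if "semantic_fractions" in top:
        top["semantic_fractions"] = tuple(
            Fraction(str(x)) for x in top["semantic_fractions"])
    try:
        return ExperimentConfig(kernel=kernel, dyn=dyn, plast=plast, ca=ca,
                                **top)
    except TypeError as err:
        raise ValueError(f"invalid configuration key: {err}") from err


def dump_config(config: ExperimentConfig, path=None) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
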