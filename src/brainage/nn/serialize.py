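"""Checkpoint persistence: weights as .npz plus a JSON config sidecar."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


def save_checkpoint(path, model, config=None, extra=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {"extra": extra or {}}
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_checkpoint(path, model):
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        state = {k: z[k] for k in z.files}
    model.load_state_dict(state)
    return model


def load_sidecar(path) -> dict:
    path = Path(path)
    return json.loads(path.with_suffix(".json").read_text())
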