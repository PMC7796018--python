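"""Parameter checkpoints: a portable array container with a JSON header."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .rae_core import RAEParams


def save_checkpoint(path: str | Path, params: RAEParams, meta: dict | None = None) -> None:
    """Write weights plus a JSON metadata header (shapes, config, seed)."""
    header = {
        "n": params.n,
        "n_labels": params.n_labels,
        "decode_activation": params.decode_activation,
        "meta": meta or {},
    }
    arrays = {key: np.asarray(val) for key, val in params.arrays().items()}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[RAEParams, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        params = RAEParams(
            W1=data["W1"],
            b1=data["b1"],
            W2=data["W2"],
            b2=data["b2"],
            Wlabel=data["Wlabel"] if "Wlabel" in data.files else None,
            decode_activation=header["decode_activation"],
        )
    return params, header["meta"]
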