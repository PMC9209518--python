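"""File-format helpers: multi-page TIFF stacks and ground-truth sidecars."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def save_stack(path, stack: np.ndarray) -> None:
    """Write an image stack as a single multi-page TIFF (leading axes paged)."""
    tifffile.imwrite(str(path), np.asarray(stack))


def load_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_truth(path, truth: dict) -> None:
    """Write a ground-truth sidecar JSON next to a generated file."""
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1))


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x
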