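"""Shared helpers: errors, seed derivation, atomic file writes."""
from __future__ import annotations

import hashlib
import logging
import os
import tempfile
from pathlib import Path

import numpy as np

logger = logging.getLogger("vepbench")


class VepbenchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VepbenchError):
    """Invalid configuration value; message names the offending field."""


class DataConsistencyError(VepbenchError):
    """Inputs contradict each other (e.g. carried variant without an effect)."""


class PairingContractError(VepbenchError):
    """Paired bootstrap distributions of unequal length."""


class UndefinedMetricError(VepbenchError):
    """Metric undefined on this input (single-class labels, zero variance...).

    The bootstrap layer catches this to drop an iteration combo-wide.
    """


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-stream generator from a root seed and string labels.

    Each label is hashed (sha256, folded below 2**31) so streams depend only
    on (seed, labels), never on execution order.
    """
    entropy = [int(seed)]
    for lab in labels:
        h = hashlib.sha256(lab.encode()).digest()
        entropy.append(int.from_bytes(h[:8], "big") % (2**31))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to path via a temp file + rename so readers never see partial files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
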