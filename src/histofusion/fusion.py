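"""Multiscale high-level feature extraction and fusion.

Two high-level feature vectors are read off a trained coding network in a
single inference-mode forward pass (dropout off, normalization applied
exactly as in prediction):

* ``cfr`` — the flattened output of the final max-pool stage (4x4x128 = 2048
  values for the full-size network).  Flattening is row-major over
  (height, width, channel) so serialized features are reproducible.
* ``ffr`` — the full-connection layer activations (256 for the full-size
  network), taken before dropout.

The multiscale high-level feature is their row-wise concatenation,
``cfr`` columns first (2048 + 256 = 2304 for the full-size network).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .network import TrainedNetwork, _prepare, forward
from .synthetic import ConfigurationError, DimensionError


@dataclasses.dataclass
class FusedFeatureMatrix:
    values: np.ndarray  # m x (d_cfr + d_ffr)
    d_cfr: int
    d_ffr: int
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.values.shape[1] != self.d_cfr + self.d_ffr:
            raise DimensionError("width must equal d_cfr + d_ffr")

    @property
    def cfr(self) -> np.ndarray:
        return self.values[:, : self.d_cfr]

    @property
    def ffr(self) -> np.ndarray:
        return self.values[:, self.d_cfr :]


def _captured(net: TrainedNetwork, images, key: str) -> np.ndarray:
    X = _prepare(net, images)
    blocks = []
    for start in range(0, len(X), 128):
        capture: dict = {}
        forward(net, X[start : start + 128], capture=capture)
        if key not in capture:
            raise ConfigurationError(f"network has no stage providing {key!r}")
        blocks.append(capture[key])
    return np.vstack([b.reshape(b.shape[0], -1) for b in blocks])


def extract_cfr(net: TrainedNetwork, images) -> np.ndarray:
    """Flattened final max-pool activations, one row per image."""
    return _captured(net, images, "last_pool")


def extract_ffr(net: TrainedNetwork, images) -> np.ndarray:
    """Full-connection activations (inference mode, dropout disabled)."""
    return _captured(net, images, "fc")


def fuse(cfr: np.ndarray, ffr: np.ndarray, labels=None) -> FusedFeatureMatrix:
    """Row-wise concatenation, cfr columns first."""
    cfr = np.atleast_2d(cfr)
    ffr = np.atleast_2d(ffr)
    if ffr.size == 0:
        ffr = ffr.reshape(cfr.shape[0], 0)
    if cfr.shape[0] != ffr.shape[0]:
        raise DimensionError(
            f"row counts differ: cfr {cfr.shape[0]} vs ffr {ffr.shape[0]}"
        )
    return FusedFeatureMatrix(
        values=np.hstack([cfr, ffr]),
        d_cfr=cfr.shape[1],
        d_ffr=ffr.shape[1],
        labels=None if labels is None else np.asarray(labels),
    )


def extract_fused(net: TrainedNetwork, images, labels=None) -> FusedFeatureMatrix:
    """cfr and ffr from one pass each, fused."""
    return fuse(extract_cfr(net, images), extract_ffr(net, images), labels=labels)


def write_features(feats: FusedFeatureMatrix, path) -> None:
    """Tab-separated text with a header naming the two blocks plus labels."""
    cols = [f"cfr_{i + 1:04d}" for i in range(feats.d_cfr)] + [
        f"ffr_{i + 1:04d}" for i in range(feats.d_ffr)
    ]
    df = pd.DataFrame(feats.values, columns=cols)
    if feats.labels is not None:
        df["label"] = feats.labels
    df.to_csv(path, sep="\t", index=False)


def read_features(path) -> FusedFeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    labels = df.pop("label").to_numpy() if "label" in df.columns else None
    d_cfr = sum(c.startswith("cfr_") for c in df.columns)
    d_ffr = sum(c.startswith("ffr_") for c in df.columns)
    return FusedFeatureMatrix(
        values=df.to_numpy(dtype=np.float64), d_cfr=d_cfr, d_ffr=d_ffr, labels=labels
    )
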