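"""Seed-stream derivation and feature standardization helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def substream(master_seed: int, *keys: int) -> np.random.Generator:
    """Independent RNG stream derived from a master seed and integer keys.

    Streams keyed the same way are identical across runs, and adding new
    keys never perturbs existing streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, keys)]))


def spawn_seed(master_seed: int, *keys: int) -> int:
    """A small (< 2**31) integer seed deterministically derived from keys."""
    rng = substream(master_seed, *keys)
    return int(rng.integers(0, 2**31 - 1))


@dataclass
class Standardizer:
    """Column-wise (x - mean) / sd transform with frozen training parameters.

    Zero-variance columns get sd 1 so a constant feature maps to zero
    instead of NaN.
    """

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, values: pd.DataFrame) -> "Standardizer":
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1).replace(0.0, 1.0).fillna(1.0)
        return cls(mean=mean, sd=sd)

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return (values[self.mean.index] - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {
            "columns": list(self.mean.index),
            "mean": [float(v) for v in self.mean],
            "sd": [float(v) for v in self.sd],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        idx = pd.Index(d["columns"])
        return cls(mean=pd.Series(d["mean"], index=idx), sd=pd.Series(d["sd"], index=idx))
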