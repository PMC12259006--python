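"""Shared in-memory containers: feature matrices and equilibrium ensemble samples."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureDescriptor", "FeatureMatrix", "EnsembleSample"]

_ALLOWED_KINDS = {"dihedral_cos", "dihedral_sin", "distance", "synthetic"}


@dataclass(frozen=True)
class FeatureDescriptor:
    """What a feature column measures: its kind, atoms involved and a label."""

    kind: str
    atom_indices: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if self.kind not in _ALLOWED_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class FeatureMatrix:
    """``n_frames x n_features`` real features with per-column descriptors."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.descriptors) != self.values.shape[1]:
            raise ValueError("descriptor count must equal column count")
        for j, d in enumerate(self.descriptors):
            col = self.values[:, j]
            if d.kind in ("dihedral_cos", "dihedral_sin"):
                if np.any(np.abs(col) > 1 + 1e-9):
                    raise ValueError(f"column {j} ({d.label}) outside [-1, 1]")
            elif d.kind == "distance":
                if np.any(col < 0):
                    raise ValueError(f"distance column {j} ({d.label}) negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class EnsembleSample:
    """Equilibrium-weighted (trajectory id, frame index) references.

    All figure-level ensemble statistics are computed over such a sample:
    states are drawn from a Markov model's stationary distribution and frames
    uniformly within each state, so plain frame averages over the sample are
    equilibrium averages.
    """

    entries: np.ndarray  # (n, 2) ints: trajectory id, frame index
    seed: int | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.intp)
        if self.entries.ndim != 2 or self.entries.shape[1] != 2:
            raise ValueError("entries must have shape (n, 2)")
        if self.entries.shape[0] == 0:
            raise ValueError("empty ensemble sample")

    @property
    def n(self) -> int:
        return self.entries.shape[0]
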