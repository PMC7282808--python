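"""Observation container: ordered feature vectors with per-feature kind.

An observation is a D-dimensional feature vector; a session's worth of
sensory evidence is summarized as one vector.  Features are either linear
(real-valued, e.g. enclosure shape on an abstract axis) or circular
(angles in degrees, e.g. cue bearings), and the two kinds are handled by
different likelihood families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._angles import wrap_360

__all__ = ["ObservationSet", "LINEAR", "CIRCULAR"]

LINEAR = "linear"
CIRCULAR = "circular"


@dataclass(frozen=True)
class ObservationSet:
    """T x D table of feature values, rows ordered by presentation time.

    Circular features are stored in degrees, wrapped to [0, 360).
    """

    data: np.ndarray
    feature_kinds: tuple[str, ...] = field(default=())

    def __init__(self, data, feature_kinds=None) -> None:
        arr = np.atleast_2d(np.asarray(data, dtype=float))
        if arr.ndim != 2:
            raise ValueError("observations must form a 2-D (T x D) array")
        if feature_kinds is None:
            feature_kinds = (LINEAR,) * arr.shape[1]
        feature_kinds = tuple(feature_kinds)
        if len(feature_kinds) != arr.shape[1]:
            raise ValueError(
                f"{len(feature_kinds)} feature kinds for {arr.shape[1]} features"
            )
        if any(k not in (LINEAR, CIRCULAR) for k in feature_kinds):
            raise ValueError(f"feature kinds must be '{LINEAR}' or '{CIRCULAR}'")
        arr = arr.copy()
        for d, kind in enumerate(feature_kinds):
            if kind == CIRCULAR:
                arr[:, d] = wrap_360(arr[:, d])
        arr.flags.writeable = False
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "feature_kinds", feature_kinds)

    @classmethod
    def linear(cls, data) -> "ObservationSet":
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        return cls(arr, (LINEAR,) * arr.shape[1])

    @classmethod
    def circular(cls, angles_deg) -> "ObservationSet":
        arr = np.asarray(angles_deg, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        return cls(arr, (CIRCULAR,) * arr.shape[1])

    @classmethod
    def empty(cls, feature_kinds) -> "ObservationSet":
        return cls(np.empty((0, len(feature_kinds))), tuple(feature_kinds))

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def all_linear(self) -> bool:
        return all(k == LINEAR for k in self.feature_kinds)

    @property
    def all_circular(self) -> bool:
        return all(k == CIRCULAR for k in self.feature_kinds)

    def select(self, indices) -> "ObservationSet":
        """Sub-set of rows (e.g. the members of one hidden state)."""
        return ObservationSet(self.data[np.asarray(indices, dtype=int)], self.feature_kinds)

    def head(self, n: int) -> "ObservationSet":
        """The first n rows (training prefix)."""
        return ObservationSet(self.data[:n], self.feature_kinds)

    def __len__(self) -> int:
        return self.n_obs
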