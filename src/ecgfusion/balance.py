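"""SMOTE oversampling of minority classes.

Each minority class is filled to the majority-class count with
synthetic points

    x_new = x_i + u * (x_nn - x_i),   u ~ Uniform(0, 1),

where ``x_nn`` is one of the ``k`` nearest same-class neighbours of a
randomly chosen class member ``x_i`` (Euclidean metric on the raw
segment vectors). Original samples are retained bit-identically and the
majority class is left untouched, so balancing never distorts observed
data — it only adds convex combinations inside each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from sklearn.neighbors import NearestNeighbors

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .segmentation import SegmentSet

__all__ = ["SMOTEConfig", "smote_oversample"]


@dataclass(frozen=True)
class SMOTEConfig:
    """``target_count`` is ``"majority"`` or an explicit per-class count."""

    k_neighbors: int = 5
    target_count: int | str = "majority"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be positive")
        if isinstance(self.target_count, str) and self.target_count != "majority":
            raise ValueError("target_count must be 'majority' or an integer")


def smote_oversample(data: "SegmentSet", cfg: SMOTEConfig | None = None) -> "SegmentSet":
    """Balance ``data`` by SMOTE; returns a new :class:`SegmentSet`.

    Synthetic rows are appended after the originals and flagged in
    ``synthetic``. Raises if any class to be oversampled has at most
    ``k_neighbors`` members (neighbour search would be degenerate).
    """
    from .segmentation import SegmentSet  # local import: avoid cycle

    cfg = cfg or SMOTEConfig()
    counts = data.class_counts()
    target = (
        max(counts.values())
        if cfg.target_count == "majority"
        else int(cfg.target_count)
    )
    rng = np.random.default_rng(cfg.seed)

    new_X, new_y = [], []
    for label in sorted(counts):
        need = target - counts[label]
        if need <= 0:
            continue
        if counts[label] <= cfg.k_neighbors:
            raise ValueError(
                f"class {label!r} has {counts[label]} members, "
                f"need > k_neighbors={cfg.k_neighbors}"
            )
        Xc = data.X[data.y == label]
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xc)
        # drop column 0: each point is its own nearest neighbour
        neighbours = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xc), size=need)
        pick = rng.integers(0, cfg.k_neighbors, size=need)
        u = rng.random(size=need).astype(Xc.dtype)
        anchors = Xc[base]
        mates = Xc[neighbours[base, pick]]
        new_X.append(anchors + u[:, None] * (mates - anchors))
        new_y.append(np.full(need, label, dtype=data.y.dtype))

    if not new_X:
        return SegmentSet(data.X.copy(), data.y.copy(), data.synthetic.copy())
    X = np.concatenate([data.X, *new_X])
    y = np.concatenate([data.y, *new_y])
    synthetic = np.concatenate(
        [data.synthetic, np.ones(len(X) - len(data.X), dtype=bool)]
    )
    return SegmentSet(X, y, synthetic)
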