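"""Brain parcellations: ROI identifiers with functional-network labels.

The analyses in this package operate on a fixed parcellation of R regions of
interest (ROIs) grouped into functional networks.  The study setting is a
215-ROI parcellation over seven networks: medial frontal (MF), frontoparietal
(FP), default mode (DM), subcortical-cerebellum (SC), motor (M), visual (VIS)
and visual association (VA).  The parcellation is an *input* to every
analysis; nothing here touches image space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "make_parcellation",
    "DEFAULT_NETWORK_NAMES",
    "DEFAULT_NETWORK_SIZES",
]

#: Canonical seven-network naming used throughout.
DEFAULT_NETWORK_NAMES: tuple[str, ...] = ("MF", "FP", "DM", "SC", "M", "VIS", "VA")

#: Default block sizes for the 215-ROI setting (SC is deliberately the
#: largest block: the subcortical-cerebellum network dominates the study's
#: discriminative-edge structure).
DEFAULT_NETWORK_SIZES: tuple[int, ...] = (29, 34, 40, 43, 27, 24, 18)


@dataclass(frozen=True)
class Parcellation:
    """ROI ids, one network label per ROI, optional coordinates.

    Invariants: unique ``roi_ids``, exactly one label per ROI, at least
    three ROIs (a correlation matrix needs that many to have a nontrivial
    lower triangle).
    """

    roi_ids: np.ndarray
    network_labels: np.ndarray
    coordinates: np.ndarray | None = None
    network_names: tuple[str, ...] = field(default=DEFAULT_NETWORK_NAMES)

    def __post_init__(self) -> None:
        roi_ids = np.asarray(self.roi_ids)
        labels = np.asarray(self.network_labels)
        object.__setattr__(self, "roi_ids", roi_ids)
        object.__setattr__(self, "network_labels", labels)
        if roi_ids.size != labels.size:
            raise ValueError("roi_ids and network_labels must have equal length")
        if roi_ids.size < 3:
            raise ValueError("a parcellation needs at least 3 ROIs")
        if np.unique(roi_ids).size != roi_ids.size:
            raise ValueError("roi_ids must be unique")
        unknown = set(np.unique(labels)) - set(self.network_names)
        if unknown:
            raise ValueError(f"labels not in network_names: {sorted(unknown)}")

    @property
    def n_rois(self) -> int:
        return int(self.roi_ids.size)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def network_codes(self) -> np.ndarray:
        """Integer network index per ROI, following ``network_names`` order."""
        lookup = {name: k for k, name in enumerate(self.network_names)}
        return np.array([lookup[str(l)] for l in self.network_labels], dtype=np.intp)

    def rois_in(self, network: str) -> np.ndarray:
        """Positional indices (0-based) of ROIs belonging to ``network``."""
        return np.flatnonzero(self.network_labels == network)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"roi_id": self.roi_ids, "network": self.network_labels})
        if self.coordinates is not None:
            out[["x", "y", "z"]] = np.asarray(self.coordinates)
        return out


def make_parcellation(
    n_rois: int,
    network_sizes: tuple[int, ...] | list[int] | None = None,
    network_names: tuple[str, ...] | None = None,
) -> Parcellation:
    """Build a deterministic block parcellation.

    ROIs ``1..n_rois`` are assigned to networks in contiguous blocks, in the
    declared network order.  With the defaults this reproduces the 215-ROI /
    seven-network layout; for other ``n_rois`` the default sizes are scaled
    proportionally (largest-remainder rounding).
    """
    if n_rois < 3:
        raise ValueError("n_rois must be >= 3")
    if network_sizes is None:
        network_sizes = _scaled_sizes(n_rois, DEFAULT_NETWORK_SIZES)
    network_sizes = tuple(int(s) for s in network_sizes)
    if any(s <= 0 for s in network_sizes):
        raise ValueError("network sizes must be positive")
    if sum(network_sizes) != n_rois:
        raise ValueError(
            f"network_sizes sum to {sum(network_sizes)}, expected n_rois={n_rois}"
        )
    if network_names is None:
        network_names = (
            DEFAULT_NETWORK_NAMES
            if len(network_sizes) == len(DEFAULT_NETWORK_NAMES)
            else tuple(f"N{k + 1}" for k in range(len(network_sizes)))
        )
    if len(network_names) != len(network_sizes):
        raise ValueError("one name per network required")
    labels = np.repeat(np.array(network_names, dtype=object), network_sizes)
    return Parcellation(
        roi_ids=np.arange(1, n_rois + 1),
        network_labels=labels,
        network_names=tuple(network_names),
    )


def _scaled_sizes(n_rois: int, template: tuple[int, ...]) -> tuple[int, ...]:
    total = sum(template)
    exact = [n_rois * t / total for t in template]
    base = [int(np.floor(x)) for x in exact]
    # largest-remainder: hand out the leftover ROIs, ties to earlier blocks
    rem = n_rois - sum(base)
    order = np.argsort([-(x - b) for x, b in zip(exact, base)], kind="stable")
    for k in order[:rem]:
        base[k] += 1
    if any(b == 0 for b in base):  # tiny parcellations: collapse to one block
        return (n_rois,)
    return tuple(base)
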