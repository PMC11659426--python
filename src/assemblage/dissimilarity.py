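"""Pairwise dissimilarities between samples and great-circle distances
between sampling locations.

All three community metrics are abundance-aware and computed on
per-sample proportion vectors: Bray-Curtis, Hellinger (Euclidean
distance between square-root-transformed proportion vectors, range
[0, sqrt 2]) and the quantitative Ruzicka form of Jaccard
(1 - sum min / sum max, equal to 2*BC/(1+BC)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .table import CommunityTable, to_proportions

__all__ = [
    "DistanceMatrix",
    "DistanceError",
    "pairwise_dissimilarity",
    "geographic_distances",
    "haversine_km",
    "METRICS",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0
METRICS = ("bray_curtis", "hellinger", "jaccard")


class DistanceError(ValueError):
    """Raised for malformed or mismatched distance matrices."""


@dataclass
class DistanceMatrix:
    """Labeled symmetric nonnegative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise DistanceError("duplicate labels")
        if self.values.shape != (n, n):
            raise DistanceError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        # NaN entries mark pairs with missing data (e.g. |delta env| with
        # an unmeasured variable); they must still be symmetric.
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0,
                           equal_nan=True):
            raise DistanceError("matrix is not symmetric")
        if not (np.diag(self.values) == 0).all():
            raise DistanceError("diagonal must be exactly zero")
        if self.values.size and np.nanmin(self.values) < 0:
            raise DistanceError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries, row by row (the n(n-1)/2 pairs)."""
        idx = np.tril_indices(self.n, k=-1)
        return self.values[idx]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Return a copy aligned to ``labels`` (must be the same set)."""
        if set(labels) != set(self.labels):
            raise DistanceError("label sets differ")
        pos = {lab: i for i, lab in enumerate(self.labels)}
        perm = np.array([pos[lab] for lab in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(perm, perm)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        # guard against asymmetric rounding introduced by text round-trips
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls([str(x) for x in df.index], values)


def pairwise_dissimilarity(t: CommunityTable, metric: str) -> DistanceMatrix:
    """All-pairs dissimilarity between samples of a community table.

    The table is converted to proportions first; the computation runs
    over the union of taxa (absent taxa contribute zeros).
    """
    if metric not in METRICS:
        raise DistanceError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if len(t.sample_ids) < 2:
        raise DistanceError("need at least 2 samples")
    props, _ = to_proportions(t)
    P = props.values  # taxa x samples
    n = P.shape[1]
    D = np.zeros((n, n))
    if metric == "hellinger":
        R = np.sqrt(P)
    for a in range(n):
        for b in range(a):
            p, q = P[:, a], P[:, b]
            if metric == "bray_curtis":
                tot = (p + q).sum()
                d = np.abs(p - q).sum() / tot if tot > 0 else 0.0
            elif metric == "hellinger":
                d = float(np.sqrt(((R[:, a] - R[:, b]) ** 2).sum()))
            else:  # jaccard (Ruzicka)
                mx = np.maximum(p, q).sum()
                d = 1.0 - np.minimum(p, q).sum() / mx if mx > 0 else 0.0
            D[a, b] = D[b, a] = d
    return DistanceMatrix(list(t.sample_ids), D)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def geographic_distances(coords: Mapping[str, tuple[float, float]]) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between sampling locations.

    ``coords`` maps sample ID to (latitude, longitude) in degrees.
    """
    labels = list(coords)
    if len(labels) < 2:
        raise DistanceError("need at least 2 coordinates")
    for sid, (lat, lon) in coords.items():
        if not (-90 <= lat <= 90):
            raise DistanceError(f"latitude out of range for {sid!r}: {lat}")
        if not (-180 <= lon <= 180):
            raise DistanceError(f"longitude out of range for {sid!r}: {lon}")
    n = len(labels)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a):
            la, lo = coords[labels[a]]
            lb, lo2 = coords[labels[b]]
            D[a, b] = D[b, a] = haversine_km(la, lo, lb, lo2)
    return DistanceMatrix(labels, D)
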