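"""Release-site definition by agglomerative clustering.

Within an active zone, fusion-event localizations are partitioned into
release sites with complete-linkage hierarchical clustering, cutting
the dendrogram so that no cluster's maximum intra-cluster pairwise
distance exceeds the clustering diameter (default 50 nm). Complete
linkage is the natural choice here because its merge height *is* the
cluster diameter; single or average linkage cannot bound it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

DEFAULT_CLUSTERING_DIAMETER_NM = 50.0

SITE_TABLE_COLUMNS = [
    "synapse_id",
    "site_id",
    "n_events",
    "centroid_x_nm",
    "centroid_y_nm",
    "diameter_nm",
]


@dataclass
class ReleaseSite:
    """One release site: its member events, centroid and diameter (all nm)."""

    members: np.ndarray  # indices into the event array
    centroid: np.ndarray
    diameter: float


@dataclass
class ReleaseSiteSet:
    """Partition of one synapse's events into release sites."""

    synapse_id: str | int | None
    labels: np.ndarray  # cluster label per event, 0-based
    clusters: list[ReleaseSite]
    clustering_diameter: float

    @property
    def n_sites(self) -> int:
        return len(self.clusters)

    @property
    def n_events(self) -> int:
        return self.labels.size


def cluster_events(
    events: np.ndarray,
    clustering_diameter: float = DEFAULT_CLUSTERING_DIAMETER_NM,
    synapse_id=None,
) -> ReleaseSiteSet:
    """Partition event positions into release sites.

    Complete-linkage agglomerative clustering, cut at the clustering
    diameter (threshold inclusive): every resulting cluster's maximum
    pairwise distance is ≤ ``clustering_diameter``. A single event forms
    a single site of diameter 0. Centroids are unweighted member means.
    """
    pts = np.atleast_2d(np.asarray(events, dtype=float))
    if pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("events must be an (n, 2) array with n >= 1")
    if clustering_diameter <= 0:
        raise ValueError("clustering_diameter must be positive")
    n = pts.shape[0]
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        d = pdist(pts)
        z = linkage(d, method="complete")
        labels = fcluster(z, t=clustering_diameter, criterion="distance") - 1

    clusters = []
    dmat = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    # order sites by first-appearing member for a stable, input-order labelling
    order = []
    seen = set()
    for lab in labels:
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[l] for l in labels], dtype=int)
    for lab in range(len(order)):
        members = np.nonzero(labels == lab)[0]
        sub = dmat[np.ix_(members, members)]
        clusters.append(
            ReleaseSite(
                members=members,
                centroid=pts[members].mean(axis=0),
                diameter=float(sub.max()),
            )
        )
    return ReleaseSiteSet(
        synapse_id=synapse_id,
        labels=labels,
        clusters=clusters,
        clustering_diameter=clustering_diameter,
    )


def site_table(site_set: ReleaseSiteSet) -> pd.DataFrame:
    """Flatten one synapse's sites into the tabular form used on disk."""
    rows = [
        (
            site_set.synapse_id,
            i,
            len(s.members),
            s.centroid[0],
            s.centroid[1],
            s.diameter,
        )
        for i, s in enumerate(site_set.clusters)
    ]
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)


def site_counts(sets: list[ReleaseSiteSet]) -> tuple[pd.DataFrame, dict]:
    """Per-synapse release-site counts with group mean and SEM."""
    if not sets:
        raise ValueError("site_counts requires at least one ReleaseSiteSet")
    per = pd.DataFrame(
        {
            "synapse_id": [s.synapse_id for s in sets],
            "n_sites": [s.n_sites for s in sets],
        }
    )
    counts = per["n_sites"].to_numpy(dtype=float)
    summary = {
        "mean": float(counts.mean()),
        "sem": float(counts.std(ddof=1) / np.sqrt(counts.size)) if counts.size > 1 else 0.0,
        "n_synapses": int(counts.size),
    }
    return per, summary


def events_per_site(sets: list[ReleaseSiteSet]) -> pd.DataFrame:
    """Distribution of events per release site across synapses.

    Returns one row per distinct event count with the number of sites,
    the fraction of all sites, and the cumulative fraction.
    """
    if not sets:
        raise ValueError("events_per_site requires at least one ReleaseSiteSet")
    counts = np.concatenate([[len(c.members) for c in s.clusters] for s in sets]).astype(int)
    values, n_sites = np.unique(counts, return_counts=True)
    frac = n_sites / n_sites.sum()
    return pd.DataFrame(
        {
            "n_events": values,
            "n_sites": n_sites,
            "fraction": frac,
            "cumulative_fraction": np.cumsum(frac),
        }
    )
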