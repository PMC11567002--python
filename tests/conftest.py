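"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (exhaustive
search, O(n^3) clustering, ray-casting containment) kept independent of
the library code paths they validate.
"""

import numpy as np
import pandas as pd
import pytest

from relsite.synth import render_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_complete_linkage(points: np.ndarray, diameter: float) -> set:
    """O(n^3) complete-linkage agglomeration cut at `diameter`.

    Merges the pair of clusters with the smallest complete-linkage
    distance (ties broken by the lexicographically smallest index
    pair) while that distance is <= diameter. Returns the partition as
    a set of frozensets of point indices.
    """
    pts = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(pts))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    np.hypot(*(pts[i] - pts[j]))
                    for i in clusters[a]
                    for j in clusters[b]
                )
                key = (d, tuple(sorted(clusters[a])), tuple(sorted(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        if d > diameter:
            break
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return set(clusters)


def partition_from_labels(labels) -> set:
    """Convert a label array into a set-of-frozensets partition."""
    labels = np.asarray(labels)
    return {frozenset(np.nonzero(labels == lab)[0].tolist()) for lab in np.unique(labels)}


def point_in_polygon(x: float, y: float, vertices: np.ndarray) -> bool:
    """Ray-casting point-in-polygon check (boundary counts as inside)."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-segment check
        d = np.hypot(x2 - x1, y2 - y1)
        if d > 0:
            t = ((x - x1) * (x2 - x1) + (y - y1) * (y2 - y1)) / d**2
            if 0 <= t <= 1:
                px, py = x1 + t * (x2 - x1), y1 + t * (y2 - y1)
                if np.hypot(x - px, y - py) < 1e-9:
                    return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def render_single_spot(
    x_nm,
    y_nm,
    photons,
    background,
    seed,
    shape=(15, 15),
    pixel_size=87.0,
    psf_sigma=110.0,
    poisson_noise=True,
):
    """Render one spot in frame 0 of a small movie."""
    events = pd.DataFrame({"frame": [0], "x_nm": [x_nm], "y_nm": [y_nm]})
    return render_movie(
        events,
        psf_sigma=psf_sigma,
        photons_per_event=photons,
        background=background,
        pixel_size=pixel_size,
        shape=shape,
        seed=seed,
        n_frames=1,
        poisson_noise=poisson_noise,
    )
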