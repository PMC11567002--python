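"""Release-site clustering and active-zone geometry on an event stream.

Draws 200 single-AP stimuli on a 6-site active zone with 27 nm
localization noise, clusters the events with the 50-nm diameter cut,
and computes the convex-hull geometry and distance distributions.
"""

import numpy as np

from relsite import az_hull, cluster_events, distances_to_center, make_az, sample_events
from relsite.azgeom import consecutive_event_distances
from relsite.synth import SINGLE_AP_PROTOCOL

az = make_az(6, az_radius=300.0, rate_profile=[0.05] * 6, seed=11, min_spacing=80.0)
events = sample_events(az, SINGLE_AP_PROTOCOL, seed=12)
pts = events[["x_nm", "y_nm"]].to_numpy()
print(f"{len(events)} release events from {az.n_sites} planted sites "
      f"over {SINGLE_AP_PROTOCOL.n_pulses} action potentials")

site_set = cluster_events(pts, clustering_diameter=50.0)
print(f"release sites found at 50 nm clustering diameter: {site_set.n_sites}")
print("events per site:", sorted((len(c.members) for c in site_set.clusters), reverse=True))

geom = az_hull(pts)
print(f"active-zone hull area: {geom.area / 1e6:.3f} um^2 "
      f"(center at {geom.center[0]:.0f}, {geom.center[1]:.0f} nm)")

d_center, _ = distances_to_center(pts, geom)
d_consec, _ = consecutive_event_distances(events)
print(f"mean distance to AZ center: {d_center.mean():.0f} nm")
print(f"mean distance between consecutive events: {d_consec.mean():.0f} nm")
print()
print("With 27 nm localization noise against a 50 nm clustering")
print("diameter, repeatedly used sites can split into more clusters")
print("than were planted - the regime real recordings operate in.")
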