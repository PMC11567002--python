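# relsite

Single-vesicle release-site mapping and synaptic-vesicle retrieval
kinetics from presynaptic fluorescence imaging.

Presynaptic boutons release neurotransmitter by fusing synaptic
vesicles at specialized release sites inside the active zone (AZ), a
membrane domain a few hundred nanometres across. With a vesicular
pHluorin reporter and near-TIRF imaging, individual fusion events
appear as diffraction-limited flashes that can be localized far below
the diffraction limit; after a stimulus train, the decay of the same
reporter measures how fast vesicles are retrieved and re-acidified.
`relsite` implements the full analysis chain for both measurements,
plus synthetic-data generators so every stage is testable against
known ground truth. It is a library for use from Python; the
`examples/` scripts show each capability end to end.

## What it computes

* **Sub-pixel localization** — candidate fusion events are detected
  in difference images and fit with mixtures of integrated 2D
  Gaussians (k chosen by a nested F-test); each event carries a
  precision estimate `σ_xy` propagated from the fit covariance. In the
  sparse-photon regime of vesicle imaging the precision is ~27 nm.
* **Release sites** — events of one bouton are partitioned by
  complete-linkage hierarchical clustering with a bounded cluster
  diameter (default 50 nm): every site satisfies
  `max‖xᵢ − xⱼ‖ ≤ d_cluster`.
* **AZ geometry** — the functional AZ is the convex hull of all
  events; its centre is the mean event position `c = (1/n)Σxᵢ`;
  distance-to-centre and consecutive-event distance distributions are
  reported as fractions of total events.
* **Release probability** — `Pr = n_events / n_AP` per bouton.
* **Retrieval kinetics** — post-stimulus decays are fit with
  `F(t) = F_∞ + ΔF·e^{−(t−t_end)/τ}`; the fractional retrieval block
  is `ΔF_{2τ_c}/ΔF_max`, evaluated at two *control* time constants,
  which equals `e^{−2τ_c/τ}` for an ideal exponential.
* **Sensor responses** — peak ΔF/F₀ of metabolite-sensor step
  responses and two-channel ratios for ratiometric indicators.

## Worked example

`examples/01_release_site_mapping.py` simulates two boutons with three
planted release sites each, renders a photon-noise movie, and runs the
full pipeline:

```
synapse_id   group  n_events  release_pr  n_sites  az_area_nm2  az_degenerate  mean_dist_to_center_nm  mean_consecutive_dist_nm
 demo/syn0 control        15         0.3        4     26117.97          False                  129.68                    191.17
 demo/syn1 control        20         0.4        3     40022.83          False                  139.60                    152.47

candidates 36, fitted 36, merged 36, assigned 35
```

Each row is one bouton: 15 and 20 of the planted events were detected
and localized, giving per-AP release probabilities of 0.3 and 0.4; the
50-nm clustering recovers the 3 planted sites (one split into 4 by
localization noise); the hull areas (~0.03–0.04 µm²) and distance
statistics describe the spatial footprint of release.

`examples/02_localization_precision.py` shows the precision/photon
trade-off and that the reported precision tracks the true scatter:

```
 photons  median precision (nm)  empirical scatter (nm)
     100                   28.3                    31.5
     250                   13.1                    15.2
     700                    6.1                     6.9
```

`examples/04_retrieval_kinetics.py` recovers the endocytic time
constant (9.86 s fitted vs 10 s true) and the closed-form retrieval
blocks (0.141 vs e⁻² = 0.135 for control; 0.524 vs e^(−2/3) = 0.513
for a 3× slowed group).

## Layout

```
src/relsite/
  synth.py      synthetic AZs, event streams, movies, traces
  detect.py     candidate detection + mixture-model localization
  sites.py      release-site clustering and utilization statistics
  azgeom.py     convex-hull AZ geometry, distance distributions
  kinetics.py   ΔF/F₀, Pr, rates, τ fits, retrieval block, peaks, ratios
  pipeline.py   end-to-end orchestration, group comparisons, reports
  io.py         TIFF movies + JSON sidecars, ROI/trace/event CSV tables
examples/       one narrative script per capability
docs/methods.md models, defaults, numerical choices, limitations
```
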