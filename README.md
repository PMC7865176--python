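# vesta

Subtomogram analysis of synaptic-vesicle docking sites, with a synthetic
cryo-electron-tomography scene generator that makes every stage verifiable
by parameter recovery.

## The problem

Cryo-ET of presynaptic terminals shows ~40-nm synaptic vesicles (SVs)
docked to the presynaptic membrane (PrM). Resolving the protein machinery
in the few-nanometre gap between the two bilayers requires subtomogram
averaging: classify thousands of picked vesicles by view (side vs
top/bottom) and by SV–PrM interbilayer distance, pool the *primed* subset
(interbilayer distance ≤ 6 nm; *tethered* ≥ 8 nm), align the subtomograms
in 3D under the missing-wedge constraint of single-axis tilting (±51°, 3°
increment), average with and without sixfold rotational (C6) symmetry,
and measure the result. The reported outcome of that analysis is six
protein densities symmetrically arranged on a ~38-nm circle, bridging a
~3.5-nm membrane gap, under vesicles of diameter 43.88 ± 5.32 nm of which
~75% are primed.

`vesta` is a tested, reusable implementation of that pipeline for anyone
who wants to run, probe or extend it:

* `vesta.phantom` — parametric ground-truth scenes (vesicle + membrane +
  interface ring or disordered tethers), ideal single-axis tilt series,
  white projection noise, full cohort sampling;
* `vesta.tomo` — projection, binning, cosine-edge low-pass, weighted
  back-projection and SIRT reconstruction;
* `vesta.census` — view classification, interbilayer distance and
  diameter with the 5-nm bilayer-center correction, docking-state
  assignment, diameter gating, distance histograms;
* `vesta.sta` — analytic wedge masks, wedge-constrained cross-correlation,
  pose initialization from picked coordinates, exhaustive and batch
  alignment, PCA + Ward classification ("alignment by classification"),
  wedge-compensated averaging, Cn symmetrization, iterative refinement;
* `vesta.metrics` — Fourier shell correlation, interface peak census,
  ring diameter, membrane gap, rotational-symmetry order;
* `vesta.pipeline` / the `vesta` CLI — the end-to-end study from one
  seeded YAML config, with per-stage tables, MRC volumes and a JSON run
  report.

Key conventions: distances in nm; interbilayer distance =
membrane-center-to-center distance − 5 nm; vesicle diameter = diametric
bilayer-peak distance + 5 nm; volumes are (z, y, x) with the beam along z
and the tilt axis along y; Euler angles ZYZ intrinsic.

## Worked example

Run the whole desk-scale study (40 vesicles, mixed views, noisy,
reconstructed with the ±51° wedge) from Python:

```python
from vesta import RunConfig, run_pipeline
from vesta.phantom import AcquisitionSpec, CohortConfig

cfg = RunConfig(
    cohort=CohortConfig(n_vesicles=40, view_mix=0.5),
    acquisition=AcquisitionSpec(snr=1.0),
    output_dir="run_demo", seed=42,
)
report = run_pipeline(cfg)
print(report["comparison"])
```

which printed, for this config and seed (~1 minute on one CPU):

```
ring_diameter_nm   recovered 36.14   truth_peak_centers 36.0
membrane_gap_nm    recovered 3.58    truth_mean 3.5
peak_count         recovered 6       truth 6
primed_fraction    recovered 0.708   truth 0.775  configured 0.75
mean_diameter_nm   recovered 44.52   truth 44.32  configured 43.88
```

Reading it: the C6-symmetrized average of the primed pool shows exactly
six interface densities whose peak centers sit on a 36.1-nm circle (the
planted rod centers lie at 36 nm — one rod radial extent inside the 38-nm
circumscribing ring); the bilayer-peak gap at the docking point is 3.58 nm
against the planted 3.5; the census calls 70.8% of the 24 side views
primed where the sampled truth is 77.5% (binomial noise at n=24); and the
mean measured diameter tracks the sampled cohort mean to 0.2 nm.
`run_demo/` holds the truth and census tables (TSV + STAR), the C1/C6
averages (MRC), and `run_report.json` with every number above plus
provenance links.

The same stages are available as shell subcommands
(`vesta simulate | reconstruct | bin | filter | census | average | report |
run`), e.g. `vesta run config.yaml`.

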