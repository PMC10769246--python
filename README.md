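# flashmap

Simulation and analysis of multiplexed **FLASH-PAINT** single-molecule
localization microscopy, built around the question it is typically used to
answer: *given seven Golgi proteins imaged in sequential DNA-PAINT rounds on
the same sample, how far is each species from each other species, and what
sub-compartment ordering does that imply?*

In FLASH-PAINT each target species carries an antibody/nanobody-conjugated
DNA docking site; transiently binding imager strands make the target blink,
one species per round, with an "eraser" oligo silencing each species after
its round.  The analysis reduces the localization clouds to a species ×
species matrix of **median neighbor distances** — for every localization of
species A, the distance to its nearest localization of species B, keeping
only pairs closer than 500 nm:

    d_i = min_j ‖x_i^A − x_j^B‖,   median over {d_i : d_i ≤ 500 nm}

Ranking these medians from a reference species recovers the cis→trans
ordering of Golgi layers at nanometre scale, far below the optical
diffraction limit.

The package provides, as separately usable stages:

- `flashmap.geometry` / `flashmap.simulate` — a layered-Golgi ground-truth
  model and a generative acquisition simulator (two-state blinking
  kinetics, eraser residue, stage drift, photon-dependent localization
  noise), emitting either localization tables directly (*list mode*) or
  rendered 16-bit camera frames (*frame mode*).
- `flashmap.localize` — spot detection and maximum-likelihood
  integrated-Gaussian PSF fitting with the standard precision formula,
  plus blink linking.
- `flashmap.register` — redundant cross-correlation (RCC) drift correction
  within rounds and rigid alignment across rounds.
- `flashmap.proximity` — the neighbor-filtered distance matrix with
  bootstrap confidence intervals and target ranking.
- `flashmap.pipeline` / the `flashmap` CLI — YAML-configured orchestration
  with per-stage seeding and a provenance manifest.

See `docs/methods.md` for the model, parameter defaults, calibration
choices and known limitations.

## Worked example

Simulate a seven-target acquisition over the curved-ribbon Golgi preset
(3,000 frames/round here; the default protocol is 30,000) and compute the
distance matrix:

```yaml
# golgi.yaml
geometry:
  preset: golgi7
  labeling_efficiency: 0.7
  linkage_sigma: 6.0
imaging:
  n_rounds: 7
  frames_per_round: 3000
drift: {step_sigma: 0.0, velocity_x: 0.0, velocity_y: 0.0}
registration: {drift_correction: false, align: false}
proximity: {n_boot: 200}
seed: 1
mode: list
```

```bash
flashmap run --config golgi.yaml --out out/
```

The manifest reports 1,972 docking sites, 11,582 blink events and 11,269
blink-linked localizations; `out/summary.json` ranks the stack markers by
median neighbor distance from VPS13B:

```
GRASP65      21.9 nm  (95% CI 21.1-22.6)
GM130        28.5 nm  (95% CI 27.9-29.2)
Giantin      44.0 nm  (95% CI 43.2-44.7)
bCOP         48.6 nm  (95% CI 47.8-49.3)
Golgin97    150.9 nm  (95% CI 150.4-151.5)
TGN46       170.5 nm  (95% CI 170.0-171.3)
```

Reading the ranking: the VPS13B layer (simulated 30 nm trans-ward of
GM130) sits closest to the cis markers GRASP65 and GM130 and farthest from
the trans markers Golgin97 and TGN46 — the medians recover the injected
cis→trans geometry, inflated a few nm by localization error, labeling
linkage and the nearest-neighbor noise floor (quantified in the tests).
`out/distance_matrix.csv` holds every ordered pair with counts and CIs,
and `out/distance_matrix.png` is the matching heat map.  The example
disables drift injection and registration to isolate the proximity
statistic; see `docs/methods.md` on why translation alignment across
rounds that share no structure is ill-posed on idealized phantoms.

Frame mode (`mode: frame`) instead renders TIFF stacks with a YAML
sidecar, localizes every frame (`flashmap localize`), drift-corrects by
RCC (`flashmap drift`), aligns rounds (`flashmap align`) and then computes
the same matrix (`flashmap distances`).

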