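# nanopsd

Quantification of PSD95 nanocluster architecture in hippocampal synapses
from two orthogonal super-resolution modalities: gated-STED-like pixel
images and PALM-like single-molecule localisation tables.

Excitatory synapses concentrate the scaffold protein PSD95 into
nanoclusters (NCs) of roughly 100–200 nm that sit inside the postsynaptic
density (PSD); a synapse may contain one, two, or more NCs, and the NC
count — not the NC size — is the main axis of synaptic structural
diversity.  `nanopsd` is an open implementation of the image-analysis
pipeline behind that kind of survey, for microscopists and quantitative
neurobiologists who want a scriptable, testable alternative to commercial
segmentation tools:

* a **synthetic scene generator** producing ground-truth fields of
  multi-NC PSDs (elliptical NCs, log-normal axes around 86 × 189 nm
  medians, inter-NC separations confined to 100–300 nm), rendered through
  Gaussian PSFs (confocal 240 nm FWHM, STED 85 nm, 20 nm pixels), as
  localisation tables (~40 nm precision), or as two-channel pre/post
  synaptic puncta fields;
* a **segmentation engine**: Gaussian prefilter, local background
  subtraction, seeded-watershed object splitting at a physical seed-point
  diameter, pixel-count and border filters, and containment-based NC→PSD
  assignment with subtype classification (1NC / 2NC / 3+NC);
* a **PALM pipeline**: least-squares 2D Gaussian peak fitting, DBSCAN
  cluster definition, nearest-neighbour-weighted disc rendering, and
  PALM-parameterised segmentation;
* **morphometry**: circle-equivalent diameters (`d = 2·sqrt(A/π)`),
  second-moment ellipse axes and aspect ratios, and the classic
  two-perpendicular-line-profile FWHM diameter
  (`FWHM = 2·sqrt(2 ln 2)·σ` of a fitted Gaussian);
* **spatial statistics**: the pair-correlation function g(r) to 1 μm with
  translation edge correction and 49-simulation Monte-Carlo CSR envelopes,
  and object-based juxtaposition (600 nm rule) with a 90° rotation control;
* **cohort statistics**: per-mouse median aggregation (mean ± SD over
  mice), one-way ANOVA with Tukey HSD, distance-from-soma gradients
  (Pearson over seven 20 μm bins), and a subtype-weighted consistency
  check.

See `docs/methods.md` for the model, parameter semantics, and the design
choices made where the source protocol is underspecified.

## Worked example

Simulate six STED fields (two per "mouse"), segment them, and aggregate:

```python
import pandas as pd, nanopsd as n
from nanopsd.io import records_to_frame
from nanopsd.cohort import summarise_region

cfg = n.SimulationConfig(field_width_nm=10_000, field_height_nm=10_000)
frames = []
for mouse in (1, 2, 3):
    for field in (0, 1):
        scene = n.sample_scene(cfg, seed=10 * mouse + field)
        confocal, sted = n.render_scene_pair(scene, cfg)
        records, _ = n.run_sted_workflow(confocal, sted)
        frames.append(records_to_frame(records, mouse=f"m{mouse}", field=field))
ncs = pd.concat(frames, ignore_index=True)
psds = ncs.drop_duplicates(["mouse", "field", "psd_id"])

s = summarise_region(psds, "psd_equivalent_diameter")
print(f"PSDs: {len(psds)}  NCs: {len(ncs)}")
print("1NC/2NC/3+NC (%): "
      + " / ".join(f"{s.subtype_fractions[k]:.1f}" for k in ("1NC", "2NC", "3+NC")))
nc_s = summarise_region(ncs, "nc_equivalent_diameter")
print(f"median NC diameter (mean +- SD over mice): "
      f"{nc_s.group_mean:.0f} +- {nc_s.group_sd:.0f} nm")
```

prints

```
PSDs: 495  NCs: 762
1NC/2NC/3+NC (%): 61.2 / 26.5 / 12.3
median NC diameter (mean +- SD over mice): 124 +- 1 nm
```

The generator drew subtypes at 63.7 / 24.3 / 11.9 % and NC axes with a
127.5 nm median equivalent diameter; the segmentation recovers the subtype
mixture within ~2 percentage points (NC pairs closer than ~150 nm merge at
STED resolution, PSD pairs occasionally fuse at confocal resolution — the
two biases nearly cancel) and the NC diameter within ~3%.

The same scenes can be analysed as localisation data
(`n.simulate_palm` → `nanopsd.palm.run_palm_workflow`), and a CLI mirrors
the library:

```sh
nanopsd simulate --seed 1 --out out/
nanopsd segment-sted --confocal out/confocal.tif --sted out/sted.tif --out seg/
nanopsd pcf --centroids seg/sted_records.csv --width-nm 20000 --height-nm 20000 \
            --rmax 1000 --bins 10 --sims 49 --seed 1 --out pcf.csv
```

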