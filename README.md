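# synaptoloc

Object-based colocalization analysis for single synapses in multichannel
punctate fluorescence images.

Glutamatergic synapses appear in super-resolution immunofluorescence as
juxtaposed pairs of diffraction-limited puncta: a presynaptic active-zone
marker (bassoon) and a postsynaptic scaffold (homer, PSD95 or SAP102),
typically ~150–200 nm apart. `synaptoloc` detects these puncta, pairs them
into synapses, classifies each synapse's input by vesicular glutamate
transporter overlap (VGLUT1 = corticothalamic, VGLUT2 = sensory), and
assigns receptor puncta (e.g. NMDA receptor GluN1/GluN2 subunits) to
postsynaptic or presynaptic compartments — the workflow used to ask which
receptor subtypes occupy which inputs onto thalamocortical neurons. It also
implements the supporting analyses: a nearest-neighbor interaction-strength
statistic with rotation and CSR nulls, per-cell single-molecule FISH
particle counting, and per-mouse aggregation with Welch's t-test.

Because this class of study rarely deposits raw microscopy data, the
package ships a synthetic image generator with complete ground truth
(synapse positions, input classes, receptor occupancy and offsets), so
every stage is testable end to end.

## The core statistics

* **Synapse pairing.** A punctum is a local intensity maximum with
  prominence ≥ a noise tolerance inside a `[min, max]` intensity window;
  its region is the flood from the maximum to
  `max(min_intensity, peak − tolerance)`. After dilating regions by a 2 px
  Euclidean disk, each postsynaptic punctum overlapping ≥ 1 presynaptic
  region becomes one synapse, paired to the nearest (maxima-to-maxima)
  presynaptic punctum.
* **Receptor assignment.** Each receptor punctum goes to the nearest
  overlapping synaptic marker; postsynaptic calls farther than 400 nm are
  discarded. Rates are reported per synapse and per receptor punctum,
  overall and per input class.
* **NN interaction strength.** With q(d) the distance distribution from a
  uniform random point to the reference pattern, observed nearest-neighbor
  distances are modeled as p(d) ∝ q(d)·exp(ε·1[d<t]); the fitted ε is
  positive when the two signals are spatially attracted. Significance is
  judged against a 90°-rotated control and a Monte-Carlo CSR null.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

```python
import synaptoloc as sl
from synaptoloc.nn_interaction import pattern_from_puncta, fit_interaction, rotate_90

config = sl.SynthConfig(fov_size_px=(1024, 1024),
                        n_ct_synapses=100, n_sensory_synapses=10, seed=7)
images, truth = sl.generate_fov(config)          # 5 channels + ground truth
result = sl.analyze_fov(images, sl.default_analysis_config())
m = result.metrics

print(f"synapses detected: {int(m['n_synapses'])} (ground truth {len(truth)})")
print(f"VGLUT1 share: {m['pct_vglut1']:.1f}%   VGLUT2 share: {m['pct_vglut2']:.1f}%")
print(f"median pre-post distance: {m['median_pre_post_distance_nm']:.0f} nm")
print(f"pct VGLUT1 synapses with postsynaptic receptor: "
      f"{m['pct_vglut1_synapses_with_postsynaptic_receptor']:.1f}")

X = pattern_from_puncta(result.puncta['homer'])
Y = pattern_from_puncta(result.puncta['bassoon'])
fit, ctl = fit_interaction(X, Y), fit_interaction(rotate_90(X), Y)
print(f"NN interaction strength: {fit.epsilon:.2f} (rotated control {ctl.epsilon:.2f})")
```

prints

```
synapses detected: 110 (ground truth 110)
VGLUT1 share: 90.9%   VGLUT2 share: 9.1%
median pre-post distance: 180 nm
pct VGLUT1 synapses with postsynaptic receptor: 50.0
NN interaction strength: 8.00 (rotated control -0.35)
```

All 110 simulated synapses are recovered with their input labels; the
measured VGLUT1-synapse receptor occupancy matches the configured 50%; the
median pre–post distance (180 nm) sits within one 50 nm pixel of the
configured 190 nm; and the marker pair shows strong spatial attraction
while its rotated control does not.

A command-line interface wraps the same functions:

```bash
synaptoloc simulate --out sim/ --seed 4        # synthetic FOV + ground truth
synaptoloc run --fov sim/fov.tif --out results/
synaptoloc nn --x homer.csv --y bassoon.csv --region 0 0 20000 20000 \
              --reps 99 --out nn.json
synaptoloc fish --channel probe.tif --negative neg.tif \
                --roi-threshold 50 --out counts.csv
synaptoloc report --fovs fov_metrics.csv --out mice.csv
```

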