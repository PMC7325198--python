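"""Quantify diffractogram similarity with the cross-correlation score (CCS).

Renders five same-substance diffractograms with different preferred-
orientation perturbations plus five unrelated compounds, preprocesses all
ten through the full pipeline (background, smoothing, Kalpha2 stripping,
unit-max normalization), and prints the windowed CCS of each against the
first same-substance pattern taken as the standard.
"""

import numpy as np

import powderid as pid

rng = np.random.default_rng(3)
lib = pid.fixture_library(6, seed=3)
base = lib[2]  # phases 0 and 1 are a deliberately similar analog pair

patterns, labels = [], []
for k in range(5):
    ph = pid.perturb_intensities(base, sigma=0.5, seed=int(rng.integers(2**31)))
    patterns.append(pid.preprocess_pattern(
        pid.render(ph, pid.SimConfig(seed=int(rng.integers(2**31))))))
    labels.append(f"{base.name} sample {k + 1}")
for ph in (lib[0], lib[1], lib[3], lib[4], lib[5]):
    patterns.append(pid.preprocess_pattern(
        pid.render(ph, pid.SimConfig(seed=int(rng.integers(2**31))))))
    labels.append(f"unrelated {ph.name}")

standard = patterns[0]
print(f"standard: {labels[0]}   (windowed CCS, max_lag = 0.5 deg 2theta)")
for lbl, p in zip(labels[1:], patterns[1:]):
    res = pid.score(standard, p, mode="windowed")
    print(f"  {lbl:<22} CCS = {res.score:.3f}")

print()
print("Same-substance samples keep most of the standard's correlation mass "
      "(scores near 1); unrelated compounds only overlap by accidental "
      "near-coincident lines and score close to 0. The full-lag score "
      "(mode='full') would instead reduce to a position-blind intensity "
      "ratio - see docs/methods.md.")
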