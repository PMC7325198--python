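"""Screen an adulterated street-sample analog (30% active + 70% diluent).

Street drug samples are usually cut: heroin samples rarely exceed 30%
active substance.  This mixes a 0.30-weighted render of an 'active' phase
with a 0.70-weighted 'diluent', runs the full noisy pipeline, matches the
detected peaks against the active phase, and flags the leftover peaks.
"""

import numpy as np

import powderid as pid
from powderid.peaks import phase_peaklist

lib = pid.fixture_library(4, seed=19)
active, diluent = lib[2], lib[3]

mix = pid.mix_patterns(
    [pid.render(active, pid.SimConfig(seed=1)),
     pid.render(diluent, pid.SimConfig(seed=2))],
    [0.30, 0.70],
)
proc = pid.preprocess_pattern(mix)
peaks = pid.detect_peaks(proc)
report = pid.match_peaks(peaks, phase_peaklist(active, proc.wavelength), 0.10)

print(f"active phase {active.name}: {len(active)} reference lines, "
      f"{len(report.matched)} matched "
      f"(fraction {report.fraction_matched:.2f}) at 0.10 deg tolerance")

strongest = np.sort(diluent.positions[np.argsort(diluent.rel_intensities)[-3:]])
flagged = [s for s in strongest
           if any(abs(e - s) <= 0.10 for e in report.extra_sample_peaks)]
print(f"diluent's three strongest lines: "
      + ", ".join(f"{s:.2f}" for s in strongest) + " deg")
print(f"flagged among the extra (unassigned) sample peaks: "
      + (", ".join(f"{s:.2f}" for s in flagged) or "none"))
print()
print("Even as the 30% minor component, the active phase is matched line by "
      "line; the unassigned extra peaks localize the cutting agent.")
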