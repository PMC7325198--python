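"""Reproducible validation experiments on synthetic diffractograms.

Each function builds its own inputs with the simulator, runs the regular
pipeline (preprocess -> peaks/CCS), and measures an end-to-end figure of
merit.  They are used by the test suite and by ``scripts/acceptance.py`` and
are deliberately plain functions so the same experiment can be re-run with
different sizes or seeds.
"""

from __future__ import annotations

import numpy as np

from . import ccs
from .pattern import Phase, CU_KALPHA1
from .peaks import detect_peaks, identify, match_peaks, phase_peaklist
from .preprocess import KAlphaParams, PreprocessParams, preprocess, strip_kalpha2
from .simulate import (
    GridSpec,
    SimConfig,
    fixture_library,
    mix_patterns,
    perturb_intensities,
    render,
)


def _spawn(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def separation_experiment(
    n_reps: int = 200,
    seed: int = 0,
    sigma: float = 0.5,
    max_lag: float = ccs.DEFAULT_MAX_LAG,
    n_same: int = 7,
    n_unrelated: int = 6,
) -> dict:
    """Same-substance vs unrelated-compound score-matrix contrast.

    Per repetition: render ``n_same`` intensity-perturbed diffractograms of
    one phase plus ``n_unrelated`` unrelated phases (full instrument model:
    doublet, background, counting noise), preprocess all, and compute the
    pairwise windowed CCS matrix.  Within-phase entries are the ordered pairs
    among the same-substance renders; between-phase entries pair a
    same-substance render with an unrelated compound, in both score
    directions.  Reports how often the strict extreme-value separation
    (min within > max between) holds, plus the average-level contrast.
    """
    rng = np.random.default_rng(seed)
    strict = 0
    mean_within, mean_between = [], []
    for _ in range(n_reps):
        lib = fixture_library(1 + n_unrelated, _spawn(rng))
        base = lib[2]  # outside the deliberately similar pair (0, 1)
        unrelated = [ph for i, ph in enumerate(lib) if i != 2]
        pats = []
        for _k in range(n_same):
            ph = perturb_intensities(base, sigma, _spawn(rng))
            pats.append(preprocess(render(ph, SimConfig(seed=_spawn(rng)))))
        for ph in unrelated:
            pats.append(preprocess(render(ph, SimConfig(seed=_spawn(rng)))))
        m = ccs.score_matrix(pats, mode="windowed", max_lag=max_lag)
        within = [m[i, j] for i in range(n_same) for j in range(n_same) if i != j]
        between = [m[i, j] for i in range(n_same)
                   for j in range(n_same, n_same + n_unrelated)]
        between += [m[j, i] for i in range(n_same)
                    for j in range(n_same, n_same + n_unrelated)]
        strict += min(within) > max(between)
        mean_within.append(float(np.mean(within)))
        mean_between.append(float(np.mean(between)))
    return {
        "strict_separation_rate": strict / n_reps,
        "mean_within": float(np.mean(mean_within)),
        "mean_between": float(np.mean(mean_between)),
        "n_reps": n_reps,
    }


def identification_experiment(
    n_trials: int = 100,
    seed: int = 0,
    sigma: float = 0.5,
    n_phases: int = 10,
    tolerance: float = 0.10,
) -> dict:
    """Closed-loop identification with habit-permuted relative intensities.

    Noise-free, Kalpha1-only renders isolate the preferred-orientation effect
    (intensity permutation) the grinding experiment demonstrates; since the
    input emulates already-stripped data, the Kalpha2 stripping stage is
    disabled (stripping a singlet would erode real lines), and detection
    thresholds are set accordingly low (0.002/0.001 of the maximum).
    """
    rng = np.random.default_rng(seed)
    params = PreprocessParams(kalpha=KAlphaParams(ratio=0.0))
    top1 = 0
    fractions = []
    for _ in range(n_trials):
        lib = fixture_library(n_phases, _spawn(rng))
        k = int(rng.integers(n_phases))
        ph = perturb_intensities(lib[k], sigma, _spawn(rng))
        sample = render(
            ph,
            SimConfig(doublet=False, bg_coeffs=(), noise_scale=0.0,
                      seed=_spawn(rng)),
        )
        reports = identify(
            sample, lib, params, tolerance=tolerance,
            min_rel_height=0.002, min_rel_prominence=0.001,
        )
        top = reports[0]
        top1 += top.candidate == lib[k].name
        fractions.append(
            next(r.fraction_matched for r in reports
                 if r.candidate == lib[k].name)
        )
    return {
        "top1_accuracy": top1 / n_trials,
        "min_fraction_matched": float(np.min(fractions)),
        "n_trials": n_trials,
    }


def kalpha2_stripping_experiment(
    positions: "list[float] | None" = None,
    params: PreprocessParams | None = None,
) -> dict:
    """Residual at the Kalpha2 position after stripping simulated doublets.

    The doublet-off render is the ground truth; the residual is reported as
    a fraction of the original Kalpha2 companion height at each position.
    """
    positions = positions or [10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0,
                              45.0, 50.0, 55.0, 59.0]
    params = params or PreprocessParams()
    worst = 0.0
    from .simulate import kalpha2_position

    for pos in positions:
        phase = Phase("doublet_probe", np.array([pos]), np.array([100.0]),
                      CU_KALPHA1)
        on = render(phase, SimConfig(doublet=True, bg_coeffs=(), noise_scale=0.0))
        off = render(phase, SimConfig(doublet=False, bg_coeffs=(), noise_scale=0.0))
        ka2 = float(kalpha2_position(pos))
        i2 = int(np.argmin(np.abs(on.two_theta - ka2)))
        original = on.intensity[i2] - off.intensity[i2]
        stripped = strip_kalpha2(on, params)
        resid = abs(stripped.intensity[i2] - off.intensity[i2]) / original
        worst = max(worst, float(resid))
    return {"max_residual_fraction": worst, "n_positions": len(positions)}


def peak_recovery_experiment(n_renders: int = 100, seed: int = 0) -> dict:
    """Apex-position error for isolated noisy peaks at SNR >= 20.

    One reflection at a random position in [10, 55] deg, rendered with the
    full instrument model (doublet, 50-count background, Poisson noise; apex
    SNR ~ 30), preprocessed, and located with the parabolic-refinement peak
    detector.  Reports the worst absolute position error.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    within_one_step = 0
    step = GridSpec().step
    for _ in range(n_renders):
        truth = float(rng.uniform(10.0, 55.0))
        phase = Phase("probe", np.array([truth]), np.array([100.0]), CU_KALPHA1)
        p = render(phase, SimConfig(seed=_spawn(rng)))
        proc = preprocess(p)
        pl = detect_peaks(proc)
        if len(pl) == 0:
            worst = max(worst, np.inf)
            continue
        best = int(np.argmax(pl.prominences))
        err = abs(float(pl.positions[best]) - truth)
        worst = max(worst, err)
        within_one_step += err <= step
    return {
        "max_position_error_deg": worst,
        "within_one_step_rate": within_one_step / n_renders,
        "n_renders": n_renders,
    }


def mixture_experiment(
    seed: int = 0,
    active_weight: float = 0.30,
    tolerance: float = 0.10,
) -> dict:
    """Adulterated two-phase street-sample analog (30% active, 70% diluent).

    Measures the matched fraction of the minor (active) phase's lines and
    whether the diluent's strongest *resolvable* lines (> 0.15 deg away from
    every active line) surface as extra (possible-adulterant) peaks.
    """
    rng = np.random.default_rng(seed)
    lib = fixture_library(4, _spawn(rng))
    active, diluent = lib[2], lib[3]
    mix = mix_patterns(
        [render(active, SimConfig(seed=_spawn(rng))),
         render(diluent, SimConfig(seed=_spawn(rng)))],
        [active_weight, 1.0 - active_weight],
    )
    proc = preprocess(mix)
    pl = detect_peaks(proc)
    report = match_peaks(pl, phase_peaklist(active, proc.wavelength), tolerance)
    strongest = diluent.positions[np.argsort(diluent.rel_intensities)[-3:]]
    resolvable = [s for s in strongest
                  if np.min(np.abs(active.positions - s)) > 0.15]
    flagged = [
        s for s in resolvable
        if any(abs(e - s) <= tolerance for e in report.extra_sample_peaks)
    ]
    return {
        "minor_fraction_matched": report.fraction_matched,
        "n_resolvable_diluent_lines": len(resolvable),
        "n_flagged": len(flagged),
        "all_flagged": len(flagged) == len(resolvable),
    }
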