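"""Compliance-weighted ZEST vs naive ZEST under attention lapses.

Simulates an observer (true threshold 25 dB, 1 dB frequency-of-seeing
slope) who fully lapses on 30% of trials.  Naive ZEST treats every
response as trustworthy; the weighted variant raises each trial's
likelihood term to alpha = 0 on lapsed trials (discarding them) and
alpha = 1 otherwise.  Paired over shared random seeds.
"""
import numpy as np

from vigilfield.zest import (
    PsychometricModel,
    StoppingRule,
    ZestConfig,
    run_threshold_estimation,
)

TRUTH = 25.0
model = PsychometricModel(sigma=1.0, guess_rate=0.03, lapse_rate=0.03)
config = ZestConfig(stopping=StoppingRule(max_trials=30))

root = np.random.SeedSequence(1)
errors = {"naive": [], "weighted": []}
for rep in root.spawn(200):
    lapse_rng = np.random.default_rng(rep.spawn(1)[0])
    lapses = (lapse_rng.random(30) < 0.3).tolist()
    for label, alphas in (
        ("naive", None),
        ("weighted", [0.0 if flag else 1.0 for flag in lapses]),
    ):
        rng = np.random.default_rng(rep)
        res = run_threshold_estimation(
            TRUTH, model, config, rng, alpha_stream=alphas, lapse_stream=lapses
        )
        errors[label].append(res.estimate - TRUTH)

print(f"true threshold {TRUTH} dB, 30 trials, 30% lapsed, 200 paired replicates\n")
print(f"{'method':10s} {'RMSE (dB)':>10s} {'bias (dB)':>10s}")
for label, errs in errors.items():
    errs = np.asarray(errs)
    print(f"{label:10s} {np.sqrt((errs**2).mean()):10.3f} {errs.mean():10.3f}")
print(
    "\nLapses look like misses, so naive ZEST is dragged far below the"
    "\ntrue threshold; zero-weighting the unreliable trials removes almost"
    "\nall of that bias at no cost to the compliant trials."
)
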