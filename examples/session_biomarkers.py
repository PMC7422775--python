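"""Compute the seven compliance biomarkers for one synthetic session.

Generates a single simulated assessment (5 Hz webcam feature stream +
trial log + ZEST-estimated thresholds) for a moderately compliant
subject and prints the session-level biomarker vector.
"""
import numpy as np

from vigilfield.biomarkers import session_biomarkers
from vigilfield.perimetry import mean_sensitivity
from vigilfield.synthetic import GeneratorConfig, SubjectTruth, generate_session

config = GeneratorConfig()
rng = np.random.default_rng(0)
subject = SubjectTruth(
    subject_id="demo",
    trait=0.4,  # 0 = fully compliant, 1 = frequently lapsing
    true_thresholds_db=rng.normal(28.0, 1.5, 24),
)
session, truth = generate_session(config, subject, rng)

vec = session_biomarkers(session)
print(f"frames: {len(session.frames)} ({100 * session.valid_fraction:.1f}% valid), "
      f"trials: {len(session.trials)}")
print(f"estimated mean sensitivity: {mean_sensitivity(session.thresholds):.2f} dB "
      f"(true {subject.true_thresholds_db.mean():.2f} dB)")
print(f"latent lapsed-frame fraction: {truth.frame_states.mean():.2f}\n")
for name, value in vec.as_dict().items():
    print(f"  {name:28s} {value:8.3f}")
print(
    "\nDispersions are Rousseeuw-Croux Sn values (gaze in degrees, head"
    "\nlocation in mm, head rotation in degrees); sadness/surprise/blink"
    "\nare mean action-unit intensity sums (a.u.); latency is seconds."
    "\nLarger values indicate more movement/expression, i.e. lower compliance."
)
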