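"""Hidden-Markov state dynamics across conditions.

Builds the HMM feature set (EC scores, their derivatives, postural speed
and acceleration, z-scored within animal), fits one Gaussian HMM on the
pooled control + poke cohort, and reports occupancy fold changes of the
stimulus condition over the spontaneous baseline.
"""

import dataclasses

import numpy as np

from cionakit.bodyplan import default_body_plan
from cionakit.efd import fit_shape_space, frame_spectra, project
from cionakit.io import downsample, mask_low_confidence
from cionakit.state_hmm import build_features, fit_hmm, state_metrics
from cionakit.synthetic import StimulusConfig, SynthConfig, simulate_cohort

plan = default_body_plan()
base = SynthConfig(n_frames=6000, seed=1)
stim = dataclasses.replace(base, stimulus=StimulusConfig(onset_frame=1000))
cohort = (simulate_cohort(3, base, condition="control")
          + simulate_cohort(3, stim, seeds=[101, 102, 103], condition="poke"))

blocks, meta = [], []
for series, _ in cohort:
    prepared = downsample(mask_low_confidence(series), 5)
    spectra, _, _ = frame_spectra(prepared.coords, plan, order=30, n_keep=10)
    blocks.append(spectra)
    meta.append((series.animal_id, series.condition, len(spectra)))
X = np.vstack(blocks)
space = fit_shape_space(X, min_var=0.85)

per_animal, condition_of, pos = {}, {}, 0
for animal, condition, n in meta:
    per_animal[animal] = project(X[pos:pos + n], space, n_components=5)
    condition_of[animal] = condition
    pos += n

features = build_features(per_animal)
model, decoded = fit_hmm(features, n_states=4, seed=0, n_restarts=3,
                         n_iter=100, min_bout=5)
metrics = state_metrics(decoded, condition_of, fps=4.0,
                        n_states=model.n_states, baseline="control")
print("state occupancy by condition (rows sum to 1):")
print(metrics.occupancy.round(3).to_string())
print("\noccupancy fold change vs control:")
print(metrics.fold_change.loc["occupancy"].round(2).to_string())
# poke shifts occupancy toward the contracted end of the state ordering
# and toward post-response quiescence; a 4-state model keeps this example
# fast — the reference analysis uses 8 states
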