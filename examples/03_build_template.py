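"""Build an average symmetric template mask from a small cohort.

Registering a preliminary mask to each skull, averaging via generalized
Procrustes analysis, and reflection-averaging removes both individual shape
and individual asymmetry from the template.
"""

import numpy as np

from densecranio import build_template
from densecranio.registration import NonRigidConfig
from densecranio.synthetic import (
    SyntheticPopulationSpec,
    generate_population,
    initialization_landmarks,
    template_initialization_landmarks,
)
from densecranio.template_builder import asymmetry_score, mirror_pairing
from densecranio.mesh_core import MaskedShape

base, individuals = generate_population(
    SyntheticPopulationSpec(n_individuals=5, deformation_amplitude=2.0, seed=3)
)
mask_lm = template_initialization_landmarks(base, seed=0)
per_target_lm = [initialization_landmarks(i, base, seed=0) for i in individuals]

template = build_template(
    [i.mesh for i in individuals], base, per_target_lm, mask_lm,
    NonRigidConfig(num_iterations=40),
)
pairing = mirror_pairing(template.vertices)
asym = asymmetry_score(MaskedShape(template.vertices, template.faces), pairing)
print(f"template: {template.n_vertices} quasi-landmarks "
      f"(same topology as the preliminary mask)")
print(f"residual asymmetry after reflection averaging: {asym:.2e} mm")
# Asymmetry at numerical zero: left and right template halves are exact
# mirror images, so downstream left/right comparisons are unbiased.
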