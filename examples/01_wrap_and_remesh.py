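"""Shrink-wrap a synthetic skull and remesh it to an even triangulation.

CBCT-derived bone surfaces are uneven and full of holes; wrapping a simple
half-cylinder onto them yields a single regular sheet ready for masking.
"""

import numpy as np

from densecranio import make_half_cylinder, remesh_isotropic, shrink_wrap
from densecranio.synthetic import SyntheticPopulationSpec, generate_population

# one synthetic skull with an orbital hole, like a real CBCT extraction
spec = SyntheticPopulationSpec(n_individuals=1, seed=1,
                               hole_spec=[((25.0, 62.0, 17.0), 7.0)])
_, (individual,) = generate_population(spec)
skull = individual.mesh
print(f"input skull: {skull.n_vertices} vertices, {skull.n_faces} faces")

wrap = make_half_cylinder(skull, margin=10.0, res_u=60, res_v=60)
wrapped = shrink_wrap(wrap, skull, iterations=10)
even = remesh_isotropic(wrapped, target_faces=5000)

edges = even.edges_unique()
lengths = np.linalg.norm(even.vertices[edges[:, 0]] - even.vertices[edges[:, 1]], axis=1)
print(f"wrapped surface: {wrapped.n_vertices} vertices (grid topology)")
print(f"remeshed: {even.n_faces} faces, edge-length CV {lengths.std() / lengths.mean():.3f}")
# The CV (coefficient of variation) near 0.2 means triangles are close to
# uniform, which is what makes vertices usable as evenly spread quasi-landmarks.
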