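"""Shared generator for randomized small GB test systems."""

import numpy as np

from atomstress.model_io import AtomRecord, ForceFieldTopology


def random_gb_system(rng, n):
    atoms = [
        AtomRecord(i, "X", 0, "GBR", 12.0, rng.uniform(-0.8, 0.8), 0.3, 0.3,
                   rng.uniform(0.11, 0.2), rng.uniform(0.7, 0.9))
        for i in range(n)
    ]
    top = ForceFieldTopology(atoms, [], set(), {})
    while True:
        coords = rng.normal(scale=0.25, size=(n, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if n == 1 or d[np.triu_indices(n, 1)].min() > 0.08:
            return top, coords
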