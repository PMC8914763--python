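"""Shared constructors for synthetic in-memory test objects."""

import numpy as np

from thermasym.symmetry import RegionPair


def random_region_pair(rng: np.random.Generator) -> RegionPair:
    """A RegionPair with random temperatures and dummy disjoint pixel sets."""
    na, nb = (int(v) for v in rng.integers(2, 50, size=2))
    return RegionPair(
        side_a_temps=rng.uniform(30, 36, na).round(3),
        side_b_temps=rng.uniform(30, 36, nb).round(3),
        side_a_pixels=np.column_stack([np.zeros(na, int), np.arange(na)]),
        side_b_pixels=np.column_stack([np.ones(nb, int), np.arange(nb)]),
    )
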