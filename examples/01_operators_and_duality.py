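"""Scalar representation operators, tensor combination, and duality.

Builds a tiny categorical dataset, represents it under a panel of two
empirical probability models with the self-information operator, and shows
that each element's spectrum and each model's co-spectrum are transposed
views of the same tensor.
"""

import numpy as np

from prism import (
    ProbabilityModel,
    cospectrum_of,
    self_information,
    spectrum_of,
    tensor_representation,
)

# two probability models of the same token universe: one thinks "x" is
# common, the other thinks it is rare
m1 = ProbabilityModel.from_counts("m1", {"x": 8, "y": 1, "z": 1})
m2 = ProbabilityModel.from_counts("m2", {"x": 1, "y": 8, "z": 1})

data = ["x", "y", "x", "z"]
tensor = tensor_representation(data, [m1, m2], ["info"])

print("self-information of 'x' under m1:", round(self_information(m1, "x"), 4))
print("self-information of 'x' under m2:", round(self_information(m2, "x"), 4))

for eid in tensor.element_ids:
    s = spectrum_of(tensor, eid)
    print(f"spectrum of {eid}: {np.round(s.values[:, 0], 4)}")

cs = cospectrum_of(tensor, "m1")
print("co-spectrum of m1:", np.round(cs.values[:, 0], 4))
print(
    "duality: cospectrum_of('m1')[0] == spectrum_of(first element)[m1] ->",
    cs.values[0, 0] == spectrum_of(tensor, tensor.element_ids[0]).values[0, 0],
)
# Each element's spectrum says how surprising it is under each model; each
# model's co-spectrum says how surprising every element is under it.  The
# two are the same numbers read along different axes of one tensor.
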