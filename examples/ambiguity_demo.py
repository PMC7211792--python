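"""Why a single indentation depth cannot size a nodule.

Two very different nodules — a 10-mm circle 20 mm deep and a 16-mm circle
40 mm deep — produce maximum palpation forces within a fraction of a
percent of each other at a 10-mm indentation: from one indentation depth
alone the two are indistinguishable.  The curvature of the force profile
at a second indentation depth, however, separates them clearly, which is
what the multi-depth calibration inversion exploits.
"""

import numpy as np

from palpquant import (
    IndentationProtocol,
    NoduleSpec,
    TissueDomain,
    ambiguity_envelope,
    build_mesh,
    second_derivative,
    sweep,
)
from palpquant.materials import CANCEROUS_NODULE, HEALTHY_PROSTATE

mats = {"healthy": HEALTHY_PROSTATE, "cancerous": CANCEROUS_NODULE}
domain = TissueDomain(100.0, 100.0, mesh_size=4.0)
positions = tuple(np.linspace(25.0, 75.0, 11))

env = ambiguity_envelope(
    domain, mats,
    IndentationProtocol(positions=positions, depths=(10.0,), increments=10),
    depth_grid=[20.0, 40.0], size_grid=[10.0, 16.0],
)
print("max force feedback at 10-mm indentation (N/mm):")
print(env.table.to_string(index=False))
print()
for a, b, rel in env.near_pairs:
    print(f"indistinguishable pair: depth/size {a} vs {b}  "
          f"(max forces differ by {rel:.2%})")

prot5 = IndentationProtocol(positions=positions, depths=(5.0,), increments=10)
d2 = {}
for dep, size in [(20.0, 10.0), (40.0, 16.0)]:
    mesh = build_mesh(domain, NoduleSpec(shape="circle", diameter=size,
                                         depth=dep, center_x=50.0))
    d2[(dep, size)] = second_derivative(sweep(mesh, mats, prot5)[0], 50.0)
(a, va), (b, vb) = d2.items()
print()
print(f"profile curvature at 5-mm indentation: {a}: {va:.3e}, {b}: {vb:.3e}")
print(f"curvature separation: {abs(va - vb) / max(abs(va), abs(vb)):.1%} "
      "-> a second indentation depth resolves the ambiguity")
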