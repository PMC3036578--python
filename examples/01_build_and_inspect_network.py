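"""Build a Boolean gene network, propagate states, and read off the phenotype.

The trait is the on-fraction of the network's terminal genes (out-degree
zero) scaled to the environmental range of 140 trait units.
"""

import numpy as np

from netherit import build_network, phenotype_network, propagate_states, terminal_mask
from netherit.genotype import write_dot

rng = np.random.default_rng(1)

chrom = build_network(n=13, topology="scale_free", rng=rng)
states = propagate_states(chrom)
terminals = terminal_mask(chrom)

print("heads     :", chrom.heads.tolist())
print("functions :", chrom.functions.tolist(), "(1 = activator, 0 = repressor)")
print("states    :", states.tolist())
print("terminals :", np.nonzero(terminals)[0].tolist())
print(f"phenotype : {phenotype_network(chrom):.2f}  "
      f"(= 140 / {terminals.sum()} terminals x {states[terminals].sum()} on)")

write_dot(chrom, "network.dot")
print("wrote network.dot (render with graphviz: dot -Tpng network.dot)")
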