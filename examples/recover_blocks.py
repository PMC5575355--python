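"""Recover hidden sample blocks from a noisy, shuffled copy-number matrix.

Generates the standard benchmark (100 cells in four orthogonal copy-number
groups over 300 bins, Gaussian noise at SNR 2.82, rows shuffled), runs the
TCP solver, and reports how well the arrangement reconstitutes the groups.
"""

import numpy as np

from tcperm import (
    SyntheticConfig,
    TCPConfig,
    count_label_blocks,
    generate,
    ordering_block_ari,
    solve_tcp,
)

ds = generate(SyntheticConfig(seed=0, target_snr=2.82))
print(f"input: {ds.matrix.n_samples} samples x {ds.matrix.n_bins} bins, "
      f"achieved SNR {ds.achieved_snr:.3f}")
print(f"label blocks before solving: "
      f"{1 + int(np.sum(ds.labels[1:] != ds.labels[:-1]))} (shuffled)")

result = solve_tcp(ds.matrix, TCPConfig(max_iters=300))

n_blocks = count_label_blocks(result.ordering, ds.labels)
ari = ordering_block_ari(result.ordering, ds.labels)
print(f"ran {result.state.iteration} sweeps "
      f"(final energy {result.state.objective_history[-1]:.1f})")
print(f"label blocks after solving: {n_blocks}")
print(f"block adjusted Rand index: {ari:.3f}")
print("arrangement (group label per display position):")
print("".join(str(l) for l in ds.labels[result.ordering.order]))

# n_blocks == number of groups and ARI == 1 mean every group came back as
# exactly one contiguous block; each digit run above is one recovered block.
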