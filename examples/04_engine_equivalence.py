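"""Show that the batched engine reproduces the serial chains exactly.

Both engines consume the same pre-generated random streams (one Normal
and one Uniform draw per iteration and parameter, per voxel); with the
reduction order fixed, the retained samples agree bitwise.
"""

import numpy as np

from ballstick import (
    BallStickParams,
    generate_stream,
    lm_fit,
    make_scheme,
    run_mcmc,
    run_mcmc_batch,
    simulate_voxel,
)
from ballstick.mcmc import MCMCOptions

scheme = make_scheme()
truth = BallStickParams(S0=100.0, d=1e-3, f=[0.7], theta=[np.pi / 3], phi=[np.pi / 4])
opts = MCMCOptions(burnin=800, njumps=500, sampleevery=10)

n_vox = 8
datas = np.stack([simulate_voxel(truth, scheme, snr=30, seed=i) for i in range(n_vox)])
fits = [lm_fit(d, scheme, 1).params for d in datas]
streams = [generate_stream(100 + i, opts, 5) for i in range(n_vox)]

batched = run_mcmc_batch(datas, scheme, fits, opts, streams)
diffs = []
for v in range(n_vox):
    serial = run_mcmc(datas[v], scheme, fits[v], opts, streams[v])
    diffs.append(np.max(np.abs(batched[v].samples - serial.samples)))
print(f"{n_vox} voxels, {opts.n_iterations} iterations each")
print(f"max absolute difference between engines: {max(diffs):.1e}")
print("identical random streams -> identical chains; the batched engine is a"
      " re-organisation of the arithmetic, not an approximation")
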