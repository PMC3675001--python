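"""Bars benchmark: recover the generating causes under both superposition rules.

Generates 1000 patches of 5x5 pixels from ten +/-10-amplitude bars (five
horizontal, five vertical, two active on average, Gaussian noise sigma=2),
once under the occlusive max-magnitude rule (MCA) and once under linear
superposition (BSC), then fits the matching model with truncated
variational EM and scores recovery by greedy max-cosine matching.
"""

import numpy as np

from maxcauses import (
    TruncationParams,
    generate_bars_dataset,
    make_bars_params,
    run_em,
    score_recovery,
)

for kind in ("MCA", "BSC"):
    _, gt = make_bars_params(b=5, seed=0, model_kind=kind)
    patches, _ = generate_bars_dataset(gt, 1000, seed=100)
    learned, trace = run_em(
        patches, kind, H=10, trunc=TruncationParams(H_prime=6, gamma=4),
        iters=100, seed=200, start_temperature=1.5,
    )
    rep = score_recovery(learned, gt)
    print(f"{kind}: recovered={rep.success} "
          f"(worst bar cosine {rep.cosines.min():.3f})")
    print(f"     mean active units H*pi = {rep.mean_active_learned:.2f} "
          f"(generator: 2.00)")
    print(f"     noise sigma = {learned.sigma:.3f} (generator: 2.00)")

print("\nA cosine of 1.0 means a learned basis function reproduces a "
      "generating bar exactly; recovery succeeds when every bar is matched "
      "at cosine >= 0.95, and the inferred sparsity and noise should sit "
      "within a few percent of the generating values.  Bars stimuli have "
      "pronounced local optima (especially for the occlusive model), so an "
      "occasional seed converges to a partial solution; the validation "
      "battery therefore scores five seeds per model.")
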