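"""Interpolate first-decision confidence by k-nearest neighbors.

Double-decision trials carry no confidence report for the first decision;
the rated single-decision trials (same coherence and accuracy, nearest
reaction times) stand in for it.  Leave-one-out cross-validation on the
rated trials shows how much of the rating variance the interpolation
captures.
"""

import numpy as np

from confbound import (
    AgentParams,
    ConfidencePool,
    DesignSpec,
    annotate_conf_hat,
    loo_variance_explained,
    simulate_dataset,
)

trials = simulate_dataset(DesignSpec(), AgentParams(), seed=2)
pool = ConfidencePool.from_trials(trials)
print(f"pool: {len(pool)} rated single first decisions")

r2 = loo_variance_explained(pool, small_cell="shrink")
print(f"leave-one-out variance explained: {r2:.3f}")
# The rating a trial would have received is predicted from its neighbors;
# the unexplained remainder is rating noise plus confidence variation that
# coherence, accuracy, and RT cannot see (e.g. post-decision evidence).

annotated = annotate_conf_hat(trials, pool)
dd = annotated[annotated["trial_type"] == "double"]
r = np.corrcoef(dd["conf_hat"], dd["conf_true"])[0, 1]
print(f"correlation of interpolated with true (hidden) confidence: {r:.3f}")
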