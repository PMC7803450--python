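"""Individual-level microsimulation oracle for the cohort engine.

Samples each simulated person's state path from the same per-cycle transition
matrices and compares the resulting state frequencies against the cohort
trace.  Deliberately uses a different propagation mechanism (per-person
categorical sampling) from the engine's matrix-vector products.
"""

import numpy as np

from hypercea.engine import STATES, build_transition_matrix


def microsimulate(p, arm, n_people, seed):
    """State frequencies by cycle boundary from ``n_people`` sampled paths."""
    rng = np.random.default_rng(seed)
    n_states = len(STATES)
    state = np.zeros(n_people, dtype=np.int64)  # everyone starts well
    freq = np.zeros((p.n_cycles + 1, n_states))
    freq[0] = np.bincount(state, minlength=n_states) / n_people
    for t in range(p.n_cycles):
        m = build_transition_matrix(p, arm, t)
        cum = np.cumsum(m, axis=1)
        cum[:, -1] = 1.0  # guard against float round-off in the last column
        u = rng.random(n_people)
        state = (u[:, None] > cum[state]).sum(axis=1)
        freq[t + 1] = np.bincount(state, minlength=n_states) / n_people
    return freq


def binomial_3se(expected, n_people, floor=1e-12):
    """Allowed absolute deviation: three binomial standard errors (plus a tiny floor)."""
    return 3.0 * np.sqrt(np.clip(expected * (1.0 - expected), 0.0, None) / n_people) + floor
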