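"""Shared test utilities (kept out of conftest so tests can import them)."""


def random_label_matrix(rng, n_max=50, d_max=4):
    """Random true/predicted label sets (every true set non-empty)."""
    n = int(rng.integers(1, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    labels = [f"L{j}" for j in range(d)]
    true_sets, pred_sets = [], []
    for _ in range(n):
        k = int(rng.integers(1, d + 1))
        true_sets.append(set(rng.choice(labels, size=k, replace=False)))
        kp = int(rng.integers(0, d + 1))
        pred_sets.append(
            set(rng.choice(labels, size=kp, replace=False)) if kp else set()
        )
    return labels, true_sets, pred_sets
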