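"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_rm_ss(y):
    """Textbook two-way within-subject sums of squares via explicit loops
    (independent of the vectorized implementation under test)."""
    n, a, b = y.shape
    gm = y.mean()
    out = {}
    out["A"] = n * b * sum((y[:, i, :].mean() - gm) ** 2 for i in range(a))
    out["B"] = n * a * sum((y[:, :, j].mean() - gm) ** 2 for j in range(b))
    out["AB"] = n * sum(
        (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + gm) ** 2
        for i in range(a)
        for j in range(b)
    )
    out["AS"] = b * sum(
        (y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + gm) ** 2
        for s in range(n)
        for i in range(a)
    )
    out["BS"] = a * sum(
        (y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + gm) ** 2
        for s in range(n)
        for j in range(b)
    )
    out["ABS"] = sum(
        (
            y[s, i, j]
            - y[s, i, :].mean()
            - y[s, :, j].mean()
            - y[:, i, j].mean()
            + y[s].mean()
            + y[:, i, :].mean()
            + y[:, :, j].mean()
            - gm
        )
        ** 2
        for s in range(n)
        for i in range(a)
        for j in range(b)
    )
    out["subj"] = a * b * sum((y[s].mean() - gm) ** 2 for s in range(n))
    return out
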