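"""Deterministic random fixtures shared by the golden-oracle test.

The golden expected values in ``tests/data/golden_stats.json`` were
computed once with an independent statistics implementation on exactly
these fixtures; the test regenerates the fixtures and compares the
package's results against the frozen values.
"""

from __future__ import annotations

import numpy as np

MASTER_SEED = 20_260_925
N_FIXTURES = 60
KINDS = ("wilcoxon", "paired_t", "welch_t", "chisq", "binom", "correlation")


def make_fixtures() -> list[dict]:
    """60 fixtures, ten per statistical operation, deterministic."""
    fixtures = []
    for i in range(N_FIXTURES):
        rng = np.random.default_rng([MASTER_SEED, i])
        kind = KINDS[i % len(KINDS)]
        fx: dict = {"id": i, "kind": kind}
        if kind == "wilcoxon":
            n = int(rng.integers(8, 40))
            if i % 2 == 0:  # continuous: no ties, exact path when n <= 25
                n = min(n, 25)
                x = rng.normal(50, 15, n)
                y = x + rng.normal(2, 8, n)
            else:  # integer-valued: ties force the normal approximation
                x = rng.integers(0, 30, n).astype(float)
                y = np.clip(x + rng.integers(-4, 6, n), 0, None).astype(float)
                if np.all(x == y):
                    y[0] += 1.0
            fx["x"], fx["y"] = x.tolist(), y.tolist()
        elif kind == "paired_t":
            n = int(rng.integers(5, 40))
            x = rng.normal(100, 30, n)
            y = x + rng.normal(5, 20, n)
            fx["x"], fx["y"] = x.tolist(), y.tolist()
        elif kind == "welch_t":
            na, nb = int(rng.integers(5, 25)), int(rng.integers(5, 25))
            fx["x"] = rng.normal(0.3, 0.5, na).tolist()
            fx["y"] = rng.normal(-0.2, 1.1, nb).tolist()
        elif kind == "chisq":
            k = int(rng.integers(2, 6))
            fx["counts"] = rng.integers(1, 60, k).tolist()
        elif kind == "binom":
            fx["k1"] = int(rng.integers(0, 100))
            fx["k2"] = int(rng.integers(1, 100))
        else:  # correlation of arcsine-sqrt transformed percentages
            n = int(rng.integers(10, 60))
            a = rng.uniform(0, 100, n)
            b = np.clip(0.6 * a + rng.normal(0, 25, n), 0, 100)
            fx["a"], fx["b"] = a.tolist(), b.tolist()
        fixtures.append(fx)
    return fixtures
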