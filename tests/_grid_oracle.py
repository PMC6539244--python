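"""Brute-force likelihood-lattice oracle for small logistic fits.

Kept independent of the package's fitting code: it evaluates the
log-likelihood directly on an iteratively refined parameter lattice.
"""

import numpy as np


def loglik(b0, b, X, y):
    eta = b0 + X @ b
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def grid_mle(X, y, span=8.0, points=21, refinements=9):
    """Maximize the likelihood over a shrinking (intercept, slopes) lattice."""
    p = X.shape[1]
    center = np.zeros(p + 1)
    width = span
    for _ in range(refinements):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grids], axis=1)
        lls = np.array([loglik(row[0], row[1:], X, y) for row in flat])
        center = flat[int(np.argmax(lls))]
        width = 2 * width / (points - 1)  # keep the previous lattice covered
    return center
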