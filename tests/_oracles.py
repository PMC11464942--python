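"""Independent reference implementations used only to check the package.

These deliberately take different computational routes from the library
code: closed-form log-gamma enumeration for the HWE exact test, direct
normal-equation least squares for regression slopes, and dense grid
search for turning points.
"""

import numpy as np
from scipy.special import gammaln


def hwe_enumeration_pvalue(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact HWE p by full enumeration with closed-form probabilities.

    P(h | n, nA) = n! / (hom_r! h! hom_c!) * 2^h * nA! (2n-nA)! / (2n)!
    evaluated in log space for every reachable heterozygote count.
    """
    n = n_hom_a1 + n_het + n_hom_a2
    n_a1 = 2 * n_hom_a1 + n_het
    r = min(n_a1, 2 * n - n_a1)
    if r == 0:
        return 1.0
    hets = np.arange(r % 2, r + 1, 2)
    hom_r = (r - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
        + hets * np.log(2.0)
        + gammaln(r + 1)
        + gammaln(2 * n - r + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(probs[probs <= p_obs * (1 + 1e-10)].sum(), 1.0))


def hwe_enumeration_pvalues(n: int, n_rare: int) -> np.ndarray:
    """P-values for every reachable het count at (n, n_rare)."""
    if n_rare == 0:
        return np.array([1.0])
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    order = np.argsort(probs, kind="stable")
    cum = np.cumsum(probs[order])
    idx = np.searchsorted(probs[order], probs * (1 + 1e-10), side="right")
    return np.minimum(cum[idx - 1], 1.0)


def ols_slope_se(x: np.ndarray, y: np.ndarray):
    """Textbook simple-regression slope and SE."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    se = np.sqrt(float(resid @ resid) / (n - 2) / sxx)
    return beta, float(se)


def lstsq_fit(X: np.ndarray, y: np.ndarray):
    """General least squares via numpy.linalg.lstsq: (coef, rss, llf, se)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n, k = X.shape
    sigma2 = rss / n
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    cov = np.linalg.inv(X.T @ X) * (rss / (n - k))
    return coef, rss, llf, np.sqrt(np.diag(cov))


def grid_turning_points(coefs, z_range, n_points: int = 10_001):
    """Stationary points of b1 z + b2 z^2 (+ b3 z^3) by dense grid search."""
    z = np.linspace(z_range[0], z_range[1], n_points)
    b = np.asarray(coefs, float)
    y = sum(c * z ** (k + 1) for k, c in enumerate(b))
    out = []
    interior = np.arange(1, z.size - 1)
    mins = interior[(y[interior] < y[interior - 1]) & (y[interior] <= y[interior + 1])]
    maxs = interior[(y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1])]
    for i in mins:
        out.append((float(z[i]), "minimum"))
    for i in maxs:
        out.append((float(z[i]), "maximum"))
    return sorted(out)
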