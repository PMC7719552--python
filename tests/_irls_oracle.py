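"""Independent textbook IRLS for the quasibinomial logistic regression.

Written from the generic weighted-least-squares recursion, deliberately
not sharing any code with the package's fit path, so it can serve as an
oracle for coefficient, dispersion and p-value agreement.
"""

import numpy as np
from scipy.special import expit
from scipy.stats import t as t_dist


def irls_quasibinomial(y, n, X, max_iter=100, tol=1e-12):
    """Fit successes y of totals n on design X by IRLS.

    Returns (beta, se, dispersion, p_values) where se and the two-sided
    p-values are dispersion-scaled with a t reference on n_obs - p degrees
    of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    n_obs, n_par = X.shape
    beta = np.zeros(n_par)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = n * mu * (1 - mu)
        z = eta + (y - n * mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = expit(eta)
    pearson = np.sum((y - n * mu) ** 2 / (n * mu * (1 - mu)))
    df = n_obs - n_par
    dispersion = pearson / df
    w = n * mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X) * dispersion
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2 * t_dist.sf(np.abs(tstat), df)
    return beta, se, dispersion, p
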