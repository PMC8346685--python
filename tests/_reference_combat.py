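"""Independent, loop-based reference implementation of parametric
empirical-Bayes location/scale batch harmonization (Johnson et al. 2007
equations), used only as a test oracle. Deliberately written with explicit
per-feature / per-batch Python loops, no shared code with the package."""

import numpy as np


def reference_combat(Y, batch, covars=None, restore_covariates=False, tol=1e-4, max_iter=100):
    """Harmonize Y (n_samples x n_features) across batches.

    covars: optional n_samples x p matrix (already centered/coded).
    Returns the adjusted data matrix.
    """
    Y = np.asarray(Y, dtype=float)
    n, G = Y.shape
    batches = list(dict.fromkeys(batch))
    idx_of = {b: [j for j in range(n) if batch[j] == b] for b in batches}
    p = 0 if covars is None else covars.shape[1]

    # design: batch one-hot then covariates
    D = np.zeros((n, len(batches) + p))
    for i, b in enumerate(batches):
        for j in idx_of[b]:
            D[j, i] = 1.0
    if p:
        D[:, len(batches):] = covars

    B = np.linalg.lstsq(D, Y, rcond=None)[0]
    w = np.array([len(idx_of[b]) for b in batches], dtype=float) / n
    alpha = np.zeros(G)
    for g in range(G):
        alpha[g] = sum(w[i] * B[i, g] for i in range(len(batches)))

    resid = Y - D @ B
    sigma = np.sqrt(np.mean(resid**2, axis=0))

    cov_term = covars @ B[len(batches):] if p else np.zeros_like(Y)
    Z = (Y - alpha[None, :] - cov_term) / sigma[None, :]

    out = np.empty_like(Y)
    for i, b in enumerate(batches):
        rows = idx_of[b]
        ni = len(rows)
        zb = Z[rows, :]
        ghat = np.array([np.mean(zb[:, g]) for g in range(G)])
        d2hat = np.array([np.mean((zb[:, g] - ghat[g]) ** 2) for g in range(G)])

        gbar = float(np.mean(ghat))
        t2 = float(np.var(ghat, ddof=1)) if G > 1 else 0.0
        m = float(np.mean(d2hat))
        s2 = float(np.var(d2hat, ddof=1)) if G > 1 else 0.0

        if s2 <= 1e-12:
            d2star = d2hat.copy()
            if t2 <= 1e-12:
                gstar = ghat.copy()
            else:
                gstar = ghat.copy()
                for _ in range(max_iter):
                    gnew = (ni * t2 * ghat + d2star * gbar) / (ni * t2 + d2star)
                    if np.max(np.abs(gnew - gstar)) < tol:
                        gstar = gnew
                        break
                    gstar = gnew
        else:
            lam = (2 * s2 + m * m) / s2
            theta = (m * s2 + m**3) / s2
            gstar = ghat.copy()
            d2star = d2hat.copy()
            for _ in range(max_iter):
                gnew = (ni * t2 * ghat + d2star * gbar) / (ni * t2 + d2star)
                ssq = np.array(
                    [np.sum((zb[:, g] - gnew[g]) ** 2) for g in range(G)]
                )
                dnew = (theta + 0.5 * ssq) / (ni / 2.0 + lam - 1.0)
                change = max(np.max(np.abs(gnew - gstar)), np.max(np.abs(dnew - d2star)))
                gstar, d2star = gnew, dnew
                if change < tol:
                    break

        for g in range(G):
            for j in rows:
                out[j, g] = (Z[j, g] - gstar[g]) / np.sqrt(d2star[g]) * sigma[g] + alpha[g]

    if restore_covariates and p:
        out = out + cov_term
    return out
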