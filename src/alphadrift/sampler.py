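"""Blocked Gibbs sampler for Gaussian multilevel regression.

Model:  y = X b + Z u_[g] + e,   e ~ N(0, sigma^2),
        u_i ~ N(0, diag(tau^2)) per grouping level i,
with N(0, 1) priors on every fixed effect and half-Normal(0, 1) priors on
sigma and each tau.  Fixed and varying coefficients have conjugate Gaussian
full conditionals; the scale parameters are updated by univariate slice
sampling on the log scale.  Designed for balanced within-subject EEG
designs (tens of subjects, hundreds of rows) where this mixes quickly.
"""

from __future__ import annotations

import numpy as np


def slice_sample(logp, x0: float, rng, w: float = 1.0,
                 max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logp(x0) - rng.exponential()
    left = x0 - w * rng.uniform()
    right = left + w
    for _ in range(max_steps):
        if logp(left) < logy:
            break
        left -= w
    for _ in range(max_steps):
        if logp(right) < logy:
            break
        right += w
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logp(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _draw_mvn(precision_chol: np.ndarray, lin: np.ndarray, rng):
    """Draw from N(P^-1 lin, P^-1) given chol(P) (lower)."""
    from scipy.linalg import solve_triangular
    tmp = solve_triangular(precision_chol, lin, lower=True)
    mean_part = solve_triangular(precision_chol.T, tmp, lower=False)
    noise = solve_triangular(precision_chol.T,
                             rng.standard_normal(len(lin)), lower=False)
    return mean_part + noise


def find_invariant_moves(X: np.ndarray, Z: np.ndarray,
                         groups: np.ndarray) -> list:
    """Likelihood-invariant translation directions between fixed and
    varying effects.

    Returns (j, k, c) triples where fixed column j restricted to subject i
    equals ``c[i]`` times varying column k (e.g. a between-subject factor
    column is the factor code times the varying intercept).  Along each
    such direction the likelihood is flat and only the priors are
    informative, which stalls naive Gibbs; an exact extra Gibbs step on the
    shift restores mixing.
    """
    S = int(groups.max()) + 1
    idx = [np.where(groups == i)[0] for i in range(S)]
    moves = []
    for j in range(X.shape[1]):
        for k in range(Z.shape[1]):
            c = np.zeros(S)
            ok = True
            for i in range(S):
                zi = Z[idx[i], k]
                xi = X[idx[i], j]
                denom = zi @ zi
                ci = (zi @ xi) / denom if denom > 0 else 0.0
                if np.max(np.abs(xi - ci * zi)) > 1e-10:
                    ok = False
                    break
                c[i] = ci
            if ok and np.any(c != 0):
                moves.append((j, k, c))
                break
    return moves


def gibbs_chain(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                groups: np.ndarray, n_warmup: int, n_draws: int, rng,
                prior_sd: float = 1.0, moves=None):
    """Run one chain; returns draws dict with 'beta' (draws, p),
    'sigma' (draws,), 'tau' (draws, q), 'u' (draws, S, q)."""
    n, p = X.shape
    q = Z.shape[1]
    S = int(groups.max()) + 1
    idx = [np.where(groups == i)[0] for i in range(S)]
    Xs = [X[ix] for ix in idx]
    Zs = [Z[ix] for ix in idx]
    ys = [y[ix] for ix in idx]
    ZtZ = np.stack([Zi.T @ Zi for Zi in Zs])          # (S, q, q)
    XtX = X.T @ X

    beta = np.linalg.lstsq(X.T @ X + np.eye(p), X.T @ y, rcond=None)[0]
    u = np.zeros((S, q))
    sigma = max(float(np.std(y - X @ beta)), 1e-3)
    tau = np.full(q, 0.3)

    out_beta = np.empty((n_draws, p))
    out_sigma = np.empty(n_draws)
    out_tau = np.empty((n_draws, q))
    out_u = np.empty((n_draws, S, q))

    eye_p = np.eye(p) / prior_sd ** 2
    for it in range(n_warmup + n_draws):
        inv_s2 = 1.0 / sigma ** 2
        # --- fixed effects ---
        Zu = np.einsum("nq,nq->n", Z, u[groups])
        P = XtX * inv_s2 + eye_p
        lin = X.T @ (y - Zu) * inv_s2
        beta = _draw_mvn(np.linalg.cholesky(P), lin, rng)

        # --- varying effects (batched over subjects) ---
        resid_f = y - X @ beta
        Pz = ZtZ * inv_s2 + np.diag(1.0 / tau ** 2)[None, :, :]
        rhs = np.stack([Zs[i].T @ resid_f[idx[i]] for i in range(S)])
        rhs *= inv_s2
        L = np.linalg.cholesky(Pz)                     # (S, q, q)
        mean = np.linalg.solve(Pz, rhs[:, :, None])[:, :, 0]
        eps = rng.standard_normal((S, q, 1))
        noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), eps)[:, :, 0]
        u = mean + noise

        # --- translation moves along beta_j + delta, u_{i,k} - delta*c_i —
        # exact Gibbs steps on the likelihood-invariant directions found by
        # find_invariant_moves; only the priors enter these conditionals.
        if moves is not None:
            for j, k, c in moves:
                prec = 1.0 / prior_sd ** 2 + (c @ c) / tau[k] ** 2
                lin = (-beta[j] / prior_sd ** 2
                       + (c @ u[:, k]) / tau[k] ** 2)
                delta = lin / prec + rng.standard_normal() / np.sqrt(prec)
                beta[j] += delta
                u[:, k] -= delta * c

        # --- residual scale (half-Normal(0,1) prior, log-scale slice) ---
        Zu = np.einsum("nq,nq->n", Z, u[groups])
        ssr = float(np.sum((y - X @ beta - Zu) ** 2))

        def logp_sigma(ls, _ssr=ssr):
            s = np.exp(ls)
            return -n * ls - _ssr / (2 * s ** 2) - s ** 2 / 2 + ls

        sigma = float(np.exp(slice_sample(logp_sigma, np.log(sigma), rng,
                                          w=0.3)))

        # --- varying-effect scales ---
        for k in range(q):
            ssk = float(np.sum(u[:, k] ** 2))

            def logp_tau(lt, _ssk=ssk):
                t = np.exp(lt)
                return -S * lt - _ssk / (2 * t ** 2) - t ** 2 / 2 + lt

            tau[k] = float(np.exp(slice_sample(logp_tau, np.log(tau[k]),
                                               rng, w=0.5)))

        if it >= n_warmup:
            j = it - n_warmup
            out_beta[j] = beta
            out_sigma[j] = sigma
            out_tau[j] = tau
            out_u[j] = u
    return {"beta": out_beta, "sigma": out_sigma, "tau": out_tau, "u": out_u}


def sample_posterior(y, X, Z, groups, n_chains: int = 4,
                     n_warmup: int = 500, n_draws: int = 1000,
                     seed: int = 0, prior_sd: float = 1.0):
    """Run ``n_chains`` independent chains; returns list of draw dicts."""
    moves = find_invariant_moves(X, Z, groups)
    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng([seed, 0xBAE5, c])
        chains.append(gibbs_chain(y, X, Z, groups, n_warmup, n_draws, rng,
                                  prior_sd=prior_sd, moves=moves))
    return chains
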