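"""Numba-compiled inner loop of the reversible-jump sampler.

One call advances a chain by ``n_retained * thin`` iterations (plus an
optional frozen-before-sampling adaptation phase) and records the beta
vector and sigma_beta at every thin-th iteration.  The state (gamma
implicitly via beta != 0 slots, beta, sigma_beta) is passed in and out so
chains can be extended deterministically with fresh per-segment seeds.

Move types: 0 add (beta drawn from its conditional prior, so prior and
proposal densities cancel in the acceptance ratio), 1 delete, 2 Gaussian
random-walk update of one included beta, 3 reflected random walk on
sigma_beta inside its uniform bounds.  Moves impossible in the current
state get zero weight and the remaining weights are renormalized; the
acceptance ratio uses the state-dependent normalized selection
probabilities.
"""

import numpy as np
from numba import njit

# log P(gamma | k) by model size is precomputed outside numba via betaln.


@njit(cache=True)
def _move_probs(k, F, sigma_fixed, w):
    """Normalized selection probabilities of the four moves at model size k."""
    p = np.empty(4)
    p[0] = w[0] if k < F else 0.0
    p[1] = w[1] if k > 0 else 0.0
    p[2] = w[2] if k > 0 else 0.0
    p[3] = 0.0 if sigma_fixed else w[3]
    s = p[0] + p[1] + p[2] + p[3]
    return p / s


@njit(cache=True)
def run_chain_kernel(
    X,              # (F, F) decay design
    Y,              # (F,) residuals
    beta,           # (F,) in/out current strengths (0 = excluded)
    gamma,          # (F,) int8 in/out inclusion indicators
    sigma_arr,      # (1,) in/out sigma_beta
    log_prior_k,    # (F+1,) log model prior by model size
    n_retained, thin, adapt_iters,
    w,              # (4,) base move weights
    beta_scale_arr,  # (1,) in/out random-walk scale for beta updates
    sigma_scale, sigma_lo, sigma_hi,
    sigma_fixed,    # bool: clamp sigma_beta (oracle comparisons)
    seed,
    out_beta,       # (n_retained, F) output samples
    out_sigma,      # (n_retained,) output sigma samples
    accept_counts,  # (4,) accepted per move type
    propose_counts,  # (4,) proposed per move type
):
    np.random.seed(seed)
    F = len(Y)
    mu = X @ (beta * gamma)
    resid = Y - mu
    ss = np.dot(resid, resid)  # current sum of squared residuals
    k = int(np.sum(gamma))
    sigma = sigma_arr[0]
    beta_scale = beta_scale_arr[0]
    sqb = 0.0  # sum of beta^2 over included (for sigma moves)
    for q in range(F):
        if gamma[q] == 1:
            sqb += beta[q] * beta[q]

    total = adapt_iters + n_retained * thin
    retained = 0
    for it in range(total):
        adapting = it < adapt_iters
        probs = _move_probs(k, F, sigma_fixed, w)
        u = np.random.random()
        move = 0
        c = probs[0]
        while u > c and move < 3:
            move += 1
            c += probs[move]

        if move == 0:
            # ADD: uniform over excluded fragments, beta* ~ N(0, sigma^2)
            q = np.random.randint(F)
            while gamma[q] == 1:
                q = np.random.randint(F)
            b = np.random.normal() * sigma
            # delta log-lik from mu -> mu + b * X[:, q]
            d_ss = 0.0
            for p in range(F):
                r_new = resid[p] - b * X[p, q]
                d_ss += r_new * r_new - resid[p] * resid[p]
            dll = -0.5 * d_ss
            # beta prior cancels with the proposal draw
            d_logprior = log_prior_k[k + 1] - log_prior_k[k]
            probs_new = _move_probs(k + 1, F, sigma_fixed, w)
            n_exc = F - k
            log_g = np.log(probs_new[1] / (k + 1)) - np.log(probs[0] / n_exc)
            log_mhr = dll + d_logprior + log_g
            propose_counts[0] += 1
            if np.log(np.random.random()) < log_mhr:
                accept_counts[0] += 1
                gamma[q] = 1
                beta[q] = b
                sqb += b * b
                for p in range(F):
                    resid[p] -= b * X[p, q]
                ss += d_ss
                k += 1

        elif move == 1:
            # DELETE: uniform over included; reverse move is a prior-draw add
            j = np.random.randint(k)
            q = -1
            cnt = -1
            for idx in range(F):
                if gamma[idx] == 1:
                    cnt += 1
                    if cnt == j:
                        q = idx
                        break
            b = beta[q]
            d_ss = 0.0
            for p in range(F):
                r_new = resid[p] + b * X[p, q]
                d_ss += r_new * r_new - resid[p] * resid[p]
            dll = -0.5 * d_ss
            d_logprior = log_prior_k[k - 1] - log_prior_k[k]
            probs_new = _move_probs(k - 1, F, sigma_fixed, w)
            n_exc_new = F - (k - 1)
            log_g = np.log(probs_new[0] / n_exc_new) - np.log(probs[1] / k)
            log_mhr = dll + d_logprior + log_g
            propose_counts[1] += 1
            if np.log(np.random.random()) < log_mhr:
                accept_counts[1] += 1
                gamma[q] = 0
                beta[q] = 0.0
                sqb -= b * b
                for p in range(F):
                    resid[p] += b * X[p, q]
                ss += d_ss
                k -= 1

        elif move == 2:
            # UPDATE one included beta by symmetric Gaussian random walk
            j = np.random.randint(k)
            q = -1
            cnt = -1
            for idx in range(F):
                if gamma[idx] == 1:
                    cnt += 1
                    if cnt == j:
                        q = idx
                        break
            b_old = beta[q]
            b_new = b_old + np.random.normal() * beta_scale
            db = b_new - b_old
            d_ss = 0.0
            for p in range(F):
                r_new = resid[p] - db * X[p, q]
                d_ss += r_new * r_new - resid[p] * resid[p]
            dll = -0.5 * d_ss
            d_logprior = -0.5 * (b_new * b_new - b_old * b_old) / (sigma * sigma)
            log_mhr = dll + d_logprior
            propose_counts[2] += 1
            accepted = np.log(np.random.random()) < log_mhr
            if accepted:
                accept_counts[2] += 1
                beta[q] = b_new
                sqb += b_new * b_new - b_old * b_old
                for p in range(F):
                    resid[p] -= db * X[p, q]
                ss += d_ss
            if adapting:
                # Robbins-Monro toward ~0.3 acceptance; frozen afterwards
                if accepted:
                    beta_scale *= np.exp(0.02)
                else:
                    beta_scale *= np.exp(-0.02 * 0.3 / 0.7)
                if beta_scale < 1e-4:
                    beta_scale = 1e-4
                if beta_scale > 10.0:
                    beta_scale = 10.0

        else:
            # SIGMA: reflected random walk inside (lo, hi); flat hyper-prior,
            # but the beta-prior density of the k included strengths changes
            s_new = sigma + np.random.normal() * sigma_scale
            span = sigma_hi - sigma_lo
            # reflect into the interval
            for _ in range(100):
                if s_new < sigma_lo:
                    s_new = 2 * sigma_lo - s_new
                elif s_new > sigma_hi:
                    s_new = 2 * sigma_hi - s_new
                else:
                    break
            log_mhr = -k * (np.log(s_new) - np.log(sigma)) - 0.5 * sqb * (
                1.0 / (s_new * s_new) - 1.0 / (sigma * sigma)
            )
            propose_counts[3] += 1
            if np.log(np.random.random()) < log_mhr:
                accept_counts[3] += 1
                sigma = s_new

        if not adapting and (it - adapt_iters + 1) % thin == 0:
            for p in range(F):
                out_beta[retained, p] = beta[p] * gamma[p]
            out_sigma[retained] = sigma
            retained += 1

    sigma_arr[0] = sigma
    beta_scale_arr[0] = beta_scale
    return retained
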