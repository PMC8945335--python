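"""Gibbs sampler kernel for the binary admixture model (numba-compiled).

Model: cluster-by-locus band frequencies theta_kl ~ Beta(1, 1); per
individual admixture q_i ~ Dirichlet(1, ..., 1); per individual-locus
allocation z_il ~ Categorical(q_i); band x_il ~ Bernoulli(theta_{z_il, l}).
The sampler alternates the full conditionals of z, theta and q, and
records thinned draws of theta and q plus the marginal (z-summed) data
log-likelihood for each retained draw.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_admixture(x, K, n_burnin, n_sample, thin, seed):
    np.random.seed(seed)
    n, L = x.shape
    n_keep = max(n_sample // thin, 1)

    theta = np.full((K, L), 0.5)
    q = np.full((n, K), 1.0 / K)
    z = np.empty((n, L), np.int64)
    for i in range(n):
        for l in range(L):
            z[i, l] = np.random.randint(0, K)

    band_ct = np.zeros((K, L))
    tot_ct = np.zeros((K, L))
    alloc_ct = np.zeros((n, K))

    theta_out = np.empty((n_keep, K, L))
    q_out = np.empty((n_keep, n, K))
    ll_out = np.empty(n_keep)
    kept = 0

    probs = np.empty(K)
    n_iter = n_burnin + n_sample
    for it in range(n_iter):
        # conjugate updates of theta and q given allocations
        band_ct[:, :] = 0.0
        tot_ct[:, :] = 0.0
        alloc_ct[:, :] = 0.0
        for i in range(n):
            for l in range(L):
                k = z[i, l]
                tot_ct[k, l] += 1.0
                alloc_ct[i, k] += 1.0
                if x[i, l] == 1:
                    band_ct[k, l] += 1.0
        for k in range(K):
            for l in range(L):
                theta[k, l] = np.random.beta(
                    1.0 + band_ct[k, l], 1.0 + tot_ct[k, l] - band_ct[k, l]
                )
        for i in range(n):
            s = 0.0
            for k in range(K):
                g = np.random.gamma(1.0 + alloc_ct[i, k], 1.0)
                q[i, k] = g
                s += g
            for k in range(K):
                q[i, k] /= s

        # allocation update
        for i in range(n):
            for l in range(L):
                s = 0.0
                if x[i, l] == 1:
                    for k in range(K):
                        probs[k] = q[i, k] * theta[k, l]
                        s += probs[k]
                else:
                    for k in range(K):
                        probs[k] = q[i, k] * (1.0 - theta[k, l])
                        s += probs[k]
                u = np.random.random() * s
                acc = 0.0
                kk = K - 1
                for k in range(K):
                    acc += probs[k]
                    if u <= acc:
                        kk = k
                        break
                z[i, l] = kk

        if it >= n_burnin and (it - n_burnin) % thin == 0 and kept < n_keep:
            ll = 0.0
            for i in range(n):
                for l in range(L):
                    s = 0.0
                    if x[i, l] == 1:
                        for k in range(K):
                            s += q[i, k] * theta[k, l]
                    else:
                        for k in range(K):
                            s += q[i, k] * (1.0 - theta[k, l])
                    ll += np.log(s)
            theta_out[kept] = theta
            q_out[kept] = q
            ll_out[kept] = ll
            kept += 1

    return theta_out[:kept], q_out[:kept], ll_out[:kept]
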