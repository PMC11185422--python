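"""Independent brute-force oracles for the observer machinery.

Everything here is computed with explicit sums of scipy multivariate-normal
densities, one hypothesis at a time, deliberately sharing no code with the
vectorized implementation under test.
"""

import numpy as np
from scipy.stats import multivariate_normal

_I2 = np.eye(2)


def _pdf(d, mu):
    return multivariate_normal.pdf(d, mean=mu, cov=_I2)


def marginal_orientation_posterior_left(d, c_grid):
    """p(S=left | d) marginalized over a uniform grid of strengths."""
    num_l = sum(_pdf(d, [c, 0.0]) for c in c_grid) / len(c_grid)
    num_r = sum(_pdf(d, [0.0, c]) for c in c_grid) / len(c_grid)
    return num_l / (num_l + num_r)


def hierarchical_orientation_posterior_left(d, c_grid):
    """p(S=left | d) at the per-orientation most likely strengths."""
    best_l = max(_pdf(d, [c, 0.0]) for c in c_grid)
    best_r = max(_pdf(d, [0.0, c]) for c in c_grid)
    return best_l / (best_l + best_r)


def visibility_log_one_minus_p_neutral(model_id, d, c_grid):
    """log(1 - p(N | d)) for visibility observers 5, 6, 7."""
    k = len(c_grid)
    p_signal = 0.5 * (
        sum(_pdf(d, [c, 0.0]) for c in c_grid) / k
        + sum(_pdf(d, [0.0, c]) for c in c_grid) / k
    )
    if model_id == 5:
        p_neutral = _pdf(d, [0.0, 0.0])
    elif model_id == 6:
        p_neutral = sum(_pdf(d, [c / 2, c / 2]) for c in c_grid) / k
    else:  # model 7: all hypotheses at the chosen orientation's best strength
        dens_l = [_pdf(d, [c, 0.0]) for c in c_grid]
        dens_r = [_pdf(d, [0.0, c]) for c in c_grid]
        k_star = (int(np.argmax(dens_l)) if max(dens_l) >= max(dens_r)
                  else int(np.argmax(dens_r)))
        c_star = c_grid[k_star]
        p_neutral = _pdf(d, [c_star / 2, c_star / 2])
        p_signal = 0.5 * (_pdf(d, [c_star, 0.0]) + _pdf(d, [0.0, c_star]))
    # both hypotheses carry prior 0.5, which cancels
    return np.log(p_signal) - np.log(p_neutral + p_signal)


def enumerate_monotone_fit(p_correct_grid, n_correct, n_incorrect, c_grid, eps=1e-6):
    """Exhaustive search over all nondecreasing strength assignments."""
    import itertools

    p = np.clip(np.asarray(p_correct_grid, float), eps, 1 - eps)
    best_val, best_ks = -np.inf, None
    K, L = len(p), len(n_correct)
    for ks in itertools.combinations_with_replacement(range(K), L):
        val = sum(
            n_correct[l] * np.log(p[k]) + n_incorrect[l] * np.log(1 - p[k])
            for l, k in enumerate(ks)
        )
        if val > best_val + 1e-12:
            best_val, best_ks = val, ks
    return np.asarray(c_grid)[list(best_ks)], best_val
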