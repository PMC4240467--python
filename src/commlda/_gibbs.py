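"""Numba-compiled inner loops of the collapsed Gibbs sampler.

All randomness enters through a per-sweep array of uniforms drawn by the
caller from a seeded generator, so runs are reproducible bit-for-bit.
"""

import numpy as np
from numba import njit


@njit(fastmath=False)
def gibbs_sweep(
    z,
    token_unit,
    token_species,
    n_uc,
    m_cs,
    m_c,
    d,
    obs_count,
    is_restricted,
    sru_flat,
    sru_off,
    alpha,
    gamma,
    n_species,
    u,
):
    """One full sweep over all tokens, updating counts in place.

    For fully observed units the conditional is the standard collapsed form
    p(c) ∝ (n_uc + α)(m_cs + γ)/(m_c + Sγ).  For units with masked species
    the φ-normaliser is restricted to that unit's observed species:
    ``d[l, c]`` holds Σ_{s observed at l} m_cs[c, s] and ``obs_count[l]`` the
    number of observed species, so the denominator is d[l, c] + obs_count·γ.
    ``sru_flat``/``sru_off`` is a CSR list of restricted units observing each
    species, used to keep ``d`` consistent as tokens move.
    """
    n_tokens = z.shape[0]
    C = m_c.shape[0]
    p = np.empty(C, dtype=np.float64)
    for i in range(n_tokens):
        l = token_unit[i]
        s = token_species[i]
        c_old = z[i]
        n_uc[l, c_old] -= 1
        m_cs[c_old, s] -= 1
        m_c[c_old] -= 1
        for k in range(sru_off[s], sru_off[s + 1]):
            d[sru_flat[k], c_old] -= 1
        total = 0.0
        if is_restricted[l]:
            sg = obs_count[l] * gamma
            for c in range(C):
                p[c] = (n_uc[l, c] + alpha) * (m_cs[c, s] + gamma) / (d[l, c] + sg)
                total += p[c]
        else:
            sg = n_species * gamma
            for c in range(C):
                p[c] = (n_uc[l, c] + alpha) * (m_cs[c, s] + gamma) / (m_c[c] + sg)
                total += p[c]
        r = u[i] * total
        c_new = 0
        acc = p[0]
        while r > acc and c_new < C - 1:
            c_new += 1
            acc += p[c_new]
        z[i] = c_new
        n_uc[l, c_new] += 1
        m_cs[c_new, s] += 1
        m_c[c_new] += 1
        for k in range(sru_off[s], sru_off[s + 1]):
            d[sru_flat[k], c_new] += 1


@njit(fastmath=False)
def foldin_sweep(z, token_unit, token_species, n_uc, phi, denom, alpha, u):
    """Sweep over new-unit tokens with φ held fixed.

    p(c) ∝ (n_uc[l, c] + α) · φ[c, s] / denom[l, c], where denom restricts
    φ's mass to the species observed at the new unit.
    """
    n_tokens = z.shape[0]
    C = n_uc.shape[1]
    p = np.empty(C, dtype=np.float64)
    for i in range(n_tokens):
        l = token_unit[i]
        s = token_species[i]
        c_old = z[i]
        n_uc[l, c_old] -= 1
        total = 0.0
        for c in range(C):
            p[c] = (n_uc[l, c] + alpha) * phi[c, s] / denom[l, c]
            total += p[c]
        r = u[i] * total
        c_new = 0
        acc = p[0]
        while r > acc and c_new < C - 1:
            c_new += 1
            acc += p[c_new]
        z[i] = c_new
        n_uc[l, c_new] += 1
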