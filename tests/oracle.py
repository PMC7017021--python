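"""Independent brute-force reference implementation.

Everything here is written with plain Python floats, ``math`` and explicit
double loops — no numpy, no shared code with the package — so it can serve
as an oracle for the vectorized spectrum and likelihood pipeline at small
(Ne, Ns).
"""

import math


def oracle_sojourn(z, mu, gamma, L_c=1.0):
    if gamma == 0.0:
        return 2.0 * mu * L_c / z
    if -4.0 * gamma > 700.0:  # avoid exp overflow for strong purifying selection
        # (1 - e^{-4g(1-z)}) / (1 - e^{-4g}) = e^{4gz} (1 - e^{4g(1-z)}) / (1 - e^{4g})
        ratio = (
            math.exp(4.0 * gamma * z)
            * (1.0 - math.exp(4.0 * gamma * (1.0 - z)))
            / (1.0 - math.exp(4.0 * gamma))
        )
        return 2.0 * mu * L_c * ratio / (z * (1.0 - z))
    num = 1.0 - math.exp(-4.0 * gamma * (1.0 - z))
    den = 1.0 - math.exp(-4.0 * gamma)
    return 2.0 * mu * L_c * num / (z * (1.0 - z) * den)


def oracle_sample_probs(ne, ns, theta, gamma, f_c=1.0):
    """Unfolded sample probabilities for k = 1..Ns-1 by explicit double sum."""
    mu = theta / (4.0 * ne)
    out = []
    for k in range(1, ns):
        total = 0.0
        for j in range(1, 2 * ne):
            z = j / (2.0 * ne)
            g = oracle_sojourn(z, mu, gamma, f_c)
            binom = math.comb(ns, k) * z**k * (1.0 - z) ** (ns - k)
            total += g * binom
        out.append(total)
    return out


def oracle_folded_probs(ne, ns, theta, dfe_classes, alpha_per_class=None):
    """Folded class probabilities [p0, p1, .., p_{Ns//2}].

    ``dfe_classes``: [(gamma_or_None, f), ...] for the non-neutral classes
    (None = lethal); the neutral class fills the remaining fraction.
    ``alpha_per_class``: multiplier per folded class 1..Ns//2.
    """
    nf = ns // 2
    f0 = 1.0 - sum(f for _, f in dfe_classes)
    classes = [(0.0, f0)] + list(dfe_classes)
    poly = []
    for m in range(1, nf + 1):
        total = 0.0
        for gamma, f in classes:
            if gamma is None or f == 0.0:
                continue
            pk = oracle_sample_probs(ne, ns, theta, gamma, f)
            total += pk[m - 1]
            if ns - m != m:
                total += pk[ns - m - 1]
        if alpha_per_class is not None:
            total *= alpha_per_class[m - 1]
        poly.append(total)
    p0 = 1.0 - sum(poly)
    return [p0] + poly


def oracle_loglik(k0, counts, probs):
    """Multinomial log-likelihood sum k log p (no coefficient)."""
    ll = 0.0
    if k0 > 0:
        ll += k0 * math.log(probs[0])
    for m, k in enumerate(counts, start=1):
        if k > 0:
            ll += k * math.log(probs[m])
    return ll


def oracle_joint_loglik(
    ne, ns, theta, dfe_classes, alpha_per_class, sfs4d, sfs_si
):
    """Joint 4D (selection) + SI (neutral) log-likelihood; each sfs is
    (k0, [k_1..k_{Ns//2}])."""
    p4 = oracle_folded_probs(ne, ns, theta, dfe_classes, alpha_per_class)
    psi = oracle_folded_probs(ne, ns, theta, [], alpha_per_class)
    return oracle_loglik(sfs4d[0], sfs4d[1], p4) + oracle_loglik(
        sfs_si[0], sfs_si[1], psi
    )
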