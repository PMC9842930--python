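"""Stand-alone brute-force recomputation of the NSP measures.

Deliberately naive: its own eigendecomposition call, modules kept as
Python lists of member indices, explicit sign-split loops, and H_i /
regional components accumulated term by term. Used only as an
independent check of the library's vectorized pipeline.
"""

import numpy as np

TIE = 1e-12


def oracle_nsp(c, variant="quadratic"):
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    lam_raw, u_raw = np.linalg.eigh(c)
    order = sorted(range(n), key=lambda i: -lam_raw[i])
    lam = [max(lam_raw[i], 0.0) for i in order]
    u = u_raw[:, order]

    modules = [list(range(n))]
    h = []
    p_list = []
    for i in range(n):
        if i > 0:
            new_modules = []
            for mod in modules:
                pos = [j for j in mod if u[j, i] >= -TIE]
                neg = [j for j in mod if u[j, i] < -TIE]
                if pos:
                    new_modules.append(pos)
                if neg:
                    new_modules.append(neg)
            modules = new_modules
        m_i = len(modules)
        p_i = 0.0
        for mod in modules:
            p_i += abs(len(mod) - n / m_i)
        p_i /= n
        lam_term = lam[i] ** 2 if variant == "quadratic" else lam[i]
        h.append(lam_term * m_i * (1.0 - p_i) / n)
        p_list.append(p_i)

    h_in = h[0] / n
    h_se = sum(h[1:]) / n
    h_b = h_in - h_se

    h_in_j = [h[0] * u[j, 0] ** 2 for j in range(n)]
    h_se_j = [
        sum(h[i] * u[j, i] ** 2 for i in range(1, n)) for j in range(n)
    ]
    return {
        "lambdas": np.array(lam),
        "h": np.array(h),
        "p": np.array(p_list),
        "h_in": h_in,
        "h_se": h_se,
        "h_b": h_b,
        "h_in_j": np.array(h_in_j),
        "h_se_j": np.array(h_se_j),
    }
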