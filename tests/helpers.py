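"""Shared test helpers and independent oracles."""

import numpy as np

from scetr.finemap import log_abf
from scetr.genotype_qc import GenotypeTable


def tr_table(a1, a2, ids=None) -> GenotypeTable:
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n, m = a1.shape
    return GenotypeTable(
        samples=[f"s{i}" for i in range(n)],
        variant_ids=ids or [f"tr{j}" for j in range(m)],
        kind="tr",
        allele1=a1,
        allele2=a2,
    )


def bruteforce_coloc(b1, s1, b2, s2, p1=1e-4, p2=1e-4, p12=1e-5,
                     W1=0.0225, W2=0.0225):
    """Oracle: explicit enumeration over all (causal-in-1, causal-in-2)
    configuration pairs, collapsed to the five hypotheses."""
    abf1 = np.exp(log_abf(np.asarray(b1), np.asarray(s1), W1))
    abf2 = np.exp(log_abf(np.asarray(b2), np.asarray(s2), W2))
    J = abf1.size
    L = dict.fromkeys("01234", 0.0)
    L["0"] = 1.0
    for i in range(J):
        L["1"] += p1 * abf1[i]
        L["2"] += p2 * abf2[i]
        L["4"] += p12 * abf1[i] * abf2[i]
        for j in range(J):
            if i != j:
                L["3"] += p1 * p2 * abf1[i] * abf2[j]
    total = sum(L.values())
    return {f"H{k}": v / total for k, v in L.items()}
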