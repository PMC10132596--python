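"""Independent scalar reference for the outranking indices.

Deliberately naive: pure-Python loops and branch-by-branch transcription of
the index definitions, with no shared code or vectorization from the package.
Used to cross-check the production engine on randomized instances.
"""

from __future__ import annotations


def ref_concordance(a: float, b: float, q: float, p: float) -> float:
    if a >= b - q:
        return 1.0
    if a <= b - p:
        return 0.0
    return (a - (b - p)) / (p - q)


def ref_discordance(a: float, b: float, p: float, v: float) -> float:
    deficit = b - a
    if deficit <= p:
        return 0.0
    if deficit >= v:
        return 1.0
    return (deficit - p) / (v - p)


def ref_sigma(avals, bvals, q: float, p: float, v: float, weights) -> float:
    """Credibility that profile `avals` outranks profile `bvals`."""
    big_c = 0.0
    for a, b, w in zip(avals, bvals, weights):
        big_c += w * ref_concordance(a, b, q, p)
    sigma = big_c
    for a, b in zip(avals, bvals):
        d = ref_discordance(a, b, p, v)
        if d >= 1.0:
            return 0.0
        if d > big_c:
            sigma *= (1.0 - d) / (1.0 - big_c)
    return sigma
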