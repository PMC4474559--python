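"""Independent brute-force oracles for the disparity metrics.

Deliberately written with plain Python loops and ``math`` only, so they share
no code path with the package's vectorised implementations.
"""

import math


def oracle_led(les):
    return max(les) - min(les)


def oracle_ler(les):
    return max(les) / min(les)


def oracle_md(les, include_reference=True):
    best = max(les)
    total = 0.0
    for v in les:
        total += best - v
    n = len(les) if include_reference else len(les) - 1
    return total / n if n > 0 else 0.0


def oracle_id(les, include_reference=True):
    return 100.0 * oracle_md(les, include_reference) / max(les)


def oracle_weighted_mean(les, pops):
    num = 0.0
    den = 0.0
    for v, w in zip(les, pops):
        num += v * w
        den += w
    return num / den


def oracle_bgv(les, pops):
    mu = oracle_weighted_mean(les, pops)
    total_pop = sum(pops)
    out = 0.0
    for v, w in zip(les, pops):
        out += (w / total_pop) * (v - mu) ** 2
    return out


def oracle_bgv_expanded(les, int_pops):
    """Unweighted-expansion cross-check: replicate each country int_pops[i]
    times and take the plain population variance of the expanded list."""
    expanded = []
    for v, w in zip(les, int_pops):
        expanded.extend([v] * int(w))
    mu = sum(expanded) / len(expanded)
    return sum((x - mu) ** 2 for x in expanded) / len(expanded)


def oracle_theil(les, pops):
    mu = oracle_weighted_mean(les, pops)
    total_pop = sum(pops)
    out = 0.0
    for v, w in zip(les, pops):
        out += (w / total_pop) * (v / mu) * math.log(v / mu)
    return out


def oracle_mld(les, pops):
    mu = oracle_weighted_mean(les, pops)
    total_pop = sum(pops)
    out = 0.0
    for v, w in zip(les, pops):
        out += (w / total_pop) * math.log(mu / v)
    return out


def oracle_sti(les, pops, scale=1.0):
    return scale * (oracle_theil(les, pops) + oracle_mld(les, pops)) / 2.0
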