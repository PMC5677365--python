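"""Independent straight-line transcription of the classification rules.

Everything here is written from the definitions, gene by gene, with
plain loops and the closed-form df=2 Student tail — deliberately sharing
no code with the package, so it can serve as an oracle for
pipeline-vs-definition equivalence tests.
"""

from __future__ import annotations

import math

from scipy import stats


def t_p(a: list[float], b: list[float]) -> float:
    """Two-sided pooled-variance Student t p-value via the closed-form
    df=2 tail when possible, scipy otherwise."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss = sum((x - m1) ** 2 for x in a) + sum((x - m2) ** 2 for x in b)
    df = n1 + n2 - 2
    sp2 = ss / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0.0:
        return 1.0 if m1 == m2 else 0.0
    t = abs(m1 - m2) / se
    if df == 2:
        # P(|T| > t) = 1 - t / sqrt(2 + t^2) for Student t, df = 2
        return 1.0 - t / math.sqrt(2.0 + t * t)
    return 2.0 * stats.t.sf(t, df)


def classify(
    fcs: dict[str, dict[str, list[float]]],
    alpha: float = 0.05,
    mid_tol: float = 1e-9,
):
    """fcs: gene -> strain role -> replicate FC list, with roles
    WT / ASYM_A / ASYM_B / DOUBLE.  Returns (responsive, mid, clusters)
    where clusters maps gene -> 'I' | 'II' | 'III' | 'UNASSIGNED'."""
    fca = {
        g: {role: sum(v) / len(v) for role, v in roles.items()}
        for g, roles in fcs.items()
    }

    responsive = set()
    for g in fcs:
        if t_p(fcs[g]["WT"], fcs[g]["DOUBLE"]) < alpha:
            responsive.add(g)

    mid = set()
    for g in sorted(responsive):
        wt, dbl = fca[g]["WT"], fca[g]["DOUBLE"]
        span = abs(wt - dbl)
        if span <= 1e-12 * max(1.0, abs(wt), abs(dbl)):
            continue  # betweenness undefined
        ok = True
        for asym in ("ASYM_A", "ASYM_B"):
            a = fca[g][asym]
            m = (abs(a - wt) + abs(a - dbl)) / span
            if m > 1.0 + mid_tol:
                ok = False
        if ok:
            mid.add(g)

    def gss_of(g: str, asym: str) -> float:
        a, wt, dbl = fca[g][asym], fca[g]["WT"], fca[g]["DOUBLE"]
        num, den = abs(a - dbl), abs(a - wt)
        if den == 0.0:
            return math.inf
        if num == 0.0:
            return -math.inf
        return math.log2(num / den)

    sig = {}
    for g in mid:
        for asym in ("ASYM_A", "ASYM_B"):
            sig[(g, asym, "WT")] = t_p(fcs[g][asym], fcs[g]["WT"]) < alpha
            sig[(g, asym, "DOUBLE")] = t_p(fcs[g][asym], fcs[g]["DOUBLE"]) < alpha

    cluster_ii = {
        g
        for g in mid
        if all(
            sig[(g, asym, ref)]
            for asym in ("ASYM_A", "ASYM_B")
            for ref in ("WT", "DOUBLE")
        )
    }

    finite = [
        s
        for g in cluster_ii
        for asym in ("ASYM_A", "ASYM_B")
        for s in [gss_of(g, asym)]
        if math.isfinite(s)
    ]
    gss_max = max(finite) if finite else None
    gss_min = min(finite) if finite else None

    cluster_iii, cluster_i = set(), set()
    if finite:
        for g in mid - cluster_ii:
            if all(
                not sig[(g, asym, "WT")]
                and sig[(g, asym, "DOUBLE")]
                and gss_of(g, asym) > gss_max
                for asym in ("ASYM_A", "ASYM_B")
            ):
                cluster_iii.add(g)
        for g in mid - cluster_ii - cluster_iii:
            if all(
                sig[(g, asym, "WT")]
                and not sig[(g, asym, "DOUBLE")]
                and gss_of(g, asym) < gss_min
                for asym in ("ASYM_A", "ASYM_B")
            ):
                cluster_i.add(g)

    clusters = {}
    for g in mid:
        if g in cluster_ii:
            clusters[g] = "II"
        elif g in cluster_iii:
            clusters[g] = "III"
        elif g in cluster_i:
            clusters[g] = "I"
        else:
            clusters[g] = "UNASSIGNED"
    return responsive, mid, clusters
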