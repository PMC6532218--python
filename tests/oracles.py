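"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (per-pixel loops, pairwise counts,
hand product-limit tabulation) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import numpy as np

# class / zone codes mirrored as plain ints so the oracle stays independent
NON_TISSUE, NEGATIVE, WEAK, MODERATE, STRONG = 0, 1, 2, 3, 4
Z_NON, Z_INTRA, Z_CAP, Z_PARA, Z_INTER = 0, 1, 2, 3, 4


def classify_loop(dab, tissue, t_pos, t_weak_mod, t_mod_strong):
    h, w = dab.shape
    out = np.zeros((h, w), dtype=int)
    for i in range(h):
        for j in range(w):
            if not tissue[i, j]:
                out[i, j] = NON_TISSUE
            elif dab[i, j] >= t_mod_strong:
                out[i, j] = STRONG
            elif dab[i, j] >= t_weak_mod:
                out[i, j] = MODERATE
            elif dab[i, j] >= t_pos:
                out[i, j] = WEAK
            else:
                out[i, j] = NEGATIVE
    return out


def percent_sa_loop(positive, tissue):
    pos = 0
    tot = 0
    for i in range(positive.shape[0]):
        for j in range(positive.shape[1]):
            if tissue[i, j]:
                tot += 1
                if positive[i, j]:
                    pos += 1
    return 100.0 * pos / tot


def zone_loop(nuclei_mask, tissue, um_per_px, cyto, cap, para):
    """Per-pixel nearest-nucleus-distance zoning (no nest closing):
    consecutive shells of the distance to the nearest nucleus pixel."""
    h, w = nuclei_mask.shape
    nuc = [(i, j) for i in range(h) for j in range(w) if nuclei_mask[i, j]]
    out = np.zeros((h, w), dtype=int)
    for i in range(h):
        for j in range(w):
            if not tissue[i, j]:
                out[i, j] = Z_NON
                continue
            d = min((np.hypot(i - a, j - b) for a, b in nuc),
                    default=np.inf) * um_per_px
            if d <= cyto:
                out[i, j] = Z_INTRA
            elif d <= cyto + cap:
                out[i, j] = Z_CAP
            elif d <= cyto + cap + para:
                out[i, j] = Z_PARA
            else:
                out[i, j] = Z_INTER
    return out


def mann_whitney_u_pairs(a, b):
    """U for sample a by pairwise counting: #(a>b) + 0.5*#(a==b)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def kruskal_h(values, groups):
    """Rank formula with tie correction, computed from first principles."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    ranks = np.empty(len(values))
    i = 0
    sorted_v = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank (1-based)
        i = j
    n = len(values)
    h = 0.0
    for g in set(groups):
        sel = [k for k in range(n) if groups[k] == g]
        h += ranks[sel].sum() ** 2 / len(sel)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    ct = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    return h / ct if ct > 0 else 0.0


def km_hand(times, events):
    """Product-limit estimator tabulated by hand over unique event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    event_times = np.unique(times[events])
    s = 1.0
    steps = []
    for t in event_times:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / at_risk
        steps.append((t, s))
    return steps


def km_survival_at(steps, t):
    s = 1.0
    for tt, ss in steps:
        if tt <= t:
            s = ss
    return s


def logrank_hand(times, events, groups):
    """Observed-minus-expected tabulation with hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & groups).sum())
        d = int(((times == t) & events).sum())
        d1 = int(((times == t) & events & groups).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0
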