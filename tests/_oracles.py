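"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: position-set and
per-base expansions for interval/track arithmetic, full enumeration for the
rank test, and a regex-free nested-loop matcher for IUPAC scanning.
"""

import itertools

import numpy as np

from methsite.motifs import IUPAC, reverse_complement


def mw_enumeration_oracle(x, y, alternative):
    """Exact Mann-Whitney p by enumerating all C(n+m, n) assignments (no ties)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    u_obs = sum(sum(1 for b in y if a > b) for a in x)
    us = []
    for combo in itertools.combinations(range(n + m), n):
        xs = {pooled[i] for i in combo}
        us.append(sum(sum(1 for b in pooled if b not in xs and a > b) for a in xs))
    us = np.array(us)
    total = len(us)
    p_less = (us <= u_obs).sum() / total
    p_greater = (us >= u_obs).sum() / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def oracle_scan(sequence, iupac, strands="both"):
    """Position-by-position nested-loop IUPAC matcher; returns {(start, strand)}."""
    seq = sequence.upper()

    def matches_at(pat, pos):
        for k, code in enumerate(pat):
            if seq[pos + k] not in IUPAC[code]:
                return False
        return True

    hits = set()
    w = len(iupac)
    rc = reverse_complement(iupac)
    for i in range(len(seq) - w + 1):
        if matches_at(iupac, i):
            hits.add((i, "+"))
        if strands == "both" and matches_at(rc, i):
            hits.add((i, "-"))
    return hits


def per_base_expand(track, chrom, length):
    """Per-base view of a binned track (NaN for missing bins)."""
    return np.repeat(track.data[chrom], track.bin_size)[:length]


def oracle_mean(track, region, length):
    base = per_base_expand(track, region.chrom, length)[region.start : region.end]
    finite = base[np.isfinite(base)]
    return float("nan") if finite.size == 0 else float(finite.mean())
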