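"""Independent straight-from-formula oracles used to cross-check the package.

Everything here is written directly from the defining equations with plain
Python loops, independently of the library's code paths.
"""

import math


def bf_count(seq: str) -> dict:
    """Brute-force triplet scan (DNA in, RNA codons out, no exclusions)."""
    seq = seq.upper().replace("U", "T")
    assert len(seq) % 3 == 0
    out: dict = {}
    for i in range(0, len(seq), 3):
        tri = seq[i:i + 3]
        if any(b not in "ACGT" for b in tri):
            continue
        codon = tri.replace("T", "U")
        out[codon] = out.get(codon, 0) + 1
    return out


def bf_rscu(counts: dict, families: dict, zero_sub: float = 0.5) -> dict:
    """RSCU_ij = X_ij / ((1/n_i) * sum_j X_ij), zeros replaced by 0.5."""
    out = {}
    for aa, codons in families.items():
        if len(codons) < 2:
            continue
        x = [counts.get(c, 0) or zero_sub for c in codons]
        total = 0.0
        for xi in x:
            total += xi
        for c, xi in zip(codons, x):
            out[c] = xi / (total / len(codons))
    return out


def bf_scuo(counts: dict, families: dict):
    """Per-family 1 - H/Hmax; gene value = unweighted family mean."""
    per = {}
    for aa, codons in families.items():
        n_i = len(codons)
        if n_i < 2:
            continue
        x = [counts.get(c, 0) for c in codons]
        n = sum(x)
        if n == 0:
            continue
        h = 0.0
        for xi in x:
            if xi > 0:
                p = xi / n
                h -= p * math.log2(p)
        per[aa] = 1.0 - h / math.log2(n_i)
    value = sum(per.values()) / len(per) if per else float("nan")
    return value, per


def bf_homozygosity(x):
    """F = (n * sum p^2 - 1) / (n - 1); None when unusable."""
    n = sum(x)
    if n < 2:
        return None
    s = 0.0
    for xi in x:
        s += (xi / n) ** 2
    f = (n * s - 1.0) / (n - 1.0)
    return f if f > 0 else None


def bf_pearson(x, y):
    """Pearson r and two-tailed p via the t transform with n-2 df."""
    from scipy.stats import t as tdist
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * tdist.sf(abs(tstat), n - 2)
    return r, p


def random_count_table(rng, families: dict, max_count: int = 20) -> dict:
    """A random small codon count table over all sense codons."""
    counts = {}
    for codons in families.values():
        for c in codons:
            n = int(rng.integers(0, max_count + 1))
            if n:
                counts[c] = n
    return counts
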