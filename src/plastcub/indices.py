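"""Per-gene codon usage indices: RSCU, SCUO, ENC, CAI and the MILC proxy.

Definitions
-----------
RSCU_ij = X_ij / ((1/n_i) * sum_j X_ij) for codon j of family i with
degeneracy n_i; a zero count is replaced by 0.5 before the computation, so
family sums always equal the degeneracy and no codon has RSCU = 0.

SCUO_i = 1 - H_i / log2(n_i) with H_i the Shannon entropy of the family's
codon usage; the gene value is the unweighted mean over families with
degeneracy >= 2 that were observed at least once.

Observed ENC follows Wright's estimator: per-family homozygosity
F = (n * sum p_j^2 - 1) / (n - 1), averaged within degeneracy classes, then
ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped into [20, 61].  A missing 3-fold
class is imputed as (F2 + F4)/2; any other missing class leaves ENC
undefined for that gene.  The expected ENC at a given GC3 is the null curve
2 + GC3 + 29 / (GC3^2 + (1-GC3)^2).

CAI uses the Sharp & Li relative-adaptiveness construction: w_ij =
RSCU_ij / max_j RSCU_ij from a reference set, and CAI is the count-weighted
geometric mean of w over a gene's analyzable codons.  The expression proxy
reported alongside is MILC = 1 - CAI.  Note this is an idiosyncratic usage:
it is *not* the Supek-Vlahovicek "Measure Independent of Length and
Composition"; here the name simply labels the 1 - CAI complement used as an
expression-level proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (DEFAULT_CODE, CodonCountTable, GeneticCode,
                           PositionalComposition, count_codons, pool_counts,
                           positional_composition, AA_THREE_LETTER)

__all__ = [
    "RSCUVector", "GeneCUBProfile", "rscu", "scuo", "family_homozygosity",
    "enc_observed", "enc_expected", "relative_adaptiveness", "cai", "milc",
    "profile_gene", "profile_genes", "profiles_to_frame",
]

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class RSCUVector:
    """RSCU values over the analyzable codons of one count table."""

    values: dict                      # RNA codon -> RSCU
    zero_substituted: frozenset       # codons whose count was replaced by 0.5
    code: GeneticCode = DEFAULT_CODE

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]

    def family_sum(self, aa: str) -> float:
        return sum(self.values[c] for c in self.code.families[aa])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name="RSCU")


def rscu(counts: CodonCountTable, code: GeneticCode = DEFAULT_CODE,
         zero_sub: float = 0.5) -> RSCUVector:
    """Relative synonymous codon usage with the 0.5 zero-substitution rule.

    Every zero count inside a multi-codon family is replaced by ``zero_sub``
    before normalisation, so values are strictly positive and each family's
    RSCU values still sum to its degeneracy.
    """
    if counts.total_codons == 0:
        raise ValueError(f"empty count table for {counts.source!r}")
    values: dict[str, float] = {}
    subbed = set()
    for aa, codons in code.multi_codon_families.items():
        x = []
        for c in codons:
            xc = counts.counts.get(c, 0)
            if xc == 0:
                xc = zero_sub
                subbed.add(c)
            x.append(float(xc))
        mean = sum(x) / len(x)
        for c, xc in zip(codons, x):
            values[c] = xc / mean
    return RSCUVector(values=values, zero_substituted=frozenset(subbed),
                      code=code)


def scuo(counts: CodonCountTable, code: GeneticCode = DEFAULT_CODE):
    """Synonymous codon usage order of a gene.

    Returns ``(value, per_family)`` where ``per_family`` maps amino acid to
    its SCUO_i.  Families of degeneracy 1 are excluded; families never
    observed are excluded from the average.  With no observed multi-codon
    family the value is NaN (flagged undefined).
    """
    per_family: dict[str, float] = {}
    for aa, codons in code.multi_codon_families.items():
        x = counts.family_counts(code, aa)
        n = sum(x)
        if n == 0:
            continue
        h = -sum((xi / n) * math.log2(xi / n) for xi in x if xi > 0)
        hmax = math.log2(len(codons))
        per_family[aa] = 1.0 - h / hmax
    value = (sum(per_family.values()) / len(per_family)
             if per_family else float("nan"))
    return value, per_family


def family_homozygosity(family_counts: Sequence[int]):
    """Wright's codon homozygosity F for one synonymous family.

    F = (n * sum p_j^2 - 1) / (n - 1).  Returns ``None`` (unusable) when the
    family total n < 2 or the estimate is not positive.
    """
    n = sum(family_counts)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in family_counts)
    f = (n * sum_p2 - 1.0) / (n - 1.0)
    if f <= 0.0:
        return None
    return f


def enc_observed(counts: CodonCountTable, code: GeneticCode = DEFAULT_CODE,
                 cap: bool = True):
    """Wright's observed effective number of codons.

    Returns ``(enc, raw)``: the value capped into [20, 61] and the raw
    estimate.  Both are NaN when a degeneracy class other than the 3-fold
    one has no usable family.
    """
    class_f: dict[int, list[float]] = {}
    for aa, codons in code.multi_codon_families.items():
        f = family_homozygosity(counts.family_counts(code, aa))
        if f is not None:
            class_f.setdefault(len(codons), []).append(f)

    class_sizes = {k: v for k, v in code.degeneracy_census().items() if k >= 2}
    fbar: dict[int, float] = {}
    for k in class_sizes:
        if class_f.get(k):
            fbar[k] = float(np.mean(class_f[k]))
    if 3 in class_sizes and 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if set(class_sizes) - set(fbar):
        return float("nan"), float("nan")

    raw = 2.0 + sum(class_sizes[k] / fbar[k] for k in class_sizes)
    enc = min(max(raw, ENC_MIN), ENC_MAX) if cap else raw
    return enc, raw


def enc_expected(gc3: float) -> float:
    """Null-curve ENC expected from third-position GC alone."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"GC3 must lie in [0, 1], got {gc3}")
    return 2.0 + gc3 + 29.0 / (gc3 ** 2 + (1.0 - gc3) ** 2)


def relative_adaptiveness(reference: RSCUVector) -> dict:
    """Sharp-Li w: each codon's reference RSCU over its family maximum."""
    w: dict[str, float] = {}
    code = reference.code
    for aa, codons in code.multi_codon_families.items():
        top = max(reference.values[c] for c in codons)
        for c in codons:
            w[c] = reference.values[c] / top
    return w


def cai(counts: CodonCountTable, reference) -> float:
    """Codon adaptation index against a reference usage.

    ``reference`` is an :class:`RSCUVector` or a dict of precomputed w
    values.  CAI is the geometric mean of w over the gene's analyzable
    codons, weighted by their counts; the reference's zero-substitution
    guarantees w > 0.
    """
    w = (relative_adaptiveness(reference)
         if isinstance(reference, RSCUVector) else dict(reference))
    if not w:
        raise ValueError("empty CAI reference")
    total = 0
    log_sum = 0.0
    for codon, x in counts.counts.items():
        if codon in w and x > 0:
            total += x
            log_sum += x * math.log(w[codon])
    if total == 0:
        raise ValueError(
            f"no analyzable codons in {counts.source!r} for CAI")
    return math.exp(log_sum / total)


def milc(cai_value: float) -> float:
    """Expression proxy 1 - CAI (see module docstring for the caveat)."""
    return 1.0 - cai_value


@dataclass
class GeneCUBProfile:
    """All per-gene codon-usage metrics in one record."""

    gene_id: str
    composition: PositionalComposition
    rscu: RSCUVector
    scuo: float
    scuo_per_family: dict
    enc_obs: float
    enc_raw: float
    enc_exp: float
    enc_ratio: float
    cai: float
    milc: float
    pr2_x: float
    pr2_y: float
    gene_name: str = ""

    def as_row(self) -> dict:
        row = {"gene": self.gene_id, "gene_name": self.gene_name}
        row.update(self.composition.as_dict())
        row.update({
            "SCUO": self.scuo, "ENC": self.enc_obs, "ENC_raw": self.enc_raw,
            "ENC_exp": self.enc_exp, "ENC_ratio": self.enc_ratio,
            "CAI": self.cai, "MILC": self.milc,
            "PR2_x": self.pr2_x, "PR2_y": self.pr2_y,
        })
        return row


def _pr2(comp: PositionalComposition):
    at = comp.counts3.get("A", 0) + comp.counts3.get("T", 0)
    gc = comp.counts3.get("G", 0) + comp.counts3.get("C", 0)
    y = comp.counts3.get("A", 0) / at if at else float("nan")
    x = comp.counts3.get("G", 0) / gc if gc else float("nan")
    return x, y


def profile_gene(seq, code: GeneticCode = DEFAULT_CODE, *,
                 reference_w: Mapping[str, float] | None = None) -> GeneCUBProfile:
    """Compute the full metric profile of one coding sequence.

    ``reference_w`` holds the CAI relative-adaptiveness weights; when absent
    the gene's own usage is the reference (CAI of a self-referenced uniform
    gene is 1).
    """
    counts = count_codons(seq, code)
    comp = positional_composition(seq, code)
    vec = rscu(counts, code)
    w = reference_w if reference_w is not None else relative_adaptiveness(vec)
    scuo_val, per_fam = scuo(counts, code)
    enc, enc_raw = enc_observed(counts, code)
    exp = enc_expected(comp.gc3)
    ratio = (exp - enc) / exp if math.isfinite(enc) else float("nan")
    cai_val = cai(counts, w)
    x, y = _pr2(comp)
    return GeneCUBProfile(
        gene_id=getattr(seq, "id", "<sequence>"),
        gene_name=getattr(seq, "gene_name", ""),
        composition=comp, rscu=vec, scuo=scuo_val, scuo_per_family=per_fam,
        enc_obs=enc, enc_raw=enc_raw, enc_exp=exp, enc_ratio=ratio,
        cai=cai_val, milc=milc(cai_val), pr2_x=x, pr2_y=y)


def profile_genes(seqs: Sequence, code: GeneticCode = DEFAULT_CODE, *,
                  reference: str = "self") -> list:
    """Profile a gene set with a shared CAI reference.

    ``reference="self"`` derives the relative adaptiveness from the pooled
    counts of the set itself (the self-contained default); alternatively
    pass an :class:`RSCUVector` computed from a user-supplied reference set.
    """
    if not seqs:
        raise ValueError("no sequences to profile")
    if reference == "self":
        pooled = pool_counts(count_codons(s, code) for s in seqs)
        ref_vec = rscu(pooled, code)
    elif isinstance(reference, RSCUVector):
        ref_vec = reference
    else:
        raise ValueError("reference must be 'self' or an RSCUVector")
    w = relative_adaptiveness(ref_vec)
    return [profile_gene(s, code, reference_w=w) for s in seqs]


def profiles_to_frame(profiles: Iterable[GeneCUBProfile]) -> pd.DataFrame:
    """One row per gene with every scalar metric; the profile TSV payload."""
    return pd.DataFrame([p.as_row() for p in profiles]).set_index("gene")


def rscu_table(profiles_or_vec, code: GeneticCode = DEFAULT_CODE) -> pd.DataFrame:
    """Long-format RSCU table (amino acid, codon, RSCU) for reporting."""
    vec = profiles_or_vec
    rows = []
    for aa, codons in code.multi_codon_families.items():
        for c in codons:
            rows.append({"aa": AA_THREE_LETTER[aa], "codon": c,
                         "RSCU": vec.values[c]})
    return pd.DataFrame(rows)
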