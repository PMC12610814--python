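"""Synthetic plastome-like CDS sets with known codon-usage structure.

The generator emulates the statistical shape of a filtered chloroplast CDS
set — 50-90 genes, lengths 300-4500 nt in multiples of 3, ATG start, one
terminal stop, no internal stops — while the codon-usage regime is fully
controlled, so every pipeline stage can be verified against construction:

``uniform``
    every synonymous codon equally likely; pooled RSCU converges to 1.
``at_biased``
    A/U-ending codons up-weighted within every family (default weight 3);
    each family's top-RSCU codon ends A/U.
``mutation_gradient``
    each gene draws a GC pressure g ~ Uniform(0.2, 0.8) that tilts base
    choice toward G/C at all three codon positions jointly, so GC12 tracks
    GC3 across genes (neutrality slope near 1) and genes sit on the
    expected-ENC curve.
``selection_regime``
    a fixed set of A/U-ending preferred codons is up-weighted identically
    in every gene while the amino-acid composition (hence first/second
    position GC) is held fixed, decoupling GC12 from GC3 (slope near 0) and
    pushing observed ENC below the expected curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cds_io import CodingSequence, write_fasta
from .genetic_code import DEFAULT_CODE, GeneticCode, _dna

__all__ = ["UsageRegime", "generate_cds_set", "regime_truth", "REGIMES"]

REGIMES = ("uniform", "at_biased", "mutation_gradient", "selection_regime")


@dataclass
class UsageRegime:
    """Parameters of one synthetic CDS set.

    ``n_genes`` and ``length_range`` default to a plastome-like set (55
    genes, 300-4500 nt); ``gc_range`` is the per-gene GC-pressure interval
    of the mutation_gradient regime and ``preferred_weight`` the up-weight
    of A/U-ending codons in the at_biased and selection regimes.
    """

    name: str
    n_genes: int = 55
    length_range: tuple = (300, 4500)
    gc_range: tuple = (0.2, 0.8)
    preferred_weight: float = 3.0
    seed: int = 0
    code_id: int = 11

    def __post_init__(self):
        if self.name not in REGIMES:
            raise ValueError(f"unknown regime {self.name!r}; one of {REGIMES}")
        lo, hi = self.length_range
        if lo < 300 or hi > 4500 or lo > hi:
            raise ValueError("length_range must lie within [300, 4500]")


def _sense_codons(code: GeneticCode):
    return sorted(code.codon_to_aa)


def _family_probs(code: GeneticCode, weight_fn) -> dict:
    """Per-amino-acid codon probability vectors from a codon weight rule."""
    probs = {}
    for aa, codons in code.families.items():
        w = np.array([weight_fn(c) for c in codons], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError(f"invalid codon weights for {aa}")
        probs[aa] = w / w.sum()
    return probs


def _preferred_codons(code: GeneticCode) -> set:
    """One fixed A/U-ending preferred codon per multi-codon family."""
    pref = set()
    for aa, codons in code.multi_codon_families.items():
        au = [c for c in codons if c[-1] in "AU"]
        if au:
            pref.add(au[0])  # alphabetically first, fixed across runs
    return pref


def _gene_lengths(rng, regime: UsageRegime) -> np.ndarray:
    """Codon totals per gene: log-uniform over the allowed length range."""
    lo, hi = regime.length_range
    n_cod = np.exp(rng.uniform(np.log(lo // 3), np.log(hi // 3),
                               size=regime.n_genes))
    return np.clip(n_cod.astype(int), lo // 3, hi // 3)


def _draw_by_family(rng, n_body: int, aa_probs, fam_probs, code) -> list:
    aas = list(fam_probs)
    aa_p = np.array([aa_probs[a] for a in aas])
    aa_p = aa_p / aa_p.sum()
    chosen = rng.choice(len(aas), size=n_body, p=aa_p)
    body = []
    counts = np.bincount(chosen, minlength=len(aas))
    for ai, k in enumerate(counts):
        if k == 0:
            continue
        aa = aas[ai]
        codons = code.families[aa]
        picks = rng.choice(len(codons), size=k, p=fam_probs[aa])
        body.extend(codons[j] for j in picks)
    rng.shuffle(body)
    return body


def _draw_by_codon(rng, n_body: int, codon_probs: np.ndarray, codons) -> list:
    picks = rng.choice(len(codons), size=n_body, p=codon_probs)
    return [codons[j] for j in picks]


def generate_cds_set(regime: UsageRegime):
    """Generate a CDS set under a usage regime.

    Returns ``(sequences, metadata)``: a list of
    :class:`~plastcub.cds_io.CodingSequence` (ATG + i.i.d. body codons + one
    UAA stop each, guaranteed to pass the QC filters with zero rejections)
    and a JSON-serializable metadata dict recording the regime and, for
    mutation_gradient, the per-gene GC pressures.
    """
    code = GeneticCode.from_ncbi_id(regime.code_id)
    rng = np.random.default_rng(regime.seed)
    lengths = _gene_lengths(rng, regime)
    aa_uniform = {aa: 1.0 for aa in code.families}
    meta: dict = {"regime": asdict(regime)}
    meta["regime"]["length_range"] = list(regime.length_range)
    meta["regime"]["gc_range"] = list(regime.gc_range)

    seqs: list[CodingSequence] = []
    if regime.name in ("uniform", "at_biased", "selection_regime"):
        if regime.name == "uniform":
            fam_probs = _family_probs(code, lambda c: 1.0)
        elif regime.name == "at_biased":
            fam_probs = _family_probs(
                code, lambda c: regime.preferred_weight if c[-1] in "AU" else 1.0)
        else:
            pref = _preferred_codons(code)
            meta["preferred_codons"] = sorted(pref)
            fam_probs = _family_probs(
                code, lambda c: regime.preferred_weight if c in pref else 1.0)
        for i, n_cod in enumerate(lengths):
            body = _draw_by_family(rng, int(n_cod) - 2, aa_uniform,
                                   fam_probs, code)
            nt = "ATG" + "".join(_dna(c) for c in body) + "TAA"
            seqs.append(CodingSequence(
                id=f"{regime.name}_g{i:03d}", gene_name=f"g{i:03d}",
                nucleotides=nt, source_file=f"synthetic:{regime.name}"))
    else:  # mutation_gradient
        codons = _sense_codons(code)
        g_values = rng.uniform(*regime.gc_range, size=regime.n_genes)
        meta["gc_pressure"] = [float(g) for g in g_values]
        for i, (n_cod, g) in enumerate(zip(lengths, g_values)):
            w = {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "U": (1 - g) / 2}
            cw = np.array([w[c[0]] * w[c[1]] * w[c[2]] for c in codons])
            cw = cw / cw.sum()
            body = _draw_by_codon(rng, int(n_cod) - 2, cw, codons)
            nt = "ATG" + "".join(_dna(c) for c in body) + "TAA"
            seqs.append(CodingSequence(
                id=f"{regime.name}_g{i:03d}", gene_name=f"g{i:03d}",
                nucleotides=nt, source_file=f"synthetic:{regime.name}"))
    return seqs, meta


def regime_truth(regime: UsageRegime) -> dict:
    """Expected diagnostic signature of a regime, for recovery tests.

    mutation_gradient sets should yield a neutrality slope in [0.7, 1.1]
    with genes hugging the expected-ENC curve; selection_regime sets a slope
    in [-0.1, 0.25] with genes below the curve.  Regimes without a
    mutation/selection signature are flagged.
    """
    if regime.name == "mutation_gradient":
        return {"signature": "mutation", "slope_band": (0.7, 1.1),
                "enc_behavior": "on_curve"}
    if regime.name == "selection_regime":
        return {"signature": "selection", "slope_band": (-0.1, 0.25),
                "enc_behavior": "below_curve"}
    return {"signature": None,
            "reason": f"regime {regime.name!r} has no "
                      "mutation-vs-selection signature"}


def write_cds_set(seqs, meta, fasta_path, sidecar_path=None) -> None:
    """Write the set as FASTA plus a JSON metadata sidecar."""
    Path(fasta_path).parent.mkdir(parents=True, exist_ok=True)
    write_fasta(seqs, fasta_path)
    sidecar = Path(sidecar_path or str(fasta_path) + ".json")
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
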