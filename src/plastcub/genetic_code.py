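"""Genetic code structure, codon counting and positional nucleotide composition.

The genetic code is represented as an explicit family structure: each amino
acid owns an ordered list of synonymous codons, and all downstream statistics
(RSCU, SCUO, ENC, CAI) are defined per synonymous family.  Codons are reported
in the RNA alphabet (``UUA`` rather than ``TTA``), the convention of the codon
usage literature, while input sequences are read as DNA.

The default code is NCBI translation table 11, the table used for annotated
plastid CDS.  Under it 59 of the 64 codons are "analyzable": all codons minus
the two single-codon families (AUG/Met, UGG/Trp) and the three stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodonCountTable",
    "PositionalComposition",
    "FrameError",
    "count_codons",
    "positional_composition",
    "pool_counts",
    "AA_THREE_LETTER",
    "DNA_BASES",
]

DNA_BASES = "ACGT"

#: three-letter amino-acid names used in output tables
AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


class FrameError(ValueError):
    """Raised when a sequence length is not a multiple of three."""


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


def _dna(codon: str) -> str:
    return codon.replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A translation table organised by synonymous codon family.

    Parameters
    ----------
    code_id : int
        NCBI translation table identifier.
    codon_to_aa : mapping
        RNA codon -> one-letter amino acid, over the 61 sense codons.
    stop_codons : frozenset
        RNA stop codons.
    families : mapping
        Amino acid -> ordered tuple of its synonymous RNA codons
        (alphabetical order, fixed for reproducible output).
    """

    code_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset
    families: Mapping[str, tuple]

    def __post_init__(self):
        n = len(self.codon_to_aa) + len(self.stop_codons)
        if n != 64:
            raise ValueError(f"genetic code must cover 64 codons, got {n}")

    @classmethod
    @lru_cache(maxsize=None)
    def from_ncbi_id(cls, code_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        codon_to_aa = {_rna(c): aa for c, aa in table.forward_table.items()}
        stops = frozenset(_rna(c) for c in table.stop_codons)
        families: dict[str, tuple] = {}
        for aa in sorted(set(codon_to_aa.values())):
            families[aa] = tuple(sorted(c for c, a in codon_to_aa.items() if a == aa))
        return cls(code_id=code_id, codon_to_aa=codon_to_aa,
                   stop_codons=stops, families=families)

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])

    @property
    def analyzable_codons(self) -> tuple:
        """Codons in families of degeneracy >= 2, in family order."""
        out = []
        for aa, codons in self.families.items():
            if len(codons) >= 2:
                out.extend(codons)
        return tuple(out)

    @property
    def multi_codon_families(self) -> dict:
        return {aa: c for aa, c in self.families.items() if len(c) >= 2}

    def degeneracy_census(self) -> dict:
        """Count of families per degeneracy class, e.g. {1: 2, 2: 9, ...}."""
        census: dict[int, int] = {}
        for codons in self.families.values():
            census[len(codons)] = census.get(len(codons), 0) + 1
        return census


DEFAULT_CODE = GeneticCode.from_ncbi_id(11)


@dataclass
class CodonCountTable:
    """Raw codon counts for one gene or a pooled gene set.

    ``counts`` maps RNA codons to non-negative integers; ``total_codons`` is
    their sum.  Stop codons may appear in ``counts`` (internal stops, or the
    terminal stop when explicitly kept) but are never part of amino-acid
    family statistics.
    """

    counts: dict
    source: str = ""
    n_skipped: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, code: GeneticCode, aa: str):
        """Counts for every codon of one family, in family order."""
        return [self.counts.get(c, 0) for c in code.families[aa]]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = dict(self.counts)
        for c, n in other.counts.items():
            merged[c] = merged.get(c, 0) + n
        return CodonCountTable(counts=merged, source="pooled",
                               n_skipped=self.n_skipped + other.n_skipped)


def pool_counts(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    """Sum codon counts over many genes into one pooled table."""
    pooled = CodonCountTable(counts={}, source="pooled")
    for t in tables:
        pooled = pooled + t
    pooled.source = "pooled"
    return pooled


def _triplets(seq: str, name: str = "<sequence>"):
    """Yield (index, DNA triplet, is_clean) over an in-frame sequence."""
    s = seq.upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise FrameError(
            f"length of {name!r} is {len(s)}, not a multiple of 3")
    for i in range(0, len(s), 3):
        tri = s[i:i + 3]
        yield i // 3, tri, all(b in DNA_BASES for b in tri)


def count_codons(seq, code: GeneticCode = DEFAULT_CODE, *,
                 drop_terminal_stop: bool = True,
                 source: str | None = None) -> CodonCountTable:
    """Count in-frame codons of a coding sequence.

    Triplets containing ambiguity letters (N, R, ...) are excluded from the
    counts and tallied in ``n_skipped``.  By default a terminal stop codon is
    not counted (it encodes no amino acid); headless fragments without a stop
    are counted in full.

    Raises
    ------
    FrameError
        If the sequence length is not a multiple of three.
    """
    nt = getattr(seq, "nucleotides", seq)
    name = source or getattr(seq, "id", "<sequence>")
    counts: dict[str, int] = {}
    skipped = 0
    trips = list(_triplets(nt, name))
    last = len(trips) - 1
    for i, tri, clean in trips:
        if not clean:
            skipped += 1
            continue
        codon = _rna(tri)
        if drop_terminal_stop and i == last and codon in code.stop_codons:
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(counts=counts, source=name, n_skipped=skipped)


@dataclass
class PositionalComposition:
    """Nucleotide composition overall and at each codon position.

    All ``*_frac`` attributes are fractions in [0, 1]; raw counts are kept so
    that downstream ratios (PR2 coordinates) can detect empty denominators.
    """

    counts: dict            # base -> count over all positions
    counts1: dict           # base -> count at codon position 1
    counts2: dict
    counts3: dict
    n_codons: int = 0

    def _frac(self, d: dict, base: str) -> float:
        tot = sum(d.values())
        return d.get(base, 0) / tot if tot else float("nan")

    @property
    def a(self): return self._frac(self.counts, "A")
    @property
    def t(self): return self._frac(self.counts, "T")
    @property
    def g(self): return self._frac(self.counts, "G")
    @property
    def c(self): return self._frac(self.counts, "C")
    @property
    def a3(self): return self._frac(self.counts3, "A")
    @property
    def t3(self): return self._frac(self.counts3, "T")
    @property
    def g3(self): return self._frac(self.counts3, "G")
    @property
    def c3(self): return self._frac(self.counts3, "C")

    def _gc(self, d: dict) -> float:
        tot = sum(d.values())
        return (d.get("G", 0) + d.get("C", 0)) / tot if tot else float("nan")

    @property
    def gc1(self): return self._gc(self.counts1)
    @property
    def gc2(self): return self._gc(self.counts2)
    @property
    def gc3(self): return self._gc(self.counts3)
    @property
    def gc(self): return self._gc(self.counts)
    @property
    def gc12(self): return (self.gc1 + self.gc2) / 2.0

    def as_dict(self) -> dict:
        return {
            "A": self.a, "T": self.t, "G": self.g, "C": self.c,
            "A3": self.a3, "T3": self.t3, "G3": self.g3, "C3": self.c3,
            "GC1": self.gc1, "GC2": self.gc2, "GC3": self.gc3,
            "GC12": self.gc12, "GC": self.gc, "n_codons": self.n_codons,
        }


def positional_composition(seqs, code: GeneticCode = DEFAULT_CODE, *,
                           drop_terminal_stop: bool = True) -> PositionalComposition:
    """Nucleotide composition by codon position for one sequence or a pool.

    Accepts a single sequence (string or object with ``nucleotides``) or an
    iterable of them; ambiguous triplets and, by default, terminal stop codons
    are excluded, consistent with :func:`count_codons`.
    """
    if isinstance(seqs, str) or hasattr(seqs, "nucleotides"):
        seqs = [seqs]
    seqs = list(seqs)
    if not seqs:
        raise ValueError("composition is undefined for empty input")

    counts = {b: 0 for b in DNA_BASES}
    pos = [{b: 0 for b in DNA_BASES} for _ in range(3)]
    n_codons = 0
    for seq in seqs:
        nt = getattr(seq, "nucleotides", seq)
        name = getattr(seq, "id", "<sequence>")
        trips = list(_triplets(nt, name))
        last = len(trips) - 1
        for i, tri, clean in trips:
            if not clean:
                continue
            if drop_terminal_stop and i == last and _rna(tri) in code.stop_codons:
                continue
            n_codons += 1
            for k, b in enumerate(tri):
                counts[b] += 1
                pos[k][b] += 1
    if n_codons == 0:
        raise ValueError("composition is undefined: no unambiguous codons")
    return PositionalComposition(counts=counts, counts1=pos[0],
                                 counts2=pos[1], counts3=pos[2],
                                 n_codons=n_codons)
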