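"""Reading CDS from GenBank/FASTA and the quality filters for the gene set.

A plastome submission typically annotates 75-90 CDS features; the analysis
set is the subset passing the standard codon-usage QC chain: in frame,
>= 300 bp, non-duplicate, ATG start, a proper terminal stop and no internal
stop.  Rules are applied in a fixed order and every rejection is attributed
to the first rule it fails, so filter reports are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetic_code import DEFAULT_CODE, GeneticCode, _rna

__all__ = ["CodingSequence", "FilterReport", "read_cds", "filter_cds",
           "write_fasta"]

_VALID = set("ACGTURYSWKMBDHVN")

#: filter rules in application order (frame first; the rest follow the
#: length -> duplicate -> start -> terminal stop -> internal stop chain)
FILTER_ORDER = ("frame", "length", "duplicate", "start",
                "terminal_stop", "internal_stop")


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence: identifier, gene name and DNA string."""

    id: str
    gene_name: str = ""
    nucleotides: str = ""
    source_file: str = ""

    def __post_init__(self):
        nt = self.nucleotides.upper().replace("U", "T")
        if not nt:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(nt) - _VALID
        if bad:
            raise ValueError(
                f"invalid letters {sorted(bad)} in sequence {self.id!r}")
        object.__setattr__(self, "nucleotides", nt)

    def __len__(self):
        return len(self.nucleotides)


@dataclass
class FilterReport:
    """Counts surviving each filter stage plus per-sequence rejections."""

    n_input: int = 0
    n_after_frame: int = 0
    n_after_length: int = 0
    n_after_dedup: int = 0
    n_after_start: int = 0
    n_after_stop: int = 0
    n_after_internal_stop: int = 0
    rejections: list = field(default_factory=list)  # (id, rule)

    @property
    def n_retained(self) -> int:
        return self.n_after_internal_stop

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def to_tsv(self, path) -> None:
        lines = ["stage\tn"]
        for stage, n in [("input", self.n_input),
                         ("after_frame", self.n_after_frame),
                         ("after_length", self.n_after_length),
                         ("after_dedup", self.n_after_dedup),
                         ("after_start", self.n_after_start),
                         ("after_terminal_stop", self.n_after_stop),
                         ("after_internal_stop", self.n_after_internal_stop)]:
            lines.append(f"{stage}\t{n}")
        lines.append("")
        lines.append("rejected_id\trule")
        for sid, rule in self.rejections:
            lines.append(f"{sid}\t{rule}")
        Path(path).write_text("\n".join(lines) + "\n")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".gb", ".gbk", ".gbff", ".genbank"}:
        return "genbank"
    return "fasta"


def read_cds(path, fmt: str | None = None) -> list:
    """Read coding sequences from a FASTA or GenBank file.

    For GenBank records every CDS feature is extracted with full location
    semantics (minus-strand features are reverse-complemented, joined exons
    concatenated in order, via Biopython's ``feature.extract``).  For FASTA,
    records are taken verbatim.
    """
    path = Path(path)
    fmt = fmt or _guess_format(path)
    out: list[CodingSequence] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(CodingSequence(id=rec.id, gene_name=rec.id,
                                      nucleotides=str(rec.seq),
                                      source_file=str(path)))
    elif fmt == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            idx = 0
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                idx += 1
                gene = feat.qualifiers.get(
                    "gene", feat.qualifiers.get("locus_tag", [""]))[0]
                try:
                    seq = str(feat.extract(rec.seq))
                except Exception as exc:  # unresolvable coordinates
                    import warnings
                    warnings.warn(
                        f"skipping CDS {gene or idx} in {rec.id}: {exc}")
                    continue
                out.append(CodingSequence(
                    id=f"{rec.id}:{gene or f'CDS{idx}'}",
                    gene_name=gene, nucleotides=seq, source_file=str(path)))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return out


def write_fasta(seqs: Iterable[CodingSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.nucleotides), 70):
                fh.write(s.nucleotides[i:i + 70] + "\n")


def _first_failure(seq: CodingSequence, seen: set, *, min_len: int,
                   require_atg: bool, require_terminal_stop: bool,
                   forbid_internal_stop: bool, dedup: bool,
                   dedup_by: str, code: GeneticCode) -> str | None:
    nt = seq.nucleotides
    if len(nt) % 3 != 0:
        return "frame"
    if len(nt) < min_len:
        return "length"
    if dedup:
        key = nt if dedup_by == "sequence" else (seq.gene_name or seq.id)
        if key in seen:
            return "duplicate"
        seen.add(key)
    if require_atg and not nt.startswith("ATG"):
        return "start"
    codons = [_rna(nt[i:i + 3]) for i in range(0, len(nt), 3)]
    if require_terminal_stop and codons[-1] not in code.stop_codons:
        return "terminal_stop"
    if forbid_internal_stop and any(c in code.stop_codons for c in codons[:-1]):
        return "internal_stop"
    return None


def filter_cds(seqs: Sequence[CodingSequence], *, min_len: int = 300,
               require_atg: bool = True, require_terminal_stop: bool = True,
               forbid_internal_stop: bool = True, dedup: bool = True,
               dedup_by: str = "sequence",
               code: GeneticCode = DEFAULT_CODE):
    """Apply the QC chain and return ``(retained, FilterReport)``.

    Rules run in the order frame, length, duplicate, start codon, terminal
    stop, internal stop; a sequence is charged to the first rule it fails.
    Deduplication keeps the first occurrence in input order and compares
    exact nucleotide strings by default (``dedup_by="gene_name"`` dedups on
    the annotated name instead).  Filtering never raises on content and is
    idempotent.
    """
    if dedup_by not in ("sequence", "gene_name"):
        raise ValueError("dedup_by must be 'sequence' or 'gene_name'")
    report = FilterReport(n_input=len(seqs))
    retained: list[CodingSequence] = []
    seen: set = set()
    survivors = {rule: 0 for rule in FILTER_ORDER}
    for seq in seqs:
        rule = _first_failure(
            seq, seen, min_len=min_len, require_atg=require_atg,
            require_terminal_stop=require_terminal_stop,
            forbid_internal_stop=forbid_internal_stop, dedup=dedup,
            dedup_by=dedup_by, code=code)
        if rule is None:
            retained.append(seq)
            for r in FILTER_ORDER:
                survivors[r] += 1
        else:
            # survived every stage before the failing one
            for r in FILTER_ORDER:
                if r == rule:
                    break
                survivors[r] += 1
            report.rejections.append((seq.id, rule))
    report.n_after_frame = survivors["frame"]
    report.n_after_length = survivors["length"]
    report.n_after_dedup = survivors["duplicate"]
    report.n_after_start = survivors["start"]
    report.n_after_stop = survivors["terminal_stop"]
    report.n_after_internal_stop = survivors["internal_stop"]
    return retained, report
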