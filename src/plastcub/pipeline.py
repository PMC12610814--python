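"""End-to-end orchestration: per-taxon profiling and cross-taxon comparison.

``run_species`` executes the full single-taxon chain — read, filter,
profile, correlation tables, ENC/PR2/neutrality diagnostics, optimal
codons — and writes every table (and optionally figure) under the output
directory.  ``run_compare`` pools each taxon's filtered CDS, builds the
RSCU matrix and dendrogram, and reports the codons over-represented
(RSCU > 1.6) in every taxon.  Runs are deterministic for a given config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, diagnostics, optimal, plots
from .cds_io import filter_cds, read_cds, write_fasta
from .genetic_code import GeneticCode, count_codons, pool_counts
from .indices import profile_genes, profiles_to_frame, pool_counts as _pc  # noqa: F401
from .indices import rscu

log = logging.getLogger("plastcub")

__all__ = ["RunConfig", "SpeciesResult", "CompareResult", "run_species",
           "run_compare"]

#: Table-1/2 style variable sets
COMPOSITION_ROWS = ("A", "T", "G", "C", "GC")
COMPOSITION_COLS = ("A3", "T3", "G3", "C3", "GC3")
SCUO_COLS = ("A", "T", "G", "C", "GC", "A3", "T3", "G3", "C3", "GC3")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``inputs`` maps taxon name -> CDS file path; ``formats`` is a single
    format or a per-taxon map ("fasta"/"genbank"/None for auto).  All
    thresholds default to the standard analysis values (300 bp length
    cut, 0.05 ENC-ratio window, ENC > 45 census, 10% expression tails,
    dRSCU >= 0.08, RSCU > 1.6 over-representation).
    """

    inputs: dict
    formats: dict | str | None = None
    outdir: str = "results"
    code_id: int = 11
    min_len: int = 300
    dedup_by: str = "sequence"
    cai_reference: str = "self"
    library_metric: str = "milc"
    library_fraction: float = 0.1
    library_min_genes: int = 5
    enc_window: float = 0.05
    enc_threshold: float = 45.0
    delta_rscu_min: float = 0.08
    overrep_threshold: float = 1.6
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    make_plots: bool = True
    seed: int = 0

    def fmt(self, taxon: str):
        if isinstance(self.formats, dict):
            return self.formats.get(taxon)
        return self.formats

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SpeciesResult:
    taxon: str
    retained: list
    filter_report: object
    profiles: list
    profile_frame: pd.DataFrame
    comp_corr: diagnostics.CorrelationTable
    scuo_corr: diagnostics.CorrelationTable
    enc: diagnostics.ENCPlotResult
    pr2: pd.DataFrame
    neutrality: diagnostics.NeutralityResult
    libraries: object | None
    optimal: object | None


def _header(config: RunConfig) -> str:
    eff = {k: v for k, v in dataclasses.asdict(config).items()
           if k not in ("inputs", "formats", "outdir", "make_plots")}
    return "# " + " ".join(f"{k}={v}" for k, v in sorted(eff.items()))


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig,
               index=True) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config) + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_species(config: RunConfig, taxon: str) -> SpeciesResult:
    """Run the full single-taxon analysis and write its outputs."""
    if taxon not in config.inputs:
        raise KeyError(f"taxon {taxon!r} not in config inputs")
    path = Path(config.inputs[taxon])
    if not path.exists():
        raise FileNotFoundError(f"input for {taxon!r} not found: {path}")
    outdir = Path(config.outdir) / taxon
    outdir.mkdir(parents=True, exist_ok=True)
    code = GeneticCode.from_ncbi_id(config.code_id)

    seqs = read_cds(path, config.fmt(taxon))
    log.info("%s: %d CDS read", taxon, len(seqs))
    retained, report = filter_cds(seqs, min_len=config.min_len,
                                  dedup_by=config.dedup_by, code=code)
    report.to_tsv(outdir / "filter_report.tsv")
    log.info("%s: %d retained of %d", taxon, report.n_retained, len(seqs))
    if not retained:
        raise RuntimeError(
            f"{taxon}: no sequences survive filtering "
            f"(report at {outdir / 'filter_report.tsv'})")
    write_fasta(retained, outdir / "filtered_cds.fasta")

    profiles = profile_genes(retained, code, reference=config.cai_reference)
    frame = profiles_to_frame(profiles)
    _write_tsv(frame, outdir / "gene_profiles.tsv", config)

    comp_corr = diagnostics.correlation_table(
        frame, COMPOSITION_ROWS, COMPOSITION_COLS)
    _write_tsv(comp_corr.annotated(), outdir / "composition_correlations.tsv",
               config)
    scuo_corr = diagnostics.correlation_table(frame, ("SCUO",), SCUO_COLS)
    _write_tsv(scuo_corr.annotated(), outdir / "scuo_correlations.tsv", config)

    enc = diagnostics.enc_plot(profiles, window=config.enc_window,
                               enc_threshold=config.enc_threshold)
    _write_tsv(enc.table, outdir / "enc_plot.tsv", config, index=False)
    pr2 = diagnostics.pr2_points(profiles)
    _write_tsv(pr2, outdir / "pr2.tsv", config, index=False)
    neut = diagnostics.neutrality(profiles)
    _write_tsv(neut.table, outdir / "neutrality.tsv", config, index=False)

    libraries = opt = None
    if len(profiles) >= 2 * config.library_min_genes:
        libraries = optimal.build_libraries(
            profiles, metric=config.library_metric,
            fraction=config.library_fraction,
            min_genes=config.library_min_genes)
        by_id = {p.gene_id: p for p in profiles}
        hi = pool_counts(count_codons(_seq_of(by_id[g], retained), code)
                         for g in libraries.high)
        lo = pool_counts(count_codons(_seq_of(by_id[g], retained), code)
                         for g in libraries.low)
        opt = optimal.optimal_codon_set(hi, lo, code,
                                        delta_min=config.delta_rscu_min)
        opt.to_tsv(outdir / "optimal_codons.tsv")
    else:
        log.warning("%s: too few genes for expression libraries", taxon)

    if config.make_plots:
        plots.enc_plot_figure(enc, outdir / "enc_plot.png")
        plots.enc_ratio_histogram(enc, outdir / "enc_ratio_hist.png")
        plots.pr2_figure(pr2, outdir / "pr2.png")
        plots.neutrality_figure(neut, outdir / "neutrality.png")

    return SpeciesResult(taxon=taxon, retained=retained,
                         filter_report=report, profiles=profiles,
                         profile_frame=frame, comp_corr=comp_corr,
                         scuo_corr=scuo_corr, enc=enc, pr2=pr2,
                         neutrality=neut, libraries=libraries, optimal=opt)


def _seq_of(profile, retained):
    for s in retained:
        if s.id == profile.gene_id:
            return s
    raise KeyError(profile.gene_id)


@dataclass
class CompareResult:
    matrix: pd.DataFrame
    tree: object
    newick: str
    shared_overrepresented: set
    per_taxon_overrepresented: dict


def run_compare(config: RunConfig, species_results: dict | None = None) -> CompareResult:
    """Cross-taxon comparison: RSCU matrix, dendrogram, shared codons.

    ``species_results`` may carry already-computed :class:`SpeciesResult`
    objects; missing taxa are (re)run.  Requires at least two taxa.
    """
    taxa = list(config.inputs)
    if len(taxa) < 2:
        raise ValueError("run_compare needs at least 2 taxa")
    species_results = dict(species_results or {})
    for t in taxa:
        if t not in species_results:
            species_results[t] = run_species(config, t)

    code = GeneticCode.from_ncbi_id(config.code_id)
    pooled = {t: pool_counts(count_codons(s, code)
                             for s in species_results[t].retained)
              for t in taxa}
    matrix = clustering.rscu_matrix(pooled, code)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(matrix, outdir / "rscu_matrix.tsv", config)
    dist = clustering.distance_matrix(matrix, config.cluster_metric)
    _write_tsv(dist, outdir / "rscu_distances.tsv", config)
    tree = clustering.cluster_taxa(matrix, metric=config.cluster_metric,
                                   method=config.cluster_linkage)
    newick = clustering.to_newick(tree)
    (outdir / "rscu_tree.nwk").write_text(newick + "\n")

    per_taxon = {t: set(matrix.index[matrix[t] > config.overrep_threshold])
                 for t in taxa}
    shared = set.intersection(*per_taxon.values()) if per_taxon else set()
    census = pd.DataFrame(
        [{"codon": c, **{t: c in per_taxon[t] for t in taxa}}
         for c in sorted(set.union(*per_taxon.values()) or set())])
    _write_tsv(census, outdir / "overrepresented_codons.tsv", config,
               index=False)
    return CompareResult(matrix=matrix, tree=tree, newick=newick,
                         shared_overrepresented=shared,
                         per_taxon_overrepresented=per_taxon)
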