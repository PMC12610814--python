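#!/usr/bin/env python
"""Optimal codons per cohort taxon from high/low-expression libraries.

For each taxon, genes are ranked by the MILC expression proxy, the 10%
tails are pooled, and codons with dRSCU >= 0.08 and RSCU_high >= 1 are
reported with their star tiers.  Prints each taxon's count and the
fraction of optimal codons ending in A/U (the expectation for an
A/U-biased plastome-like cohort).
"""

import pandas as pd

from plastcub import RunConfig, run_species

CONFIG = "results/cohort/cohort_config.yaml"


def main() -> None:
    cfg = RunConfig.from_yaml(CONFIG)
    rows = []
    for taxon in cfg.inputs:
        res = run_species(cfg, taxon)
        entries = res.optimal.entries
        au = (entries["codon"].str[-1].isin(["A", "U"]).mean()
              if len(entries) else float("nan"))
        rows.append({"taxon": taxon, "n_optimal": len(entries),
                     "frac_AU_ending": au,
                     "top": ", ".join(
                         entries.nlargest(3, "dRSCU")["codon"])
                     if len(entries) else ""})
        print(f"\n{taxon}: {len(entries)} optimal codons "
              f"(table: {cfg.outdir}/{taxon}/optimal_codons.tsv)")
        if len(entries):
            print(entries.round(3).to_string(index=False))
    summary = pd.DataFrame(rows)
    out = "results/optimal_codon_summary.tsv"
    summary.to_csv(out, sep="\t", index=False, float_format="%.3g")
    print(f"\nsummary written to {out}")


if __name__ == "__main__":
    main()
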