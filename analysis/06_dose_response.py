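#!/usr/bin/env python
"""Dose-response statistics for the headline phenotypic readouts.

Normalizes each headline feature to the vehicle-control mean (per
biological replicate), runs per-compound one-way ANOVA across the five
dose groups and Tukey HSD against vehicle, and writes the tidy table with
significance tiers to results/dose_response.csv.
"""

from pathlib import Path

import pandas as pd

from edcprofiler.catalogue import FEATURE_NAMES, HEADLINE_FEATURES
from edcprofiler.stats import dose_response_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "well_features.csv")
    ok = ~table[list(FEATURE_NAMES)].isna().all(axis=1)
    dr = dose_response_table(table.loc[ok], features=HEADLINE_FEATURES)
    dr.to_csv(RESULTS / "dose_response.csv", index=False)

    from edcprofiler.plots import dose_response_panel

    figs = ROOT / "scratch" / "figures"
    for feat in ("living_cell_count", "asyn_intensity_in_th_pos_cells",
                 "neurite_length_per_cell_um", "membrane_TH_intensity_mean"):
        dose_response_panel(dr, feat, save_to=figs / f"dose_response_{feat}.png")

    sig = dr[(dr.dose_uM > 0) & (dr.stars != "ns")]
    print(f"{len(sig)} significant dose-vs-vehicle contrasts "
          f"of {len(dr[dr.dose_uM > 0])}")
    for feat in dr.feature.unique():
        hits = sig[sig.feature == feat]
        if len(hits):
            desc = "; ".join(
                f"{r.compound}@{r.dose_uM}uM {r.stars} ({r.normalized_mean:.2f}x)"
                for r in hits.itertuples()
            )
            print(f"  {feat}: {desc}")
        elif feat == "living_cell_count":
            print(f"  {feat}: no significant change (viability null holds)")
        else:
            print(f"  {feat}: no significant change")


if __name__ == "__main__":
    main()
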