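#!/usr/bin/env python
"""Build phenotypic profiles and cluster the treatment conditions.

Robust-scales the well table, median-aggregates per condition, computes
the pairwise cosine distance matrix with average-linkage clustering, and
embeds the wells in 2-D with UMAP.  Checks the compound-class structure:
bisphenol profiles should sit closer to each other than to perfluoroalkyl
profiles at the top dose.
"""

import json
from pathlib import Path

import pandas as pd

from edcprofiler.catalogue import FEATURE_NAMES
from edcprofiler.classify import label_wells
from edcprofiler.pipeline import stage_seed
from edcprofiler.profiling import (
    aggregate_profiles,
    cosine_distance_matrix,
    embed_wells,
    robust_scale,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "well_features.csv")
    ok = ~table[list(FEATURE_NAMES)].isna().all(axis=1)
    sub = table.loc[ok].reset_index(drop=True)
    feats = sub[list(FEATURE_NAMES)]
    sub[list(FEATURE_NAMES)] = feats.fillna(feats.median())
    scaled = robust_scale(sub)
    profiles = aggregate_profiles(scaled)
    dm, _, order, newick = cosine_distance_matrix(profiles)
    dm.to_csv(RESULTS / "condition_cosine_distance.csv")
    (RESULTS / "condition_dendrogram.nwk").write_text(newick + "\n")

    from edcprofiler.plots import condition_distance_heatmap

    condition_distance_heatmap(
        dm, order, save_to=ROOT / "scratch" / "figures" / "condition_distance.png"
    )

    top = dm.loc[
        [("BPA", 2.0), ("BPS", 2.0)], [("PFOS", 2.0), ("PFOA", 2.0)]
    ]
    within_bp = dm.loc[("BPA", 2.0), ("BPS", 2.0)]
    within_pf = dm.loc[("PFOS", 2.0), ("PFOA", 2.0)]
    between = float(top.to_numpy().mean())
    print(f"cosine distance at 2 uM: BPA-BPS {within_bp:.3f}, "
          f"PFOS-PFOA {within_pf:.3f}, between classes {between:.3f}")
    print("leaf order:", " | ".join("_".join(map(str, o)) for o in order))

    labels = label_wells(scaled.table)
    coords, sil = embed_wells(
        scaled.table, method="umap", seed=stage_seed(SEED, "profile"), labels=labels
    )
    coords.assign(label=labels.to_numpy()).to_csv(RESULTS / "embedding_umap.csv", index=False)
    (RESULTS / "embedding_umap_silhouette.json").write_text(
        json.dumps({"silhouette_treated_vs_control": sil})
    )
    print(f"UMAP silhouette (treated vs control): {sil:.3f}" if sil is not None
          else "UMAP silhouette not defined")


if __name__ == "__main__":
    main()
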