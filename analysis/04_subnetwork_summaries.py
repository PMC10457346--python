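#!/usr/bin/env python
"""Subnetwork local-efficiency summaries and derived phenotypes.

Averages nodal local efficiency over the default mode network, visual
network (control), hippocampus (4 ROIs) and superior temporal gyrus
(2-ROI control), per subject and cost; derives amyloid status from
global SUVR (> 1.11) and the hippocampal-volume/ICV ratio.

Run: python analysis/04_subnetwork_summaries.py
"""

import argparse
from pathlib import Path

import pandas as pd

from amynet import io
from amynet.summaries import derive_phenotypes, load_roi_metadata, summarize_subnetworks

parser = argparse.ArgumentParser()
parser.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

metrics = io.read_metrics(args.metrics)
meta = load_roi_metadata()
present = set(metrics.loc[metrics["roi_id"] != "", "roi_id"])
summaries = summarize_subnetworks(metrics, meta[meta["roi_id"].isin(present)])
summaries.to_csv(args.out_dir / "subnetwork_summaries.csv", index=False)

pheno = derive_phenotypes(pd.read_csv(args.cohort_dir / "phenotypes.csv"))
pheno.to_csv(args.out_dir / "phenotypes_derived.csv", index=False)

print("mean local efficiency by target (averaged over subjects and costs):")
print(summaries.groupby("target")["value"].mean().round(3))
n_pos = int(pheno["abeta_positive"].sum())
print(f"\namyloid-positive: {n_pos}/{len(pheno)} "
      f"({100 * n_pos / len(pheno):.1f}%) by the SUVR > 1.11 rule")
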