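"""Regional summaries of node metrics and phenotype derivations.

Covers the bookkeeping around the graph metrics: averaging nodal local
efficiency over declared ROI sets (whole network, default mode network,
visual network, hippocampus, superior temporal gyrus control), amyloid
classification from global florbetapir SUVR, and hippocampal volume
normalization by intracranial volume.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SUVR_THRESHOLD",
    "load_roi_metadata",
    "roi_set",
    "subnetwork_local_efficiency",
    "summarize_subnetworks",
    "classify_amyloid",
    "normalize_hippocampal_volume",
    "derive_phenotypes",
]

#: Global florbetapir SUVR cutoff: strictly greater -> amyloid positive.
SUVR_THRESHOLD = 1.11

TARGETS = ("whole_network", "DMN", "visual", "hippocampus", "STG")


def load_roi_metadata() -> pd.DataFrame:
    """Load the packaged 135-ROI metadata table.

    The subnetwork labels (DMN/visual/other), hippocampus flags (4 ROIs:
    rostral/caudal x left/right) and superior-temporal-gyrus control flags
    (2 ROIs) are a synthetic stand-in with the documented schema; any table
    with the same columns can be passed to the summary functions instead.
    """
    with resources.files("amynet.data").joinpath(
        "roi_metadata_synthetic.csv"
    ).open() as fh:
        meta = pd.read_csv(fh)
    return meta


def roi_set(meta: pd.DataFrame, target: str) -> list[str]:
    """ROI ids belonging to a summary target."""
    if target == "whole_network":
        ids = meta["roi_id"]
    elif target == "hippocampus":
        ids = meta.loc[meta["is_hippocampus"] == 1, "roi_id"]
    elif target == "STG":
        ids = meta.loc[meta["is_stg_control"] == 1, "roi_id"]
    elif target in ("DMN", "visual"):
        ids = meta.loc[meta["subnetwork"] == target, "roi_id"]
    else:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    out = [str(r) for r in ids]
    if not out:
        raise ValueError(f"target {target!r} has an empty ROI set")
    return out


def subnetwork_local_efficiency(
    node_values: pd.Series | dict, meta: pd.DataFrame, target: str
) -> float:
    """Unweighted mean of nodal local efficiency over a target ROI set.

    ``node_values`` maps roi_id -> local efficiency (one cost level of one
    subject). Every member ROI of the target must be present.
    """
    values = pd.Series(node_values)
    members = roi_set(meta, target)
    missing = [r for r in members if r not in values.index]
    if missing:
        raise KeyError(f"target {target!r}: missing node values for {missing[:5]}")
    return float(values.loc[members].mean())


def summarize_subnetworks(
    metrics: pd.DataFrame, meta: pd.DataFrame, targets=TARGETS
) -> pd.DataFrame:
    """Per-subject, per-cost subnetwork means of nodal local efficiency.

    ``metrics`` is the tidy metric table; rows with metric=='local_efficiency'
    and a nonempty roi_id are the nodal values. Returns a tidy table with a
    ``target`` column appended.
    """
    nodal = metrics[
        (metrics["metric"] == "local_efficiency") & (metrics["roi_id"] != "")
    ]
    rows = []
    for (sid, cost), grp in nodal.groupby(["subject_id", "cost"], sort=True):
        values = grp.set_index("roi_id")["value"]
        for target in targets:
            rows.append(
                {
                    "subject_id": sid,
                    "cost": cost,
                    "metric": "local_efficiency",
                    "target": target,
                    "value": subnetwork_local_efficiency(values, meta, target),
                }
            )
    return pd.DataFrame(rows)


def classify_amyloid(global_suvr: float, threshold: float = SUVR_THRESHOLD) -> bool:
    """Amyloid-positive iff global SUVR strictly exceeds the threshold."""
    suvr = np.asarray(global_suvr, dtype=float)
    if np.any(suvr <= 0):
        raise ValueError("global SUVR must be positive")
    out = suvr > threshold
    return bool(out) if out.ndim == 0 else out


def normalize_hippocampal_volume(volume: float, icv: float) -> float:
    """Hippocampal volume as a fraction of total intracranial volume."""
    icv_arr = np.asarray(icv, dtype=float)
    if np.any(icv_arr <= 0):
        raise ValueError("intracranial volume must be positive")
    out = np.asarray(volume, dtype=float) / icv_arr
    return float(out) if out.ndim == 0 else out


def derive_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns: abeta_positive and hv_ratio (where volumes exist)."""
    out = pheno.copy()
    out["abeta_positive"] = classify_amyloid(out["global_suvr"].to_numpy()).astype(int)
    if {"hippocampal_volume", "icv"}.issubset(out.columns):
        out["hv_ratio"] = normalize_hippocampal_volume(
            out["hippocampal_volume"].to_numpy(), out["icv"].to_numpy()
        )
    return out
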