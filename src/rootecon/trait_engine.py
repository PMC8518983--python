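"""Derived root-economics traits, genotype means and panel summaries.

Combines per-plant root architecture features (diameter-split at 0.3 mm into
axial vs lateral tissue), shoot/root dry masses and the total respiration
flux into the named trait set used throughout the analysis:

======  ==========================================  ==============
column  meaning                                     unit
======  ==========================================  ==============
SDW     shoot dry weight                            g
TDW     total dry weight (SDW + RDW)                g
RDW     root dry weight                             g
TRR     total root respiration                      nmol CO2 s-1
SRR_L   specific respiration per root length        nmol s-1 m-1
SRR_M   specific respiration per root mass          nmol s-1 g-1
SRL     specific root length                        m g-1
RMF     root mass fraction                          %
TRL     total root length                           mm
ARL     axial root length (> 0.3 mm diameter)       mm
LRL     lateral root length (<= 0.3 mm diameter)    mm
L_A_L   lateral:axial root length ratio             mm mm-1
TRV     total root volume                           mm3
ARV     axial root volume                           mm3
LRV     lateral root volume                         mm3
L_A_V   lateral:axial root volume ratio             mm3 mm-3
TSA     total root surface area                     mm2
ASA     axial root surface area                     mm2
LSA     lateral root surface area                   mm2
AvgD    average root diameter                       mm
Tip     number of root tips                         n
BP      number of branch points                     n
BF      branching frequency (BP/TRL)                n mm-1
BD      branching density (Tip per cm axial root)   n cm-1
RTD     root tissue density                         g cm-3
======  ==========================================  ==============

The residual respiration trait SRR_R (nmol s-1) is appended later by
:mod:`rootecon.respiration_partition`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the 25 core traits, in reporting order
CORE_TRAITS = [
    "SDW", "TDW", "RDW", "TRR", "SRR_L", "SRR_M", "SRL", "RMF",
    "TRL", "ARL", "LRL", "L_A_L", "TRV", "ARV", "LRV", "L_A_V",
    "TSA", "ASA", "LSA", "AvgD", "Tip", "BP", "BF", "BD", "RTD",
]

#: expected columns of a root-feature table (RhizoVision-style export)
FEATURE_COLUMNS = [
    "sample_id", "tips", "branch_points",
    "trl_mm", "arl_mm", "lrl_mm",
    "trv_mm3", "arv_mm3", "lrv_mm3",
    "tsa_mm2", "asa_mm2", "lsa_mm2",
    "avg_diameter_mm",
]

MASS_COLUMNS = ["sample_id", "sdw_g", "rdw_g"]

#: length/volume additivity tolerance (axial + lateral vs total)
_ADDITIVITY_RTOL = 0.01


def validate_features(features: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    for total, parts in (("trl_mm", ("arl_mm", "lrl_mm")),
                        ("trv_mm3", ("arv_mm3", "lrv_mm3"))):
        tot = features[total].to_numpy(float)
        s = features[list(parts)].sum(axis=1).to_numpy(float)
        bad = ~np.isclose(s, tot, rtol=_ADDITIVITY_RTOL, atol=1e-9)
        if bad.any():
            log.warning(
                "%d samples violate %s = %s + %s within %.0f%%",
                int(bad.sum()), total, parts[0], parts[1], 100 * _ADDITIVITY_RTOL,
            )


def derive_traits(
    features: pd.DataFrame,
    masses: pd.DataFrame,
    flux: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the 25-trait plant-level table.

    Parameters
    ----------
    features : feature table with :data:`FEATURE_COLUMNS` (extra columns such
        as ``genotype_id``/``block_id`` are carried through)
    masses : table with ``sample_id, sdw_g, rdw_g``
    flux : flux table with ``sample_id, flux_nmol_s`` (from
        :func:`rootecon.gas_flux.batch_flux`)

    Returns
    -------
    (traits, rejects) : plant-level trait table (one row per sample) and a
        table of samples rejected for zero/invalid denominators.
    """
    validate_features(features)
    merged = features.merge(masses[MASS_COLUMNS], on="sample_id", how="inner")
    merged = merged.merge(flux[["sample_id", "flux_nmol_s"]], on="sample_id", how="inner")

    rejects: list[dict] = []
    ok_rows: list[int] = []
    for idx, row in merged.iterrows():
        reason = None
        if not row["rdw_g"] > 0:
            reason = "non-positive root dry weight"
        elif not row["sdw_g"] > 0:
            reason = "non-positive shoot dry weight"
        elif not row["trl_mm"] > 0:
            reason = "non-positive total root length"
        elif not row["arl_mm"] > 0:
            reason = "non-positive axial root length"
        elif not row["trv_mm3"] > 0:
            reason = "non-positive total root volume"
        elif not row["arv_mm3"] > 0:
            reason = "non-positive axial root volume"
        if reason:
            rejects.append(dict(sample_id=row["sample_id"], reason=reason))
        else:
            ok_rows.append(idx)
    d = merged.loc[ok_rows].reset_index(drop=True)

    out = pd.DataFrame({"sample_id": d["sample_id"]})
    for extra in ("genotype_id", "block_id"):
        if extra in d.columns:
            out[extra] = d[extra]
    out["SDW"] = d["sdw_g"]
    out["RDW"] = d["rdw_g"]
    out["TDW"] = d["sdw_g"] + d["rdw_g"]
    out["TRR"] = d["flux_nmol_s"]
    out["SRR_L"] = d["flux_nmol_s"] / (d["trl_mm"] / 1000.0)      # per m
    out["SRR_M"] = d["flux_nmol_s"] / d["rdw_g"]                   # per g
    out["SRL"] = (d["trl_mm"] / 1000.0) / d["rdw_g"]               # m g-1
    out["RMF"] = 100.0 * d["rdw_g"] / out["TDW"]                   # percent
    out["TRL"] = d["trl_mm"]
    out["ARL"] = d["arl_mm"]
    out["LRL"] = d["lrl_mm"]
    out["L_A_L"] = d["lrl_mm"] / d["arl_mm"]
    out["TRV"] = d["trv_mm3"]
    out["ARV"] = d["arv_mm3"]
    out["LRV"] = d["lrv_mm3"]
    out["L_A_V"] = d["lrv_mm3"] / d["arv_mm3"]
    out["TSA"] = d["tsa_mm2"]
    out["ASA"] = d["asa_mm2"]
    out["LSA"] = d["lsa_mm2"]
    out["AvgD"] = d["avg_diameter_mm"]
    out["Tip"] = d["tips"]
    out["BP"] = d["branch_points"]
    out["BF"] = d["branch_points"] / d["trl_mm"]                   # n mm-1
    out["BD"] = d["tips"] / (d["arl_mm"] / 10.0)                   # n cm-1
    out["RTD"] = d["rdw_g"] / (d["trv_mm3"] / 1000.0)              # g cm-3
    # reporting order
    lead = [c for c in ("sample_id", "genotype_id", "block_id") if c in out.columns]
    out = out[lead + CORE_TRAITS]
    return out, pd.DataFrame(rejects, columns=["sample_id", "reason"])


def genotype_means(plant_traits: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic genotype means per trait, missing values ignored.

    Requires a ``genotype_id`` column; returns one row per genotype with an
    ``n_reps`` column (replicates contributing to that genotype).
    """
    if "genotype_id" not in plant_traits.columns:
        raise ValueError("plant-level table needs a genotype_id column")
    trait_cols = [c for c in plant_traits.columns
                  if c not in ("sample_id", "genotype_id", "block_id")]
    g = plant_traits.groupby("genotype_id", sort=True)
    means = g[trait_cols].mean()
    means.insert(0, "n_reps", g.size())
    return means.reset_index()


def summarize(genotype_traits: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait mean/min/max and fold variation (max/min, 1 decimal).

    Computed on genotype means; fold variation is reported as NaN when the
    minimum is not positive (undefined).
    """
    if traits is None:
        traits = [c for c in genotype_traits.columns
                  if c in CORE_TRAITS or c == "SRR_R"]
    if len(genotype_traits) < 2:
        raise ValueError("summary needs at least 2 genotypes")
    rows = []
    for t in traits:
        col = genotype_traits[t].astype(float)
        lo, hi = col.min(), col.max()
        fold = round(hi / lo, 1) if lo > 0 else np.nan
        rows.append(dict(trait=t, mean=col.mean(), min=lo, max=hi, fold_variation=fold))
    return pd.DataFrame(rows)
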