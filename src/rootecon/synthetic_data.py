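"""Synthetic study generator with known ground truth.

Emulates every input the analysis consumes, at the scale of the wheat
seedling study the pipeline is built for: a randomized complete block
design of 276 genotypes x 4 blocks (1104 plants), chamber CO2 traces
recorded at 1 Hz for 90 s, RhizoVision-style root feature tables split at
the 0.3 mm diameter threshold, shoot/root dry masses, and a diploid
biallelic dosage matrix with missingness, a MAF spectrum and optional
two-population Balding-Nichols structure.

Root-system respiration truth follows the tissue-class model

    TRR = r_axial * ARV + r_lateral * (LRV - tipV) + r_tip * tipV

with default volume-specific rates in the ratio tip : lateral-axis : axial
= 30.5 : 8.1-fold-under-tip : 1 (i.e. tips respire 30.5x the axial rate
and 8.1x the lateral-axis rate), scaled so that mean total respiration
lands near 0.54 nmol s^-1 for a typical seedling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gas_flux import ChamberConfig, GasTrace
from .quant_genetics import GenotypeData

# default volume-specific respiration rates (nmol s^-1 mm^-3)
SRR_TIP_DEFAULT = 0.0244
SRR_AXIAL_DEFAULT = SRR_TIP_DEFAULT / 30.5       # 8.0e-4
SRR_LATERAL_AXIS_DEFAULT = SRR_TIP_DEFAULT / 8.1  # 3.012e-3


@dataclass(frozen=True)
class SimulationConfig:
    """Scale and sampling parameters of a synthetic study."""

    n_genotypes: int = 276
    n_blocks: int = 4
    n_markers: int = 5000
    n_chromosomes: int = 21
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    fst: float = 0.0  # two-population divergence; 0 = unstructured
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_blocks", "n_markers", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lower <= upper <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")


def simulate_genotypes(config: SimulationConfig) -> GenotypeData:
    """Sample a dosage matrix under Hardy-Weinberg per marker.

    Per-marker allele frequencies are uniform on ``maf_range``; with
    ``fst > 0`` the panel splits into two subpopulations whose frequencies
    are Balding-Nichols draws around the ancestral frequency.  Missing
    calls are i.i.d. at ``missing_rate``.  Markers are spread over
    ``n_chromosomes`` with ascending positions.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_m = config.n_genotypes, config.n_markers
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=n_m)

    if config.fst > 0:
        f = config.fst
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_pop = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2, n_m)
        p_pop = np.clip(p_pop, 1e-4, 1.0 - 1e-4)
        populations = np.zeros(n_g, dtype=int)
        populations[n_g // 2:] = 1
        p_geno = p_pop[populations]  # (n_g, n_m)
    else:
        populations = None
        p_geno = np.broadcast_to(p_anc, (n_g, n_m))

    dosages = rng.binomial(2, p_geno).astype(float)
    if config.missing_rate > 0:
        miss = rng.random((n_g, n_m)) < config.missing_rate
        dosages[miss] = np.nan

    # marker map: markers dealt round the chromosomes in order, with
    # strictly increasing positions from cumulative gaps
    chrom_idx = np.sort(np.arange(n_m) % config.n_chromosomes)
    positions = np.empty(n_m, dtype=int)
    for c in range(config.n_chromosomes):
        sel = chrom_idx == c
        gaps = rng.integers(1_000, 200_000, size=int(sel.sum()))
        positions[sel] = np.cumsum(gaps)
    marker_map = pd.DataFrame(
        {
            "marker_id": [f"M{i + 1:06d}" for i in range(n_m)],
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "pos": positions,
        }
    )
    return GenotypeData(
        dosages=dosages,
        genotype_ids=[f"G{i + 1:04d}" for i in range(n_g)],
        marker_map=marker_map,
        populations=populations,
    )


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`simulate_traits`."""

    genetic_values: pd.DataFrame          # genotype x trait, polygenic + QTL
    sigma_g2: np.ndarray                  # polygenic variance per trait
    sigma_e2: np.ndarray
    block_effects: np.ndarray
    qtl: list[tuple[str, np.ndarray]]     # (marker_id, per-trait effect)
    qtl_variance: np.ndarray              # additive variance added per trait
    h2_true: np.ndarray                   # includes QTL variance


def simulate_traits(
    genotypes: GenotypeData,
    sigma_g2: float | Sequence[float] = 1.0,
    sigma_e2: float | Sequence[float] = 3.0,
    block_effects: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
    qtl: Sequence[tuple[str, float | Sequence[float]]] = (),
    n_traits: int = 1,
    genetic_corr: np.ndarray | None = None,
    seed: int = 0,
    population_effect: float = 0.0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Replicated RCBD observations with planted variance components.

    ``y_ijt = mu + block_j + g_it + sum_q x_iq beta_qt + e_ijt`` with
    polygenic values ``g_i ~ N(0, Sigma_g)`` (``Sigma_g`` built from
    ``sigma_g2`` and ``genetic_corr``), i.i.d. residuals per plant, and
    optional QTL effects on the (mean-imputed) dosages.
    ``population_effect`` shifts every trait by that amount in the second
    subpopulation (confounding with structure, for calibration studies).
    The returned truth includes per-trait broad-sense heritability
    ``H2 = Vg_total / (Vg_total + sigma_e2 / r)``.
    """
    rng = np.random.default_rng(seed)
    n_g = genotypes.n_genotypes
    r = len(block_effects)
    sg2 = np.broadcast_to(np.asarray(sigma_g2, float), (n_traits,)).copy()
    se2 = np.broadcast_to(np.asarray(sigma_e2, float), (n_traits,)).copy()
    if (sg2 < 0).any() or (se2 < 0).any():
        raise ValueError("variances must be non-negative")
    if genetic_corr is None:
        genetic_corr = np.eye(n_traits)
    genetic_corr = np.asarray(genetic_corr, float)
    if genetic_corr.shape != (n_traits, n_traits):
        raise ValueError("genetic_corr shape must be (n_traits, n_traits)")
    if np.linalg.eigvalsh(0.5 * (genetic_corr + genetic_corr.T)).min() < -1e-8:
        raise ValueError("genetic_corr must be positive semi-definite")

    sd = np.sqrt(sg2)
    cov = genetic_corr * np.outer(sd, sd)
    g = rng.multivariate_normal(np.zeros(n_traits), cov, size=n_g, method="eigh")

    imputed = genotypes.imputed()
    marker_index = {m: j for j, m in enumerate(genotypes.marker_map["marker_id"])}
    qtl_resolved: list[tuple[str, np.ndarray]] = []
    qtl_var = np.zeros(n_traits)
    for marker_id, effect in qtl:
        if marker_id not in marker_index:
            raise KeyError(f"unknown QTL marker {marker_id!r}")
        eff = np.zeros(n_traits)
        effect_arr = np.atleast_1d(np.asarray(effect, float))
        if effect_arr.size == 1:
            eff[0] = effect_arr[0]
        elif effect_arr.size == n_traits:
            eff = effect_arr
        else:
            raise ValueError("QTL effect must be scalar or one value per trait")
        x = imputed[:, marker_index[marker_id]]
        g = g + np.outer(x - x.mean(), eff)
        p_hat = x.mean() / 2.0
        qtl_var += 2.0 * p_hat * (1.0 - p_hat) * eff**2
        qtl_resolved.append((marker_id, eff))

    if population_effect != 0.0 and genotypes.populations is not None:
        g = g + population_effect * genotypes.populations[:, None]

    rows = []
    trait_cols = [f"trait_{t + 1}" for t in range(n_traits)]
    for j in range(r):
        e = rng.normal(0.0, np.sqrt(se2), size=(n_g, n_traits))
        vals = block_effects[j] + g + e
        block = pd.DataFrame(vals, columns=trait_cols)
        block.insert(0, "block_id", f"B{j + 1}")
        block.insert(0, "genotype_id", genotypes.genotype_ids)
        block.insert(0, "sample_id",
                     [f"{gid}_B{j + 1}" for gid in genotypes.genotype_ids])
        rows.append(block)
    plants = pd.concat(rows, ignore_index=True)

    vg_total = sg2 + qtl_var
    h2 = np.where(vg_total + se2 / r > 0, vg_total / (vg_total + se2 / r), 0.0)
    truth = TruthRecord(
        genetic_values=pd.DataFrame(g, index=genotypes.genotype_ids,
                                    columns=trait_cols),
        sigma_g2=sg2, sigma_e2=se2,
        block_effects=np.asarray(block_effects, float),
        qtl=qtl_resolved, qtl_variance=qtl_var, h2_true=h2,
    )
    return plants, truth


def flux_to_slope(true_flux: float, chamber: ChamberConfig,
                  corrected_volume_ml: float | None = None) -> float:
    """Invert the ideal-gas flux equation to a CO2 slope (µmol mol^-1 s^-1)."""
    v = chamber.chamber_volume_ml if corrected_volume_ml is None else corrected_volume_ml
    moles = chamber.pressure_kPa * (v / 1000.0) / (
        chamber.gas_constant * chamber.temperature_K
    )
    return true_flux / (moles * 1e3)


def simulate_gas_trace(
    true_flux: float,
    chamber: ChamberConfig | None = None,
    noise_sd: float = 0.2,
    transient_amplitude: float = 3.0,
    transient_halflife: float = 6.0,
    seed: int = 0,
    sample_id: str = "SIM0001",
    baseline_co2: float = 420.0,
    corrected_volume_ml: float | None = None,
) -> GasTrace:
    """91 chamber readings at 1 Hz consistent with a known flux.

    The underlying CO2 slope is the ideal-gas inversion of ``true_flux``;
    an additive exponential transient (halved every ``transient_halflife``
    seconds, so mostly decayed within the 20 s dead band) models chamber
    equilibration, plus i.i.d. Gaussian read noise.
    """
    if true_flux < 0:
        raise ValueError("true_flux must be non-negative")
    chamber = chamber or ChamberConfig()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 91.0)
    slope = flux_to_slope(true_flux, chamber, corrected_volume_ml)
    co2 = baseline_co2 + slope * t
    if transient_amplitude != 0.0:
        co2 = co2 + transient_amplitude * 0.5 ** (t / transient_halflife)
    if noise_sd > 0:
        co2 = co2 + rng.normal(0.0, noise_sd, size=t.size)
    return GasTrace(sample_id=sample_id, time_s=t, co2_umol_mol=co2)


DEFAULT_ARCHITECTURE = dict(
    arl_mean=1456.0, arl_sd=350.0,       # axial root length, mm
    lrl_mean=2670.0, lrl_sd=700.0,       # lateral root length, mm
    d_axial_mean=0.46, d_axial_sd=0.03,  # axial diameter, mm (> 0.3)
    d_lateral_mean=0.20, d_lateral_sd=0.015,
    tip_density_per_mm=0.15,             # lateral tips per mm lateral root
    tip_count_sd=30.0,
    seminal_count=4,
    bp_per_mm=0.32,                      # branch points per mm total length
    tip_unit_volume_mm3=0.01,
    resp_noise_sd=0.05,                  # nmol s^-1 on true respiration
)


def simulate_root_system(
    srr_axial: float = SRR_AXIAL_DEFAULT,
    srr_lateral_axis: float = SRR_LATERAL_AXIS_DEFAULT,
    srr_tip: float = SRR_TIP_DEFAULT,
    architecture_params: dict | None = None,
    n_samples: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Root feature records plus the true tissue-partitioned respiration.

    Lengths and diameters vary allometrically around wheat-seedling means;
    volumes and surface areas follow cylinder geometry per tissue class.
    True respiration is the volume-weighted sum over axial, lateral-axis
    and tip tissue plus Gaussian noise of ``resp_noise_sd``.
    """
    if min(srr_axial, srr_lateral_axis, srr_tip) < 0:
        raise ValueError("specific respiration rates must be non-negative")
    p = dict(DEFAULT_ARCHITECTURE)
    if architecture_params:
        p.update(architecture_params)
    rng = np.random.default_rng(seed)
    n = n_samples

    arl = np.clip(rng.normal(p["arl_mean"], p["arl_sd"], n), 150.0, None)
    lrl = np.clip(rng.normal(p["lrl_mean"], p["lrl_sd"], n), 150.0, None)
    d_ax = np.clip(rng.normal(p["d_axial_mean"], p["d_axial_sd"], n), 0.32, None)
    d_lat = np.clip(rng.normal(p["d_lateral_mean"], p["d_lateral_sd"], n), 0.05, 0.295)
    tips = p["seminal_count"] + np.maximum(
        np.round(p["tip_density_per_mm"] * lrl
                 + rng.normal(0.0, p["tip_count_sd"], n)), 1.0)
    bp = np.maximum(np.round(p["bp_per_mm"] * (arl + lrl)
                             + rng.normal(0.0, 40.0, n)), 5.0)

    arv = np.pi * (d_ax / 2.0) ** 2 * arl
    lrv = np.pi * (d_lat / 2.0) ** 2 * lrl
    asa = np.pi * d_ax * arl
    lsa = np.pi * d_lat * lrl
    trl = arl + lrl
    avg_d = (d_ax * arl + d_lat * lrl) / trl

    features = pd.DataFrame(
        {
            "sample_id": [f"R{i + 1:05d}" for i in range(n)],
            "tips": tips,
            "branch_points": bp,
            "trl_mm": trl,
            "arl_mm": arl,
            "lrl_mm": lrl,
            "trv_mm3": arv + lrv,
            "arv_mm3": arv,
            "lrv_mm3": lrv,
            "tsa_mm2": asa + lsa,
            "asa_mm2": asa,
            "lsa_mm2": lsa,
            "avg_diameter_mm": avg_d,
        }
    )
    tip_v = np.maximum(tips - p["seminal_count"], 0.0) * p["tip_unit_volume_mm3"]
    lat_axis_v = np.maximum(lrv - tip_v, 0.0)
    true_resp = (
        srr_axial * arv + srr_lateral_axis * lat_axis_v + srr_tip * tip_v
    )
    if p["resp_noise_sd"] > 0:
        true_resp = true_resp + rng.normal(0.0, p["resp_noise_sd"], n)
    return features, true_resp


# ---------------------------------------------------------------------------
# file writers (formats identical to what the pipeline reads)

def write_trace_file(trace: GasTrace, out_dir: str | Path) -> Path:
    """Write one chamber trace as ``<barcode>.txt`` in the shipped dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{trace.sample_id}.txt"
    with open(path, "w") as fh:
        fh.write("# synthetic chamber trace\n")
        fh.write("time_s co2_umol_mol\n")
        for t, c in zip(trace.time_s, trace.co2_umol_mol):
            fh.write(f"{t:.0f} {c:.4f}\n")
    return path


def simulate_annotation(
    genotypes: GenotypeData,
    genes_per_chrom: int = 10,
    near_markers: Sequence[str] = (),
    gene_length: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene annotation table (1-based inclusive coordinates) for window lookup.

    Genes tile each chromosome at random positions; additionally one gene is
    placed spanning each marker named in ``near_markers`` so that positional
    candidate-window lookups have guaranteed hits.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gid = 1
    for chrom, grp in genotypes.marker_map.groupby("chrom", sort=False):
        span = int(grp["pos"].max())
        for _ in range(genes_per_chrom):
            start = int(rng.integers(1, max(span - gene_length, 2)))
            rows.append(dict(gene_id=f"GENE{gid:05d}", chrom=chrom,
                             start=start, end=start + gene_length - 1))
            gid += 1
    mk = genotypes.marker_map.set_index("marker_id")
    for m in near_markers:
        pos = int(mk.loc[m, "pos"])
        start = max(pos - gene_length // 2, 1)
        rows.append(dict(gene_id=f"GENE{gid:05d}", chrom=str(mk.loc[m, "chrom"]),
                         start=start, end=start + gene_length - 1))
        gid += 1
    ann = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return ann
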