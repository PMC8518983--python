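"""End-to-end orchestration: fixture generation and the full analysis run.

``make_fixture`` builds a complete synthetic study on disk (chamber traces,
feature/mass tables, genotypes, annotation, truth record, run config);
``run_pipeline`` executes flux -> traits -> partition -> heritability ->
network/PCA -> GWAS from a single config and writes every stage's tables
plus a machine-readable summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gas_flux, quant_genetics, respiration_partition, synthetic_data, trait_engine, trait_network

log = logging.getLogger(__name__)

#: the six multi-trait GWAS sets (functional/structural trait groupings)
TRAIT_SETS: dict[str, list[str]] = {
    "biomass": ["RDW", "SDW"],
    "respiration": ["TRR", "RDW", "RMF", "Tip", "ARL", "BD"],
    "morphology": ["ARL", "LRL", "ARV", "LRV", "ASA", "LSA"],
    "topology": ["BP", "BF", "BD"],
    "construction": ["SRL", "RTD", "AvgD"],
    "allocation": ["RMF", "L_A_L", "L_A_V"],
}

KNOWN_TRAITS = set(trait_engine.CORE_TRAITS) | {"SRR_R"}


@dataclass
class PipelineConfig:
    traces_dir: str
    features_csv: str
    masses_csv: str
    genotypes_tsv: str | None = None
    annotation_tsv: str | None = None
    chamber: dict = field(default_factory=dict)
    seminal_count: int = 4
    tip_unit_volume_mm3: float = 0.01
    gwas_modes: list[str] = field(default_factory=lambda: ["uni", "multi", "pc"])
    trait_sets: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in TRAIT_SETS.items()})
    logp_threshold: float = 3.5
    fdr_q: float = 0.05
    window_bp: int = 250_000
    n_pcs: int = 10
    max_missing: float = 0.5
    min_maf: float = 0.05
    ggm_cutoff: float = 0.15
    seed: int = 0

    def chamber_config(self) -> gas_flux.ChamberConfig:
        return gas_flux.ChamberConfig(**self.chamber)

    def validate(self) -> None:
        for name in ("traces_dir", "features_csv", "masses_csv"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        bad_modes = set(self.gwas_modes) - {"uni", "multi", "pc"}
        if bad_modes:
            raise ValueError(f"unknown GWAS modes: {sorted(bad_modes)}")
        if self.gwas_modes and not self.genotypes_tsv:
            raise ValueError("GWAS requested but no genotypes_tsv configured")
        if self.genotypes_tsv and not Path(self.genotypes_tsv).exists():
            raise FileNotFoundError(f"genotypes_tsv does not exist: {self.genotypes_tsv}")
        if self.annotation_tsv and not Path(self.annotation_tsv).exists():
            raise FileNotFoundError(f"annotation_tsv does not exist: {self.annotation_tsv}")
        for name, members in self.trait_sets.items():
            unknown = set(members) - KNOWN_TRAITS
            if unknown:
                raise ValueError(f"trait set {name!r} has unknown traits: {sorted(unknown)}")
        self.chamber_config()  # raises on invalid chamber settings

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# fixture generation

FIXTURE_PRESETS = {
    "tiny": dict(n_genotypes=50, n_blocks=4, n_markers=500, n_chromosomes=3),
    "paper-scale": dict(n_genotypes=276, n_blocks=4, n_markers=5000, n_chromosomes=21),
}

# latent genetic drivers of the synthetic panel and the linear coefficients
# mapping them into plant-level features (units per 1 SD of driver)
_DRIVERS = ("size", "lat", "dens", "metab")
_QTL_DRIVER_SHARE = 0.25   # fraction of each driver's variance from its QTL
_ARL_G_SD, _ARL_E_SD = 250.0, 500.0          # mm -> H2 = 0.5
_LRL_SIZE_SD, _LRL_LAT_SD, _LRL_E_SD = 400.0, 350.0, 900.0
_METAB_G_SD, _RESP_E_SD = 0.03, 0.06         # nmol s^-1 -> H2 = 0.5


def _pick_qtl_markers(G: quant_genetics.GenotypeData, n: int) -> list[str]:
    """Deterministic choice: high-MAF, low-missingness, distinct chromosomes."""
    maf = G.maf()
    miss = G.missing_fraction()
    order = np.argsort(np.abs(maf - 0.45))
    chosen: list[str] = []
    used_chroms: set[str] = set()
    for j in order:
        if miss[j] > 0.05:
            continue
        chrom = G.marker_map["chrom"].iloc[j]
        if chrom in used_chroms and len(used_chroms) < G.marker_map["chrom"].nunique():
            continue
        chosen.append(G.marker_map["marker_id"].iloc[j])
        used_chroms.add(chrom)
        if len(chosen) == n:
            break
    return chosen


def make_fixture(preset: str = "tiny", seed: int = 0, out_dir: str | Path = "fixture") -> Path:
    """Generate a complete synthetic study on disk.

    Returns the fixture directory, which contains ``traces/``,
    ``features.csv``, ``masses.csv``, ``genotypes.tsv``, ``annotation.tsv``,
    ``truth.json`` and a ready-to-run ``config.yaml``.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"preset must be one of {sorted(FIXTURE_PRESETS)}")
    scale = FIXTURE_PRESETS[preset]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    config = synthetic_data.SimulationConfig(
        missing_rate=0.02, fst=0.05, seed=seed, **scale
    )
    G = synthetic_data.simulate_genotypes(config)
    imputed = G.imputed()
    mk_index = {m: j for j, m in enumerate(G.marker_map["marker_id"])}

    # drivers: unit-variance genetic axes, one planted QTL each
    qtl_markers = _pick_qtl_markers(G, len(_DRIVERS))
    drivers: dict[str, np.ndarray] = {}
    qtl_truth = {}
    for d, marker in zip(_DRIVERS, qtl_markers):
        x = imputed[:, mk_index[marker]]
        p_hat = x.mean() / 2.0
        var_x = 2.0 * p_hat * (1.0 - p_hat)
        beta = np.sqrt(_QTL_DRIVER_SHARE / var_x)
        poly = rng.normal(0.0, np.sqrt(1.0 - _QTL_DRIVER_SHARE), config.n_genotypes)
        drivers[d] = beta * (x - x.mean()) + poly
        qtl_truth[d] = dict(marker_id=marker, effect=float(beta),
                            maf=float(min(p_hat, 1 - p_hat)))

    n_g, n_b = config.n_genotypes, config.n_blocks
    arl_block = np.resize([0.0, 40.0, -30.0, 20.0], n_b)
    lrl_block = np.resize([0.0, 60.0, -50.0, 30.0], n_b)
    chamber = gas_flux.ChamberConfig()

    feat_rows, mass_rows = [], []
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(exist_ok=True)
    srr = dict(a=synthetic_data.SRR_AXIAL_DEFAULT,
               l=synthetic_data.SRR_LATERAL_AXIS_DEFAULT,
               t=synthetic_data.SRR_TIP_DEFAULT)
    for j in range(n_b):
        size, lat, dens, metab = (drivers[d] for d in _DRIVERS)
        arl = np.clip(1456.0 + _ARL_G_SD * size + arl_block[j]
                      + rng.normal(0, _ARL_E_SD, n_g), 150.0, None)
        lrl = np.clip(2670.0 + _LRL_SIZE_SD * size + _LRL_LAT_SD * lat + lrl_block[j]
                      + rng.normal(0, _LRL_E_SD, n_g), 150.0, None)
        d_ax = np.clip(0.46 + 0.02 * dens + rng.normal(0, 0.015, n_g), 0.32, 0.75)
        d_lat = np.clip(0.20 + 0.012 * dens + rng.normal(0, 0.008, n_g), 0.08, 0.295)
        tips = 4.0 + np.maximum(np.round(0.15 * lrl + rng.normal(0, 30.0, n_g)), 1.0)
        bp = np.maximum(np.round(0.32 * (arl + lrl) + rng.normal(0, 40.0, n_g)), 5.0)
        arv = np.pi * (d_ax / 2.0) ** 2 * arl
        lrv = np.pi * (d_lat / 2.0) ** 2 * lrl
        asa = np.pi * d_ax * arl
        lsa = np.pi * d_lat * lrl
        trl = arl + lrl
        trv = arv + lrv
        rtd = np.clip(0.042 + 0.003 * dens + rng.normal(0, 0.002, n_g), 0.02, 0.08)
        rdw = rtd * trv / 1000.0
        shoot_ratio = np.clip(2.79 + 0.25 * lat + rng.normal(0, 0.35, n_g), 1.2, 5.0)
        sdw = rdw * shoot_ratio

        tip_v = np.maximum(tips - 4.0, 0.0) * 0.01
        lat_axis_v = np.maximum(lrv - tip_v, 0.0)
        trr = np.clip(
            srr["a"] * arv + srr["l"] * lat_axis_v + srr["t"] * tip_v
            + _METAB_G_SD * metab + rng.normal(0, _RESP_E_SD, n_g),
            0.02, None,
        )
        for i in range(n_g):
            sid = f"{G.genotype_ids[i]}_B{j + 1}"
            feat_rows.append(dict(
                sample_id=sid, genotype_id=G.genotype_ids[i], block_id=f"B{j + 1}",
                tips=tips[i], branch_points=bp[i],
                trl_mm=trl[i], arl_mm=arl[i], lrl_mm=lrl[i],
                trv_mm3=trv[i], arv_mm3=arv[i], lrv_mm3=lrv[i],
                tsa_mm2=asa[i] + lsa[i], asa_mm2=asa[i], lsa_mm2=lsa[i],
                avg_diameter_mm=(d_ax[i] * arl[i] + d_lat[i] * lrl[i]) / trl[i],
            ))
            mass_rows.append(dict(sample_id=sid, sdw_g=sdw[i], rdw_g=rdw[i]))
            corr_vol = chamber.chamber_volume_ml - trv[i] / 1000.0
            trace = synthetic_data.simulate_gas_trace(
                trr[i], chamber=chamber, noise_sd=0.2,
                transient_amplitude=3.0, transient_halflife=6.0,
                seed=int(rng.integers(0, 2**31 - 1)), sample_id=sid,
                corrected_volume_ml=corr_vol,
            )
            synthetic_data.write_trace_file(trace, traces_dir)

    features = pd.DataFrame(feat_rows)
    masses = pd.DataFrame(mass_rows)
    features.to_csv(out_dir / "features.csv", index=False)
    masses.to_csv(out_dir / "masses.csv", index=False)
    G.to_tsv(out_dir / "genotypes.tsv")
    ann = synthetic_data.simulate_annotation(
        G, genes_per_chrom=10, near_markers=qtl_markers, seed=seed
    )
    ann.to_csv(out_dir / "annotation.tsv", sep="\t", index=False)

    h2 = lambda vg, ve, r: vg / (vg + ve / r)  # noqa: E731
    truth = dict(
        preset=preset, seed=seed,
        n_genotypes=n_g, n_blocks=n_b, n_markers=config.n_markers,
        srr_rates=dict(axial=srr["a"], lateral_axis=srr["l"], tip=srr["t"]),
        srr_ratio_tip_axial=srr["t"] / srr["a"],
        srr_ratio_tip_lateral=srr["t"] / srr["l"],
        qtl=qtl_truth,
        qtl_driver_share=_QTL_DRIVER_SHARE,
        true_h2=dict(
            ARL=h2(_ARL_G_SD**2, _ARL_E_SD**2, n_b),
            LRL=h2(_LRL_SIZE_SD**2 + _LRL_LAT_SD**2, _LRL_E_SD**2, n_b),
            SRR_R=h2(_METAB_G_SD**2, _RESP_E_SD**2, n_b),
        ),
    )
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    cfg = PipelineConfig(
        traces_dir=str(traces_dir),
        features_csv=str(out_dir / "features.csv"),
        masses_csv=str(out_dir / "masses.csv"),
        genotypes_tsv=str(out_dir / "genotypes.tsv"),
        annotation_tsv=str(out_dir / "annotation.tsv"),
        seed=seed,
    )
    cfg.to_yaml(out_dir / "config.yaml")
    return out_dir


# ---------------------------------------------------------------------------
# the full run

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order; write stage tables and ``summary.json``.

    Identical config and input files produce a byte-identical summary (the
    pipeline itself consumes no randomness).  Hard stage errors abort with
    the stage name; per-sample problems land in reject tables.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    chamber = config.chamber_config()

    # -- stage 1: flux ------------------------------------------------------
    features = pd.read_csv(config.features_csv)
    volumes = features[["sample_id", "trv_mm3"]].rename(columns={"trv_mm3": "root_volume_mm3"})
    flux, flux_rejects = gas_flux.batch_flux(config.traces_dir, volumes, chamber)
    flux.to_csv(out / "flux.csv", index=False)
    flux_rejects.to_csv(out / "flux_rejects.csv", index=False)
    summary["flux"] = dict(n_samples=len(flux), n_rejects=len(flux_rejects),
                           mean_flux_nmol_s=round(float(flux["flux_nmol_s"].mean()), 6))

    # -- stage 2: traits ----------------------------------------------------
    masses = pd.read_csv(config.masses_csv)
    plant, trait_rejects = trait_engine.derive_traits(features, masses, flux)
    trait_rejects.to_csv(out / "trait_rejects.csv", index=False)

    # -- stage 3: respiration partition -------------------------------------
    vols = respiration_partition.partition_volumes(
        features, config.seminal_count, config.tip_unit_volume_mm3
    )
    model = respiration_partition.fit_partition_model(vols, flux)
    resid = respiration_partition.residual_trait(model, vols, flux)
    plant = plant.merge(resid, on="sample_id", how="left")
    plant.to_csv(out / "plant_traits.csv", index=False)
    geno = trait_engine.genotype_means(plant)
    geno.to_csv(out / "genotype_traits.csv", index=False)
    trait_engine.summarize(geno).to_csv(out / "trait_summary.csv", index=False)
    with open(out / "partition_model.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
    summary["partition"] = dict(
        r_squared=round(model.r_squared, 6),
        ratio_tip_axial=round(model.ratio_tip_axial, 4),
        ratio_tip_lateral=round(model.ratio_tip_lateral, 4),
        n_clamped=model.n_clamped,
    )

    # -- stage 4: heritability ----------------------------------------------
    trait_cols = [c for c in plant.columns
                  if c in trait_engine.CORE_TRAITS or c == "SRR_R"]
    h2_rows = []
    for t in trait_cols:
        vc = quant_genetics.fit_rcbd_reml(plant, value_col=t)
        h2_rows.append(dict(trait=t, sigma_g2=vc.sigma_g2, sigma_e2=vc.sigma_e2,
                            n_reps=vc.n_reps, H2=quant_genetics.broad_sense_h2(vc)))
    h2_df = pd.DataFrame(h2_rows)
    h2_df.to_csv(out / "heritability.csv", index=False)
    summary["heritability"] = {r["trait"]: round(r["H2"], 4) for r in h2_rows}

    # -- stage 5: correlations, PCA, network ---------------------------------
    gmeans = geno.set_index("genotype_id")
    core = gmeans[[c for c in trait_engine.CORE_TRAITS if c in gmeans.columns]]
    r, p = trait_network.pearson_matrix(core)
    r.to_csv(out / "correlations_r.csv")
    p.to_csv(out / "correlations_p.csv")
    pca_res = trait_network.pca(core, scale=True)
    pca_res.scores.to_csv(out / "pca_scores.csv")
    pca_res.loadings.to_csv(out / "pca_loadings.csv")
    pca_res.explained_variance_pct.rename("explained_pct").to_csv(out / "pca_variance.csv")
    pca_res.contributions_pct.to_csv(out / "pca_contributions.csv")
    net_traits = gmeans[[c for c in gmeans.columns
                         if c in KNOWN_TRAITS and c not in trait_network.GGM_EXCLUDED_TRAITS
                         and c != "SRR_R"]]
    net = trait_network.ggm_partial_correlations(net_traits, subset=list(net_traits.columns))
    net.edges(config.ggm_cutoff).to_csv(out / "network_edges.csv", index=False)
    centrality = trait_network.network_centrality(net, config.ggm_cutoff)
    centrality.to_csv(out / "network_centrality.csv", index=False)
    summary["pca_explained_pct"] = [
        round(float(v), 4) for v in pca_res.explained_variance_pct.iloc[:10]
    ]
    summary["network"] = dict(
        n_edges=len(net.edges(config.ggm_cutoff)),
        top_outdegree=centrality.sort_values(
            ["outdegree", "trait"], ascending=[False, True]
        )["trait"].iloc[0],
    )

    # -- stage 6: GWAS -------------------------------------------------------
    if config.gwas_modes:
        G = quant_genetics.GenotypeData.from_tsv(config.genotypes_tsv)
        G, qc = quant_genetics.filter_markers(G, config.max_missing, config.min_maf)
        K = quant_genetics.relatedness_matrix(G)
        summary["snp_qc"] = qc
        scans = []
        if "uni" in config.gwas_modes:
            for t in trait_cols:
                scans.append(quant_genetics.lmm_scan(gmeans[t], G, K=K, trait=t))
        if "multi" in config.gwas_modes:
            for name, members in config.trait_sets.items():
                present = [m for m in members if m in gmeans.columns]
                scans.append(quant_genetics.mv_lmm_scan(gmeans[present], G, K=K, label=name))
        if "pc" in config.gwas_modes:
            scans.append(quant_genetics.pc_gwas(pca_res.scores, G, K=K, n_pcs=config.n_pcs))
        assoc = pd.concat(scans, ignore_index=True)
        assoc = quant_genetics.declare_significant(
            assoc, config.logp_threshold, config.fdr_q
        )
        assoc.to_csv(out / "associations.csv", index=False)
        sig = assoc[assoc["raw_pass"]]
        summary["gwas"] = dict(
            n_markers=G.n_markers,
            n_tests=len(assoc),
            n_raw_pass=int(assoc["raw_pass"].sum()),
            n_fdr_pass=int(assoc["fdr_pass"].sum()),
        )
        if config.annotation_tsv:
            ann = pd.read_csv(config.annotation_tsv, sep="\t")
            hits = quant_genetics.candidate_windows(
                sig.drop_duplicates("marker_id"), ann, config.window_bp
            )
            hits.to_csv(out / "candidate_genes.csv", index=False)
            summary["n_candidate_gene_hits"] = len(hits)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
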