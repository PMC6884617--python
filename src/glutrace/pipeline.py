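"""End-to-end workflows: simulate -> correct -> analyze -> report.

The study-level analyses are exposed as plain functions (dual-tracer
source apportionment, glutamine utilization split, ISA condition
comparison, labeled-pool contrast, uptake contrast, biomass-enrichment
contrast, untargeted screen); :func:`run_pipeline` composes them into
one reproducible run that writes per-stage CSVs, a summary JSON and a
log.  Every stage derives its random stream from the config seed.
"""

from __future__ import annotations

import json
import logging
import platform
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import mid_table_from_vectors, write_feature_table, write_mid_table, write_rates_table
from .isa import ISAModelSpec, compare_conditions, fit_isa
from .mid import MIDVector, correct_mid
from .rates import (
    GLN_TRACER_CARBON_SHIFTS,
    MediaMeasurement,
    exchange_rate,
    secreted_mid,
    source_apportionment,
    utilization_split,
)
from .readouts import classify_isotopologues, isotopologue_fraction, labeled_pool_fold_change
from .rates import cirms_enrichment
from .screen import ScreenConfig, presence_filter, volcano_screen
from .simulate import (
    ExperimentDesign,
    SimulatedExperiment,
    simulate_biomass_enrichment,
    simulate_experiment,
    simulate_feature_table,
    tracked_correction_matrix,
)

logger = logging.getLogger("glutrace")

__all__ = [
    "subseed",
    "corrected_mean_mid",
    "mean_rates",
    "run_dual_tracer_apportionment",
    "run_utilization",
    "run_isa_comparison",
    "run_labeled_pool_contrast",
    "run_uptake_contrast",
    "run_biomass_contrast",
    "run_screen",
    "run_pipeline",
]


def subseed(seed: int, *tags: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence([seed] + [zlib.crc32(t.encode()) for t in tags])
    return int(ss.generate_state(1)[0] % (2**31))


def corrected_mean_mid(
    bundle: SimulatedExperiment, metabolite: str, compartment: str = "cell"
) -> MIDVector:
    """Natural-abundance-correct each replicate MID, then average."""
    met = bundle.states[metabolite].metabolite
    matrix = tracked_correction_matrix(met)
    corrected = [
        correct_mid(m, matrix).abundances for m in bundle.mid_vectors(metabolite, compartment)
    ]
    mean = np.mean(corrected, axis=0)
    return MIDVector(
        metabolite=metabolite,
        tracer=bundle.tracer.name,
        abundances=mean / mean.sum(),
        corrected=True,
    )


def mean_rates(bundle: SimulatedExperiment) -> dict[str, float]:
    """Replicate-mean net exchange rates (umol/mg/day, +uptake/-secretion)."""
    out: dict[str, float] = {}
    for met, grp in bundle.media.groupby("metabolite"):
        rates = [
            exchange_rate(
                MediaMeasurement(
                    metabolite=met,
                    blank_mM=row["blank_mM"],
                    harvest_mM=row["harvest_mM"],
                    volume_l=bundle.design.media_volume_l,
                    protein_mg=bundle.design.protein_mg,
                    hours=bundle.design.hours,
                )
            )
            for _, row in grp.iterrows()
        ]
        out[met] = float(np.mean(rates))
    return out


def _media_glu_blank_harvest(bundle: SimulatedExperiment) -> tuple[float, float]:
    glu = bundle.media[bundle.media["metabolite"] == "glutamate"]
    return float(glu["blank_mM"].mean()), float(glu["harvest_mM"].mean())


def run_dual_tracer_apportionment(
    condition: str = "HEP-L",
    n_replicates: int = 7,
    mid_noise_cv: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Source apportionment of de novo secreted glutamate.

    Simulates the U-13C,15N2-glutamine and U-13C-glucose experiments,
    corrects the media-glutamate MIDs, deconvolves the pre-existing
    unlabeled pool, and apportions the secreted glutamate carbon among
    glutamine, glucose and other sources.
    """
    bundles = {}
    for tracer in ("U13C15N2-Gln", "U13C-Glc"):
        design = ExperimentDesign(
            condition=condition,
            tracer=tracer,
            n_replicates=n_replicates,
            mid_noise_cv=mid_noise_cv,
            seed=subseed(seed, "apportion", tracer),
        )
        bundles[tracer] = simulate_experiment(design)
    mids, secretion = {}, {}
    for tracer, bundle in bundles.items():
        harvest_mid = corrected_mean_mid(bundle, "Glu", "media")
        blank, harvest = _media_glu_blank_harvest(bundle)
        mids[tracer] = secreted_mid(blank, harvest, harvest_mid)
        secretion[tracer] = -mean_rates(bundle)["glutamate"]
    net = float(np.mean(list(secretion.values())))
    result = source_apportionment(
        net_secretion=net,
        gln_tracer_glu_mid=mids["U13C15N2-Gln"],
        glc_tracer_glu_mid=mids["U13C-Glc"],
        gln_tracer_secretion=secretion["U13C15N2-Gln"],
        glc_tracer_secretion=secretion["U13C-Glc"],
    )
    return {
        "glutamine_pct": 100 * result.fraction_glutamine,
        "glucose_pct": 100 * result.fraction_glucose,
        "other_pct": 100 * result.fraction_other,
        "net_secretion_umol_mg_day": net,
    }


def run_utilization(
    condition: str = "HEP-L",
    n_replicates: int = 8,
    conc_noise_cv: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Glutamine uptake vs glutamate re-secretion mass balance.

    From one U-13C,15N2-glutamine experiment: mean glutamine uptake
    rate, mean net glutamate secretion rate, the glutamine-derived
    share of the secreted glutamate (M5+M6 of the corrected secreted
    MID), and the resulting utilization split.
    """
    design = ExperimentDesign(
        condition=condition,
        tracer="U13C15N2-Gln",
        n_replicates=n_replicates,
        conc_noise_cv=conc_noise_cv,
        seed=subseed(seed, "utilization"),
    )
    bundle = simulate_experiment(design)
    rates = mean_rates(bundle)
    uptake = rates["glutamine"]
    net_secretion = -rates["glutamate"]
    harvest_mid = corrected_mean_mid(bundle, "Glu", "media")
    blank, harvest = _media_glu_blank_harvest(bundle)
    sec_mid = secreted_mid(blank, harvest, harvest_mid)
    gln_share = isotopologue_fraction(sec_mid, GLN_TRACER_CARBON_SHIFTS)
    gln_derived_secretion = net_secretion * gln_share
    split = utilization_split(uptake, gln_derived_secretion)
    return {
        "uptake_umol_mg_day": uptake,
        "net_glu_secretion_umol_mg_day": net_secretion,
        "gln_derived_share": gln_share,
        "secreted_pct_of_uptake": 100 * gln_derived_secretion / uptake,
        "utilized_pct": 100 * split.utilized_fraction,
        "utilized_umol_mg_day": split.utilized,
    }


def run_isa_comparison(
    condition_a: str = "HEP-L",
    condition_b: str = "HDF",
    n_replicates: int = 7,
    mid_noise_cv: float = 0.01,
    seed: int = 0,
) -> dict[str, float]:
    """Labeled myristate synthesis contrast from 5-13C-glutamine MIDs.

    Fits the two-parameter ISA model jointly across replicates per
    condition and reports the percent difference in D, g and the
    labeled-synthesis metric D*g (a over b).
    """
    spec = ISAModelSpec(n_units=7, unit_shift=1)
    fits = {}
    for cond in (condition_a, condition_b):
        design = ExperimentDesign(
            condition=cond,
            tracer="5-13C-Gln",
            n_replicates=n_replicates,
            mid_noise_cv=mid_noise_cv,
            seed=subseed(seed, "isa", cond),
        )
        bundle = simulate_experiment(design)
        mids = [
            MIDVector(
                metabolite="myristate",
                abundances=grp.sort_values("shift")["abundance"].to_numpy(),
                corrected=False,
            )
            for _, grp in bundle.fa_mids.groupby("replicate")
        ]
        fits[cond] = fit_isa(mids, spec)
    a, b = fits[condition_a], fits[condition_b]
    return {
        "D_a": a.D, "g_a": a.g, "D_b": b.D, "g_b": b.g,
        "labeled_synthesis_pct_diff": compare_conditions(a, b, "Dg"),
        "D_pct_diff": compare_conditions(a, b, "D"),
        "g_pct_diff": compare_conditions(a, b, "g"),
    }


def run_labeled_pool_contrast(
    metabolite: str = "Pro",
    condition_a: str = "HDF",
    condition_b: str = "HEP-L",
    n_replicates: int = 6,
    mid_noise_cv: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Fold difference in a labeled intracellular pool (EIC/mg) between
    two conditions under U-13C,15N2-glutamine."""
    pools = {}
    for cond in (condition_a, condition_b):
        design = ExperimentDesign(
            condition=cond,
            tracer="U13C15N2-Gln",
            n_replicates=n_replicates,
            mid_noise_cv=mid_noise_cv,
            seed=subseed(seed, "pool", metabolite, cond),
        )
        bundle = simulate_experiment(design)
        sub = bundle.labeled_pools[bundle.labeled_pools["metabolite"] == metabolite]
        pools[cond] = sub["eic_per_mg"].to_numpy()
    fc = labeled_pool_fold_change(pools[condition_a], pools[condition_b])
    return {"fold_change": fc.fold_change, "p_value": fc.p_value}


def run_uptake_contrast(
    metabolite: str = "glutamine",
    condition_a: str = "HEP-L",
    condition_b: str = "HDF",
    n_replicates: int = 7,
    conc_noise_cv: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Ratio of mean media-consumption rates between two conditions."""
    rates = {}
    for cond in (condition_a, condition_b):
        design = ExperimentDesign(
            condition=cond,
            tracer="U13C15N2-Gln",
            n_replicates=n_replicates,
            conc_noise_cv=conc_noise_cv,
            seed=subseed(seed, "uptake", cond),
        )
        rates[cond] = mean_rates(simulate_experiment(design))[metabolite]
    return {
        f"rate_{condition_a}": rates[condition_a],
        f"rate_{condition_b}": rates[condition_b],
        "ratio": rates[condition_a] / rates[condition_b],
    }


def run_biomass_contrast(
    condition_a: str = "HDF",
    condition_b: str = "HEP-L",
    n_replicates: int = 8,
    seed: int = 0,
) -> dict[str, float]:
    """Percent excess of biomass 13C enrichment (C/IRMS) of a over b."""
    enr = {}
    for cond in (condition_a, condition_b):
        atom_pct = simulate_biomass_enrichment(
            cond, n=n_replicates, seed=subseed(seed, "biomass", cond)
        )
        enr[cond] = float(np.mean([cirms_enrichment(v) for v in atom_pct]))
    return {
        f"enrichment_{condition_a}": enr[condition_a],
        f"enrichment_{condition_b}": enr[condition_b],
        "excess_pct": 100 * (enr[condition_a] - enr[condition_b]) / enr[condition_b],
    }


def run_screen(
    n_features: int = 858,
    n_per_group: int = 7,
    n_changed: int = 101,
    fold_change: float = 2.0,
    fdr: float = 0.005,
    seed: int = 0,
):
    """Untargeted volcano screen on a simulated feature table."""
    table = simulate_feature_table(
        n_features=n_features,
        n_per_group=n_per_group,
        n_changed=n_changed,
        seed=subseed(seed, "screen"),
    )
    filtered = presence_filter(table)
    return volcano_screen(filtered, ScreenConfig(fold_change=fold_change, fdr=fdr))


def run_pipeline(config: PipelineConfig) -> dict:
    """Full study workflow; writes per-stage outputs under the config's
    output directory and returns the summary dictionary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    logger.info("glutrace %s on %s, seed=%d", __version__, platform.python_version(), config.seed)

    # --- simulate + correct every (condition, tracer) experiment -----
    raw_records, corrected_records, rate_rows = [], [], []
    bundles: dict[tuple[str, str], SimulatedExperiment] = {}
    for cond in config.conditions:
        for tracer in config.tracers:
            design = ExperimentDesign(
                condition=cond,
                tracer=tracer,
                n_replicates=config.n_replicates,
                mid_noise_cv=config.mid_noise_cv,
                conc_noise_cv=config.conc_noise_cv,
                seed=subseed(config.seed, "experiment", cond, tracer),
            )
            bundle = simulate_experiment(design)
            bundles[(cond, tracer)] = bundle
            for met in ("Glu", "Cit", "Mal", "Lac", "Pro"):
                for rep, mid in enumerate(bundle.mid_vectors(met)):
                    sample = f"{cond}_{tracer}_r{rep + 1}"
                    raw_records.append((sample, cond, mid))
                mean_mid = corrected_mean_mid(bundle, met)
                corrected_records.append((f"{cond}_{tracer}_mean", cond, mean_mid))
        rates = mean_rates(bundles[(cond, config.tracers[0])])
        for met, rate in rates.items():
            rate_rows.append(
                {
                    "condition": cond,
                    "metabolite": met,
                    "rate_umol_per_mg_day": rate,
                    "direction": "uptake" if rate >= 0 else "secretion",
                }
            )
    write_mid_table(mid_table_from_vectors(raw_records), outdir / "mids_raw.csv")
    write_mid_table(mid_table_from_vectors(corrected_records), outdir / "mids_corrected.csv")
    write_rates_table(rate_rows, outdir / "rates.csv")
    logger.info("wrote MID and rates tables")

    # --- fate assignment tables --------------------------------------
    fate_frames = [classify_isotopologues(t).to_frame() for t in config.tracers]
    pd.concat(fate_frames).to_csv(outdir / "fate_assignments.csv", index=False)

    # --- headline analyses -------------------------------------------
    summary: dict = {"config": asdict(config), "version": __version__}
    summary["apportionment"] = run_dual_tracer_apportionment(
        n_replicates=config.n_replicates, mid_noise_cv=config.mid_noise_cv, seed=config.seed
    )
    summary["utilization"] = run_utilization(
        conc_noise_cv=config.conc_noise_cv, seed=config.seed
    )
    summary["isa"] = run_isa_comparison(seed=config.seed)
    summary["proline_pool"] = run_labeled_pool_contrast(seed=config.seed)
    summary["ornithine_pool"] = run_labeled_pool_contrast(metabolite="Orn", seed=config.seed)
    summary["uptake_contrast"] = run_uptake_contrast(
        n_replicates=config.n_replicates, conc_noise_cv=config.conc_noise_cv, seed=config.seed
    )
    summary["biomass"] = run_biomass_contrast(seed=config.seed)

    # --- untargeted screen -------------------------------------------
    table = simulate_feature_table(
        n_features=config.n_features,
        n_per_group=config.n_replicates,
        n_changed=config.n_changed_features,
        seed=subseed(config.seed, "screen"),
    )
    write_feature_table(table, outdir / "features.csv", outdir / "feature_groups.csv")
    result = volcano_screen(
        presence_filter(table),
        ScreenConfig(fold_change=config.fold_change_threshold, fdr=config.fdr_threshold),
    )
    result.table.to_csv(outdir / "screen_result.csv", index_label="feature")
    summary["screen"] = {"n_significant": result.n_significant, "n_features": len(result.table)}
    _volcano_plot(result, outdir / "volcano.png")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary


def _volcano_plot(result, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table.dropna(subset=["p_adjusted"])
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = t["significant"]
    ax.scatter(t.loc[~sig, "log2_fc"], -np.log10(t.loc[~sig, "p_adjusted"]), s=6, c="grey", alpha=0.6)
    ax.scatter(t.loc[sig, "log2_fc"], -np.log10(t.loc[sig, "p_adjusted"]), s=8, c="crimson")
    ax.axhline(-np.log10(result.config.fdr), ls="--", lw=0.8, c="k")
    for x in (-np.log2(result.config.fold_change), np.log2(result.config.fold_change)):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel(f"log2 FC ({result.groups[0]} / {result.groups[1]})")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
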