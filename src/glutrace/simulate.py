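"""Synthetic measurement emulation on top of the tracer network.

Stands in for the study's unreleased LC-MS data: given a condition
preset (flux set) and an experiment design, produces the measurement
bundle one 24-h endpoint experiment would yield — blank/harvest media
concentrations, uncorrected intracellular and media MIDs, labeled
proline/ornithine pool sizes, bulk biomass 13C atom percent, and
uncorrected fatty-acid MIDs from the ISA forward model.

The measurement model is exact where it can be: the "uncorrected" MID
of a metabolite is computed state-by-state from the positional
isotopomer distribution, convolving each labeling pattern with the
natural-abundance MID of its *unlabeled* atoms (element-aware), then
perturbed by multiplicative noise and renormalized, exactly as an
integrated isotopologue table off the instrument would look.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isa import ISAModelSpec, isa_forward
from .mid import (
    CorrectionMatrix,
    IsotopeAbundances,
    MIDVector,
    _atom_convolve,
    parse_formula,
)
from .network import (
    TRACERS,
    IsotopomerState,
    Metabolite,
    NetworkModel,
    TracerSpec,
    _popcount_array,
    steady_state_labeling,
)
from .presets import get_preset
from .rates import CIRMS_BASELINE_ATOM_PCT
from .screen import FeatureTable

__all__ = [
    "ExperimentDesign",
    "SimulatedExperiment",
    "MEDIA_BLANK_MM",
    "measured_mid",
    "tracked_correction_matrix",
    "simulate_experiment",
    "simulate_biomass_enrichment",
    "simulate_feature_table",
]

#: Blank (no-cell) media concentrations in mM, from the culture medium
#: recipe: 2 mM glutamine, 3.15 g/L glucose, 54 uM glutamate,
#: 0.03 g/L proline, 0.1 g/L ornithine.
MEDIA_BLANK_MM = {
    "glutamine": 2.0,
    "glucose": 3.15 / 180.156 * 1000.0,
    "glutamate": 0.054,
    "proline": 0.03 / 115.13 * 1000.0,
    "ornithine": 0.1 / 132.16 * 1000.0,
}

#: Intracellular metabolites whose MIDs the simulator reports.
MID_METABOLITES = ("Gln", "Glu", "AKG", "Cit", "Mal", "Suc", "Fum", "Lac", "Pro", "Orn")


@dataclass(frozen=True)
class ExperimentDesign:
    """One labeling experiment: condition, tracer, replication, noise.

    Volumes/protein amounts correspond to a 12-well plate well; noise
    CVs are multiplicative Gaussian coefficients of variation applied
    per measurement channel.
    """

    condition: str
    tracer: str = "U13C15N2-Gln"
    n_replicates: int = 7
    hours: float = 24.0
    media_volume_l: float = 0.5e-3
    protein_mg: float = 0.25
    mid_noise_cv: float = 0.05
    conc_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.hours <= 0 or self.media_volume_l <= 0 or self.protein_mg <= 0:
            raise ValueError("hours, volume and protein mass must be positive")
        if self.mid_noise_cv < 0 or self.conc_noise_cv < 0:
            raise ValueError("noise CVs must be non-negative")


def measured_mid(
    state: IsotopomerState, abundances: IsotopeAbundances | None = None
) -> np.ndarray:
    """Expected uncorrected MID of a positional labeling distribution.

    Exact measurement model: every labeling pattern contributes its
    nominal shift plus the natural-abundance envelope of the atoms it
    leaves unlabeled (including formula atoms outside the tracked
    skeleton), truncated at the tracked-shift range.
    """
    abundances = abundances or IsotopeAbundances()
    met = state.metabolite
    if not met.formula:
        raise ValueError(f"{met.name}: no elemental formula for measurement emulation")
    formula = parse_formula(met.formula)
    n = met.n_atoms
    states = np.arange(met.n_states)
    kc = _popcount_array(states & ((1 << met.carbons) - 1))
    kn = _popcount_array(states >> met.carbons)
    out = np.zeros(n + 1)
    for c in range(met.carbons + 1):
        for nn in range(met.nitrogens + 1):
            p = float(state.dist[(kc == c) & (kn == nn)].sum())
            if p <= 0:
                continue
            rest = formula.without("C", c)
            if nn:
                rest = rest.without("N", nn)
            dists = []
            for el, cnt in rest.counts.items():
                dists.extend([abundances.for_element(el)] * cnt)
            nat = _atom_convolve(dists, max_shift=n - c - nn)
            out[c + nn : c + nn + nat.size] += p * nat
    return out / out.sum()


def tracked_correction_matrix(
    met: Metabolite,
    abundances: IsotopeAbundances | None = None,
    purity: float = 1.0,
) -> CorrectionMatrix:
    """Correction matrix over a metabolite's tracked C(+N) shift channels.

    Column j assumes the j tracer atoms fill carbon positions first and
    tracked nitrogens beyond that (the dominant assignment for the
    packaged tracers); unlabeled tracked positions and all formula
    atoms outside the skeleton contribute natural abundance.
    """
    abundances = abundances or IsotopeAbundances()
    formula = parse_formula(met.formula)
    n = met.n_atoms
    rest = formula.without("C", met.carbons)
    if met.nitrogens:
        rest = rest.without("N", met.nitrogens)
    bg = []
    for el, cnt in rest.counts.items():
        bg.extend([abundances.for_element(el)] * cnt)
    matrix = np.zeros((n + 1, n + 1))
    c_dist = abundances.for_element("C")
    n_dist = abundances.for_element("N")
    for j in range(n + 1):
        jc = min(j, met.carbons)
        jn = j - jc
        dists = list(bg)
        dists.extend([c_dist] * (met.carbons - jc))
        dists.extend([n_dist] * (met.nitrogens - jn))
        col = _atom_convolve(dists, max_shift=n)
        if j:
            labeled = _atom_convolve([np.array([1 - purity, purity])] * j, max_shift=n)
            col = np.convolve(labeled, col)[: n + 1]
        matrix[:, j] = np.pad(col, (0, n + 1 - col.size))
    return CorrectionMatrix(matrix=matrix, formula=formula, tracer_element="C", purity=purity)


@dataclass
class SimulatedExperiment:
    """The measurement bundle for one simulated labeling experiment."""

    design: ExperimentDesign
    tracer: TracerSpec
    states: dict[str, IsotopomerState]
    media: pd.DataFrame
    mids: pd.DataFrame
    labeled_pools: pd.DataFrame
    biomass_atom_pct: np.ndarray
    fa_mids: pd.DataFrame
    truth: dict[str, float]

    def mid_vectors(self, metabolite: str, compartment: str = "cell") -> list[MIDVector]:
        """Measured (uncorrected) MIDs of one metabolite, one per replicate."""
        sub = self.mids[
            (self.mids["metabolite"] == metabolite) & (self.mids["compartment"] == compartment)
        ]
        out = []
        for rep, grp in sub.groupby("replicate"):
            grp = grp.sort_values("shift")
            out.append(
                MIDVector(
                    metabolite=metabolite,
                    tracer=self.tracer.name,
                    abundances=grp["abundance"].to_numpy(),
                    corrected=False,
                )
            )
        return out


def _noisy_mid(rng: np.random.Generator, mid: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return mid.copy()
    noisy = np.clip(mid * (1 + cv * rng.standard_normal(mid.size)), 0, None)
    if noisy.sum() <= 0:
        noisy = mid.copy()
    return noisy / noisy.sum()


def _accoa_labeled_fraction(state: IsotopomerState, unit_shift: int) -> float:
    """Probability that a lipogenic acetyl unit carries the tracer shift."""
    if unit_shift == 2:
        return float(state.dist[3])
    return float(state.dist[1] + state.dist[2])


def simulate_experiment(
    design: ExperimentDesign, network: NetworkModel | None = None
) -> SimulatedExperiment:
    """Run one in-silico labeling experiment.

    Steady-state label propagation gives the ground truth; per
    replicate the bundle carries blank/harvest media concentrations
    (linear accumulation/depletion over the incubation), uncorrected
    MIDs, labeled proline/ornithine pools (EIC per mg), biomass 13C
    atom percent, and uncorrected myristate MIDs from the ISA forward
    model.  All randomness flows from ``design.seed``.
    """
    preset = get_preset(design.condition)
    network = network or preset.network()
    tracer = TRACERS[design.tracer]
    rng = np.random.default_rng(design.seed)
    states = steady_state_labeling(network, tracer)
    fx = network.flux
    days = design.hours / 24.0

    # --- media concentrations (linear in time; depletion guarded) ----
    net_rates = {
        "glutamine": -fx("gln_uptake"),
        "glutamate": fx("glu_secretion") - fx("glu_uptake"),
        "glucose": -fx("glycolysis"),
    }
    media_rows = []
    harvest_means = {}
    for met, rate in net_rates.items():
        blank = MEDIA_BLANK_MM[met]
        delta_mM = rate * design.protein_mg * days / design.media_volume_l / 1000.0
        harvest = blank + delta_mM
        if harvest < 0:
            raise ValueError(
                f"{met} driven to {harvest:.3g} mM at harvest; reduce fluxes or shorten "
                "the incubation"
            )
        harvest_means[met] = harvest
        for rep in range(design.n_replicates):
            noise = 1 + design.conc_noise_cv * rng.standard_normal(2)
            media_rows.append(
                {
                    "replicate": rep,
                    "metabolite": met,
                    "blank_mM": max(blank * noise[0], 0.0),
                    "harvest_mM": max(harvest * noise[1], 0.0),
                }
            )
    media = pd.DataFrame(media_rows)

    # --- uncorrected MIDs: intracellular + media glutamate -----------
    mid_rows = []
    for met_name in MID_METABOLITES:
        clean = measured_mid(states[met_name])
        for rep in range(design.n_replicates):
            noisy = _noisy_mid(rng, clean, design.mid_noise_cv)
            for shift, ab in enumerate(noisy):
                mid_rows.append(
                    {
                        "replicate": rep,
                        "metabolite": met_name,
                        "compartment": "cell",
                        "shift": shift,
                        "abundance": ab,
                    }
                )
    # media glutamate: mixture of the pre-existing unlabeled pool and
    # de novo secreted material (intracellular distribution)
    glu_met = network.metabolites["Glu"]
    initial_umol = MEDIA_BLANK_MM["glutamate"] * design.media_volume_l * 1000.0
    secreted_umol = fx("glu_secretion") * design.protein_mg * days
    uptaken_umol = fx("glu_uptake") * design.protein_mg * days
    remaining_initial = max(initial_umol - uptaken_umol, 0.0)
    mix = np.zeros(glu_met.n_states)
    mix[0] = remaining_initial
    mix += secreted_umol * states["Glu"].dist
    if mix.sum() > 0:
        media_glu_state = IsotopomerState(glu_met, mix / mix.sum())
        clean = measured_mid(media_glu_state)
        for rep in range(design.n_replicates):
            noisy = _noisy_mid(rng, clean, design.mid_noise_cv)
            for shift, ab in enumerate(noisy):
                mid_rows.append(
                    {
                        "replicate": rep,
                        "metabolite": "Glu",
                        "compartment": "media",
                        "shift": shift,
                        "abundance": ab,
                    }
                )
    mids = pd.DataFrame(mid_rows)

    # --- labeled proline/ornithine pools (EIC per mg protein) --------
    pool_rows = []
    for met_name in ("Pro", "Orn"):
        lf = states[met_name].labeled_fraction()
        for rep in range(design.n_replicates):
            noise = 1 + design.mid_noise_cv * rng.standard_normal()
            pool_rows.append(
                {
                    "replicate": rep,
                    "metabolite": met_name,
                    "eic_per_mg": max(preset.pool_eic_scale * lf * noise, 0.0),
                }
            )
    labeled_pools = pd.DataFrame(pool_rows)

    # --- biomass 13C atom percent ------------------------------------
    af = states["Glu"].atom_fraction_13c()
    enrichment = preset.biomass_k * fx("glu_to_protein") * af
    biomass = (
        CIRMS_BASELINE_ATOM_PCT
        + enrichment
        + 0.0023 * rng.standard_normal(design.n_replicates)
    )

    # --- fatty-acid MIDs via the ISA forward model --------------------
    unit_shift = 1 if design.tracer == "5-13C-Gln" else 2
    spec = ISAModelSpec(n_units=7, unit_shift=unit_shift)
    d_true = _accoa_labeled_fraction(states["AcCoA.lipo"], unit_shift)
    fa_clean = isa_forward(spec, d_true, preset.g_lipid).abundances
    fa_rows = []
    for rep in range(design.n_replicates):
        noisy = _noisy_mid(rng, fa_clean, design.mid_noise_cv)
        for shift, ab in enumerate(noisy):
            fa_rows.append(
                {"replicate": rep, "metabolite": "myristate", "shift": shift, "abundance": ab}
            )
    fa_mids = pd.DataFrame(fa_rows)

    truth = {
        "gln_uptake_rate": fx("gln_uptake"),
        "glu_net_secretion_rate": fx("glu_secretion") - fx("glu_uptake"),
        "glu_secretion_rate": fx("glu_secretion"),
        "glu_gln_carbon_share": float(
            states["Glu"].carbon_mid().abundances[5] if tracer.name == "U13C15N2-Gln" else np.nan
        ),
        "isa_D": d_true,
        "isa_g": preset.g_lipid,
        "biomass_enrichment": enrichment,
        "harvest_glutamate_mM": harvest_means["glutamate"],
    }
    return SimulatedExperiment(
        design=design,
        tracer=tracer,
        states=states,
        media=media,
        mids=mids,
        labeled_pools=labeled_pools,
        biomass_atom_pct=biomass,
        fa_mids=fa_mids,
        truth=truth,
    )


def simulate_biomass_enrichment(
    condition: str, n: int = 8, seed: int = 0, noise_sd_pct: float = 0.0023
) -> np.ndarray:
    """Per-replicate biomass 13C atom percent under the U-13C,15N2-Gln tracer."""
    design = ExperimentDesign(
        condition=condition, tracer="U13C15N2-Gln", n_replicates=n, seed=seed
    )
    preset = get_preset(condition)
    network = preset.network()
    states = steady_state_labeling(network, TRACERS[design.tracer])
    rng = np.random.default_rng(seed)
    enrichment = preset.biomass_k * network.flux("glu_to_protein") * states["Glu"].atom_fraction_13c()
    return CIRMS_BASELINE_ATOM_PCT + enrichment + noise_sd_pct * rng.standard_normal(n)


def simulate_feature_table(
    n_features: int = 858,
    n_per_group: int = 7,
    n_changed: int = 101,
    log2_effect: float = 2.0,
    cv: float = 0.30,
    seed: int = 0,
    groups: tuple[str, str] = ("HEP-L", "HDF"),
) -> FeatureTable:
    """Log-normal two-group feature-intensity matrix with planted effects.

    ``n_changed`` randomly chosen features get a ``log2_effect``
    group-mean shift (random sign); all others are null.  Feature ids
    follow the ``mass@rt`` convention of untargeted LC-MS tables.
    """
    if n_changed > n_features:
        raise ValueError("n_changed cannot exceed n_features")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    base_log2 = rng.uniform(12, 22, size=n_features)
    sigma = np.sqrt(np.log1p(cv**2))
    changed = rng.choice(n_features, size=n_changed, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_changed)
    shift_log2 = np.zeros(n_features)
    shift_log2[changed] = signs * log2_effect
    cols, data = [], []
    for gi, g in enumerate(groups):
        mu = base_log2 + (shift_log2 if gi == 0 else 0.0)
        for s in range(n_per_group):
            cols.append(f"{g}_{s + 1}")
            data.append(2.0**mu * np.exp(sigma * rng.standard_normal(n_features)))
    mass = rng.uniform(80, 800, size=n_features)
    rt = rng.uniform(0.7, 12.0, size=n_features)
    index = [f"{m:.4f}@{t:.2f}" for m, t in zip(mass, rt)]
    intens = pd.DataFrame(np.column_stack(data), index=index, columns=cols)
    group_labels = pd.Series({c: c.rsplit("_", 1)[0] for c in cols})
    table = FeatureTable(intens, group_labels)
    table.changed_features = [index[i] for i in changed]  # ground truth annotation
    return table
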