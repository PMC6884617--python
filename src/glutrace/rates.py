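"""Media-based exchange rates, glutamine mass balance and related readouts.

All rates are in umol per mg cellular protein per day.  Sign convention,
applied at every interface: positive = net uptake from the media,
negative = net secretion into the media.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mid import MIDVector

__all__ = [
    "MediaMeasurement",
    "SourceApportionment",
    "UtilizationSplit",
    "exchange_rate",
    "secreted_mid",
    "source_apportionment",
    "utilization_split",
    "cirms_enrichment",
    "intracellular_concentration",
]

#: Glutamate mass shifts that carry the full glutamine carbon skeleton
#: under the U-13C,15N2-glutamine tracer.  M6 = 13C5,15N (deamidation
#: only); M5 = 13C5 (carbon-retaining transamination cycling).  M1 is
#: 15N-only (Fig-3-style assignment by exact mass): its *carbon* is not
#: glutamine-derived, so M1 deliberately does NOT count here — the
#: easiest mistake to make in this bookkeeping.
GLN_TRACER_CARBON_SHIFTS = (5, 6)

#: Glutamate shifts fed by glucose carbon under U-13C-glucose:
#: M2 via pyruvate dehydrogenase, M3 via pyruvate carboxylase.
GLC_TRACER_CARBON_SHIFTS = (2, 3)


@dataclass(frozen=True)
class MediaMeasurement:
    """Blank (no cells) vs harvest media concentrations for one well."""

    metabolite: str
    blank_mM: float
    harvest_mM: float
    volume_l: float
    protein_mg: float
    hours: float = 24.0

    def __post_init__(self) -> None:
        if self.volume_l <= 0 or self.protein_mg <= 0 or self.hours <= 0:
            raise ValueError("volume, protein mass and incubation time must be positive")
        if self.blank_mM < 0 or self.harvest_mM < 0:
            raise ValueError("concentrations must be non-negative")


def exchange_rate(m: MediaMeasurement) -> float:
    """Net exchange rate from a blank/harvest concentration pair.

    rate = (blank - harvest) * volume / protein / (time in days),
    in umol mg^-1 day^-1.  Positive = uptake, negative = secretion.
    """
    umol = (m.blank_mM - m.harvest_mM) * m.volume_l * 1000.0
    return umol / m.protein_mg / (m.hours / 24.0)


@dataclass(frozen=True)
class UtilizationSplit:
    """How uptaken glutamine divides between re-secretion (as glutamate)
    and intracellular utilization."""

    uptake: float
    secretion_derived: float
    utilized: float
    utilized_fraction: float


def utilization_split(uptake: float, gln_derived_glu_secretion: float) -> UtilizationSplit:
    """Mass balance of glutamine uptake vs glutamine-derived glutamate secretion."""
    if uptake <= 0:
        raise ValueError("uptake must be positive")
    if not 0 <= gln_derived_glu_secretion <= uptake:
        raise ValueError(
            f"glutamine-derived secretion ({gln_derived_glu_secretion:.4g}) outside "
            f"[0, uptake={uptake:.4g}]: mass-balance violation"
        )
    utilized = uptake - gln_derived_glu_secretion
    return UtilizationSplit(
        uptake=uptake,
        secretion_derived=gln_derived_glu_secretion,
        utilized=utilized,
        utilized_fraction=utilized / uptake,
    )


@dataclass(frozen=True)
class SourceApportionment:
    """Carbon sources of de novo synthesized and secreted glutamate."""

    fraction_glutamine: float
    fraction_glucose: float
    fraction_other: float
    net_secretion: float

    def __post_init__(self) -> None:
        for fr in (self.fraction_glutamine, self.fraction_glucose, self.fraction_other):
            if not -1e-9 <= fr <= 1 + 1e-9:
                raise ValueError("apportionment fractions must lie in [0, 1]")
        s = self.fraction_glutamine + self.fraction_glucose + self.fraction_other
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"apportionment fractions sum to {s}")


def secreted_mid(blank_mM: float, harvest_mM: float, harvest_mid: MIDVector) -> MIDVector:
    """MID of de novo secreted material, from the harvest-media MID.

    The harvest medium mixes the pre-existing (unlabeled, M0) pool with
    what the cells secreted; subtracting the blank amount channel-wise
    recovers the secreted component.  Requires net accumulation
    (harvest > blank).
    """
    if harvest_mM <= blank_mM:
        raise ValueError("no net secretion: harvest concentration does not exceed blank")
    amounts = harvest_mM * harvest_mid.renormalized().abundances.copy()
    amounts[0] -= blank_mM
    amounts = np.clip(amounts, 0.0, None)
    return MIDVector(
        metabolite=harvest_mid.metabolite,
        tracer=harvest_mid.tracer,
        abundances=amounts / amounts.sum(),
        corrected=harvest_mid.corrected,
    )


def source_apportionment(
    net_secretion: float,
    gln_tracer_glu_mid: MIDVector,
    glc_tracer_glu_mid: MIDVector,
    gln_tracer_secretion: float,
    glc_tracer_secretion: float,
) -> SourceApportionment:
    """Dual-tracer apportionment of de novo secreted glutamate.

    Each labeled-carbon share is computed within its own tracer
    experiment (U-13C,15N2-glutamine: M5+M6; U-13C-glucose: M2+M3) on
    the corrected MID of the *secreted* glutamate; the unlabeled
    remainder is attributed to non-glutamine, non-glucose sources.
    Combining the two experiments assumes they share the same net
    secretion; a >20% disagreement triggers a warning.
    """
    for mid, which in ((gln_tracer_glu_mid, "glutamine"), (glc_tracer_glu_mid, "glucose")):
        if not mid.corrected:
            raise ValueError(f"{which}-tracer glutamate MID must be natural-abundance corrected")
    if gln_tracer_secretion <= 0 or glc_tracer_secretion <= 0:
        raise ValueError("secretion rates must be positive in both tracer experiments")
    lo, hi = sorted((gln_tracer_secretion, glc_tracer_secretion))
    if hi / lo - 1 > 0.20:
        warnings.warn(
            f"net glutamate secretion differs by {100 * (hi / lo - 1):.0f}% between the "
            "two tracer experiments; apportionment assumes a shared rate",
            stacklevel=2,
        )
    gln_mid = gln_tracer_glu_mid.renormalized().abundances
    glc_mid = glc_tracer_glu_mid.renormalized().abundances
    f_gln = float(sum(gln_mid[s] for s in GLN_TRACER_CARBON_SHIFTS if s < gln_mid.size))
    f_glc = float(sum(glc_mid[s] for s in GLC_TRACER_CARBON_SHIFTS if s < glc_mid.size))
    if f_gln + f_glc > 1 + 0.05:
        raise ValueError(
            f"labeled shares sum to {f_gln + f_glc:.3f} > 1: tracer experiments inconsistent"
        )
    f_other = 1.0 - f_gln - f_glc
    if f_other < 0:
        warnings.warn("labeled shares slightly exceed 1; flooring the remainder at 0", stacklevel=2)
        f_other = 0.0
        total = f_gln + f_glc
        f_gln, f_glc = f_gln / total, f_glc / total
    return SourceApportionment(
        fraction_glutamine=f_gln,
        fraction_glucose=f_glc,
        fraction_other=f_other,
        net_secretion=net_secretion,
    )


#: 13C atom percent of biomass from cells grown without tracer
#: (combustion/isotope-ratio MS baseline).
CIRMS_BASELINE_ATOM_PCT = 1.0799


def cirms_enrichment(sample_atom_pct: float, baseline_atom_pct: float = CIRMS_BASELINE_ATOM_PCT) -> float:
    """Bulk 13C enrichment (percentage points above the no-tracer baseline)."""
    for v in (sample_atom_pct, baseline_atom_pct):
        if not 0 <= v <= 100:
            raise ValueError("atom percent must lie in [0, 100]")
    enrichment = sample_atom_pct - baseline_atom_pct
    if enrichment < 0:
        warnings.warn(
            f"negative 13C enrichment ({enrichment:.4f} points): sample below baseline",
            stacklevel=2,
        )
    return enrichment


def intracellular_concentration(amount_mol: float, cell_count: float, mean_cell_volume_l: float) -> float:
    """Molar intracellular concentration: amount / (cell count x cell volume)."""
    if cell_count <= 0 or mean_cell_volume_l <= 0:
        raise ValueError("cell count and cell volume must be positive")
    return amount_mol / (cell_count * mean_cell_volume_l)
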