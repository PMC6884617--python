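"""Packaged condition presets: flux sets emulating the three cell types.

Each preset is a named assignment of the network fluxes (umol per mg
protein per day) plus the measurement-scale constants the simulator
needs.  The presets encode the qualitative metabolic phenotypes of the
three conditions — parental dermal fibroblasts (HDF-like), reprogrammed
hepatocyte-like cells (HEP-L-like) and primary human hepatocytes
(PHH-like) — calibrated so that the packaged analysis stages reproduce
the study-scale fractional readouts (secreted-glutamate source shares,
glutamine utilization split, proline-labeling contrast, reductive
carboxylation contrast).  They are calibration knobs, not fitted
quantities: no measured data stand behind them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import NetworkModel, build_default_network

__all__ = ["ConditionPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class ConditionPreset:
    """Flux set and measurement-scale constants for one condition."""

    name: str
    fluxes: dict[str, float]
    #: fraction of the fatty-acid pool newly synthesized over the
    #: 2-day lipid labeling period (the ISA g parameter, ground truth)
    g_lipid: float
    #: EIC per mg protein of a fully labeled metabolite pool
    pool_eic_scale: float = 1000.0
    #: biomass 13C atom-percent gained per unit of amino-acid
    #: incorporation flux at full precursor labeling
    biomass_k: float = 1.0

    def network(self) -> NetworkModel:
        return build_default_network(self.fluxes)


_HEPL_FLUXES = {
    "gln_uptake": 3.26, "gls": 2.575, "glul": 0.15,
    "glu_secretion": 2.66, "glu_uptake": 0.0,
    "glu_to_akg": 1.0, "akg_to_glu": 0.91, "n_influx": 1.5,
    "akg_ox": 0.9, "mal_to_oaa": 0.25, "oaa_to_mal": 0.2, "oaa_influx": 1.5,
    "cs": 2.05, "idh_ox": 2.2, "idh_rev": 0.6, "acl": 0.45,
    "pdh": 2.05, "pc": 0.05, "me": 0.05, "ldh": 0.05, "glycolysis": 1.05,
    "glu_to_p5c": 0.12, "p5c_to_pro": 0.05, "pro_to_p5c": 0.285,
    "p5c_to_orn": 0.01, "orn_to_p5c": 0.2,
    "pro_uptake": 0.6, "orn_uptake": 0.6,
    "glu_to_protein": 0.10, "accoa_lipo_dilution": 0.02,
}

_HDF_FLUXES = {
    "gln_uptake": 1.63, "gls": 1.13, "glul": 0.3,
    "glu_secretion": 0.15, "glu_uptake": 0.23,
    "glu_to_akg": 1.0, "akg_to_glu": 0.55, "n_influx": 1.0,
    "akg_ox": 0.8, "mal_to_oaa": 0.8, "oaa_to_mal": 0.05, "oaa_influx": 0.3,
    "cs": 1.4, "idh_ox": 1.0, "idh_rev": 0.18, "acl": 0.15,
    "pdh": 1.4, "pc": 0.2, "me": 0.05, "ldh": 0.1, "glycolysis": 0.85,
    "glu_to_p5c": 0.5, "p5c_to_pro": 0.268, "pro_to_p5c": 0.1,
    "p5c_to_orn": 0.08, "orn_to_p5c": 0.1,
    "pro_uptake": 0.6, "orn_uptake": 0.6,
    "glu_to_protein": 0.187, "accoa_lipo_dilution": 0.0015,
}

_PHH_FLUXES = {
    "gln_uptake": 3.4, "gls": 3.0, "glul": 0.1,
    "glu_secretion": 2.84, "glu_uptake": 0.0,
    "glu_to_akg": 1.6, "akg_to_glu": 1.2, "n_influx": 1.5,
    "akg_ox": 0.3, "mal_to_oaa": 0.0, "oaa_to_mal": 0.3, "oaa_influx": 0.5,
    "cs": 0.9, "idh_ox": 1.0, "idh_rev": 1.1, "acl": 0.9,
    "pdh": 0.9, "pc": 0.1, "me": 0.05, "ldh": 0.05, "glycolysis": 0.7,
    "glu_to_p5c": 0.03, "p5c_to_pro": 0.02, "pro_to_p5c": 0.25,
    "p5c_to_orn": 0.01, "orn_to_p5c": 0.22,
    "pro_uptake": 0.6, "orn_uptake": 0.6,
    "glu_to_protein": 0.10, "accoa_lipo_dilution": 0.5,
}

PRESETS: dict[str, ConditionPreset] = {
    "HEP-L": ConditionPreset("HEP-L", _HEPL_FLUXES, g_lipid=0.55),
    "HDF": ConditionPreset("HDF", _HDF_FLUXES, g_lipid=0.55),
    "PHH": ConditionPreset("PHH", _PHH_FLUXES, g_lipid=0.45),
}


def get_preset(name: str) -> ConditionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown condition preset {name!r}; available: {sorted(PRESETS)}")
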