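"""Atom-resolved metabolic network and steady-state label propagation.

The tracer network covers glutamine/glutamate handling, the TCA cycle in
both oxidative and reductive directions, pyruvate metabolism, the
proline/ornithine branch and the lipogenic acetyl-CoA pool.  Each
metabolite carries an explicit carbon skeleton (plus tracked amino
nitrogens), each reaction an explicit atom map, so positional
isotopomers — not just mass shifts — are propagated.  That positional
resolution is what separates, for example, citrate made by reductive
carboxylation of labeled 2-oxoglutarate from citrate made by forward
cycling plus condensation with labeled acetyl-CoA.

Labeling states are enumerated exhaustively: a metabolite with k tracked
atoms has 2**k positional states (k <= 7 here), and the steady state is
the fixed point of the flux-weighted label-balance equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mid import MIDVector

__all__ = [
    "Metabolite",
    "Reaction",
    "TracerSpec",
    "NetworkModel",
    "IsotopomerState",
    "NetworkError",
    "TRACERS",
    "build_default_network",
    "steady_state_labeling",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
]

BALANCE_RTOL = 1e-6


class NetworkError(ValueError):
    """Invalid network topology, atom map, or flux assignment."""


@dataclass(frozen=True)
class Metabolite:
    """A network species with a tracked atom skeleton.

    Tracked atoms are indexed ``0..carbons-1`` for the carbon skeleton
    (biochemical numbering C1..Cn) followed by tracked amino nitrogens.
    ``symmetric`` marks species (succinate, fumarate) whose free
    rotation scrambles the carbon order.
    """

    name: str
    carbons: int
    nitrogens: int = 0
    symmetric: bool = False
    external: bool = False
    formula: str = ""

    @property
    def n_atoms(self) -> int:
        return self.carbons + self.nitrogens

    @property
    def n_states(self) -> int:
        return 1 << self.n_atoms


# Atom source inside a reaction: (substrate index, substrate atom index),
# or None for an unlabeled external source (CO2 fixation, free ammonia).
AtomSource = "tuple[int, int] | None"


@dataclass(frozen=True)
class Reaction:
    """One flux-carrying conversion with a per-atom transition map.

    ``products`` lists (metabolite name, atom sources) pairs, one entry
    per product molecule; atoms of substrates that appear in no product
    are released (CO2, ammonia) and leave the tracked system.
    """

    name: str
    substrates: tuple[str, ...]
    products: tuple[tuple[str, tuple], ...]
    flux: float

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise NetworkError(f"reaction {self.name}: negative flux {self.flux}")


@dataclass(frozen=True)
class TracerSpec:
    """Which substrate enters labeled, at which positions.

    Positions are 1-based on the standard biochemical numbering of the
    substrate's skeleton; every labeled position is heavy independently
    with probability ``enrichment``.
    """

    name: str
    substrate: str
    carbon_positions: tuple[int, ...] = ()
    nitrogen_positions: tuple[int, ...] = ()
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.enrichment <= 1:
            raise NetworkError("tracer enrichment must be in (0, 1]")

    @property
    def max_shift(self) -> int:
        return len(self.carbon_positions) + len(self.nitrogen_positions)


#: The four tracer designs used in the study.
TRACERS: dict[str, TracerSpec] = {
    "U13C15N2-Gln": TracerSpec(
        "U13C15N2-Gln", "Gln.media", carbon_positions=(1, 2, 3, 4, 5), nitrogen_positions=(1, 2)
    ),
    "U13C-Glc": TracerSpec("U13C-Glc", "Glc.media", carbon_positions=(1, 2, 3, 4, 5, 6)),
    "5-13C-Gln": TracerSpec("5-13C-Gln", "Gln.media", carbon_positions=(5,)),
    "1-13C-Gln": TracerSpec("1-13C-Gln", "Gln.media", carbon_positions=(1,)),
    "unlabeled": TracerSpec("unlabeled", "Gln.media", carbon_positions=(1,), enrichment=1e-12),
}


@dataclass
class IsotopomerState:
    """Probability vector over the 2**k positional labeling patterns.

    Bit i of a state index is 1 when tracked atom i carries the heavy
    isotope.
    """

    metabolite: Metabolite
    dist: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dist, dtype=float)
        if d.size != self.metabolite.n_states:
            raise NetworkError(
                f"{self.metabolite.name}: state vector size {d.size} != {self.metabolite.n_states}"
            )
        self.dist = d

    def mid(self, tracer: str = "") -> MIDVector:
        """Marginalize positional states to a total-mass-shift MID."""
        shifts = _popcounts(self.metabolite.n_atoms)
        mid = np.bincount(shifts, weights=self.dist, minlength=self.metabolite.n_atoms + 1)
        return MIDVector(
            metabolite=self.metabolite.name,
            tracer=tracer,
            abundances=np.clip(mid, 0, None) / mid.sum(),
            corrected=True,
        )

    def carbon_mid(self, tracer: str = "") -> MIDVector:
        """Carbon-only mass-shift marginal (nitrogen labels ignored)."""
        nc = self.metabolite.carbons
        cmask = (1 << nc) - 1
        states = np.arange(self.dist.size)
        shifts = _popcount_array(states & cmask)
        mid = np.bincount(shifts, weights=self.dist, minlength=nc + 1)
        return MIDVector(
            metabolite=self.metabolite.name,
            tracer=tracer,
            abundances=np.clip(mid, 0, None) / mid.sum(),
            corrected=True,
        )

    def labeled_fraction(self) -> float:
        """Probability of carrying at least one heavy atom."""
        return float(1.0 - self.dist[0])

    def atom_fraction_13c(self) -> float:
        """Mean fraction of carbon atoms that are 13C."""
        nc = self.metabolite.carbons
        if nc == 0:
            return 0.0
        states = np.arange(self.dist.size)
        nlab = _popcount_array(states & ((1 << nc) - 1))
        return float(np.dot(self.dist, nlab) / nc)

    def state_probability(self, labeled_atoms: tuple[int, ...]) -> float:
        idx = 0
        for a in labeled_atoms:
            idx |= 1 << a
        return float(self.dist[idx])


def _popcount_array(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    v = x.copy()
    while np.any(v):
        out += v & 1
        v >>= 1
    return out


def _popcounts(n_atoms: int) -> np.ndarray:
    return _popcount_array(np.arange(1 << n_atoms))


@dataclass
class NetworkModel:
    """Metabolites, atom-mapped reactions and their flux values."""

    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    _maps: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._check_atom_maps()
        self.check_balance()

    # -- validation ---------------------------------------------------
    def _check_atom_maps(self) -> None:
        for rxn in self.reactions:
            for s in rxn.substrates:
                if s not in self.metabolites:
                    raise NetworkError(f"reaction {rxn.name}: unknown substrate {s}")
            for pname, sources in rxn.products:
                if pname not in self.metabolites:
                    raise NetworkError(f"reaction {rxn.name}: unknown product {pname}")
                prod = self.metabolites[pname]
                if len(sources) != prod.n_atoms:
                    raise NetworkError(
                        f"reaction {rxn.name}: product {pname} maps {len(sources)} atoms, "
                        f"needs {prod.n_atoms}"
                    )
                for src in sources:
                    if src is None:
                        continue
                    si, ai = src
                    if si >= len(rxn.substrates):
                        raise NetworkError(f"reaction {rxn.name}: substrate index {si} out of range")
                    sub = self.metabolites[rxn.substrates[si]]
                    if ai >= sub.n_atoms:
                        raise NetworkError(
                            f"reaction {rxn.name}: atom {ai} out of range for {sub.name}"
                        )

    def check_balance(self, rtol: float = BALANCE_RTOL) -> None:
        """Verify production flux == consumption flux for internal species."""
        total = sum(r.flux for r in self.reactions) or 1.0
        prod: dict[str, float] = {}
        cons: dict[str, float] = {}
        for rxn in self.reactions:
            for s in rxn.substrates:
                if not self.metabolites[s].external:
                    cons[s] = cons.get(s, 0.0) + rxn.flux
            for pname, _ in rxn.products:
                if not self.metabolites[pname].external:
                    prod[pname] = prod.get(pname, 0.0) + rxn.flux
        bad = [
            name
            for name in set(prod) | set(cons)
            if abs(prod.get(name, 0.0) - cons.get(name, 0.0)) > rtol * total
        ]
        if bad:
            detail = ", ".join(
                f"{n} (in {prod.get(n, 0.0):.4g}, out {cons.get(n, 0.0):.4g})" for n in sorted(bad)
            )
            raise NetworkError(f"steady-state mass imbalance at: {detail}")

    # -- flux bookkeeping ---------------------------------------------
    def flux(self, name: str) -> float:
        for r in self.reactions:
            if r.name == name:
                return r.flux
        raise KeyError(name)

    def producers(self, metabolite: str) -> list[tuple[Reaction, int]]:
        """Reactions producing *metabolite*, with the product-slot index."""
        out = []
        for rxn in self.reactions:
            for i, (pname, _) in enumerate(rxn.products):
                if pname == metabolite:
                    out.append((rxn, i))
        return out

    # -- label propagation machinery ----------------------------------
    def _product_map(self, rxn: Reaction, slot: int) -> np.ndarray:
        """Combo-index -> product-state lookup for one product slot."""
        key = (rxn.name, slot)
        if key not in self._maps:
            sizes = [self.metabolites[s].n_states for s in rxn.substrates]
            if sizes:
                grids = np.meshgrid(*[np.arange(n) for n in sizes], indexing="ij")
            else:
                grids = []
            _, sources = rxn.products[slot]
            state = np.zeros([int(np.prod(sizes))] if not sizes else grids[0].shape, dtype=np.int64)
            for bitpos, src in enumerate(sources):
                if src is None:
                    continue
                si, ai = src
                state |= ((grids[si] >> ai) & 1) << bitpos
            self._maps[key] = state.ravel()
        return self._maps[key]


def _symmetrize(met: Metabolite, dist: np.ndarray) -> np.ndarray:
    """Average a distribution with its carbon-order-reversed image."""
    nc = met.carbons
    states = np.arange(dist.size)
    c = states & ((1 << nc) - 1)
    rest = states & ~((1 << nc) - 1)
    rev = np.zeros_like(states)
    for i in range(nc):
        rev |= ((c >> i) & 1) << (nc - 1 - i)
    perm = rev | rest
    return 0.5 * (dist + dist[perm])


def _external_distribution(met: Metabolite, tracer: TracerSpec | None) -> np.ndarray:
    dist = np.zeros(met.n_states)
    if tracer is None or tracer.substrate != met.name:
        dist[0] = 1.0
        return dist
    atoms = [p - 1 for p in tracer.carbon_positions] + [
        met.carbons + p - 1 for p in tracer.nitrogen_positions
    ]
    for a in atoms:
        if not 0 <= a < met.n_atoms:
            raise NetworkError(
                f"tracer {tracer.name}: position outside the {met.name} skeleton"
            )
    dist[0] = 1.0
    for a in atoms:
        new = np.zeros_like(dist)
        idx = np.arange(dist.size)
        unl = idx[(idx >> a) & 1 == 0]
        new[unl] += dist[unl] * (1 - tracer.enrichment)
        new[unl | (1 << a)] += dist[unl] * tracer.enrichment
        dist = new
    return dist


def steady_state_labeling(
    network: NetworkModel,
    tracer: TracerSpec | str | None,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> dict[str, IsotopomerState]:
    """Fixed point of the label-balance equations.

    Each internal metabolite's isotopomer distribution is the
    flux-weighted mixture of its producing reactions' mapped outputs;
    Gauss-Seidel iteration runs until the largest L1 change per sweep
    drops below *tol*.  Only flux ratios matter: the result is invariant
    under uniform flux scaling.
    """
    if isinstance(tracer, str):
        tracer = TRACERS[tracer]
    dists: dict[str, np.ndarray] = {}
    for name, met in network.metabolites.items():
        if met.external:
            dists[name] = _external_distribution(met, tracer)
        else:
            d = np.zeros(met.n_states)
            d[0] = 1.0
            dists[name] = d

    internal = [m for m in network.metabolites.values() if not m.external]
    producers = {m.name: network.producers(m.name) for m in internal}

    for iteration in range(max_iter):
        delta = 0.0
        for met in internal:
            plist = producers[met.name]
            total_flux = sum(r.flux for r, _ in plist)
            if total_flux <= 0:
                continue
            new = np.zeros(met.n_states)
            for rxn, slot in plist:
                if rxn.flux == 0:
                    continue
                if rxn.substrates:
                    joint = dists[rxn.substrates[0]]
                    for s in rxn.substrates[1:]:
                        joint = np.multiply.outer(joint, dists[s])
                    joint = joint.ravel()
                else:
                    joint = np.array([1.0])
                pmap = network._product_map(rxn, slot)
                new += rxn.flux * np.bincount(pmap, weights=joint, minlength=met.n_states)
            new /= total_flux
            if met.symmetric:
                new = _symmetrize(met, new)
            delta = max(delta, float(np.abs(new - dists[met.name]).sum()))
            dists[met.name] = new
        if delta < tol:
            break
    else:
        raise NetworkError(
            f"label propagation did not converge in {max_iter} iterations "
            f"(last sweep L1 residual {delta:.3g})"
        )
    return {
        name: IsotopomerState(network.metabolites[name], d) for name, d in dists.items()
    }


# ---------------------------------------------------------------------
# The packaged glutamine/glutamate network
# ---------------------------------------------------------------------

_METABOLITES = [
    # externals (fixed label state)
    Metabolite("Gln.media", 5, 2, external=True, formula="C5H10N2O3"),
    Metabolite("Glc.media", 6, external=True, formula="C6H12O6"),
    Metabolite("Glu.media0", 5, 1, external=True, formula="C5H9NO4"),
    Metabolite("Pro.media", 5, 1, external=True, formula="C5H9NO2"),
    Metabolite("Orn.media", 5, 1, external=True, formula="C5H12N2O2"),
    Metabolite("CO2", 1, external=True, formula="CO2"),
    Metabolite("NH4", 0, 1, external=True),
    Metabolite("Nx", 0, 1, external=True),
    Metabolite("AcX", 2, external=True, formula="C2H4O"),
    Metabolite("OAAx", 4, external=True, formula="C4H4O5"),
    # internal pools
    Metabolite("Gln", 5, 2, formula="C5H10N2O3"),
    Metabolite("Glu", 5, 1, formula="C5H9NO4"),
    Metabolite("AKG", 5, formula="C5H6O5"),
    Metabolite("Suc", 4, symmetric=True, formula="C4H6O4"),
    Metabolite("Fum", 4, symmetric=True, formula="C4H4O4"),
    Metabolite("Mal", 4, formula="C4H6O5"),
    Metabolite("OAA", 4, formula="C4H4O5"),
    Metabolite("Cit", 6, formula="C6H8O7"),
    Metabolite("AcCoA", 2, formula="C2H4O"),
    Metabolite("AcCoA.lipo", 2, formula="C2H4O"),
    Metabolite("Pyr", 3, formula="C3H4O3"),
    Metabolite("Lac", 3, formula="C3H6O3"),
    Metabolite("P5C", 5, 1, formula="C5H7NO2"),
    Metabolite("Pro", 5, 1, formula="C5H9NO2"),
    Metabolite("Orn", 5, 1, formula="C5H12N2O2"),
    Metabolite("Npool", 0, 1),
]

def _ident(n: int, sub: int = 0) -> tuple:
    return tuple((sub, i) for i in range(n))


#: User-assignable fluxes of the packaged network (umol per mg protein per day).
FLUX_KEYS = (
    "gln_uptake", "gls", "glul", "glu_secretion", "glu_uptake",
    "glu_to_akg", "akg_to_glu", "n_influx",
    "akg_ox", "mal_to_oaa", "oaa_to_mal", "oaa_influx", "cs", "idh_ox", "idh_rev", "acl",
    "pdh", "pc", "me", "ldh", "glycolysis",
    "glu_to_p5c", "p5c_to_pro", "pro_to_p5c", "p5c_to_orn", "orn_to_p5c",
    "pro_uptake", "orn_uptake", "glu_to_protein", "accoa_lipo_dilution",
)


def build_default_network(condition_fluxes: dict[str, float]) -> NetworkModel:
    """Assemble the packaged Gln/Glu/TCA/proline/fatty-acid network.

    *condition_fluxes* assigns the named exchange and pathway fluxes
    (see :data:`FLUX_KEYS`); unspecified keys default to zero.  Sink and
    source fluxes needed to close every internal mass balance are
    derived automatically, and a negative derived sink (an impossible
    flux assignment) raises :class:`NetworkError`.
    """
    unknown = set(condition_fluxes) - set(FLUX_KEYS)
    if unknown:
        raise NetworkError(f"unknown flux keys: {sorted(unknown)}")
    f = {k: float(condition_fluxes.get(k, 0.0)) for k in FLUX_KEYS}
    neg = [k for k, v in f.items() if v < 0]
    if neg:
        raise NetworkError(f"negative flux for {neg}")

    mets = {m.name: m for m in _METABOLITES}

    def bal(name: str, value: float) -> float:
        if value < -BALANCE_RTOL:
            raise NetworkError(
                f"flux assignment drives derived balance flux {name!r} negative ({value:.4g})"
            )
        return max(value, 0.0)

    # Derived balance fluxes (sinks/sources closing each pool).
    p5c_to_glu = bal(
        "p5c_to_glu",
        f["glu_to_p5c"] + f["pro_to_p5c"] + f["orn_to_p5c"] - f["p5c_to_pro"] - f["p5c_to_orn"],
    )
    gln_sink = bal("gln_sink", f["gln_uptake"] + f["glul"] - f["gls"])
    glu_in = f["gls"] + f["akg_to_glu"] + p5c_to_glu + f["glu_uptake"]
    glu_out_named = (
        f["glu_secretion"] + f["glu_to_akg"] + f["glul"] + f["glu_to_p5c"] + f["glu_to_protein"]
    )
    glu_sink = bal("glu_sink", glu_in - glu_out_named)
    akg_sink = bal(
        "akg_sink",
        f["glu_to_akg"] + f["idh_ox"] - f["akg_to_glu"] - f["akg_ox"] - f["idh_rev"],
    )
    mal_in = f["akg_ox"] + f["oaa_to_mal"]
    mal_sink = bal("mal_sink", mal_in - f["mal_to_oaa"] - f["me"])
    oaa_in = f["mal_to_oaa"] + f["pc"] + f["acl"] + f["oaa_influx"]
    oaa_sink = bal("oaa_sink", oaa_in - f["cs"] - f["oaa_to_mal"])
    cit_sink = bal("cit_sink", f["cs"] + f["idh_rev"] - f["idh_ox"] - f["acl"])
    accoa_src = max(f["cs"] - f["pdh"], 0.0)
    accoa_sink = max(f["pdh"] - f["cs"], 0.0)
    pyr_in = 2 * f["glycolysis"] + f["me"]
    pyr_sink = bal("pyr_sink", pyr_in - f["pdh"] - f["pc"] - f["ldh"])
    npool_eff = bal("npool_efflux", f["glu_to_akg"] + f["n_influx"] - f["akg_to_glu"])
    pro_sink = bal("pro_sink", f["p5c_to_pro"] + f["pro_uptake"] - f["pro_to_p5c"])
    orn_sink = bal("orn_sink", f["p5c_to_orn"] + f["orn_uptake"] - f["orn_to_p5c"])
    fas = bal("fas", f["acl"] + f["accoa_lipo_dilution"])

    R = Reaction
    reactions = [
        R("gln_uptake", ("Gln.media",), (("Gln", _ident(7)),), f["gln_uptake"]),
        # glutaminase: amide N released as ammonia
        R("gls", ("Gln",), (("Glu", _ident(6)),), f["gls"]),
        # glutamine synthetase: amide N from free (unlabeled) ammonia
        R("glul", ("Glu", "NH4"), (("Gln", _ident(6) + (None,)),), f["glul"]),
        R("glu_secretion", ("Glu",), (), f["glu_secretion"]),
        R("glu_uptake", ("Glu.media0",), (("Glu", _ident(6)),), f["glu_uptake"]),
        # GDH/transaminases: amino N enters the well-mixed amino-N pool
        R("glu_to_akg", ("Glu",), (("AKG", _ident(5)), ("Npool", ((0, 5),))), f["glu_to_akg"]),
        R("akg_to_glu", ("AKG", "Npool"), (("Glu", _ident(5) + ((1, 0),)),), f["akg_to_glu"]),
        R("n_influx", ("Nx",), (("Npool", ((0, 0),)),), f["n_influx"]),
        R("n_efflux", ("Npool",), (), npool_eff),
        # oxidative TCA: AKG C1 lost as CO2
        R("akg_ox", ("AKG",), (("Suc", tuple((0, i + 1) for i in range(4))),), f["akg_ox"]),
        R("suc_fum", ("Suc",), (("Fum", _ident(4)),), f["akg_ox"]),
        R("fum_mal", ("Fum",), (("Mal", _ident(4)),), f["akg_ox"]),
        R("mal_to_oaa", ("Mal",), (("OAA", _ident(4)),), f["mal_to_oaa"]),
        R("oaa_to_mal", ("OAA",), (("Mal", _ident(4)),), f["oaa_to_mal"]),
        # unlabeled anaplerosis into OAA (aspartate exchange, protein turnover)
        R("oaa_influx", ("OAAx",), (("OAA", _ident(4)),), f["oaa_influx"]),
        # citrate synthase: acetyl arm = Cit atoms 0,1; OAA part = atoms 2..5
        R("cs", ("AcCoA", "OAA"), (("Cit", ((0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (1, 3))),), f["cs"]),
        # oxidative IDH(+aconitase): Cit atom 5 lost as CO2
        R(
            "idh_ox",
            ("Cit",),
            (("AKG", ((0, 2), (0, 3), (0, 4), (0, 0), (0, 1))),),
            f["idh_ox"],
        ),
        # reductive carboxylation: AKG C4,C5 become the future acetyl arm
        R(
            "idh_rev",
            ("AKG", "CO2"),
            (("Cit", ((0, 3), (0, 4), (0, 0), (0, 1), (0, 2), (1, 0))),),
            f["idh_rev"],
        ),
        # ATP-citrate lyase: acetyl arm to the lipogenic pool, rest to OAA
        R(
            "acl",
            ("Cit",),
            (("AcCoA.lipo", ((0, 0), (0, 1))), ("OAA", ((0, 2), (0, 3), (0, 4), (0, 5)))),
            f["acl"],
        ),
        R("accoa_src", ("AcX",), (("AcCoA", _ident(2)),), accoa_src),
        R("accoa_sink", ("AcCoA",), (), accoa_sink),
        # pyruvate dehydrogenase: Pyr C1 lost as CO2
        R("pdh", ("Pyr",), (("AcCoA", ((0, 1), (0, 2))),), f["pdh"]),
        # pyruvate carboxylase: CO2 fixed as OAA C4
        R("pc", ("Pyr", "CO2"), (("OAA", ((0, 0), (0, 1), (0, 2), (1, 0))),), f["pc"]),
        # malic enzyme: Mal C4 lost as CO2
        R("me", ("Mal",), (("Pyr", ((0, 0), (0, 1), (0, 2))),), f["me"]),
        R("ldh", ("Pyr",), (("Lac", _ident(3)),), f["ldh"]),
        R("lac_out", ("Lac",), (), f["ldh"]),
        # glycolysis with the standard atom map (C1..C3 and C4..C6 halves)
        R(
            "glycolysis",
            ("Glc.media",),
            (
                ("Pyr", ((0, 2), (0, 1), (0, 0))),
                ("Pyr", ((0, 3), (0, 4), (0, 5))),
            ),
            f["glycolysis"],
        ),
        # proline / ornithine branch via P5C (glutamate-5-semialdehyde)
        R("glu_to_p5c", ("Glu",), (("P5C", _ident(6)),), f["glu_to_p5c"]),
        R("p5c_to_glu", ("P5C",), (("Glu", _ident(6)),), p5c_to_glu),
        R("p5c_to_pro", ("P5C",), (("Pro", _ident(6)),), f["p5c_to_pro"]),
        R("pro_to_p5c", ("Pro",), (("P5C", _ident(6)),), f["pro_to_p5c"]),
        R("p5c_to_orn", ("P5C",), (("Orn", _ident(6)),), f["p5c_to_orn"]),
        R("orn_to_p5c", ("Orn",), (("P5C", _ident(6)),), f["orn_to_p5c"]),
        R("pro_uptake", ("Pro.media",), (("Pro", _ident(6)),), f["pro_uptake"]),
        R("orn_uptake", ("Orn.media",), (("Orn", _ident(6)),), f["orn_uptake"]),
        # lipogenic acetyl-CoA pool
        R("accoa_lipo_dilution", ("AcX",), (("AcCoA.lipo", _ident(2)),), f["accoa_lipo_dilution"]),
        R("fas", ("AcCoA.lipo",), (), fas),
        # sinks closing the remaining balances (protein synthesis, cataplerosis)
        R("gln_sink", ("Gln",), (), gln_sink),
        R("glu_to_protein", ("Glu",), (), f["glu_to_protein"]),
        R("glu_sink", ("Glu",), (), glu_sink),
        R("akg_sink", ("AKG",), (), akg_sink),
        R("mal_sink", ("Mal",), (), mal_sink),
        R("oaa_sink", ("OAA",), (), oaa_sink),
        R("cit_sink", ("Cit",), (), cit_sink),
        R("pyr_sink", ("Pyr",), (), pyr_sink),
        R("pro_sink", ("Pro",), (), pro_sink),
        R("orn_sink", ("Orn",), (), orn_sink),
    ]
    return NetworkModel(metabolites=mets, reactions=reactions)


# ---------------------------------------------------------------------
# Plain-text (YAML) network serialization
# ---------------------------------------------------------------------

def network_to_dict(network: NetworkModel) -> dict:
    """Serializable description: metabolites, atom maps as position lists,
    flux values."""
    return {
        "metabolites": [
            {
                "name": m.name,
                "carbons": m.carbons,
                "nitrogens": m.nitrogens,
                "symmetric": m.symmetric,
                "external": m.external,
                "formula": m.formula,
            }
            for m in network.metabolites.values()
        ],
        "reactions": [
            {
                "name": r.name,
                "flux": r.flux,
                "substrates": list(r.substrates),
                "products": [
                    {
                        "metabolite": pname,
                        "sources": [list(s) if s is not None else None for s in sources],
                    }
                    for pname, sources in r.products
                ],
            }
            for r in network.reactions
        ],
    }


def network_from_dict(data: dict) -> NetworkModel:
    mets = {
        m["name"]: Metabolite(
            name=m["name"],
            carbons=int(m["carbons"]),
            nitrogens=int(m.get("nitrogens", 0)),
            symmetric=bool(m.get("symmetric", False)),
            external=bool(m.get("external", False)),
            formula=m.get("formula", ""),
        )
        for m in data["metabolites"]
    }
    reactions = [
        Reaction(
            name=r["name"],
            substrates=tuple(r["substrates"]),
            products=tuple(
                (
                    p["metabolite"],
                    tuple(tuple(s) if s is not None else None for s in p["sources"]),
                )
                for p in r["products"]
            ),
            flux=float(r["flux"]),
        )
        for r in data["reactions"]
    ]
    return NetworkModel(metabolites=mets, reactions=reactions)


def save_network(network: NetworkModel, path) -> None:
    """Write the network description as YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(network), fh, sort_keys=False)


def load_network(path) -> NetworkModel:
    """Load a network description from YAML (validated on construction)."""
    import yaml

    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))
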