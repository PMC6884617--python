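"""Mass-isotopomer-distribution (MID) arithmetic.

A MID is the vector of fractional abundances of the isotopologues
M0..Mn of a metabolite, indexed by nominal mass shift.  Everything in
targeted stable-isotope tracing starts from three primitives:

* the *theoretical* MID of an unlabeled species, obtained by convolving
  the single-atom isotope distributions of every atom in its formula;
* the *correction matrix* that maps a true (tracer-only) MID to the MID
  one expects to measure in the presence of naturally occurring heavy
  isotopes (and, optionally, imperfect tracer enrichment);
* natural-abundance *correction*, i.e. inverting that map by bounded
  least squares so that nonzero Mk reflects tracer-derived label only.

All MIDs handled here are plain 1-D numpy vectors wrapped in
:class:`MIDVector`, which tracks normalization and correction status.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

__all__ = [
    "ElementalFormula",
    "IsotopeAbundances",
    "MIDVector",
    "CorrectionMatrix",
    "NATURAL_ABUNDANCES",
    "parse_formula",
    "natural_mid",
    "build_correction_matrix",
    "correct_mid",
    "convolve_mids",
    "is_normalize",
]

NORM_TOL = 1e-9

#: IUPAC terrestrial isotope fractions by nominal mass shift.
NATURAL_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Unknown element or malformed elemental formula."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element symbol -> atom count, e.g. C5H9NO4 for glutamate."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if n < 0:
                raise FormulaError(f"negative atom count for {el}")

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def without(self, element: str, n: int) -> "ElementalFormula":
        """Formula with *n* atoms of *element* removed."""
        if self[element] < n:
            raise FormulaError(
                f"cannot remove {n} {element} atoms from formula with {self[element]}"
            )
        counts = dict(self.counts)
        counts[element] -= n
        return ElementalFormula(counts)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in sorted(self.counts.items()) if n
        )


def parse_formula(formula: str | ElementalFormula) -> ElementalFormula:
    """Parse a Hill-style formula string ('C6H12O6') into counts."""
    if isinstance(formula, ElementalFormula):
        return formula
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"malformed formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise FormulaError(f"malformed formula {formula!r}")
    return ElementalFormula(counts)


@dataclass(frozen=True)
class IsotopeAbundances:
    """Per element, the vector of isotope fractions by mass shift."""

    fractions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(NATURAL_ABUNDANCES)
    )

    def __post_init__(self) -> None:
        for el, fr in self.fractions.items():
            arr = np.asarray(fr, dtype=float)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"isotope fractions for {el} outside [0, 1]")
            if abs(arr.sum() - 1.0) > 1e-12:
                raise ValueError(f"isotope fractions for {el} sum to {arr.sum()}")

    def for_element(self, element: str) -> np.ndarray:
        try:
            return np.asarray(self.fractions[element], dtype=float)
        except KeyError:
            raise FormulaError(f"no isotope abundances configured for element {element!r}")

    @classmethod
    def carbon_only(cls, p13c: float = 0.0107) -> "IsotopeAbundances":
        """All elements monoisotopic except carbon at fraction *p13c*."""
        fr = {el: (1.0,) for el in NATURAL_ABUNDANCES}
        fr["C"] = (1.0 - p13c, p13c)
        return cls(fr)

    @classmethod
    def monoisotopic(cls) -> "IsotopeAbundances":
        return cls({el: (1.0,) for el in NATURAL_ABUNDANCES})


@dataclass(frozen=True)
class MIDVector:
    """Fractional isotopologue abundances M0..Mn for one species.

    ``abundances[k]`` is the fraction at nominal mass shift k.  The
    ``normalized`` and ``corrected`` flags record whether the vector
    sums to one and whether natural abundance has been removed.
    """

    metabolite: str
    abundances: np.ndarray
    tracer: str = ""
    normalized: bool = True
    corrected: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("MID must be a non-empty 1-D vector")
        if np.any(arr < -NORM_TOL):
            raise ValueError(f"negative abundance in MID for {self.metabolite}")
        if self.normalized and abs(arr.sum() - 1.0) > NORM_TOL:
            raise ValueError(
                f"MID for {self.metabolite} flagged normalized but sums to {arr.sum():.6g}"
            )

    def __len__(self) -> int:
        return self.abundances.size

    def __getitem__(self, shift: int) -> float:
        return float(self.abundances[shift])

    def renormalized(self) -> "MIDVector":
        total = self.abundances.sum()
        if total <= 0:
            raise ValueError(f"cannot normalize all-zero MID for {self.metabolite}")
        return replace(self, abundances=self.abundances / total, normalized=True)


def _atom_convolve(dists: list[np.ndarray], max_shift: int | None = None) -> np.ndarray:
    out = np.array([1.0])
    for d in dists:
        out = np.convolve(out, d)
        if max_shift is not None and out.size > max_shift + 1:
            out = out[: max_shift + 1]
    return out


def natural_mid(
    formula: str | ElementalFormula,
    abundances: IsotopeAbundances | None = None,
    max_shift: int | None = None,
    metabolite: str = "",
) -> MIDVector:
    """Theoretical MID of the unlabeled species.

    Convolution over all atoms of their single-atom mass-shift
    distributions, truncated at ``max_shift`` and renormalized.
    """
    formula = parse_formula(formula)
    abundances = abundances or IsotopeAbundances()
    if max_shift is not None and max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    dists = []
    for el, n in formula.counts.items():
        d = abundances.for_element(el)
        dists.extend([d] * n)
    out = _atom_convolve(dists, max_shift)
    if max_shift is not None:
        full = np.zeros(max_shift + 1)
        full[: out.size] = out
        out = full
    return MIDVector(
        metabolite=metabolite or str(formula), abundances=out / out.sum(), corrected=False
    )


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular map from true (tracer-only) MID to measured MID.

    Column j is the measured MID expected from a species carrying
    exactly j tracer atoms; sub-unity column sums reflect probability
    mass truncated beyond shift n.
    """

    matrix: np.ndarray
    formula: ElementalFormula
    tracer_element: str
    purity: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correction matrix must be square")
        if np.any(m.sum(axis=0) > 1 + 1e-9):
            raise ValueError("correction matrix column sums exceed 1")
        if np.any(np.diag(m) <= 0):
            raise ValueError("correction matrix has non-positive diagonal")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def build_correction_matrix(
    formula: str | ElementalFormula,
    tracer_element: str = "C",
    tracer_positions: int | None = None,
    abundances: IsotopeAbundances | None = None,
    purity: float = 1.0,
    carbon_only: bool = False,
) -> CorrectionMatrix:
    """Correction matrix for a species with *tracer_positions* labelable atoms.

    Column j stacks three independent contributions: the j labeled
    positions (heavy with probability *purity*), the remaining
    tracer-element positions at natural abundance, and every other atom
    of the formula at natural abundance.  ``carbon_only=True`` restricts
    natural-abundance bookkeeping to the tracer element itself.
    """
    formula = parse_formula(formula)
    abundances = abundances or IsotopeAbundances()
    if tracer_positions is None:
        tracer_positions = formula[tracer_element]
    if tracer_positions > formula[tracer_element]:
        raise FormulaError(
            f"{tracer_positions} tracer positions exceed {formula[tracer_element]} "
            f"{tracer_element} atoms in {formula}"
        )
    if not 0 < purity <= 1:
        raise ValueError("tracer purity must be in (0, 1]")

    n = tracer_positions
    el_dist = abundances.for_element(tracer_element)
    # Natural-abundance background common to all columns: non-tracer atoms.
    rest = formula.without(tracer_element, n)
    bg_dists = []
    for el, cnt in rest.counts.items():
        if carbon_only and el != tracer_element:
            continue
        bg_dists.extend([abundances.for_element(el)] * cnt)
    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        dists = list(bg_dists)
        # Unlabeled tracer positions still carry natural abundance.
        dists.extend([el_dist] * (n - j))
        col = _atom_convolve(dists, max_shift=n)
        # Labeled positions: heavy with probability `purity`.
        if j:
            labeled = _atom_convolve([np.array([1 - purity, purity])] * j, max_shift=n)
            col = np.convolve(labeled, col)[: n + 1]
        matrix[:, j] = np.pad(col, (0, n + 1 - col.size))
    return CorrectionMatrix(matrix=matrix, formula=formula, tracer_element=tracer_element, purity=purity)


def correct_mid(raw: MIDVector, matrix: CorrectionMatrix) -> MIDVector:
    """Remove natural-abundance (and purity) contributions from a measured MID.

    Solves ``matrix @ x ~= raw`` by non-negative least squares and
    renormalizes; NNLS keeps noisy tails from producing negative
    isotopologue fractions.
    """
    if len(raw) != matrix.size:
        raise ValueError(
            f"MID length {len(raw)} does not match correction matrix size {matrix.size}"
        )
    obs = np.asarray(raw.abundances, dtype=float)
    if obs.sum() <= 0:
        raise ValueError(f"all-zero MID for {raw.metabolite}")
    x, _ = scipy.optimize.nnls(matrix.matrix, obs)
    if x.sum() <= 0:
        raise ValueError(f"correction annihilated MID for {raw.metabolite}")
    return replace(raw, abundances=x / x.sum(), normalized=True, corrected=True)


def convolve_mids(a: MIDVector, b: MIDVector) -> MIDVector:
    """Mass-shift distribution of the union of two independent moieties."""
    out = np.convolve(a.abundances, b.abundances)
    return MIDVector(
        metabolite=a.metabolite or b.metabolite,
        tracer=a.tracer or b.tracer,
        abundances=out / out.sum(),
        corrected=a.corrected and b.corrected,
    )


def is_normalize(
    analyte_area: float,
    internal_standard_area: float,
    response_factor: float = 1.0,
    sample: str = "",
) -> float:
    """Internal-standard normalization: analyte/IS peak-area ratio x RF."""
    if internal_standard_area <= 0:
        raise ValueError(
            f"internal standard area must be positive"
            + (f" (sample {sample!r})" if sample else "")
        )
    return analyte_area / internal_standard_area * response_factor
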