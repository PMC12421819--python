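"""Natural-abundance correction of fragment mass-isotopomer distributions.

A derivatized amino-acid fragment carries many atoms besides the tracer
(backbone) carbons; their natural heavy isotopes shift measured masses
upward.  The correction matrix C collects the mass-shift distribution of
those non-tracer atoms: C[i, j] is the probability that a molecule with
j tracer labels is observed at shift i.  Measured MIDs are deconvolved
by non-negative least squares, which is robust to truncated mass ranges.

Tracer-carbon natural abundance is deliberately excluded — the matrix
covers derivatization atoms and non-backbone carbons only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "FragmentSpec",
    "CorrectionMatrix",
    "NATURAL_ABUNDANCE",
    "DEFAULT_FRAGMENTS",
    "build_correction_matrix",
    "correct_mid",
    "convolve_mid",
]

# Mass-shift probability vectors per element, index = extra neutrons.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

# TBDMS-derivatized [M-57]+ fragments containing the complete amino-acid
# carbon backbone.  The elemental formulas are standard compositions for
# this derivatization chemistry, shipped as editable defaults (the
# nominal masses alone do not determine them).
_TBDMS_FORMULAS: dict[str, dict] = {
    "Ala": {"nominal_mass": 260, "backbone_carbons": 3,
            "formula": {"C": 11, "H": 26, "N": 1, "O": 2, "Si": 2}},
    "Gly": {"nominal_mass": 246, "backbone_carbons": 2,
            "formula": {"C": 10, "H": 24, "N": 1, "O": 2, "Si": 2}},
    "Ser": {"nominal_mass": 390, "backbone_carbons": 3,
            "formula": {"C": 17, "H": 40, "N": 1, "O": 3, "Si": 3}},
    "Asp": {"nominal_mass": 418, "backbone_carbons": 4,
            "formula": {"C": 18, "H": 40, "N": 1, "O": 4, "Si": 3}},
    "Glu": {"nominal_mass": 432, "backbone_carbons": 5,
            "formula": {"C": 19, "H": 42, "N": 1, "O": 4, "Si": 3}},
}


@dataclass(frozen=True)
class FragmentSpec:
    """A fragment ion used for isotopologue analysis."""

    amino_acid: str
    nominal_mass: int
    backbone_carbons: int
    elemental_formula: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.nominal_mass <= 0:
            raise ValueError("nominal_mass must be positive")
        if self.backbone_carbons <= 0:
            raise ValueError("backbone_carbons must be positive")
        if self.elemental_formula.get("C", self.backbone_carbons) < self.backbone_carbons:
            raise ValueError("formula contains fewer carbons than the backbone")

    @property
    def non_tracer_formula(self) -> dict[str, int]:
        f = dict(self.elemental_formula)
        if "C" in f:
            f["C"] = f["C"] - self.backbone_carbons
            if f["C"] == 0:
                del f["C"]
        return f


def default_fragments() -> dict[str, FragmentSpec]:
    return {
        aa: FragmentSpec(amino_acid=aa, nominal_mass=d["nominal_mass"],
                         backbone_carbons=d["backbone_carbons"],
                         elemental_formula=dict(d["formula"]))
        for aa, d in _TBDMS_FORMULAS.items()
    }


DEFAULT_FRAGMENTS: dict[str, FragmentSpec] = default_fragments()


@dataclass
class CorrectionMatrix:
    matrix: np.ndarray  # shape (m+1, n+1); column j = shift dist for j labels
    fragment: FragmentSpec | None = None

    @property
    def n_labels(self) -> int:
        return self.matrix.shape[1] - 1

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def _convolve_formula(formula: Mapping[str, int],
                      abundance: Mapping[str, Sequence[float]],
                      size: int) -> np.ndarray:
    """Mass-shift distribution of a set of atoms, truncated to ``size``."""
    dist = np.zeros(size)
    dist[0] = 1.0
    for element, count in formula.items():
        if element not in abundance:
            raise KeyError(f"element {element!r} missing from the abundance table")
        p = np.asarray(abundance[element], dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{element}: abundance probabilities must sum to 1")
        for _ in range(int(count)):
            dist = np.convolve(dist, p)[:size]
    return dist


def build_correction_matrix(
    spec: FragmentSpec,
    abundance_table: Mapping[str, Sequence[float]] | None = None,
    n_shifts: int | None = None,
) -> CorrectionMatrix:
    """Correction matrix over mass shifts 0..m for a fragment.

    Because the tracer carbons are excluded, every column carries the
    same non-tracer shift distribution, offset by the label count.
    """
    abundance = dict(NATURAL_ABUNDANCE)
    if abundance_table is not None:
        abundance.update({k: tuple(v) for k, v in abundance_table.items()})
    n = spec.backbone_carbons
    m = (n_shifts if n_shifts is not None else n) + 1
    shift = _convolve_formula(spec.non_tracer_formula, abundance, m)
    C = np.zeros((m, n + 1))
    for j in range(n + 1):
        C[j:, j] = shift[: m - j]
    return CorrectionMatrix(matrix=C, fragment=spec)


def convolve_mid(mid: np.ndarray, C: CorrectionMatrix) -> np.ndarray:
    """Forward model: tracer MID -> observable (uncorrected) MID."""
    mid = np.asarray(mid, dtype=float)
    if len(mid) != C.matrix.shape[1]:
        raise ValueError("MID length does not match the correction matrix")
    raw = C.matrix @ mid
    return raw / raw.sum()


def correct_mid(raw: np.ndarray, C: CorrectionMatrix) -> tuple[np.ndarray, float]:
    """Recover the tracer-only MID from a measured one.

    Solves ``C x ~ raw`` by NNLS, renormalizes x to sum 1 and returns
    ``(corrected, residual)``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or len(raw) != C.matrix.shape[0]:
        raise ValueError(
            f"raw MID length {raw.shape} does not match matrix "
            f"{C.matrix.shape[0]} mass shifts")
    total = raw.sum()
    if total <= 0:
        raise ValueError("raw MID is all zero")
    x, resid = nnls(C.matrix, raw / total)
    s = x.sum()
    if s <= 0:
        raise ValueError("NNLS returned an all-zero solution")
    return x / s, float(resid)
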