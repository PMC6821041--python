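"""16S qPCR quantitation: standard curves and copies/ml conversion.

Bacterial density is expressed throughout the package as 16S rRNA gene
copies per millilitre of original sample.  It is obtained from a qPCR
cycle threshold (Ct) in three steps:

1. a standard curve ``Ct = slope * log10(copies) + intercept`` fitted by
   ordinary least squares to serial dilutions of a quantified standard;
2. inversion of the curve to copies per reaction;
3. volume algebra scaling reaction copies back to the original sample:
   ``copies/ml = copies_per_reaction * (elution/template) / input_ml``,
   with defaults of 60 ul elution, 1.5 ul template per reaction and
   250 ul of sample entering extraction.

Copy numbers of a quantified dsDNA standard follow the usual mass
formula assuming 650 Da per base pair.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import AnalysisError, ValidationError

AVOGADRO = 6.022e23
DALTONS_PER_BP = 650.0

#: extraction/reaction volumes (ul) used when none are given
DEFAULT_ELUTION_UL = 60.0
DEFAULT_TEMPLATE_UL = 1.5
DEFAULT_INPUT_UL = 250.0


def copies_from_mass(mass_ng: float, length_bp: float) -> float:
    """dsDNA copy number from mass (ng) and amplicon/genome length (bp).

    ``copies = mass_ng * N_A / (length_bp * 1e9 * 650)``.
    """
    if mass_ng <= 0 or length_bp <= 0:
        raise ValidationError("mass and length must be positive")
    return mass_ng * AVOGADRO / (length_bp * 1e9 * DALTONS_PER_BP)


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct against log10(copies per reaction).

    ``slope`` is negative (more template, earlier threshold);
    ``r_squared`` in [0, 1] reports fit quality.
    """

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not self.slope < 0:
            raise ValidationError(f"standard-curve slope must be < 0, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError(f"r_squared outside [0, 1]: {self.r_squared}")

    def copies_per_reaction(self, ct: float) -> float:
        """Invert the curve at one Ct value."""
        return float(10.0 ** ((ct - self.intercept) / self.slope))


def fit_standard_curve(ct, log10_copies) -> StandardCurve:
    """Fit ``Ct = slope * log10(copies) + intercept`` by least squares."""
    ct = np.asarray(ct, dtype=float)
    x = np.asarray(log10_copies, dtype=float)
    if ct.shape != x.shape or ct.ndim != 1:
        raise AnalysisError("ct and log10_copies must be equal-length 1-d sequences")
    if len(x) < 2 or np.unique(x).size < 2:
        raise AnalysisError("standard curve needs >= 2 distinct standard points")
    fit = stats.linregress(x, ct)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def density_from_ct(
    ct: float,
    curve: StandardCurve,
    template_volume_ul: float = DEFAULT_TEMPLATE_UL,
    elution_volume_ul: float = DEFAULT_ELUTION_UL,
    input_volume_ul: float = DEFAULT_INPUT_UL,
) -> float:
    """16S copies/ml of original sample from one Ct measurement.

    The template aliquot represents ``template/elution`` of the total
    eluted DNA, which in turn came from ``input_volume_ul`` of sample.
    """
    for name, vol in (
        ("template_volume_ul", template_volume_ul),
        ("elution_volume_ul", elution_volume_ul),
        ("input_volume_ul", input_volume_ul),
    ):
        if vol <= 0:
            raise ValidationError(f"{name} must be > 0")
    if template_volume_ul > elution_volume_ul:
        raise ValidationError("template volume cannot exceed elution volume")
    copies_rxn = curve.copies_per_reaction(ct)
    input_ml = input_volume_ul / 1000.0
    return copies_rxn * (elution_volume_ul / template_volume_ul) / input_ml
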