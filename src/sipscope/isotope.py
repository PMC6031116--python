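"""Buoyant-density physics for DNA in CsCl gradients.

DNA reaches isopycnic equilibrium in a CsCl gradient at a buoyant density
set jointly by its GC content and its heavy-isotope content.  The model here
is the standard linear one: density rises linearly with GC fraction
(Schildkraut relation, rho = 1.660 + 0.098 * GC g/mL), and fully replacing
carbon with 13C adds a further, GC-independent shift (0.036 g/mL by
default).  Atom-fraction excess (AFE) interpolates that shift linearly, so
inverting the relation for a genome of known GC content turns an observed
band density into an isotope-enrichment estimate.

Fraction densities are measured by refractometry; a linear calibration line
maps refractive index (RI) to density for CsCl solutions at the instrument's
calibration temperature.

All densities are g/mL; no temperature correction is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

#: Physically plausible buoyant-density range for DNA in CsCl (g/mL).
CSCL_DENSITY_RANGE = (1.60, 1.85)

#: Plausible refractive-index range for CsCl gradient fractions.
RI_RANGE = (1.30, 1.50)


@dataclass(frozen=True)
class IsotopeDensityModel:
    """Constants tying GC content, 13C labeling, RI and buoyant density together.

    Parameters
    ----------
    gc_slope :
        Density increase per unit GC fraction (g/mL).
    gc_intercept :
        Density of hypothetical 0% GC natural-abundance DNA (g/mL).
    max_shift_13c :
        Buoyant-density increase for 100 atom% 13C labeling (g/mL).
    ri_slope, ri_intercept :
        Coefficients of the linear refractive-index -> density calibration
        for CsCl at the calibration temperature.  Instrument calibrations
        differ, so both are overridable.
    """

    gc_slope: float = 0.098
    gc_intercept: float = 1.660
    max_shift_13c: float = 0.036
    ri_slope: float = 10.8601
    ri_intercept: float = -13.4974

    def __post_init__(self) -> None:
        if self.gc_slope <= 0:
            raise DomainError(f"gc_slope must be positive, got {self.gc_slope}")
        if self.max_shift_13c <= 0:
            raise DomainError(
                f"max_shift_13c must be positive, got {self.max_shift_13c}"
            )
        if self.ri_slope <= 0:
            raise DomainError(f"ri_slope must be positive, got {self.ri_slope}")


DEFAULT_MODEL = IsotopeDensityModel()


@dataclass(frozen=True)
class EnrichmentEstimate:
    """Atom-fraction excess 13C estimated from an observed buoyant density.

    ``afe`` is the point estimate; ``afe_lower``/``afe_upper`` bracket it
    when the estimate derives from a density interval rather than a single
    density.  All three are clamped to [0, 1]: densities at or below the
    unlabeled position carry no enrichment signal and yield zero.
    """

    afe: float
    afe_lower: float
    afe_upper: float
    observed_density: float
    unlabeled_density: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.afe_lower <= self.afe <= self.afe_upper <= 1.0):
            raise DomainError(
                "enrichment bounds must satisfy 0 <= lower <= afe <= upper <= 1, "
                f"got ({self.afe_lower}, {self.afe}, {self.afe_upper})"
            )


def _check_gc(gc: float) -> None:
    if not 0.0 <= gc <= 1.0:
        raise DomainError(f"GC fraction must lie in [0, 1], got {gc}")


def _check_afe(afe: float) -> None:
    if not 0.0 <= afe <= 1.0:
        raise DomainError(f"atom-fraction excess must lie in [0, 1], got {afe}")


def gc_to_density(gc: float, model: IsotopeDensityModel = DEFAULT_MODEL) -> float:
    """Buoyant density (g/mL) of natural-abundance DNA of the given GC fraction.

    Linear in GC: ``gc_intercept + gc_slope * gc``.  With the default
    constants, 49.95% GC DNA bands at ~1.71 g/mL.
    """
    _check_gc(gc)
    return model.gc_intercept + model.gc_slope * gc


def density_from_enrichment(
    gc: float, afe: float, model: IsotopeDensityModel = DEFAULT_MODEL
) -> float:
    """Buoyant density of DNA with the given GC fraction and 13C atom-fraction excess."""
    _check_gc(gc)
    _check_afe(afe)
    return gc_to_density(gc, model) + afe * model.max_shift_13c


def enrichment_from_density(
    observed_density: float,
    gc: float,
    model: IsotopeDensityModel = DEFAULT_MODEL,
) -> EnrichmentEstimate:
    """Estimate 13C atom-fraction excess from an observed band density.

    Inverts :func:`density_from_enrichment`: the density excess over the
    unlabeled position for this GC content, divided by the full-labeling
    shift, clamped to [0, 1].
    """
    lo, hi = CSCL_DENSITY_RANGE
    if not lo <= observed_density <= hi:
        raise DomainError(
            f"observed density {observed_density} g/mL outside the plausible "
            f"CsCl range [{lo}, {hi}]"
        )
    unlabeled = gc_to_density(gc, model)
    afe = (observed_density - unlabeled) / model.max_shift_13c
    afe = min(max(afe, 0.0), 1.0)
    return EnrichmentEstimate(
        afe=afe,
        afe_lower=afe,
        afe_upper=afe,
        observed_density=observed_density,
        unlabeled_density=unlabeled,
    )


def enrichment_from_density_interval(
    lo: float,
    hi: float,
    gc: float,
    model: IsotopeDensityModel = DEFAULT_MODEL,
) -> EnrichmentEstimate:
    """Enrichment estimate from a density interval (e.g. a pooled bin's span).

    The lower density bound gives a conservative lower AFE bound, the upper
    bound an upper AFE bound, and the interval midpoint the point estimate.
    """
    if lo > hi:
        raise DomainError(f"density interval must satisfy lo <= hi, got [{lo}, {hi}]")
    lower = enrichment_from_density(lo, gc, model)
    upper = enrichment_from_density(hi, gc, model)
    mid = enrichment_from_density((lo + hi) / 2.0, gc, model)
    return EnrichmentEstimate(
        afe=mid.afe,
        afe_lower=lower.afe,
        afe_upper=upper.afe,
        observed_density=(lo + hi) / 2.0,
        unlabeled_density=mid.unlabeled_density,
    )


def ri_to_density(ri: float, model: IsotopeDensityModel = DEFAULT_MODEL) -> float:
    """Convert a refractometer reading to CsCl solution density (g/mL)."""
    lo, hi = RI_RANGE
    if not lo <= ri <= hi:
        raise DomainError(
            f"refractive index {ri} outside the plausible range [{lo}, {hi}]"
        )
    return model.ri_slope * ri + model.ri_intercept


def density_to_ri(density: float, model: IsotopeDensityModel = DEFAULT_MODEL) -> float:
    """Exact inverse of :func:`ri_to_density`."""
    ri = (density - model.ri_intercept) / model.ri_slope
    lo, hi = RI_RANGE
    if not lo <= ri <= hi:
        raise DomainError(
            f"density {density} g/mL maps to refractive index {ri:.5f} outside "
            f"the plausible range [{lo}, {hi}]"
        )
    return ri
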