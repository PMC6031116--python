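"""Density-gradient fraction tables and light/middle/heavy binning.

A SIP experiment yields ~32 fractions per ultracentrifuge tube, collected
densest-first from the pierced bottom.  Each fraction has a measured density
(directly or via refractometry) and a DNA concentration.  Comparing the
labeled (treatment) profile against an unlabeled control lets one delimit
three density bins: *light* (unenriched DNA), *middle* (partially
13C-enriched) and *heavy* (highly enriched).  Genome coverage per fraction,
normalized to a common sequencing depth, locates a genome's band in the
gradient; its coverage-weighted density centroid feeds the enrichment
estimator in :mod:`sipscope.isotope`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EstimationError,
    FormatError,
    IncomparabilityError,
)
from .isotope import DEFAULT_MODEL, IsotopeDensityModel, ri_to_density

BIN_LABELS = ("light", "middle", "heavy")

#: Tolerance (g/mL) for small non-monotonicities in measured fraction densities.
DENSITY_MONOTONE_TOL = 5e-4


@dataclass(frozen=True)
class FractionRecord:
    """One gradient fraction: ordinal id, density (g/mL), DNA mass, sequencing depth."""

    fraction_id: int
    density: float
    dna_conc: float
    seq_depth: float | None = None


@dataclass
class GradientProfile:
    """Ordered fraction records for one sample (treatment or control).

    ``fractions`` is a DataFrame with columns ``fraction_id``, ``density``,
    ``dna_conc`` and optionally ``seq_depth``, canonicalized to descending
    density (densest fraction first, matching bottom-pierced collection).
    """

    sample_id: str
    role: str
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ("treatment", "control"):
            raise DomainError(f"role must be 'treatment' or 'control', got {self.role!r}")
        df = self.fractions
        required = {"fraction_id", "density", "dna_conc"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"profile missing columns: {sorted(missing)}")
        if len(df) < 3:
            raise FormatError(f"profile needs >= 3 fractions, got {len(df)}")
        if (df["density"] <= 0).any():
            raise FormatError("fraction densities must be positive")
        bad = df.index[df["dna_conc"] < 0]
        if len(bad):
            raise FormatError(f"negative dna_conc at row {bad[0]}")
        df = df.sort_values("density", ascending=False, kind="stable").reset_index(
            drop=True
        )
        if (np.diff(df["density"].to_numpy()) >= 0).any():
            raise FormatError("fraction densities must be distinct")
        self.fractions = df

    @property
    def densities(self) -> np.ndarray:
        return self.fractions["density"].to_numpy()

    @property
    def total_mass(self) -> float:
        return float(self.fractions["dna_conc"].sum())

    @property
    def relative_mass(self) -> np.ndarray:
        """Per-fraction DNA mass as a fraction of the profile's total."""
        total = self.total_mass
        if total <= 0:
            raise EstimationError(f"profile {self.sample_id} carries no DNA mass")
        return self.fractions["dna_conc"].to_numpy() / total

    def records(self) -> Iterable[FractionRecord]:
        has_depth = "seq_depth" in self.fractions.columns
        for row in self.fractions.itertuples(index=False):
            yield FractionRecord(
                fraction_id=int(row.fraction_id),
                density=float(row.density),
                dna_conc=float(row.dna_conc),
                seq_depth=float(row.seq_depth) if has_depth else None,
            )


def load_profile(
    path: str | Path,
    sample_id: str | None = None,
    role: str = "treatment",
    model: IsotopeDensityModel = DEFAULT_MODEL,
) -> GradientProfile:
    """Read a TSV fraction table into a validated :class:`GradientProfile`.

    The table must carry ``fraction_id``, ``dna_conc`` and either ``density``
    (g/mL) or ``refractive_index``; refractive indices are converted through
    the model's CsCl calibration line.  Densities must vary monotonically
    with fraction order (small reversals within ``DENSITY_MONOTONE_TOL`` are
    tolerated as measurement noise).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "fraction_id" not in df.columns or "dna_conc" not in df.columns:
        raise FormatError(
            f"{path.name}: fraction table requires columns fraction_id and dna_conc"
        )
    if "density" not in df.columns:
        if "refractive_index" not in df.columns:
            raise FormatError(
                f"{path.name}: need a density or refractive_index column"
            )
        df["density"] = [ri_to_density(ri, model) for ri in df["refractive_index"]]
    bad = df.index[df["dna_conc"] < 0]
    if len(bad):
        raise FormatError(f"{path.name}: negative dna_conc at row {bad[0] + 2}")

    dens = df.sort_values("fraction_id")["density"].to_numpy()
    diffs = np.diff(dens)
    if (diffs > DENSITY_MONOTONE_TOL).any() and (diffs < -DENSITY_MONOTONE_TOL).any():
        row = int(np.argmax(np.abs(np.sign(diffs) - np.sign(diffs[0])) > 0)) + 2
        raise FormatError(
            f"{path.name}: densities not monotone in fraction order (near row {row})"
        )
    return GradientProfile(
        sample_id=sample_id or path.stem, role=role, fractions=df
    )


@dataclass(frozen=True)
class BinScheme:
    """Contiguous light/middle/heavy density intervals ([lo, hi], g/mL).

    Empty intervals are ``None`` (e.g. no heavy bin when the treatment shows
    no highly enriched DNA); ``flags`` records warnings raised while the
    scheme was derived.  Printed cutoff schemes may leave small gaps between
    bins (discrete fraction boundaries); densities falling in a gap are
    resolved by :func:`assign_bins`.
    """

    light: tuple[float, float] | None
    middle: tuple[float, float] | None
    heavy: tuple[float, float] | None
    gap_tolerance: float = 0.002
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        prev = None
        for label in BIN_LABELS:
            iv = getattr(self, label)
            if iv is None:
                continue
            lo, hi = iv
            if lo > hi:
                raise DomainError(f"{label} interval reversed: [{lo}, {hi}]")
            if prev is not None:
                if lo < prev - 1e-12:
                    raise DomainError("bin intervals overlap or are out of order")
                if lo - prev > self.gap_tolerance:
                    raise DomainError(
                        f"gap of {lo - prev:.4f} g/mL between bins exceeds the "
                        f"tolerance {self.gap_tolerance}"
                    )
            prev = hi

    def intervals(self) -> Mapping[str, tuple[float, float]]:
        return {
            label: getattr(self, label)
            for label in BIN_LABELS
            if getattr(self, label) is not None
        }

    @property
    def span(self) -> tuple[float, float]:
        ivs = list(self.intervals().values())
        if not ivs:
            raise DomainError("scheme has no non-empty bins")
        return ivs[0][0], ivs[-1][1]


#: The printed light/middle/heavy cutoffs of the original rhizosphere study.
PAPER_BIN_SCHEME = BinScheme(
    light=(1.692, 1.737), middle=(1.738, 1.746), heavy=(1.747, 1.765)
)


@dataclass
class BinnedProfile:
    """A gradient profile with each fraction assigned to one density bin."""

    profile: GradientProfile
    scheme: BinScheme
    assignments: dict[int, str] = field(default_factory=dict)
    pooled_mass: dict[str, float] = field(default_factory=dict)


def _assign_one(density: float, scheme: BinScheme) -> str:
    ivs = scheme.intervals()
    inside = [label for label, (lo, hi) in ivs.items() if lo <= density <= hi]
    if inside:
        return inside[0]  # shared endpoints resolve to the lighter bin
    span_lo, span_hi = scheme.span
    if density < span_lo or density > span_hi:
        return "unbinned"
    # In a gap between printed cutoffs: nearest interval, ties to the lighter.
    best, best_dist = "unbinned", np.inf
    for label, (lo, hi) in ivs.items():
        dist = min(abs(density - lo), abs(density - hi))
        if dist < best_dist - 1e-15:
            best, best_dist = label, dist
    return best


def assign_bins(profile: GradientProfile, scheme: BinScheme) -> BinnedProfile:
    """Label every fraction light/middle/heavy (or unbinned) and pool DNA mass.

    Intervals are closed; a density in a gap between cutoffs goes to the
    nearer interval, with ties resolved to the lighter bin.  Fractions
    outside the scheme's overall span stay unbinned.
    """
    assignments: dict[int, str] = {}
    pooled = {label: 0.0 for label in (*BIN_LABELS, "unbinned")}
    for rec in profile.records():
        label = _assign_one(rec.density, scheme)
        assignments[rec.fraction_id] = label
        pooled[label] += rec.dna_conc
    return BinnedProfile(
        profile=profile, scheme=scheme, assignments=assignments, pooled_mass=pooled
    )


def auto_bin(
    treatment: GradientProfile,
    control: GradientProfile,
    epsilon: float = 0.05,
    delta: float = 0.02,
) -> BinScheme:
    """Derive a light/middle/heavy scheme by comparing treatment to control.

    Scanning densities above the control's modal density:

    * the heavy bin starts at the smallest density where the control holds
      less than ``epsilon`` of its own total DNA mass while the treatment
      still holds at least ``epsilon`` — DNA present only because of labeling;
    * the middle bin starts at the smallest density where the treatment's
      relative mass exceeds the control's by more than ``delta`` — the onset
      of the labeled shoulder;
    * everything below is light.

    Both thresholds are fractions of per-sample total mass.  If no density
    satisfies a rule the corresponding bin is empty and a flag is recorded.
    """
    if not 0 < epsilon <= 1 or not 0 < delta <= 1:
        raise DomainError(
            f"epsilon and delta must lie in (0, 1], got {epsilon}, {delta}"
        )
    t_lo, t_hi = treatment.densities.min(), treatment.densities.max()
    c_lo, c_hi = control.densities.min(), control.densities.max()
    if t_lo > c_hi or c_lo > t_hi:
        raise IncomparabilityError(
            "treatment and control gradients span disjoint density ranges "
            f"([{t_lo:.3f}, {t_hi:.3f}] vs [{c_lo:.3f}, {c_hi:.3f}])"
        )

    # Evaluate both profiles on the treatment's density grid (ascending).
    order = np.argsort(treatment.densities)
    grid = treatment.densities[order]
    t_rel = treatment.relative_mass[order]
    c_order = np.argsort(control.densities)
    c_rel = np.interp(
        grid,
        control.densities[c_order],
        control.relative_mass[c_order],
        left=0.0,
        right=0.0,
    )
    control_mode = control.densities[np.argmax(control.relative_mass)]
    above = grid > control_mode

    heavy_ok = above & (c_rel < epsilon) & (t_rel >= epsilon)
    heavy_lo = float(grid[heavy_ok][0]) if heavy_ok.any() else None

    middle_ok = above & ((t_rel - c_rel) > delta)
    middle_lo = float(grid[middle_ok][0]) if middle_ok.any() else None
    if heavy_lo is not None and middle_lo is not None:
        middle_lo = min(middle_lo, heavy_lo)

    span_lo, span_hi = float(grid[0]), float(grid[-1])
    flags: list[str] = []
    heavy = (heavy_lo, span_hi) if heavy_lo is not None else None
    if heavy is None:
        flags.append("empty_heavy")
    middle_hi = heavy_lo if heavy_lo is not None else span_hi
    middle = (
        (middle_lo, middle_hi)
        if middle_lo is not None and middle_lo < middle_hi
        else None
    )
    if middle is None:
        flags.append("empty_middle")
    light_hi = middle_lo if middle is not None else (
        heavy_lo if heavy is not None else span_hi
    )
    light = (span_lo, light_hi)
    return BinScheme(
        light=light, middle=middle, heavy=heavy, gap_tolerance=0.002, flags=tuple(flags)
    )


@dataclass
class CoverageByFraction:
    """Per-fraction read coverage of one genome across the gradient.

    ``fractions`` carries ``fraction_id``, ``coverage`` (×) and ``seq_depth``
    (total sequenced bases of that fraction's library); ``normalized`` is
    added by :func:`normalize_coverage`.
    """

    genome_id: str
    fractions: pd.DataFrame
    reference_depth: float | None = None

    def __post_init__(self) -> None:
        required = {"fraction_id", "coverage"}
        missing = required - set(self.fractions.columns)
        if missing:
            raise FormatError(f"coverage table missing columns: {sorted(missing)}")
        if (self.fractions["coverage"] < 0).any():
            raise FormatError("coverage values must be non-negative")


def load_coverage(path: str | Path) -> dict[str, CoverageByFraction]:
    """Read a TSV coverage table (genome_id, fraction_id, coverage[, seq_depth])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "fraction_id", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: coverage table missing {sorted(missing)}")
    return {
        str(gid): CoverageByFraction(genome_id=str(gid), fractions=sub.reset_index(drop=True))
        for gid, sub in df.groupby("genome_id")
    }


def normalize_coverage(
    raw: CoverageByFraction, reference_depth: float | None = None
) -> CoverageByFraction:
    """Rescale per-fraction coverage to a common sequencing depth.

    ``normalized_i = coverage_i * reference_depth / seq_depth_i``; the
    reference defaults to the minimum depth across fractions so normalized
    values never exceed what the shallowest library would have produced.
    """
    df = raw.fractions.copy()
    if "seq_depth" not in df.columns:
        raise FormatError(
            f"coverage table for {raw.genome_id} lacks seq_depth; cannot normalize"
        )
    zero = df.index[df["seq_depth"] <= 0]
    if len(zero):
        frac = df.loc[zero[0], "fraction_id"]
        raise DomainError(
            f"fraction {frac} of {raw.genome_id} has non-positive sequencing depth"
        )
    if reference_depth is None:
        reference_depth = float(df["seq_depth"].min())
    df["normalized"] = df["coverage"] * reference_depth / df["seq_depth"]
    return CoverageByFraction(
        genome_id=raw.genome_id, fractions=df, reference_depth=reference_depth
    )


def genome_density_centroid(
    cov: CoverageByFraction, profile: GradientProfile
) -> float:
    """Coverage-weighted mean density of a genome across the gradient (g/mL).

    Uses normalized coverage when present, raw coverage otherwise.  This
    centroid is the genome's band position and feeds
    :func:`sipscope.isotope.enrichment_from_density`.
    """
    weights_col = "normalized" if "normalized" in cov.fractions.columns else "coverage"
    merged = cov.fractions.merge(
        profile.fractions[["fraction_id", "density"]], on="fraction_id", how="inner"
    )
    if merged.empty:
        raise EstimationError(
            f"coverage table for {cov.genome_id} shares no fractions with "
            f"profile {profile.sample_id}"
        )
    w = merged[weights_col].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise EstimationError(
            f"genome {cov.genome_id} has zero coverage in every fraction"
        )
    return float(np.average(merged["density"].to_numpy(), weights=w))
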