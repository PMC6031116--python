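"""Synthetic genomes and density gradients with known ground truth.

Real SIP sequencing data cannot ship with the package, so this module
generates inputs carrying the same statistical structure the analysis
modules assume:

* genomes of controlled length, GC content and replication-strand skew —
  the first half of the sequence over-uses C and the second half G by a set
  amplitude, so the true origin (the bias switch point, mid-sequence) and
  terminus (the sequence start/end) are known by construction — together
  with non-overlapping gene intervals;
* CsCl gradient profiles for a community of taxa: each taxon bands at the
  density implied by its GC content and 13C atom-fraction excess, its DNA
  mass spreading over fractions as a Gaussian of fixed standard deviation
  (the standard isopycnic band approximation), with per-fraction genome
  coverage proportional to taxon mass over genome length.

Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DomainError
from .gradient import CoverageByFraction, GradientProfile
from .isotope import DEFAULT_MODEL, IsotopeDensityModel, density_from_enrichment

#: CAZy family pool sampled when decorating synthetic gene tables.
_CAZY_FAMILIES = ("GH5", "GH13", "GH3", "GT2", "GT4", "CBM44", "CE1", "PL1")


@dataclass(frozen=True)
class SimTaxon:
    """One community member: relative DNA mass, GC content, 13C enrichment."""

    taxon_id: str
    abundance: float
    gc: float
    afe: float
    genome_length: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 <= self.afe <= 1:
            raise DomainError(f"{self.taxon_id}: afe must lie in [0, 1], got {self.afe}")
        if not 0 < self.gc < 1:
            raise DomainError(f"{self.taxon_id}: gc must lie in (0, 1), got {self.gc}")
        if self.abundance < 0:
            raise DomainError(f"{self.taxon_id}: negative abundance")


@dataclass
class SimGradientConfig:
    """Gradient geometry and noise settings.

    Defaults emulate a ~32-fraction CsCl gradient spanning 1.692–1.765 g/mL
    with Gaussian band spread of 0.003 g/mL, so a taxon's mass lands in a
    handful of adjacent fractions.
    """

    n_fractions: int = 32
    density_min: float = 1.692
    density_max: float = 1.765
    band_sd: float = 0.003
    total_dna_mass: float = 100.0
    noise_sd: float = 0.0
    depth_per_fraction: float = 1e9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_min >= self.density_max:
            raise DomainError("density_min must be below density_max")
        if self.n_fractions < 3:
            raise DomainError("need at least 3 fractions")
        if self.band_sd <= 0:
            raise DomainError("band_sd must be positive")


@dataclass
class SimulatedGradient:
    """Output bundle of :func:`simulate_gradient`."""

    profile: GradientProfile
    coverages: dict[str, CoverageByFraction]
    truncated_mass: dict[str, float] = field(default_factory=dict)


def _half_composition(h: int, p: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    """Exact-count base array of length h with probabilities p, shuffled."""
    counts = {b: int(round(h * p[b])) for b in "CGA"}
    counts["T"] = h - sum(counts.values())
    if counts["T"] < 0:  # rounding overshoot; take it out of A
        counts["A"] += counts["T"]
        counts["T"] = 0
    bases = np.concatenate(
        [np.full(counts[b], ord(b), dtype=np.uint8) for b in "ACGT"]
    )
    rng.shuffle(bases)
    return bases


def simulate_genome(
    length: int,
    gc: float,
    skew_amplitude: float,
    n_genes: int,
    seed: int,
    unannotated_frac: float = 0.4,
    cazy_frac: float = 0.03,
) -> tuple[str, pd.DataFrame]:
    """Generate a genome sequence with imposed replication-strand skew.

    The first half over-uses C and the second half G by ``skew_amplitude``
    (per-base probability shift within the GC pool), so the cumulative GC
    skew has its minimum at the halfway switch point (the constructed
    origin) and its maximum near the sequence ends (the terminus).  Base
    counts per half are exact up to rounding, keeping realized GC within
    ±0.5% of target.  ``n_genes`` non-overlapping intervals are emitted with
    annotation-status and CAZy-family flags.
    """
    if not 0 < gc < 1:
        raise DomainError(f"gc must lie in (0, 1), got {gc}")
    if not 0 <= skew_amplitude < min(gc, 1 - gc):
        raise DomainError(
            f"skew_amplitude must lie in [0, min(gc, 1-gc)), got {skew_amplitude}"
        )
    if n_genes < 0 or length < 1:
        raise DomainError("length must be >= 1 and n_genes >= 0")
    rng = np.random.default_rng(seed)
    h1 = length // 2
    h2 = length - h1
    at = (1 - gc) / 2
    first = _half_composition(
        h1, {"C": (gc + skew_amplitude) / 2, "G": (gc - skew_amplitude) / 2, "A": at}, rng
    )
    second = _half_composition(
        h2, {"C": (gc - skew_amplitude) / 2, "G": (gc + skew_amplitude) / 2, "A": at}, rng
    )
    seq = np.concatenate([first, second]).tobytes().decode("ascii")

    rows = []
    if n_genes:
        slot = length // n_genes
        for i in range(n_genes):
            max_len = max(min(slot - 2, 1200), 30)
            gene_len = int(rng.integers(min(300, max_len), max_len + 1))
            start = slot * i + int(rng.integers(0, slot - gene_len + 1)) + 1
            cazy = (
                str(rng.choice(_CAZY_FAMILIES)) if rng.random() < cazy_frac else ""
            )
            rows.append(
                {
                    "gene_id": f"gene_{i + 1:05d}",
                    "start": start,
                    "end": start + gene_len - 1,
                    "annotated": int(rng.random() >= unannotated_frac),
                    "cazy_family": cazy,
                }
            )
    genes = pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "annotated", "cazy_family"]
    )
    return seq, genes


def simulate_gradient(
    taxa: list[SimTaxon],
    config: SimGradientConfig,
    role: str = "treatment",
    sample_id: str = "sim",
    model: IsotopeDensityModel = DEFAULT_MODEL,
    coverage_scale: float | None = None,
) -> SimulatedGradient:
    """Forward-model a community's CsCl gradient and per-taxon coverages.

    Each taxon bands at ``density_from_enrichment(gc, afe)``; its mass is
    apportioned to equal-width density fractions by integrating a Gaussian
    of sd ``band_sd`` over each fraction's interval.  Fraction DNA
    concentration sums the taxon masses; per-taxon coverage is mass over
    genome length, scaled so the busiest fraction reaches ~15× by default
    (a realism anchor).  Multiplicative log-normal noise of sd ``noise_sd``
    perturbs per-taxon fraction masses when requested.  Mass falling outside
    the gradient's density span is truncated and reported per taxon.
    """
    total_ab = sum(t.abundance for t in taxa)
    if abs(total_ab - 1.0) > 1e-9:
        raise DomainError(f"taxon abundances must sum to 1, got {total_ab}")
    rng = np.random.default_rng(config.seed)
    edges = np.linspace(config.density_min, config.density_max, config.n_fractions + 1)
    mids = (edges[:-1] + edges[1:]) / 2

    masses = {}
    truncated = {}
    for t in taxa:
        centre = density_from_enrichment(t.gc, t.afe, model)
        cdf = norm.cdf(edges, loc=centre, scale=config.band_sd)
        frac_mass = np.diff(cdf) * config.total_dna_mass * t.abundance
        tail = 1.0 - (cdf[-1] - cdf[0])
        truncated[t.taxon_id] = float(tail * config.total_dna_mass * t.abundance)
        if config.noise_sd > 0:
            frac_mass = frac_mass * rng.lognormal(0.0, config.noise_sd, len(frac_mass))
        masses[t.taxon_id] = frac_mass

    dna_conc = np.sum(list(masses.values()), axis=0)
    # fraction 1 is the densest (bottom-pierced collection)
    order = np.argsort(mids)[::-1]
    profile = GradientProfile(
        sample_id=sample_id,
        role=role,
        fractions=pd.DataFrame(
            {
                "fraction_id": np.arange(1, config.n_fractions + 1),
                "density": mids[order],
                "dna_conc": dna_conc[order],
                "seq_depth": config.depth_per_fraction,
            }
        ),
    )
    per_length = {
        t.taxon_id: masses[t.taxon_id] / t.genome_length for t in taxa
    }
    if coverage_scale is None:
        peak = max(arr.max() for arr in per_length.values())
        coverage_scale = 15.0 / peak if peak > 0 else 1.0
    coverages = {
        tid: CoverageByFraction(
            genome_id=tid,
            fractions=pd.DataFrame(
                {
                    "fraction_id": np.arange(1, config.n_fractions + 1),
                    "coverage": per_length[tid][order] * coverage_scale,
                    "seq_depth": config.depth_per_fraction,
                }
            ),
        )
        for tid in per_length
    }
    return SimulatedGradient(
        profile=profile, coverages=coverages, truncated_mass=truncated
    )


def _write_coverage_tsv(coverages: dict[str, CoverageByFraction], path: Path) -> None:
    frames = []
    for tid, cov in coverages.items():
        df = cov.fractions.copy()
        df.insert(0, "genome_id", tid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def make_study_fixture(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a complete synthetic study to ``out_dir`` and return its truth.

    Mirrors the original experimental design: a labeled treatment community
    (three high-GC unlabeled background taxa around 66% GC plus one focal
    low-GC taxon at 49.95% GC, 75% 13C atom-fraction excess) against an
    all-unlabeled control of the same background.  Writes the focal genome
    FASTA and gene table, treatment/control fraction TSVs, a coverage TSV,
    and ``truth.json`` recording the generating parameters (true AFE, true
    origin/terminus, gene counts) for parameter-recovery tests.
    """
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    focal_len = 300_000
    focal_gc = 0.4995
    focal_afe = 0.75
    seq, genes = simulate_genome(
        length=focal_len,
        gc=focal_gc,
        skew_amplitude=0.12,
        n_genes=300,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    fasta_path = out / "genomes" / "focal.fasta"
    with open(fasta_path, "w") as fh:
        fh.write(">focal synthetic labeled genome\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    genes_path = out / "genomes" / "focal_genes.tsv"
    genes.to_csv(genes_path, sep="\t", index=False)

    background = [
        SimTaxon("bg_60", 0.30, 0.60, 0.0),
        SimTaxon("bg_66", 0.35, 0.66, 0.0),
        SimTaxon("bg_72", 0.20, 0.72, 0.0),
    ]
    focal = SimTaxon("focal", 0.15, focal_gc, focal_afe, genome_length=focal_len)
    cfg_kwargs = dict(noise_sd=0.1)
    treat_cfg = SimGradientConfig(seed=int(rng.integers(0, 2**31 - 1)), **cfg_kwargs)
    ctrl_cfg = SimGradientConfig(seed=int(rng.integers(0, 2**31 - 1)), **cfg_kwargs)
    treatment = simulate_gradient(
        background + [focal], treat_cfg, role="treatment", sample_id="rhizosphere"
    )
    ctrl_scale = 1.0 / sum(t.abundance for t in background)
    control_taxa = [
        SimTaxon(t.taxon_id, t.abundance * ctrl_scale, t.gc, 0.0, t.genome_length)
        for t in background
    ]
    control = simulate_gradient(
        control_taxa, ctrl_cfg, role="control", sample_id="bulk"
    )

    treat_path = out / "treatment.tsv"
    ctrl_path = out / "control.tsv"
    cov_path = out / "coverage.tsv"
    treatment.profile.fractions.to_csv(treat_path, sep="\t", index=False)
    control.profile.fractions.to_csv(ctrl_path, sep="\t", index=False)
    _write_coverage_tsv(treatment.coverages, cov_path)

    truth = {
        "seed": seed,
        "focal": {
            "taxon_id": "focal",
            "gc": focal_gc,
            "afe": focal_afe,
            "genome_length": focal_len,
            "band_density": density_from_enrichment(focal_gc, focal_afe),
            "ori_pos": focal_len // 2 + 1,
            "ter_pos": 1,
            "n_genes": int(len(genes)),
            "unannotated_genes": int((genes["annotated"] == 0).sum()),
            "cazy_genes": int((genes["cazy_family"].str.len() > 0).sum()),
        },
        "background": [
            {"taxon_id": t.taxon_id, "gc": t.gc, "afe": t.afe, "abundance": t.abundance}
            for t in background
        ],
        "files": {
            "focal_fasta": str(fasta_path),
            "focal_genes": str(genes_path),
            "treatment": str(treat_path),
            "control": str(ctrl_path),
            "coverage": str(cov_path),
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
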