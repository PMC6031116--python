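"""Fraction tables, light/middle/heavy binning, coverage normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sipscope import (
    PAPER_BIN_SCHEME,
    BinScheme,
    CoverageByFraction,
    GradientProfile,
    SimGradientConfig,
    SimTaxon,
    assign_bins,
    auto_bin,
    density_from_enrichment,
    genome_density_centroid,
    load_profile,
    normalize_coverage,
    simulate_gradient,
)
from sipscope.errors import (
    DomainError,
    EstimationError,
    FormatError,
    IncomparabilityError,
)


def make_profile(densities, masses, role="treatment", sample_id="p", depths=None):
    df = pd.DataFrame(
        {
            "fraction_id": np.arange(1, len(densities) + 1),
            "density": densities,
            "dna_conc": masses,
        }
    )
    if depths is not None:
        df["seq_depth"] = depths
    return GradientProfile(sample_id=sample_id, role=role, fractions=df)


class TestLoadProfile:
    def test_reads_synthetic_table(self, tmp_path):
        cfg = SimGradientConfig(seed=1)
        sim = simulate_gradient([SimTaxon("t", 1.0, 0.5, 0.3)], cfg)
        path = tmp_path / "t.tsv"
        sim.profile.fractions.to_csv(path, sep="\t", index=False)
        profile = load_profile(path, role="treatment")
        assert len(profile.fractions) == 32
        assert (np.diff(profile.densities) < 0).all()

    def test_refractive_index_column_converted(self, tmp_path):
        ris = [1.4010, 1.4005, 1.4000]
        pd.DataFrame(
            {"fraction_id": [1, 2, 3], "refractive_index": ris, "dna_conc": [1, 2, 1]}
        ).to_csv(tmp_path / "ri.tsv", sep="\t", index=False)
        profile = load_profile(tmp_path / "ri.tsv")
        expected = sorted((10.8601 * ri - 13.4974 for ri in ris), reverse=True)
        assert profile.densities == pytest.approx(expected, abs=1e-9)

    def test_negative_mass_names_row(self, tmp_path):
        pd.DataFrame(
            {"fraction_id": [1, 2, 3], "density": [1.75, 1.74, 1.73],
             "dna_conc": [1.0, -0.5, 1.0]}
        ).to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="row 3"):
            load_profile(tmp_path / "bad.tsv")

    def test_non_monotone_densities_rejected(self, tmp_path):
        pd.DataFrame(
            {"fraction_id": [1, 2, 3, 4], "density": [1.75, 1.70, 1.74, 1.69],
             "dna_conc": [1, 1, 1, 1]}
        ).to_csv(tmp_path / "zig.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="monotone"):
            load_profile(tmp_path / "zig.tsv")

    def test_missing_columns_rejected(self, tmp_path):
        pd.DataFrame({"fraction_id": [1, 2, 3], "dna_conc": [1, 1, 1]}).to_csv(
            tmp_path / "nocol.tsv", sep="\t", index=False
        )
        with pytest.raises(FormatError, match="density or refractive_index"):
            load_profile(tmp_path / "nocol.tsv")


class TestAssignBins:
    @pytest.mark.parametrize(
        "density,expected",
        [
            (1.740, "middle"),
            (1.692, "light"),
            (1.765, "heavy"),
            (1.737, "light"),
            (1.747, "heavy"),
            (1.7375, "light"),   # mid-gap tie resolves to the lighter bin
            (1.7378, "middle"),  # nearer to the middle cutoff
            (1.680, "unbinned"),
            (1.780, "unbinned"),
        ],
    )
    def test_paper_cutoffs(self, density, expected):
        profile = make_profile([1.760, density, 1.600], [1, 1, 1])
        binned = assign_bins(profile, PAPER_BIN_SCHEME)
        assignments = {
            d: binned.assignments[fid]
            for fid, d in zip(
                profile.fractions["fraction_id"], profile.fractions["density"]
            )
        }
        assert assignments[density] == expected

    def test_partition_and_mass_conservation(self):
        rng = np.random.default_rng(0)
        densities = np.sort(rng.uniform(1.68, 1.78, 20))[::-1]
        masses = rng.uniform(0, 5, 20)
        profile = make_profile(densities, masses)
        binned = assign_bins(profile, PAPER_BIN_SCHEME)
        assert set(binned.assignments) == set(profile.fractions["fraction_id"])
        assert sum(binned.pooled_mass.values()) == pytest.approx(masses.sum())

    def test_scheme_validation(self):
        with pytest.raises(DomainError):
            BinScheme(light=(1.70, 1.74), middle=(1.72, 1.75), heavy=None)
        with pytest.raises(DomainError):
            BinScheme(light=(1.70, 1.71), middle=(1.75, 1.76), heavy=None)


class TestAutoBin:
    def test_identical_profiles_yield_no_enriched_bins(self):
        cfg = SimGradientConfig(seed=5)
        sim = simulate_gradient([SimTaxon("t", 1.0, 0.66, 0.0)], cfg)
        ctrl = GradientProfile(
            sample_id="c", role="control", fractions=sim.profile.fractions.copy()
        )
        scheme = auto_bin(sim.profile, ctrl)
        assert scheme.middle is None and scheme.heavy is None
        assert {"empty_heavy", "empty_middle"} <= set(scheme.flags)
        binned = assign_bins(sim.profile, scheme)
        assert set(binned.assignments.values()) == {"light"}

    def test_threshold_saturation_leaves_everything_light(self):
        taxa = [SimTaxon("bg", 0.8, 0.51, 0.0), SimTaxon("lab", 0.2, 0.51, 1.0)]
        cfg = SimGradientConfig(seed=5)
        sim = simulate_gradient(taxa, cfg)
        ctrl = simulate_gradient([SimTaxon("bg", 1.0, 0.51, 0.0)], cfg, role="control")
        scheme = auto_bin(sim.profile, ctrl.profile, epsilon=1.0, delta=0.999)
        assert scheme.heavy is None and scheme.middle is None
        binned = assign_bins(sim.profile, scheme)
        assert set(binned.assignments.values()) == {"light"}

    def test_disjoint_ranges_incomparable(self):
        t = make_profile([1.76, 1.75, 1.74], [1, 1, 1])
        c = make_profile([1.71, 1.70, 1.69], [1, 1, 1], role="control")
        with pytest.raises(IncomparabilityError):
            auto_bin(t, c)

    def test_bounds_match_brute_force_rule(self):
        """auto_bin on a 1.71-mode control vs a treatment with a labeled mode
        near 1.745 reproduces a direct evaluation of the binning rule on the
        simulated Gaussian-mixture masses (seed 42, simulator defaults)."""
        gc = 0.5102  # natural-abundance band at ~1.710 g/mL
        afe = (1.745 - density_from_enrichment(gc, 0.0)) / 0.036
        taxa = [SimTaxon("bg", 0.8, gc, 0.0), SimTaxon("lab", 0.2, gc, afe)]
        cfg = SimGradientConfig(seed=42)
        sim = simulate_gradient(taxa, cfg)
        ctrl = simulate_gradient([SimTaxon("bg", 1.0, gc, 0.0)], cfg, role="control")
        eps, delta = 0.05, 0.02
        scheme = auto_bin(sim.profile, ctrl.profile, epsilon=eps, delta=delta)

        # brute force: rebuild the per-fraction mixture masses from the
        # generating parameters and apply the verbal rule on the grid
        edges = np.linspace(cfg.density_min, cfg.density_max, cfg.n_fractions + 1)
        mids = (edges[:-1] + edges[1:]) / 2

        def band(centre, ab):
            cdf = norm.cdf(edges, loc=centre, scale=cfg.band_sd)
            return np.diff(cdf) * ab

        bg_centre = density_from_enrichment(gc, 0.0)
        lab_centre = density_from_enrichment(gc, afe)
        t_mass = band(bg_centre, 0.8) + band(lab_centre, 0.2)
        c_mass = band(bg_centre, 1.0)
        t_rel, c_rel = t_mass / t_mass.sum(), c_mass / c_mass.sum()
        above = mids > mids[np.argmax(c_rel)]
        heavy_lo = mids[above & (c_rel < eps) & (t_rel >= eps)].min()
        middle_lo = min(mids[above & ((t_rel - c_rel) > delta)].min(), heavy_lo)

        assert scheme.heavy[0] == pytest.approx(heavy_lo, abs=1e-12)
        assert scheme.middle[0] == pytest.approx(middle_lo, abs=1e-12)
        # bounds sit within one fraction width of the labeled band's support
        width = edges[1] - edges[0]
        assert lab_centre - 3 * cfg.band_sd - width <= middle_lo <= lab_centre + width

    @pytest.mark.parametrize("delta2", [0.05, 0.1, 0.3])
    def test_raising_delta_never_widens_middle(self, delta2):
        taxa = [SimTaxon("bg", 0.7, 0.51, 0.0), SimTaxon("lab", 0.3, 0.51, 0.9)]
        cfg = SimGradientConfig(seed=7)
        sim = simulate_gradient(taxa, cfg)
        ctrl = simulate_gradient([SimTaxon("bg", 1.0, 0.51, 0.0)], cfg, role="control")
        base = auto_bin(sim.profile, ctrl.profile, delta=0.02)
        raised = auto_bin(sim.profile, ctrl.profile, delta=delta2)

        def width(scheme):
            return 0.0 if scheme.middle is None else scheme.middle[1] - scheme.middle[0]

        assert width(raised) <= width(base) + 1e-12


class TestCoverage:
    def test_normalization_identity_and_scaling(self):
        cov = CoverageByFraction(
            "g",
            pd.DataFrame(
                {"fraction_id": [1, 2, 3], "coverage": [10.0, 0.0, 4.0],
                 "seq_depth": [2e9, 1e9, 1e9]}
            ),
        )
        out = normalize_coverage(cov, reference_depth=1e9)
        assert out.fractions["normalized"].tolist() == [5.0, 0.0, 4.0]
        equal = CoverageByFraction(
            "g",
            pd.DataFrame(
                {"fraction_id": [1, 2], "coverage": [3.0, 7.0], "seq_depth": [1e9, 1e9]}
            ),
        )
        out2 = normalize_coverage(equal)
        assert out2.fractions["normalized"].tolist() == [3.0, 7.0]

    def test_zero_depth_names_fraction(self):
        cov = CoverageByFraction(
            "g",
            pd.DataFrame(
                {"fraction_id": [1, 7], "coverage": [1.0, 1.0], "seq_depth": [1e9, 0.0]}
            ),
        )
        with pytest.raises(DomainError, match="fraction 7"):
            normalize_coverage(cov)


class TestCentroid:
    def test_single_fraction_and_symmetry(self):
        profile = make_profile([1.72, 1.71, 1.70], [1, 1, 1])
        single = CoverageByFraction(
            "g", pd.DataFrame({"fraction_id": [1, 2, 3], "coverage": [0, 5.0, 0]})
        )
        assert genome_density_centroid(single, profile) == pytest.approx(1.71)
        sym = CoverageByFraction(
            "g", pd.DataFrame({"fraction_id": [1, 2, 3], "coverage": [2.0, 0, 2.0]})
        )
        assert genome_density_centroid(sym, profile) == pytest.approx(1.71)

    def test_all_zero_coverage_rejected(self):
        profile = make_profile([1.72, 1.71, 1.70], [1, 1, 1])
        zero = CoverageByFraction(
            "g", pd.DataFrame({"fraction_id": [1, 2, 3], "coverage": [0.0, 0, 0]})
        )
        with pytest.raises(EstimationError):
            genome_density_centroid(zero, profile)

    @pytest.mark.parametrize("afe", [0.0, 0.5])
    def test_simulated_taxon_centroid_matches_band_centre(self, afe):
        errors = []
        for seed in range(10):
            cfg = SimGradientConfig(seed=seed, noise_sd=0.1)
            sim = simulate_gradient([SimTaxon("t", 1.0, 0.5, afe)], cfg)
            centroid = genome_density_centroid(sim.coverages["t"], sim.profile)
            errors.append(abs(centroid - density_from_enrichment(0.5, afe)))
        assert max(errors) < 0.002
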