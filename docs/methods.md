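# Methods

## Buoyant-density model

DNA at isopycnic equilibrium in CsCl bands at a density set by composition
and isotope content. `sipscope` uses the standard linear model

ρ(GC, AFE) = ρ₀ + s·GC + Δ·AFE

with defaults ρ₀ = 1.660 g/mL and s = 0.098 g/mL per unit GC fraction (the
Schildkraut relation for natural-abundance DNA in CsCl) and Δ = 0.036 g/mL
for the density gain at 100 atom% ¹³C (the accepted full-labeling shift for
carbon). AFE (atom-fraction excess) interpolates Δ linearly. Inversion gives
AFE = (ρ_obs − ρ₀ − s·GC)/Δ, clamped to [0, 1]: densities at or below the
unlabeled position carry no enrichment signal and report zero rather than a
negative value. When the observation is a density *interval* (e.g. the span
of the pooled bin where a genome was mainly detected), the lower bound gives
a conservative lower AFE bound — this is the "at least X% enriched" style of
statement — the upper bound an upper AFE bound, and the midpoint the point
estimate.

The shift is modelled as GC-independent. A GC-dependent variant (the carbon
fraction of DNA varies slightly with composition) would change AFE by a few
percent at most and is out of scope. Fraction densities measured by
refractometry are converted through the linear CsCl calibration
ρ = 10.8601·RI − 13.4974; instrument calibrations differ, so both
coefficients (like all model constants) are overridable via
`IsotopeDensityModel` and the run config. Densities are g/mL at the
calibration temperature; no temperature correction is applied.

Plausibility guards reject densities outside [1.60, 1.85] g/mL and
refractive indices outside [1.30, 1.50].

## Gradient profiles and binning

Fraction tables are canonicalized to descending density (bottom-pierced
tubes collect the densest fraction first) and validated: ≥ 3 fractions,
positive distinct densities, non-negative DNA mass, and densities monotone
in collection order up to a 5×10⁻⁴ g/mL tolerance for measurement jitter.

**Explicit binning.** Bin intervals are closed. Published cutoff schemes are
discrete fraction boundaries, not a continuous rule, so they may leave small
gaps (e.g. a light bin ending at 1.737 and a middle bin starting at 1.738);
a density falling inside a gap is assigned to the nearer interval, ties to
the lighter bin (the conservative choice: never over-call enrichment).
Densities outside the scheme's overall span stay unbinned. A scheme
validator enforces interval ordering and a configurable inter-bin gap
tolerance (default 0.002 g/mL).

**Automatic binning** (`auto_bin`) formalizes the visual
treatment-vs-control comparison. With per-fraction *relative* masses
(fraction of each sample's own total DNA), scanning densities above the
control's modal density:

- the heavy bin starts at the smallest density where the control holds
  < ε of its mass while the treatment still holds ≥ ε (DNA present only
  because of labeling); defaults ε = 0.05;
- the middle bin starts at the smallest density where treatment − control
  relative mass exceeds δ (the labeled shoulder's onset); default δ = 0.02;
  the middle's upper bound is the heavy bin's start when one exists, which
  also makes the middle interval shrink monotonically as δ rises;
- light is the remainder below.

Both scans are restricted to densities above the control mode: below it,
both tails are small and the rules would fire spuriously on the light side.
The control's relative-mass curve is linearly interpolated onto the
treatment's density grid. Identical profiles produce empty middle and heavy
bins (flagged, not an error); saturated thresholds leave everything light.
The thresholds are qualitative choices, so they are printed to the log and
serialized with the run config.

**Coverage normalization** rescales per-fraction coverage by
reference_depth / fraction_depth, with the reference defaulting to the
minimum library depth. Whether a given study normalized by reads, bases or
something else is generally unstated; the basis used here (total sequenced
bases per fraction library) is recorded in output metadata rather than
presented as ground truth. A genome's **density centroid** is its
coverage-weighted mean fraction density — an interpolating statistic that
is finer-grained than reading off the dominant bin and feeds the enrichment
inversion directly.

## GC skew and circularization

Per-window skew is (G − C)/(G + C) in windows of 1000 bp advancing by
10 bp by default; N and all non-G/C bases are excluded from both counts, and
a window with no G or C gets skew 0. The cumulative curve is the running sum
of window skews (overlapping windows are summed as-is; only the extrema
locations matter downstream and they are invariant to the resulting uniform
scaling). Window positions are stored as 1-based window starts; calls are
reported at window centres, wrapped around the end for circular sequences.

Under bidirectional replication with a G-rich leading strand, the cumulative
curve attains its minimum at the origin and maximum at the terminus; ties
break to the smallest coordinate, and an inversion flag serves organisms
with the opposite bias. A flat cumulative curve (no strand bias, e.g. a
shuffled or symmetric sequence) raises a degenerate-profile error rather
than returning an arbitrary call. A clean single-trough/single-peak curve on
a closed genome is evidence of correct assembly; `rotate_to_origin` then
re-linearizes the circle at the predicted origin.

`circularize` performs the curation step of trimming a terminal overlap:
overlap lengths are scanned from longest (half the sequence, capped at
20 kb) to shortest (`min_overlap`, ≥ 10 bp) and the first prefix/suffix pair
whose Hamming mismatch rate is ≤ `max_mismatch_rate` (default 2%) wins; one
copy is trimmed. Assembly-graph-based circularization is out of scope; a
sequence with no qualifying overlap returns a not-circular *value*, not an
error.

## Comparative genome statistics

From a FASTA and a gene table (TSV with 1-based inclusive intervals,
annotation flags and optional CAZy families, or GFF3 with equivalent
attributes): genome size, gene number, unannotated gene count, mean gene
length, total coding length as the *union* of gene intervals (overlaps
counted once), coding density = 100·coding/size, CAZy gene count and
distinct CAZy families. Consistency invariants (coding ≤ size, recomputed
coding density within 0.5 points of any supplied value) are enforced at
construction.

The two comparative statistics both denominate by the focal genome's value:
*difference from average* = 100·(focal − mean)/focal with the focal genome
included in the mean, and *percent larger than largest* =
100·(focal − max(others))/focal. This reading is the one that reproduces the
published difference-from-average row of the Saccharibacteria comparison
(32.4 / 33.2 / 39.1 / −3.7 / 30.6 / −3 / 39.9 / 31.7 percent) from its
printed columns; that seven-genome table ships in `sipscope/data/` as
comparison input. Percentages are printed at one decimal in TSV output (the
published precision); raw values stay in machine output.

## Synthetic data generator

`simulate_genome` draws bases with exact per-half composition: overall GC
hits the target up to rounding (well within the documented ±0.5%), and the
first half over-uses C, the second half G, by the skew amplitude — placing
the true origin at the halfway switch point and the terminus at the sequence
start/end by construction. Gene intervals are non-overlapping by slotting
one gene per equal-width segment. Defaults for annotation status (40%
unannotated) and CAZy decoration (3% of genes) echo the magnitudes seen in
small host-associated genomes.

`simulate_gradient` is a forward model of the fraction tables: each taxon
bands at ρ(GC, AFE) and its mass spreads over equal-width density fractions
as a Gaussian with σ = 0.003 g/mL integrated over each fraction interval —
the standard isopycnic band approximation, with σ chosen so a taxon's mass
occupies a handful of adjacent fractions as in real gradient profiles.
The default gradient has 32 fractions spanning 1.692–1.765 g/mL. Mass
falling outside the span is truncated and reported per taxon. Optional
multiplicative log-normal noise (default off; 0.1 in the recovery tests)
perturbs per-taxon fraction masses. Coverage is taxon mass over genome
length, scaled so the busiest fraction reaches ~15× — a realism anchor, not
an assertion. Everything is deterministic per seed.

`make_study_fixture` mirrors the original design: one treatment community
(three unlabeled background taxa at 60/66/72% GC plus a focal 49.95% GC
taxon at AFE 0.75, i.e. banding mid-gradient) against an all-unlabeled
control, written as FASTA + gene table + fraction and coverage TSVs + a
truth JSON.

What the generator does *not* emulate: read-level noise and assembly (it
produces clean genomes and exact coverages, not FASTQ), DNA recovery
efficiency across the gradient, compositional heterogeneity within a
genome, and multi-replicon organisms. Passing recovery tests therefore show
the estimators are correct under the band model and chosen noise — not that
they are robust to assembly artifacts or extraction biases in real data.

## Problem sizes and tolerances

Recovery tests use 60–100 kb genomes (origin/terminus error ≤ 2 kb over
20 seeds), 32-fraction gradients with log-normal noise σ = 0.1 (AFE
recovered within ±0.05 over 10 seeds for AFE ∈ {0, 0.25, 0.5, 1}), and a
10 kb scaffold with a 500 bp terminal repeat for circularization — sizes at
which the full suite runs in seconds while the statistics remain
well-resolved. Forward/inverse density–enrichment conversions are exact to
1e−9. The density centroid of a simulated band is accurate to ±0.002 g/mL
(≈ 0.06 AFE-equivalents of headroom against the ±0.05 criterion).

## Known limitations

- The linear density model ignores second-order composition effects
  (methylation, GC-dependent carbon fraction) and gradient non-equilibrium.
- `auto_bin` assumes a unimodal control; a multimodal unlabeled community
  can shift the detected mode and hence the scan region.
- Enrichment estimates attribute the whole density excess to ¹³C; co-varying
  GC mis-estimation propagates at ∂AFE/∂GC = −s/Δ ≈ −2.7 per unit GC, so a
  1-point GC error moves AFE by ≈ 0.027.
- One treatment/control pair per run; multi-window SIP and ¹⁵N/¹⁸O labeling
  are out of scope.
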