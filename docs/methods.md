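# Methods

This note records the models, estimators and numerical conventions behind
`mitomethyl`, the choices made where the underlying protocols leave the
mathematics open, and what the synthetic-data validation does and does not
demonstrate.

## MeDIP array differential-methylation calling

**Signal model.** Each two-channel probe measures an input intensity (Cy3)
and a methylated-fraction intensity (Cy5); the per-probe statistic is
M = log2(Cy5/Cy3), so positive M means enriched methylation. Both channels
are floored at 1.0 arbitrary unit before the log to keep
background-subtracted zeros finite. The orientation (methylated/input) is a
declared convention; swapping the channels negates every M and exchanges
hyper/hypo labels exactly, which the suite verifies.

**Tm-binned Z-scores.** Probe log-ratios are standardised against probes
with similar melting temperature, using 10 equal-count Tm-quantile bins by
default (quantile bins guarantee populated bins regardless of the Tm
distribution). Within a bin the Z-score is the probe's deviation from the
bin's reference Gaussian in reference-SD units. The reference is estimated
**robustly** by default: centre = median, scale = 1.4826·MAD (the
Gaussian-consistent MAD factor). The rationale is contamination: the
reference is meant to describe the *unaffected* probe population, and a
mean/sample-SD estimate is inflated by the very probes the filter is trying
to find. Quantitatively, if a fraction f of a bin carries a planted shift,
the inclusive sample-SD Z of those probes is bounded by ≈ sqrt((1−f)/f)
regardless of the shift size — under 5 already at f = 4% — so a |Z| > 5
cutoff can never fire no matter how large the true effect. The robust scale
is unaffected by contamination below 50% and leaves true signal ~shift/σ
null-SDs out. The classical estimator (mean, sample SD, with SD = 0 ⇒ Z = 0)
is retained as `method="classical"` and carries the textbook invariants
(bin mean 0, sample SD 1; one bin ≡ global standardisation). Degenerate
robust bins (MAD = 0, e.g. noise-free data) assign Z = 0 to probes at the
median and ±inf otherwise — the continuous limit, which makes noise-free
recovery exact. Bins with fewer than two valid probes leave Z undefined and
flagged.

**Filter cascade.** A probe is called between two replicate groups when
(1) the difference of group-mean log-ratios exceeds the fourfold cutoff
(|ΔM̄| > 2) and (2) the probe's |Z| exceeds 5 in the *driving* group — the
group whose mean |M| is larger — taking the median Z across that group's
replicate arrays (median rather than mean so one aberrant array cannot veto
or force a call). The two filters are a conjunction; both cutoffs are
parameters (`fold_cut`, `z_cut`) and raising either can only shrink the
called set. No multiple-testing correction is applied: the procedure is
threshold-based, not p-value-based, by design.

**Gene aggregation and exclusivity.** A probe annotates a gene when its
[start, end) interval overlaps the gene's CpG-island interval (0-based
half-open coordinates throughout). Gene status is the majority direction of
its called probes; ties are reported unchanged with a conflict flag. For the
four-line design, per-line calls are one-vs-rest (a line's replicates vs the
pooled replicates of the other three), and a gene is *exclusive* to a line
iff called there and unchanged everywhere else. Exclusive sets are therefore
pairwise disjoint by construction, and exclusive ∪ shared ∪ unchanged
partitions the gene universe.

## qPCR quantities

Standard curves are ordinary least squares on (log10 copies, Ct), requiring
≥3 dilution points and a negative slope; amplification efficiency is
10^(−1/slope) − 1 and values outside (0, 1.1] are flagged. Copies per cell
divide absolute mtDNA copies by half the β-actin copies (β-actin is one
locus on a diploid genome, i.e. 2 copies/cell); the diploid factor is a
declared, configurable convention since the upstream calibration protocol
does not print its formula. Relative expression is 2^(−ΔΔCt) with replicate
Cts averaged arithmetically first and non-detects excluded from means.
Enrichment is reported as percent of input — the field-standard ChIP/MeDIP
readout — with the input Ct adjusted for the saved input fraction (default
0.1, configurable): %input = 100·2^((Ct_input − log2(1/f)) − Ct_IP). The
Fluidigm matrix is ΔCt = Ct_gene − Ct_18S per sample with non-detects
imputed at a configurable Ct ceiling (default 40); rows and columns are
clustered with average linkage on euclidean distances (the linkage is our
choice; only the metric is dictated by the upstream analysis), and
differential expression between sample groups is Welch's t on ΔCt — a plain
two-group statistic, deliberately not a moderated (limma-style) fit.

## Replicative efficiency

The composite statistic is efficiency = copies_per_cell ÷ (5mC/5hmC)
= copies·5hmC/5mC, with both enrichments measured at the same amplicon
(*PolgA* exon 2). "Expressed as a function of the ratio" is formalised as
division — high 5mC (replication restraint) lowers efficiency, high 5hmC
(active demethylation) raises it — and the functional form is isolated in
one pure operation so an alternative (e.g. the reciprocal) can be swapped
without touching anything else. The statistic is invariant to a common
rescaling of the two enrichments, strictly increasing in copies and 5hmC
and strictly decreasing in 5mC; 5mC = 0 leaves it undefined and flagged
rather than infinite.

## Enzyme assays

α-KG is read off the standard line as (corrected absorbance − intercept) /
slope; the assay-kit formula as printed is typographically ambiguous and is
resolved as this standard curve inversion. Whether "corrected" subtracts a
blank well or a time-zero read is left to the caller (the function takes the
already-corrected absorbance). MDH2 specific activity applies
U = (r_A·V_cuvette)/(l·ξ·V_sample·ρ) exactly, with ξ = 37/mM/cm for the
reagent dye and ρ the lysate protein concentration in mg/mL, so U is
µmol/min/mg. The kinetic rate r_A is the OLS slope (AU/min) over an
auto-selected initial window: the longest prefix of the trace whose fit
R² ≥ 0.99, followed by trimming of trailing points whose residual exceeds
3× the window RMSE. The trim matters because R² alone is insensitive to a
few plateau points when the linear span is large (total variance dominates
the residual term), which would otherwise bias the slope several percent
low on linear-then-plateau traces; residual-based trimming stops the window
at the kink. A residual-free fit counts as R² = 1, so flat noise-free
traces return rate 0 over the full window, and the rate is invariant to a
constant absorbance offset.

## mtDNA phylogenetics

**Distances.** Pairwise distances are maximum-likelihood branch lengths
under one GTR(+Γ) parameterisation shared across all pairs ("composite"
convention: parameters estimated once from the full alignment, only the
pairwise time optimised). The likelihood uses the spectral decomposition of
the reversible rate matrix and mixes 5 discrete Gamma categories
(equal-probability category means, shape 0.3734 by default; `gamma_shape =
None` gives rate homogeneity). The distance solves the score equation
dℓ/dt = 0 with Brent root-finding at xtol = 1e-14, which reaches the JC
closed form to <1e-9 in the uniform limit — a much tighter optimum than
likelihood-value bracketing, whose curvature-limited precision is only
~sqrt(machine-eps). Sites with a gap or ambiguity in either sequence are
excluded pairwise; pairs beyond 50 substitutions/site are reported
saturated (+inf with a warning). `estimate_gtr_params` provides a
moment-style parameterisation (observed frequencies; pooled mismatch counts
scaled by 1/(π_iπ_j)) — a documented heuristic, not a full ML fit.

**Tree building.** Neighbor-joining is implemented directly (Saitou–Nei
update, Q-ties broken by the lexicographically smallest cluster-label pair,
negative branch estimates clamped to 0) so outputs are deterministic;
dendropy's NJ serves only as an independent cross-check in the tests, and
additive matrices are verified against an exhaustive least-squares topology
search for ≤5 taxa. Bootstrap support resamples alignment columns with
replacement (site-pattern counts, so 1000 replicates on 16 kb take seconds),
rebuilds the NJ tree per replicate and reports the percentage of replicates
containing each original split; model parameters stay fixed at full-data
values.

**Dating.** Divergence times use a relative-rate normalisation in the
spirit of RelTime rather than its exact (unpublished-in-detail) update
equations: the tree is rooted on the outgroup; the calibrated split's
relative height is half the mean outgroup-to-ingroup-tip path; every other
ingroup node's height is the recursive mean over children of (child height
+ child branch). On ultrametric input these heights reproduce the input
node depths exactly, and all ages are invariant to a global rescaling of
branch lengths. Relative heights are unitless, so the calibrated node is
always anchored at the calibration midpoint (10 Mya for the 8–12 Mya rodent
split) and the interval endpoints propagate to per-node age bounds; there
is no meaningful "unconstrained estimate inside the interval" for a
relative-rate method. Agreement with the exact RelTime algorithm is
expected to be approximate, not numeric.

## Synthetic data: what it emulates, and what it does not

The array generator plants line-specific log2 shifts (default 20 genes per
line, half hyper/half hypo, |shift| = 3 — comfortably above the fourfold
cutoff, as expected of the effects the cascade is designed to keep) on a
baseline of 0 with i.i.d. Gaussian probe noise (default SD 0.3 log2 units)
and Tm uniform on 70–90 °C; Cy3 is held at a constant base intensity with
Cy5 derived from the ratio. Replicate count defaults to 3 (the upstream
protocol does not state one, so it is a parameter). It does **not** emulate
intensity-dependent variance, spatial artefacts, dye bias, probe
cross-hybridisation, or correlated noise between neighbouring probes — so
passing recovery tests show the cascade's correctness and its behaviour
under idealised noise, not robustness to real Agilent artefacts. The qPCR
generator is the curve model plus i.i.d. Gaussian Ct noise (no pipetting
outliers or inhibition curvature). The sequence simulator evolves i.i.d.
sites under stationary GTR+Γ along a strict clock (no among-lineage rate
variation, indels, or alignment error), which is exactly the regime where
the dating approximation should work; its 10%-recovery check therefore
validates the estimator chain, not robustness to clock violations. The
kinetic generator is globally linear; plateau behaviour is constructed in
tests where needed.

Problem sizes used throughout validation (500 genes × 2 probes × 4 lines ×
3 replicates; 16.3-kb five-taxon alignments — the mouse mitochondrial
genome length; 1000 bootstrap replicates; 1000-trial oracles) were chosen
to match the study-scale quantities the statistics are meant for while
keeping the full suite fast on a single CPU.

## Known limitations

- The robust-Z default departs from the classical Agilent-style description;
  both estimators are exposed, but published probe lists produced with the
  vendor pipeline would need `method="classical"` for like-for-like
  comparison (and will then inherit the contamination ceiling above).
- One-vs-rest is one of several defensible comparison designs for per-line
  calls; pairwise designs can be composed from `call_differential_probes`.
- `estimate_gtr_params` is a heuristic; for publication-grade model fits use
  an external ML fit and pass the parameters into `GtrModel`.
- The dating method is a documented approximation of relative-rate dating;
  it has no per-lineage rate test and no soft-bound calibration machinery.
- Fluidigm differential expression is a plain Welch test, labelled as such;
  moderated statistics are intentionally out of scope.
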