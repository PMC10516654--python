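# Methods

This note documents the models, defaults and numerical choices behind
each stage, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the design was genuinely open.

## Synthetic data

The generators exist so that every analysis stage can be exercised with
known ground truth; their defaults are the study conditions of the
recovery experiments.

* **Genome.** I.i.d. bases with a target GC fraction (default 0.44,
  length 130 kb — the scale of a large prophage region).  Operator
  sites are planted by overwriting the sequence with a consensus,
  each copy mutated independently per position at a configurable rate.
* **Operator consensus.** The fixed default 15-mer `ACAGTAAGCCCATCA`
  was chosen by a seeded search to have no strong self-overlap under
  shift or reverse complement.  This is a well-posedness condition:
  for a self-overlapping (e.g. palindromic-with-shift) consensus,
  PWMs wider than the planted width capture genuinely informative
  shifted, strand-mixed alignments, and the "true" width is
  ambiguous.  The real operator of the motivating system is a
  repeated element whose letters are not reproduced here; only the
  width (15 bp) matters to the recovery experiments.
* **Coverage.** Expected coverage is
  `depth · (1 + Σ_sites e · exp(−(x−c)²/2s²))` with enrichment
  `e = 20`, shape `s = 75 bp` and `depth = 50×` by default — smooth
  single-summit peaks, which is what the matched-filter caller
  assumes.  Counts are Poisson by default (`noise="none"` gives the
  exact expectation; a negative-binomial option adds overdispersion,
  default off).  Replicate r uses sub-seed `seed + r − 1`.
  Not emulated: read-level artifacts (mappability, GC bias, duplicate
  towers, fragment-length effects), so passing tests show correctness
  of the algorithm on its assumed signal shape, not robustness to
  mapping pathology.
* **HDX.** Per-residue exchange follows
  `D(t) = f_D2O (1 − e^{−kt})` with `f_D2O = 0.9` (ten-fold dilution
  into D2O buffer) and log-uniform rates (1e-4–1 s⁻¹) unless given.
  Two overlapping peptide tilings (offset against each other) stand in
  for the pepsin and fungal-protease digests; peptide uptake is the
  sum over its residues plus Gaussian noise (default 0.05 Da), with
  quality columns drawn so the downstream filters are exercisable.
  Observation times default to 10/30/100/1000/10000 s.  Not modelled:
  back-exchange, proline/N-terminal non-exchangers, isotope envelopes,
  EX1 behavior — the reduction pipeline is deliberately literal (see
  below), so the generator matches that convention.
* **ITC / nanoDSF.** Forward models below, plus Gaussian noise.  The
  default injection schedule is 13 injections (0.4 μl priming, then
  12 × 3 μl) into a 200 μl cell holding 20 μM DNA; syringe protein
  250 μM (chosen so the titration saturates within the schedule —
  the motivating experiments determined it empirically and do not
  report it).  Melt curves span 20–95 °C at 0.5 °C with baselines
  0.80/1.00 and transition slope 2 °C.

## Peak calling

The caller treats enrichment as bump-shaped signal on locally constant
background and applies a matched filter:

* **Kernel.** Ricker shape `(1 − x²/σ²) e^{−x²/2σ²}`, i.e. the
  *negative* second derivative of a Gaussian, so bumps score positive.
  Truncated at `ceil(4σ)` and then mean-subtracted over the truncated
  support, making the zero response to constant coverage exact
  (≤1e-9) rather than approximate.
* **Width adaptation.** `σ = ŵ/2`: the distance between the kernel's
  positive-lobe zero crossings (2σ) then equals the expected peak
  width `ŵ` — the matched-filter reading of "expanded to the expected
  width".  `ŵ` is the median half-height width of plateau-aware local
  maxima exceeding `threshold_mult`(=3)× the mean coverage; on
  noise-free rectangles this recovers the rectangle width exactly.
  If no candidate exceeds the threshold a `NoCandidatePeakError`
  asks for an explicit `fixed_width`.
* **Detection.** Summit = position where the discrete first
  derivative of the response turns from positive to negative; for a
  flat plateau the leftmost position is reported (deterministic
  tie-break).  The peak interval spans the nearest non-positive
  response values flanking the summit.  Retention requires raw summit
  coverage > 3× mean *and* positive convolution score; the upstream
  method does not state its final filter, so the only stated
  threshold (3× mean) is reused.
* **Edges.** Reflect padding by default; wrap-around convolution is a
  flag for genuinely circular chromosomes.  Reflection avoids
  spurious boundary peaks on linear excerpts.
* **Normalization.** Background coefficient
  `C = total coverage − Σ raw peak intensity` per sample;
  `normalized = raw/C × 1e6` (parts-per-million of background), which
  is invariant under global scaling of a track.  The source
  description of this step is grammatically ambiguous about the
  ratio's direction; the inverse ("literal") reading `C/raw` is kept
  behind `normalization="literal"`.
* **Replicate merging.** Single-linkage clustering of summits within
  `overlap_tol` (default `ŵ/2`); a merged peak reports the union
  interval, the mean summit (rounded), the mean normalized intensity
  and the number of distinct supporting replicates.

## Motif discovery

ZOOPS finite mixture: with probability γ a sequence carries one motif
occurrence at a uniform position *and strand*; otherwise it is pure
background (0-order, estimated from the input and symmetrized across
strands).  Both strands enter the E-step as mixture components — a
slightly stronger model than "use each sequence's best strand", chosen
because it keeps the update an exact EM step with a provably monotone
objective.  The optimized objective is the MAP log-likelihood
(including the Dirichlet pseudocount prior, 0.25 per base per column);
monotonicity is asserted on every iteration.  OOPS (γ fixed at 1, one
site per sequence) is available by flag.

* **Initialization.** A starting-point search: ~10× `restarts` short
  (2-iteration) pilot runs seeded from random sequence windows, then
  full EM from the `restarts`(=10) best pilots.  All randomness flows
  from `random_state`.
* **Width selection.** `score(w) = 2(LL_w − LL_bg) − 3w ln N` over
  `w ∈ [8, 20]` — a BIC-type penalty with one effective observation
  per sequence per column (ZOOPS allows at most one site per
  sequence).  Ties prefer the smaller width.
* **Edge trimming.** The per-sequence freedom to shift and
  strand-flip alignments lets weakly informative flanking columns
  creep into wider PWMs (measured: ~6 units of 2ΔLL per null column
  against the χ²₃ mean of 3).  After selection, edge columns whose
  information content is below `trim_ic_frac`(=0.5)× the median
  column IC are trimmed — the same pragmatic device MEME-family tools
  use.  Trimming never goes below `min_width`.
* **Scanning.** Log-odds (bits) of PWM vs background at every
  position on both strands; hits ≥ threshold are reported sorted by
  position, with palindromic double-hits kept.  Agrees exactly with a
  brute-force per-position scorer.

The selection score is an explicit stand-in for MEME's E-value
ranking; no E-value statistic is computed.

## HDX-MS reduction

Filtering applies the six quality criteria (defaults: ≥2/3
non-deuterated identifications, ≥10,000 counts, ≤30 residues, ≥2
products, ≤25 ppm, ≤0.5 min) as hard cuts, concatenates both protease
digests, and averages replicate uptake per peptide/timepoint (keeping
the replicate SD).  Filtering an already-merged table only re-applies
the cuts, so the operation is idempotent.

Residue assignment is deliberately literal: the chosen peptide's
uptake *is* the residue's value — no proline or N-terminal exclusion,
no back-exchange correction, no per-residue deconvolution.  Rule
order: fewest residues (shortest peptide) → smallest
(end − residue) distance → lexicographically smallest peptide id
(determinism).  Coordinates are 1-based inclusive.

Differential profiles report `Δ = uptake_B − uptake_A` where both
states cover a residue/timepoint; a residue is `increased`/`decreased`
when |Δ| exceeds the threshold at any timepoint (sign taken from the
largest excursion).  The default threshold is 2× the pooled replicate
SD — a convention of this package, as the visualization cutoff of the
motivating work is not stated numerically.

## ITC and nanoDSF

**Forward model.**  With cumulative injected volume `dV` into cell
volume `V0`, perfusion dilution gives cell macromolecule
`M = M0(1 − dV/2V0)/(1 + dV/2V0)` and titrant
`X = X0(dV/V0)/(1 + dV/2V0)` — expelled material accounted at the
average of pre/post concentrations.  The bound-site fraction solves
the single-site quadratic; cumulative heat `Q_i = nθ_i M_i V0 ΔH` and
injection heat `ΔQ_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i + Q_{i−1})/2`.
Verified against an independent root-finding equilibrium solver to
1e-8 relative.  Note that with a dilute syringe a few percent of the
binding heat is genuinely lost with expelled unbound macromolecule, so
the ideal total-heat limit `V0·ΔH·n·M0` is only approached when the
titration saturates within a small injected volume.

**Fitting.**  Least squares over `(n, log₁₀ Kd, ΔH)` with a fixed
five-point grid of Kd starting decades (deterministic multi-start),
bounds `Kd ∈ [1e-4, 1e4] μM`, `n ∈ [0.1, 10]`, and the priming
injection excluded by default (standard practice for the small first
injection).  Kd in log space keeps the search well-scaled across the
nM–mM range.  Standard errors are asymptotic (`s²(JᵀJ)⁻¹`, delta
method back to Kd).  When ΔH ≈ 0 the isotherm carries no information
about Kd; the fit returns a near-zero ΔH with a very wide Kd standard
error rather than failing.

**Melt curves.**  `r(T) = low + (high − low)/(1 + e^{(Tm−T)/s})`
fitted by Levenberg–Marquardt; initialization takes baselines from
the curve ends and Tm from the maximal-derivative temperature, making
the fit deterministic.  Tm is the inflection point.  Flat curves (no
transition) raise a `FitError`.

## Problem sizes and determinism

The recovery experiments use a 130-kb genome, ten planted sites, three
replicates at 50× depth (peak calling and motif width), and twenty
noisy simulations per condition for the ITC and nanoDSF Monte-Carlo
means — sizes at which the Monte-Carlo error is comfortably inside the
published uncertainties while the whole suite runs in well under a
minute.  Every stochastic component consumes an explicit seed;
identical seeds give bit-identical outputs, and replicate/stage
sub-seeds are derived deterministically from the master seed.

## Known limitations

* The caller assumes smooth single-summit peaks; closely spaced sites
  (< ~2σ apart) merge into one called peak, and no FDR control is
  attempted (none is defined for the upstream method).
* Width selection is only well-posed for motifs without strong
  self-overlap; for palindrome-with-shift repeats the reported width
  can legitimately exceed the planted core.
* The HDX reduction inherits the resolution limits of the literal
  shortest-peptide rule: residue values are block-constant within
  peptides and discontinuities at peptide boundaries are artifacts of
  the rule, not of the protein.
* The ITC fitter covers the one-set-of-sites model only; sequential
  or multi-site models and kinetic (injection-shape) information are
  out of scope.
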