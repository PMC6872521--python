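# Methods

## Antigen prioritization model

Each protein is reduced to four intrinsic characteristics that do not
depend on cell type or state: sequence length (residues), GRAVY mean
hydropathy (Kyte–Doolittle scale, dimensionless), isoelectric point (pH
units) and the Guruprasad dipeptide instability index
II = (10/L)·Σᵢ DIWV(xᵢ, xᵢ₊₁). All three non-trivial features are computed
with Biopython's ProtParam module, i.e. the standard ExPASy conventions;
the isoelectric point is found by bisection on the Henderson–Hasselbalch
net-charge function with ProtParam's (Bjellqvist) pKa set. Proteins
containing non-canonical residues (B, J, O, U, X, Z) are skipped with a
logged count by default — the hydropathy and DIWV tables are defined for
the canonical 20 letters only — and are never silently altered.

Because the raw features differ by orders of magnitude (length in the
hundreds, GRAVY of order 1), they are z-standardized against the control
set (the whole proteome) before entering the feature sum f = Σᵢ pᵢcᵢ.
Without this, the length term dominates and a factor box [−1, 1]⁴ is
meaningless. The fitted scaler is reused verbatim for candidate antigens.

The factors p are sampled by Metropolis–Hastings over the box [−1, 1]⁴
with a uniform prior and pseudo-likelihood exp(β·KS(F₁(p), F₀(p))), where
KS is the two-sample Kolmogorov–Smirnov distance between the represented
and control feature-sum samples. Defaults: β = 50, isotropic Gaussian
proposals with sd 0.1 reflected at the box boundary, burn-in 1,000,
1,000 retained samples, thinning 1, fixed seed. β controls how sharply the
posterior concentrates on separating directions; 50 puts exp(β·ΔKS) at
roughly e⁵ for a 0.1 gain in KS, which mixes well at the default proposal
scale (acceptance rates ~0.5–0.8 on realistic inputs). The KS statistic
used inside the chain is a sorted-ECDF implementation (scipy's ks_2samp
carries per-call overhead at ~10⁵ evaluations per run); the test suite
asserts exact agreement with scipy on random inputs.

**Sign convention.** The KS objective is invariant under p → −p, so the
raw posterior is symmetric under negation and its mean would be
meaningless. Every retained sample is therefore oriented so that the
median feature sum of the represented set does not exceed the control
median. This matches the convention that negative factors favor
representation, and makes the posterior mean and the planted-factor
recovery test well defined.

Candidate ranking evaluates, for every posterior sample, the density
difference F_diff = F₁ − F₀ (Gaussian KDE with Silverman bandwidth on a
512-point grid spanning the pooled range padded by 3 bandwidths) at the
candidate's feature sum, yielding a distribution of F_diff per candidate.
Candidates are ranked by the median; ties are broken lexicographically by
candidate id and flagged in a `tied` column. Feature sums falling outside
the KDE grid evaluate to 0 with a warning — the density there is
negligible by construction of the grid. Each KDE is renormalized to unit
trapezoid integral on its grid, so F_diff integrates to zero to numerical
precision rather than to within the kernel tail mass truncated at the grid
edge (~10⁻³ at 3 bandwidths).

## Splice enumeration and mapping

Substrate coordinates are closed 1-based intervals in parental numbering:
a substrate cut from a larger protein carries the parental position of its
first residue, so "position 12" always means residue 12 of the parent. A
decomposition explains a peptide as one substrate segment (non-spliced) or
two segments sr1 + sr2: cis-normal when sr1 ends before sr2 starts,
cis-reverse when sr2 ends before sr1 starts, and trans when the two
intervals overlap, i.e. a single substrate molecule cannot supply both.
Trans products are modelled against two copies of the same substrate
(matching a single-substrate digestion); inter-protein trans splicing and
products requiring three or more fragments are out of scope — the latter
are reported as "unmapped". The intervening length (residues strictly
between the reactants) is defined for cis products only. The minimum
splice-reactant length defaults to 1 and is configurable; reported
C-terminal splice-reactants can be very short, so no larger lower bound is
imposed.

A peptide's category follows the precedence non-spliced > cis > trans: a
substrate substring is never called spliced, and a peptide is trans only
when no single-molecule explanation exists. Enumeration is exhaustive at
the coordinate level (identical sequences from different intervals are
distinct entries); the candidate filters and FASTA export collapse to
unique sequences, retaining all decompositions. Correctness of both
enumerators and of the mapper is pinned to a brute-force quadruple-loop
oracle on random substrates in the test suite.

Inclusion-list m/z values use monoisotopic residue masses plus water
(pyteomics) and m/z = (M + z·1.007276)/z for charge states 1–7;
modifications are not modelled.

## Digestion analysis

PSM filtering drops hits with ion score < 20 or q-value > 0.05 and
resolves each spectrum to its rank-1 hit. When the top hit is spliced, the
identification must hold a relative delta score
(score_top − score_alt)/score_top ≥ 30% against both the best alternative
spliced sequence and the best non-spliced hit of the same spectrum,
otherwise the spectrum is rejected as ambiguous. All thresholds are
configurable.

The kinetic filters quantify criteria that are inherently qualitative
("synthesis artifacts", "non-reproducible kinetics"); the defaults are
implementation choices, configurable and logged per peptide:

* **synthesis artifact** — signal at t = 0 above 5% of the series maximum
  (a genuine digestion product cannot pre-exist the reaction);
* **alternating kinetics** — a down-then-up or up-then-down excursion
  between consecutive time points with both relative changes (normalized
  by the larger neighbor) above 50%;
* **reproducibility** — a peptide must survive in ≥ 2 technical replicates
  of a biological replicate to count as detected there, and in ≥ 2
  biological replicates overall. Biological replicates are processed
  separately; technical-replicate areas are averaged per time point after
  the filters.

Absolute quantification inverts a per-peptide ordinary-least-squares
titration line (area = slope·pmol + intercept, ≥ 3 points spanning 0–10
pmol; slope ≤ 0 marks the curve unusable). Negative inversions — routine
for blank t = 0 areas under a positive fitted intercept — clip to 0.
Deconvolution-based quantification is treated as an external alternative;
the titration route is self-contained and is what the two headline
peptides were quantified with.

SCS-P1 sums, per substrate position, the amounts of all products whose
C-terminus is that residue; PSP-P1 sums, per position, the amounts of
spliced products whose N-terminal splice-reactant ends there. Both are
normalized to 100%. A product with k admissible positions (equivalent
decompositions of its own category, e.g. the three explanations of
KLVVGAVGV with splice sites 6, 7, 8) contributes amount/k to each
position; equal splitting conserves total amount, whereas assigning the
full amount to one representative mapping would bias the profile by an
arbitrary choice. Products default to their mean amount over all time
points and replicates; a specific time point can be selected. An all-zero
profile raises rather than silently returning zeros. Only decompositions
matching the product's assigned category contribute, so a substring
peptide never leaks into PSP-P1 through an incidental spliced explanation.

## Synthetic data generators

The proteome generator draws protein lengths from a log-normal
(median 300 residues, log-sd 0.45, floor 30) and sequences from human-like
amino-acid frequencies with per-protein hydropathy and charge tilts
(log-linear reweighting, sd 0.25 and 0.45) so that GRAVY and pI vary
independently of length. The represented set (fraction 0.2 of n = 2,000 by
default) is drawn without replacement with weights logistic(−f(p*)/T) over
control-standardized features, with planted factors
p* = (−1, 0.5, 0.1, 0.5) — length favoring representation, hydrophobicity
and instability disfavoring it, pI nearly neutral, the qualitative pattern
the real analysis reports — and selection temperature T = 1. The planted
p* is returned so recovery tests are closed-loop.

The digestion generator picks 20 non-spliced and 10 cis products (8–12mers
of the KRAS 2–35 G12V substrate by default) weighted by sparse
gamma-distributed per-position cleavage and splicing propensities, gives
each a linear accumulation rate over the 0–4 h time course, and converts
amounts to areas through hidden log-normal per-peptide response factors
with multiplicative log-normal noise (sd 5%) per technical replicate
(2 biological × 3 technical). It emits matched PSMs (scores drawn to pass
the default filters, plus clearly separated runner-up hits for spliced
identifications) and a per-peptide titration table (0–10 pmol, 2% noise).
Optional switches plant t = 0 artifacts or sawtooth kinetics to exercise
the filters.

**Ground truth definition.** The "true" SCS-P1/PSP-P1 profiles are
computed by applying the package's own site-profile bookkeeping (including
the equal split over ambiguous positions) to the noiseless product
amounts. This makes the noiseless limit recover the truth exactly (L1
< 10⁻⁶) and makes the noisy-recovery test (L1 ≤ 10 percentage points at
default noise; measured ≈ 2) a measurement of noise- and filter-induced
error, not of ambiguity bookkeeping.

What the generators do **not** emulate: retention times, fragmentation,
detectability bias, saturating (non-linear) product kinetics, substrate
depletion, search-engine score distributions, or real immunopeptidome
composition. Passing the closed-loop tests therefore shows the machinery
is self-consistent and robust to multiplicative noise at realistic
replicate structure, not that it would reproduce any particular published
dataset.

## The KRAS fixture

The bundled substrate is the N-terminal region (residues 2–35) of
canonical human KRAS (UniProt P01116), with the G12V substitution applied
at parental position 12; numbering offset 2, 34 residues. The spliced
candidate KLVVGAVGV (KRAS 5–6/8–14 G12V) and the non-spliced candidate
KLVVVGAVGV (KRAS 5–14 G12V) fall out of this sequence at the documented
coordinates, which the test suite asserts.

## Problem sizes and determinism

Default test and acceptance runs use n = 2,000 proteins with 400
represented antigens and MCMC chains of 300 burn-in + 300 retained samples
(about 2 s on one CPU); the digestion analyses run on 30-product
simulations in well under a second. Every stochastic component takes an
explicit seed (numpy `default_rng`); identical configs and seeds give
byte-identical outputs, and tabular outputs have deterministic row order.

## Known limitations

* Binding-affinity prediction is an interface, not an implementation: real
  use requires an external predictor's exported table. The bundled
  anchor-motif scorer is explicitly non-predictive and exists only to
  exercise the interface offline.
* The delta-score rule operates on relative ion scores of candidate hits
  within one spectrum; search-engine-specific score semantics (homology
  thresholds, expectation values) are not modelled.
* Counts such as how many theoretical candidates survive each funnel stage
  depend on enumeration conventions (reverse-order products included or
  not, minimum splice-reactant length) for which no universal standard
  exists; both are configurable and reported in the run manifest.
* The CLI maps data errors to exit code 2 via a dedicated exception class;
  argument-parsing errors keep click's native behavior.
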