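# pepsplice

In silico identification of proteasome-generated spliced epitope candidates.

Recurrent tumor driver mutations (KRAS G12V is the motivating case) often
cannot be displayed by conventional, non-spliced peptides on the prevalent
HLA class I alleles: no contiguous fragment around the mutation binds well
enough. Proteasome-catalyzed peptide splicing (PCPS) — the re-ligation of
two substrate fragments into a peptide whose sequence is non-contiguous in
the parent protein — vastly expands the sequence space and can yield
mutation-carrying peptides that do bind. `pepsplice` implements the
computational stages of a pipeline that exploits this:

1. **Antigen prioritization.** For every protein, four intrinsic features
   are computed: length, GRAVY hydropathy, isoelectric point and the
   instability index, collected in a vector *c*. A weighted feature sum
   *f* = Σᵢ *p*ᵢ*c*ᵢ with factors *p*ᵢ ∈ [−1, 1] (negative = favoring
   representation) is scored by the two-sample Kolmogorov–Smirnov distance
   between the *f*-distribution of antigens represented in HLA-I
   immunopeptidomes (*F*₁) and that of the whole proteome (*F*₀). A
   Metropolis–Hastings sampler with pseudo-likelihood exp(β·KS) draws the
   factor posterior; candidate antigens are ranked by the density
   difference *F*diff = *F*₁ − *F*₀ evaluated at their own feature sums
   across the posterior.
2. **Product enumeration and mapping.** Exhaustive enumeration of all
   theoretical 8–12mer non-spliced and cis-spliced (normal and reverse
   order) products of a substrate, and complete decomposition of any
   observed peptide into one or two substrate segments, classified with the
   precedence non-spliced > cis > trans. Supports search-database FASTA
   export and monoisotopic m/z inclusion lists for targeted MS.
3. **Candidate funnel.** Mutation coverage, length window and a pluggable
   HLA-I binding-affinity filter (IC50 ≤ 100 nM by default; predictions are
   imported tables or callables — binding predictors themselves are out of
   scope), plus a proteome-wide uniqueness scan (can any other protein make
   this sequence by hydrolysis or cis splicing?).
4. **Digestion analysis.** PSM filtering (ion score ≥ 20, q ≤ 0.05, 30%
   delta-score rule for spliced assignments), kinetic plausibility filters
   (t₀ synthesis artifacts, alternating kinetics, replicate
   reproducibility), absolute quantification via synthetic-peptide
   titration lines, and the site profiles **SCS-P1** (percentage of total
   product amount cleaved after each substrate residue) and **PSP-P1**
   (percentage of spliced product amount using each residue as splice
   site), each normalized to 100%.

A synthetic-data module generates closed-loop test inputs for every stage:
proteomes with a planted factor vector and digestion kinetics from known
cleavage/splicing propensities, with ground truth returned alongside.

## Worked example

```sh
python examples/candidate_funnel.py
```

runs the candidate funnel on the bundled KRAS 2–35 G12V substrate with a
constructed prediction table (only the spliced candidate is a strong
binder) and prints:

```
candidate funnel (sequence-level counts):
            stage  n_candidates
       enumerated         22876
         mutation          8239
           length          8239
binding <= 100 nM             1

final candidates:
  KLVVGAVGV  category=cis-normal  IC50=50 nM
```

22,876 unique 8–12mer sequences are theoretically producible from the 34-
residue substrate; 8,239 of them can carry the G12V mutation at parental
position 12; the binding filter leaves exactly the spliced epitope
candidate KLVVGAVGV (KRAS 5–6/8–14 G12V), while the non-spliced 10mer
KLVVVGAVGV (KRAS 5–14 G12V, assigned 300 nM) is removed at the 100 nM
cutoff. `examples/map_spliced_candidate.py` shows why the 9mer is spliced:
it has exactly three equivalent cis-normal decompositions, each skipping
one of the three consecutive valines, and no other protein in a decoy
proteome can produce it.

The other examples demonstrate antigen ranking on a synthetic proteome
(`rank_antigens.py`), enumeration and inclusion lists
(`enumerate_products.py`) and the digestion analysis with SCS-P1/PSP-P1
profiles (`digestion_profiles.py`). A `pepsplice` console command exposes
the same stages for shell use (`pepsplice --help`).

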