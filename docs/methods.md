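# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic fixtures can demonstrate.

## Inputs and conventions

MSAs are accepted in A3M (lowercase = insertion, removed), A2M (lowercase
and `.` removed) and aligned FASTA. The first record is the query and must
be ungapped after normalisation; a gapped query is an error, never silently
repaired. All user-facing positions are 1-based; CSV intervals are closed;
the optional BED export is 0-based half-open. Internally arrays are
0-indexed. `X` and non-standard letters in homolog rows are treated as
gap-like for column statistics: they carry no substitution identity.

Per-column statistics: `gap_fraction`, `n_substitutions_sampled` (distinct
non-gap, non-wild-type letters, ≤ 19) and `conservation`, defined as the
modal non-gap amino-acid frequency. This is a deliberately tree-free
conservation proxy; phylogeny-aware conservation is out of scope. The MSA
summary uses query-coverage identity (matches over the full query length),
so fragments score low even if locally identical.

## Evolutionary scores

The landscape is a 19×L matrix of raw scores, more negative = more
damaging. Wild-type cells are NaN, not 0 — they are not variants and must
not distort the mixture fit. Scores normally come from an external
predictor via CSV (long `position,wt,mut,score` form or a 20×L grid).

The built-in **baseline scorer** is a column-independent log-odds:
score(i, a) = log[(cᵢ(a) + q)/(cᵢ(wtᵢ) + q)] with pseudocount q (default
1.0, Laplace smoothing) and cᵢ the non-gap counts of column i. It ignores
phylogeny and epistasis by construction, and is labelled `baseline` in all
run metadata so its outputs cannot be mistaken for a tree-aware predictor's.
With only the query present it degenerates to the constant
log(q/(1+q)), which is the documented contract for that edge case.

Partial matrices: the sensitivity profile averages whatever cells are
present (`n_scored` records how many); fully unscored positions are NaN in
the profile and imputed with the profile mean before segmentation (recorded
as a warning) so one missing column cannot abort a run; the affected
variants are classed `unscored`.

## Mixture classification

A three-component Gaussian mixture with free per-component variances is
fitted by EM (tolerance 1e-6, max 500 iterations) to all finite scores; at
least 30 are required. Initialisation is deterministic: means at the 1/6,
1/2 and 5/6 data quantiles, uniform weights, pooled variance. This makes
the fit independent of the seed; the seed only drives the 10 random
restarts attempted if a component collapses (variance below 1e-8), after
which a named error is raised. Components are reported sorted by mean.

Thresholds are the weighted-density crossovers between adjacent components,
solved by bracketed root finding on the log-density difference in the open
interval between the means; when no crossing exists there (pathological
overlap) the midpoint is used and the fallback is flagged in `gmm.json`.
A score exactly equal to a threshold takes the milder class — conservative
pathogenicity calling. Unscored substitutions count as non-neutral in the
residue rule: absence of evidence must not manufacture tolerance.

The confidence rule fires (position non-confident) iff dispersion of the 19
scores < `d_min` AND conservation < `c_min` AND (gap fraction > `g_max` OR
substitutions sampled < `s_min`). Defaults 0.2 / 0.3 / 0.5 / 5 are declared
configuration, not calibrated constants; the `reasons` column records the
clauses that fired. The mixture is fitted on all finite scores, not only
confident positions, so the fit reflects the whole protein context.

## Segmentation

The sensitivity profile is modelled as piecewise constant with iid Gaussian
noise, common variance σ², segment means μⱼ. The objective
Σⱼ Σ_{i∈segⱼ} wᵢ(yᵢ−μⱼ)² + β(K−1) is minimised exactly by FPOP: the
optimal cost conditional on the running segment mean μ is a piecewise
quadratic; each observation adds wᵢ(yᵢ−μ)², each step offers the
alternative of opening a new segment at the previous optimum plus β.
Quadratic pieces that rise above that constant everywhere are pruned.
Where extending and opening tie exactly, the new changepoint wins; this
makes the β = 0 limit return n singleton segments at zero cost, and the
β ≥ n·max(w)·range(y)² limit return one segment. An O(n²) optimal-
partitioning reference implementation is shipped
(`optimal_partition_reference`) and the pruned solver is tested against it
for exact agreement on changepoints and cost.

β = α σ² log n with α = 1.4 by default; α is the user's granularity knob.
σ² comes from the Hall fourth-order difference estimator,
σ̂² = (n−3)⁻¹ Σ (d₀yᵢ + d₁yᵢ₊₁ + d₂yᵢ₊₂ + d₃yᵢ₊₃)², with the optimal
coefficients (0.1942, 0.2809, 0.3832, −0.8582) re-normalised to sum 0 /
sum-of-squares 1 exactly (the 4-decimal tabulated values miss zero-sum by
~1e-4, which would otherwise leak a term proportional to the signal mean —
visible on constant profiles). The estimator is computed on the unweighted
profile and globally over the protein: σ² is a property of the observation
noise, whereas the weights encode structural trust. σ² can be overridden.

Weights: w = 0.1 where pLDDT > 70 (strict), 1 elsewhere; positions without
structural coverage, or unaligned to the structure, get 1. The weights
enter the squared loss; the penalty keeps the unweighted σ² log n form.

Segment scores are computed on the raw scale where lower mean = higher
sensitivity: 2 if strictly below both flanking means, 1 if below exactly
one, 0 otherwise; ties are not elevation; terminal segments have one
neighbour and score at most 1; a single segment scores 0. A segment is in
an IDR when the majority of its positions have pLDDT < 70 (missing pLDDT
counts as unstructured), and *highlighted* when in an IDR with score ≥ 1.

## Structure handling

PDB parsing keeps the first model, drops waters and heteroatoms, maps
common modified residues (MSE→M, SEP→S, TPO→T, PTR→Y, MLY/M3L→K, HYP→P,
CSO→C, KCX→K, PCA→Q) to their parents and drops anything unmappable.
Disordered atoms resolve to the highest-occupancy conformer. Per-residue
B-factor is the mean over atoms and is interpreted as pLDDT only when the
user declares the file an AlphaFold model; experimental B-factors are never
used as weights.

Sequence-structure mapping uses a global affine alignment: match 1.0,
mismatch −3.0, first internal gap residue −2.5, every further internal gap
residue −2.0, every terminal gap residue −2.0. Mismatched aligned columns
still map (the structure may be an isoform or homologue); a warning is
emitted below 30% identity. Of the co-optimal paths the aligner's first is
reported — a fixed, deterministic tie-break. Scores are verified against an
independent Gotoh dynamic program.

RSA uses Shrake–Rupley sphere sampling (probe 1.4 Å, 100 points/atom),
summed per residue, normalised by the Tien et al. (2013) theoretical
maximum ASA per residue type (recorded in output metadata). For multimers
both contexts are computed: complexed (all chains present) and free (chain
isolated); isolation can only expose, so rsa_free ≥ rsa_complexed holds
atom-for-atom. By default the complexed RSA feeds the modulation when a
multimer is supplied, otherwise the monomer RSA; both columns are always
exported. The modulation multiplier 1 − min(RSA,100)/100 lies in [0,1];
RSA is capped at 100% because sampled accessibility can exceed the
theoretical maximum for small or distorted residues. With 100 sampling
points, per-residue RSA carries a few percentage points of discretisation
jitter on the 5-atom toy residues used in tests; real all-atom residues
average this down.

B-factor exports write per-residue values (sensitivity, class code 1/0, or
mean structure-aware sensitivity) onto every atom, sentinel −99.0 for
unmapped residues, so any viewer can colour by them.

## Synthetic fixtures

The generators emulate the statistical shape of real inputs, not their
biophysics:

- **MSA**: iid column profiles; motif columns concentrate mass on the query
  letter (default conservation 0.95 inside motifs, 0.25 outside) with gap
  probabilities 0.05 / 0.3 — conserved islands in gappy IDR background.
  Columns are independent, so no phylogenetic correlation exists; passing
  tests therefore show correctness of the statistics, not robustness to
  tree structure.
- **Landscape**: each substitution cell draws one of three Gaussian classes
  (means −8/−4/0, sd 0.5, equal weights by default) plus a per-position
  segment shift; truth (cell classes, changepoints) is returned for
  recovery tests. Real score matrices have position-dependent class
  composition and heavier tails.
- **Changepoint recovery study**: n = 300, four changepoints at
  60/120/180/240, jumps of 3.5σ (σ = 0.5), pLDDT 90 on the first half and
  40 on the second so the weight pattern does not coincide with the true
  changepoints; 100 seeds. These sizes keep the full suite and the
  acceptance script in seconds on one CPU while leaving the recovery
  criterion comfortably testable.
- **Structures**: idealised helix/extended backbones with N, CA, C, O, CB
  placeholder atoms (no glycine CB); the two-chain mode translates a copy
  ~5.5–7 Å away to bury interface atoms. Geometry is plausible enough for
  parsing, SASA and alignment tests, nothing more.

## Known limitations

- The baseline scorer is a stand-in for a real evolutionary predictor;
  classifications derived from it are only as good as column log-odds.
- Conservation is the modal-frequency proxy; deep but phylogenetically
  skewed MSAs will overstate it.
- Single-chain variant scoring only; indels and multi-residue variants are
  out of scope.
- Segment models assume a global common variance; proteins whose ordered
  and disordered parts have very different score variances rely on the
  pLDDT weighting to compensate.
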