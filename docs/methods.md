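# Methods

## Scope and model

The package quantifies protein mutational robustness — the stability
cost ΔΔG (kcal/mol, positive = destabilizing) of amino-acid mutations —
as a function of the structure of the standard genetic code, the codon
usage and residue/protein features.  ΔΔG values are *inputs* (in
practice the output of a stability predictor applied to a structurome);
the package owns the enumeration, weighting and stratification logic and
a synthetic data generator used to validate the pipeline end to end.

Two modelling conventions run through everything:

* **ΔΔG is a property of the amino-acid mutation, not of the base-change
  path.**  When a mutation is reachable from a codon by *k* distinct
  single-base substitutions, the *k* events share one ΔΔG and appear *k*
  times wherever degeneracy is counted.
* **Stop-involving events are enumerated but excluded** from all
  robustness statistics: a nonsense mutation truncates the protein and
  has no meaningful folding ΔΔG.  Synonymous events carry ΔΔG = 0
  exactly and count as neutral wherever they are included.

## Genetic-code combinatorics

Amino-acid mutations are ordered (wt → mut) pairs; there are 380 of
them, of which 150 are reachable by some single base substitution
(μSBS).  Restricted to one codon position, exhaustive enumeration over
the 61 sense codons gives 62 (base I), 82 (base II) and 14 (base III)
reachable ordered mutations; the base-III set is exactly the seven
unordered pairs Phe–Leu, Ile–Met, His–Gln, Asn–Lys, Asp–Glu, Cys–Trp,
Ser–Arg in both directions.  The test suite checks the whole
combinatorics against an independent brute force built directly on
Biopython's translation.

Multiple-base events are generated per position set (I+II, I+III,
II+III, I+II+III) with every named position required to change, so the
seven position-set classes partition all 63 possible codon changes.  Two
μMBS views exist: per-event position-set profiles, and the aa-pair view
(minimum codon Hamming distance ≥ 2) used for single-versus-multiple
comparisons; both are exposed because neither subsumes the other.

## Key constants

| constant | value | role |
|---|---|---|
| RSA core threshold | 20% (inclusive) | core/surface split |
| ΔΔG class bounds | −0.5 / +0.5 kcal/mol (boundaries neutral) | stabilizing/neutral/destabilizing |
| translation-error frequencies | 31.3% / 6.2% / 62.5% (positions I/II/III) | translation-error weighting |
| bias rule | relative deviation > 12.5% from expected family frequency | biased/unbiased codons |
| fitness thresholds | (lof + wt)/2 and 1.25·wt (boundaries neutral) | deleterious/neutral/advantageous |
| length bins | ≤200, (200, 400], >400 residues | size stratification |

The bias deviation is **relative** (|obs − exp|/exp): an absolute
12.5-percentage-point rule would make six-codon families (expected
≈16.7%) almost always unbiased and empty the biased stratum.  Both an
equiprobability expectation and one proportional to the product of
organism nucleotide frequencies (renormalized within the family) are
supported.

## Weighting schemes

*Position weighting.*  Class fractions under translation errors weight
each codon position by its error frequency:
fraction(c) = Σ_p w_p · (class-c events at p / events at p).  If a
position has no events but nonzero weight, the weights are renormalized
over the populated positions with a warning (small inputs would
otherwise be undefined).

*Used versus synonymous codons.*  The used pool expands SBS events from
each residue's actual codon; the synonymous pool expands them from every
other codon of the amino acid's family.  Each alternative codon carries
equal weight per residue (mean of per-codon means) — the comparison is a
codon-level counterfactual, and per-event pooling would let
stop-adjacency differences between codons re-weight residues.  Within a
codon, positions share the scheme's frequencies (uniform for random
mutations, the error frequencies for translation), split equally over
each position's non-nonsense events.  The reported statistic is
(⟨ΔΔG_syn⟩ − ⟨ΔΔG_used⟩)/σ in percent with σ² the sum of the two pools'
population variances (at structurome scale the n/(n−1) distinction is
irrelevant; population variance is used for reproducibility).  The
statistic is antisymmetric under swapping which codon of a two-codon
family is "used", which the tests exploit as an exact oracle.

## RSA profile and numerical conventions

RSA bins are half-open [k, k+1)% with RSA = 100 folded into the last
bin.  The mean-ΔΔG-versus-RSA relation is fitted piecewise by least
squares: a straight line on bins with left edge ≥ 20% and a
second-degree polynomial on bins below; a side with fewer populated bins
than parameters + 1 omits its fit (`None`) rather than extrapolating.
Pearson correlations go through `scipy.stats.pearsonr` and report r, n
and the two-sided p-value; zero-variance inputs return a flagged result
instead of raising.  Residue positions are 1-based; codon positions are
I/II/III.  RSA values marginally above 100% (rounding in upstream
accessibility tools) are clamped.

## Synthetic structurome generator

The generator emulates the statistical structure the analyses assume,
with every choice overridable in `GeneratorConfig`:

* **lengths** — log-normal (median 215, σ = 0.55, floor 30), giving a
  mean length ≈ 250 so the default 200 proteins yield ≈ 50,000 residues
  with all three length bins populated;
* **burial** — each residue is core with probability 0.22 / 0.28 / 0.33
  by length bin (core-to-length ratio rises with size, as multi-domain
  packing suggests); RSA is 20·Beta(1.3, 2.2) in the core and
  20 + 80·Beta(1.1, 1.5) on the surface;
* **composition** — core residues are Val/Ile/Leu/Phe with probability
  0.45 / 0.41 / 0.37 by length bin (hydrophobicity of the core decreases
  with size), surface residues with probability 0.15; within each group
  the choice is uniform;
* **codons** — one preferred codon per family (alphabetically first)
  receives frequency (1 + b(k−1))/k and the others (1−b)/k, so the
  non-preferred codons deviate from equiprobability by exactly the bias
  strength b (default 0.25, hence all multi-codon families are labelled
  biased under the 12.5% rule; b = 0 gives uniform families and
  all-unbiased labels);
* **ΔΔG** — per amino-acid mutation:
  β₀ + β₁·(1 − RSA/100) + β₂·KD(wt) + β₃·dissim(wt, mut) + N(0, 1),
  with KD the Kyte–Doolittle index (β₂ = 0.06: mutating buried
  hydrophobics costs more) and dissim the negated BLOSUM62 score
  rescaled to [0, 1] (β₃ = 1.5: dissimilar replacements destabilize,
  reproducing the similarity-matrix trend without hard-coding it).  By
  default β₀ and β₁ are solved on the realized covariate sample so that
  the systematic core and surface means of SBS-reachable mutations equal
  the anchors 1.09 and 0.49 kcal/mol exactly; recovery through the full
  expansion pipeline then tests the joins, classifications and
  stratifications rather than the noise.  Setting β₀/β₁ explicitly
  bypasses the calibration, which is how the monotonicity of the
  core-surface gap in β₁ is tested.  Every residue carries a ΔΔG row for
  all 19 targets so SBS and MBS analyses share one table;
* **fitness** — wt·logistic(γ(τ − ΔΔG) + noise) with γ = 2.5, τ = 0.8
  kcal/mol, noise σ = 0.25, wt = 1, lof = 0.  Because the logistic is
  bounded by the wild-type score, the advantageous class (> 1.25·wt) is
  essentially empty by construction; the model targets the
  deleterious/neutral split only.

A single master seed drives independent substreams (residues, ΔΔG noise,
fitness noise) via `numpy` SeedSequence spawning, so adding a table does
not perturb the others and identical seeds give byte-identical TSVs.
The packaged fixtures (`small` ≈ 640 residues for unit tests, `medium`
≈ 47,000 residues for statistical tests — sizes chosen so the full suite
runs in well under a minute) carry frozen SHA-256 checksums.

### What the generator does and does not emulate

It reproduces RSA-dependent ΔΔG levels, length-dependent core fraction
and composition, similarity-dependent destabilization and biased codon
usage.  It does **not** emulate: skewed empirical ΔΔG distributions
(noise is Gaussian; class *fractions* therefore differ from empirical
ones even where means match), selection of codons for robustness (codons
are drawn independently of ΔΔG, so used-versus-synonymous deltas are
null-consistent — a correct null check of the estimator, not a
reproduction of the empirical effect), disulfide bridges and other
structural outliers, or real organism-specific usage tables.  Passing
parameter-recovery tests therefore demonstrates correctness of the
statistical machinery on data of realistic shape, not empirical claims
about real structuromes.

## Design choices on genuinely open points

* Reachability counts exclude stop-involving events; this is the rule
  under which the base-III count is 14 (7 unordered pairs × 2
  directions).
* The base-content/hydrophobicity correlation is computed over the 61
  sense codons (one point per codon, the encoded amino acid's KD value);
  amino-acid-level or usage-weighted conventions give different
  magnitudes, which is why only sign and rough size are asserted.
* μMBS position-set profiles classify per event, without deduplicating
  amino-acid pairs also reachable at lower order; the aa-pair view is
  available separately.
* `validate_cds` compares codons positionally (no alignment) and accepts
  a map at ≥ 95% identity (inclusive); mismatching positions carry no
  codon.  Gapped alignment is deliberately out of scope.
* In summaries, empty strata are reported as n = 0 rows with undefined
  means rather than dropped, so downstream joins stay total.

## Known limitations

Single-codon families (Met, Trp) are excluded from all
used-versus-synonymous and GC statistics (their counterfactual is
empty); the exclusion count is reported.  The CDS validator assumes
clean, gapless coding sequences.  Multiple-testing correction across
strata is out of scope — raw r and p are reported.  Non-standard genetic
codes, RNA alphabets and ambiguity codes are unsupported.
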