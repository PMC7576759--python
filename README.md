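# robustome

Structurome-scale statistics of **protein mutational robustness** at the
genetic-code and codon level, for molecular evolution and protein
biophysics researchers.

The central quantity is the change in folding free energy upon a single
amino-acid mutation, ΔΔG (kcal/mol, positive = destabilizing).  Given a
per-residue annotation table (wild-type codon, relative solvent
accessibility RSA) and a per-mutation ΔΔG table (e.g. from a stability
predictor run over a set of X-ray structures), the package

* enumerates every single-base substitution (SBS) of each codon,
  classifies it (synonymous / missense / nonsense, transition /
  transversion) and attaches the ΔΔG of the resulting amino-acid
  mutation — synonymous events carry ΔΔG = 0, and the *k* degenerate
  base-change paths to one mutation count *k* times;
* computes stratified means ⟨ΔΔG⟩, standard deviations and the fractions
  of stabilizing (ΔΔG < −0.5), neutral (−0.5 ≤ ΔΔG ≤ 0.5) and
  destabilizing (ΔΔG > 0.5 kcal/mol) mutations by RSA stratum
  (core ≤ 20% < surface), codon position I/II/III, wild-type base,
  transition/transversion, BLOSUM62 class, protein and length bin;
* weights class fractions by the per-position codon–anticodon
  mispairing frequencies (31.3%, 6.2%, 62.5%) to contrast random
  mutations with translation errors;
* compares events reached from the actually *used* codon with those
  reached from its synonymous codons,
  (⟨ΔΔG_syn⟩ − ⟨ΔΔG_used⟩)/σ with σ² = σ²(used) + σ²(syn), overall, per
  position, per RSA stratum and stratified by codon-usage bias (a codon
  is biased when its within-family frequency deviates from expectation
  by more than 12.5% in relative terms), plus GC-content differences;
* classifies deep-mutational-scanning fitness scores as deleterious /
  neutral / advantageous using the (lof + wt)/2 and 1.25·wt thresholds;
* ships a seedable synthetic-structurome generator whose configured
  moments (core/surface mean ΔΔG 1.09/0.49 kcal/mol, core hydrophobic
  fractions 0.45/0.41/0.37 by length bin, biased codon usage) make the
  whole pipeline testable by parameter recovery.

Pure genetic-code combinatorics need no data at all: enumeration over
the 61 sense codons shows that substituting codon base III can produce
only **14** distinct ordered amino-acid mutations, against **62** for
base I and **82** for base II (stop-involving events excluded).

## Worked example

```python
from robustome import annotate, stats, synthetic

ds = synthetic.make_fixture("medium")          # ~200 proteins, ~47k residues
exp = annotate.expand_events(ds.residues, ds.mutations, include_synonymous=False)
print(stats.summarize(exp.events, "rsa_stratum"))
```

```
  rsa_stratum       n  mean_ddg    sd_ddg  frac_stabilizing  frac_neutral  frac_destabilizing
0        core   87600  1.072142  1.082923          0.073642      0.225902            0.700457
1     surface  234653  0.470316  1.103976          0.189748      0.321287            0.488965
```

Core mutations are on average twice as destabilizing as surface ones
(the generator anchors, 1.09 and 0.49 kcal/mol, are recovered within
sampling error), and the destabilizing fraction is far higher in the
core — the familiar picture of a tightly packed interior.

The numbered drivers under `analysis/` run the complete study on the
synthetic structurome and write their tables under `results/`:

```bash
python analysis/01_code_structure.py      # code combinatorics, no data
python analysis/02_simulate.py            # writes scratch/structurome/
python analysis/03_residue_robustness.py  # RSA, length, composition
python analysis/04_code_robustness.py     # positions, ti/tv, BLOSUM, fitness
python analysis/05_codon_usage.py         # used vs synonymous codons, bias
```

For example, `04_code_robustness.py` prints the destabilization ranking
of the position sets (III is mildest, I+II+III worst) and the
anticorrelation between the per-position mean ΔΔG (with synonymous
mutations and degeneracy) and the translation-error frequencies, and
`05_codon_usage.py` prints the used-versus-synonymous deltas, which are
consistent with zero on this dataset because the generator draws codons
independently of ΔΔG — a null check of the estimator.

There is also a CLI mirroring the drivers
(`robustome simulate|annotate|stats|code-analysis|report`); see
`robustome --help`.

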