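#!/usr/bin/env python
"""Genetic-code-level robustness on the synthetic structurome.

Compares single versus multiple base substitutions, codon positions under
both weighting schemes (with/without synonymous mutations and path
degeneracy), translation-error-weighted class fractions, transition/
transversion and wild-type-base stratifications, BLOSUM62 classes, and
the fitness classification of the simulated deep-mutational-scanning
table.

Writes results/code_robustness/.
"""

from pathlib import Path

import pandas as pd

from robustome import annotate, genetic_code as gc, io as rio, stats, synthetic

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "structurome"
OUT = ROOT / "results" / "code_robustness"


def load_dataset():
    if (DATA / "residues.tsv").exists():
        return (rio.read_residues(DATA / "residues.tsv"),
                rio.read_mutations(DATA / "mutations.tsv"),
                rio.read_fitness(DATA / "fitness.tsv"))
    ds = synthetic.make_fixture("medium")
    return ds.residues, ds.mutations, ds.fitness


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    residues, mutations, fitness = load_dataset()
    exp_syn = annotate.expand_events(residues, mutations, include_synonymous=True)
    exp_mis = annotate.expand_events(residues, mutations, include_synonymous=False)

    # SBS versus MBS (per-event position-set classes and mu-MBS pairs)
    mbs = annotate.expand_mbs_events(residues, mutations, include_synonymous=False)
    mu_mbs = stats.add_mu_class(mbs.events)
    mu_mbs = mu_mbs[mu_mbs["mu_class"] == "mu_mbs"]
    sbs_mbs = stats.summarize(
        pd.concat(
            [exp_mis.events.assign(kind="mu_sbs"), mu_mbs.assign(kind="mu_mbs")],
            ignore_index=True,
        )[["kind", "ddg"]],
        "kind",
    )
    rio.write_tsv(sbs_mbs, OUT / "sbs_vs_mbs.tsv")
    print("single vs multiple base substitutions:")
    print(sbs_mbs.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    pos_sets = stats.summarize(
        pd.concat(
            [exp_mis.events.assign(
                position_set=exp_mis.events["codon_position"].map(gc.POSITION_LABELS)),
             mbs.events],
            ignore_index=True,
        )[["position_set", "ddg"]],
        "position_set",
    ).sort_values("mean_ddg")
    rio.write_tsv(pos_sets, OUT / "by_position_set.tsv")
    print("\ndestabilization ranking over position sets (mean ddG, kcal/mol):")
    print(pos_sets[["position_set", "n", "mean_ddg"]].to_string(
        index=False, float_format=lambda v: f"{v:.3f}"))

    with_syn = stats.position_means(exp_syn.events, "with_syn_and_degeneracy")
    without = stats.position_means(exp_mis.events, "without")
    rio.write_tsv(with_syn, OUT / "position_means_with_syn.tsv")
    rio.write_tsv(without, OUT / "position_means_without.tsv")
    corr = stats.pearson([f * 100 for f in stats.TRANSLATION_ERROR_FREQS],
                         with_syn["mean_ddg"])
    print("\nmean ddG per codon position (with synonymous + degeneracy):")
    print(with_syn.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"anticorrelation with translation-error frequencies: r = {corr.r:.3f}")

    fr_rand = stats.weighted_class_fractions(exp_syn.events,
                                             stats.RANDOM_MUTATION_FREQS)
    fr_trans = stats.weighted_class_fractions(exp_syn.events,
                                              stats.TRANSLATION_ERROR_FREQS)
    rio.write_report({"random": fr_rand, "translation": fr_trans},
                     OUT / "weighted_fractions.json")
    print("\nclass fractions, random mutations vs translation errors:")
    for name, fr in (("random", fr_rand), ("translation", fr_trans)):
        print(f"  {name:>12}: " + ", ".join(f"{k} {v:.1%}" for k, v in fr.items()))

    titv_w = stats.titv_means(exp_syn.events, include_synonymous=True)
    titv_wo = stats.titv_means(exp_mis.events, include_synonymous=False)
    rio.write_tsv(titv_w, OUT / "titv_with_syn.tsv")
    rio.write_tsv(titv_wo, OUT / "titv_without_syn.tsv")
    print("\ntransitions vs transversions (with synonymous):")
    print(titv_w.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    base_table = stats.summarize(exp_mis.events, "wt_base")
    rio.write_tsv(base_table, OUT / "by_wt_base.tsv")
    hydro = pd.DataFrame(
        [{"base": b, "r": stats.hydrophobicity_correlation(b).r,
          "p": stats.hydrophobicity_correlation(b).p_value} for b in gc.BASES]
    )
    rio.write_tsv(hydro, OUT / "base_hydrophobicity.tsv")
    print("\nbase content vs Kyte-Doolittle hydrophobicity over 61 codons:")
    print(hydro.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    blosum = stats.summarize(stats.add_blosum(exp_mis.events), "blosum62")
    rio.write_tsv(blosum, OUT / "by_blosum.tsv")
    bc = stats.pearson(blosum["blosum62"], blosum["mean_ddg"])
    print(f"\nmean ddG vs BLOSUM62 class: r = {bc.r:.3f} over {bc.n} classes")

    labels = stats.fitness_classify_series(
        fitness["fitness"], fitness["wt_score"], fitness["lof_score"])
    frac = labels.value_counts(normalize=True)
    ddg_frac = stats.class_fractions(exp_mis.events)
    rio.write_report(
        {"fitness_fractions": frac.to_dict(), "ddg_fractions": ddg_frac},
        OUT / "fitness_vs_stability.json",
    )
    print("\nfitness classes vs stability classes:")
    print("  fitness:  " + ", ".join(f"{k} {v:.1%}" for k, v in frac.items()))
    print("  stability: " + ", ".join(f"{k} {v:.1%}" for k, v in ddg_frac.items()))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
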