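#!/usr/bin/env python
"""Structure of the standard genetic code, before any data.

Enumerates all single-base substitution events of the 61 sense codons,
counts the ordered amino-acid mutations reachable at each codon position,
tabulates degeneracy and synonymy, and correlates the published
per-position mean ddG with the translation-error frequencies.

Writes results/code_structure/ and prints the headline numbers.
"""

from pathlib import Path

from robustome import genetic_code as gc, io as rio, pipeline, stats

OUT = Path(__file__).resolve().parent.parent / "results" / "code_structure"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    results = pipeline.code_analysis()

    reach = results["reachable_per_position"]
    print("Ordered amino-acid mutations reachable per codon position")
    print("(synonymous and stop-involving events excluded):")
    for label, n in reach.items():
        print(f"  base {label:>3}: {n}")
    print(f"mu-SBS pairs (union over positions): {results['n_mu_sbs_pairs']} "
          f"of {results['n_aa_pairs']} ordered pairs")
    print("Base III reaches by far the fewest non-synonymous mutations; the")
    print("seven base-III pairs are Phe-Leu, Ile-Met, His-Gln, Asn-Lys,")
    print("Asp-Glu, Cys-Trp and Ser-Arg, each in both directions.")

    syn_total = sum(gc.synonymous_count(c) for c in gc.SENSE_CODONS)
    print(f"\nSynonymous single-base events over all sense codons: {syn_total} "
          f"of {61 * 9}")

    # published per-position means (with synonymous mutations and path
    # degeneracy) against the translation-error frequencies
    means = (0.64, 0.91, 0.16)
    freqs = (31.3, 6.2, 62.5)
    corr = stats.pearson(freqs, means)
    print(f"\nPearson r, per-position mean ddG vs translation-error frequency: "
          f"{corr.r:.3f} (p = {corr.p_value:.3f})")
    print("The least error-prone position (II) is also the most destabilizing")
    print("one to substitute: the code is shaped to absorb translation errors.")

    rio.write_tsv(results["degeneracy_table"], OUT / "degeneracy.tsv")
    rio.write_tsv(results["synonymous_counts"], OUT / "synonymous_counts.tsv")
    gc.export_code_table(OUT / "code_table.tsv")
    rio.write_report(
        {"reachable_per_position": reach,
         "n_mu_sbs_pairs": results["n_mu_sbs_pairs"],
         "position_error_correlation": corr},
        OUT / "summary.json",
    )
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
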