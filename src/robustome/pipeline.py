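"""End-to-end analysis: from residue + ddG tables to the full table suite.

``full_analysis`` reproduces the complete set of robustness statistics on
one dataset: core/surface and SBS-versus-MBS summaries, per-codon-position
means under both weighting schemes, translation-error-weighted class
fractions, BLOSUM62 stratification with its correlation, wild-type-base
and transition/transversion summaries, used-versus-synonymous codon
deltas (overall, per position, per RSA stratum, and stratified by
codon-usage bias), GC-content deltas, hydrophobicity correlations, RSA
profiles and per-protein/composition summaries, and (when fitness data
are present) the deleterious/neutral/advantageous fractions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import annotate, genetic_code as gc, stats
from .stats import CodonUsageTable

log = logging.getLogger("robustome")


def bias_stratified_delta(
    residues: pd.DataFrame,
    mutations: pd.DataFrame,
    usage: CodonUsageTable,
    weighting="random",
    mode: str = "equiprobability",
) -> pd.DataFrame:
    """Used-versus-synonymous delta split by the used codon's bias label."""
    labels = residues["wt_codon"].map(
        lambda c: stats.bias_classify(c, usage, mode=mode)
        if len(gc.CODONS_FOR_AA[gc.CODON_TO_AA[c]]) >= 2
        else None
    )
    rows = []
    for label in ("biased", "unbiased"):
        sub = residues[labels == label]
        if sub.empty:
            rows.append({"bias": label, "delta_pct": np.nan, "n_residues": 0})
            continue
        d = stats.codon_usage_delta(sub, mutations, weighting=weighting)
        rows.append({"bias": label, "delta_pct": d.delta_pct, "n_residues": d.n_residues})
    return pd.DataFrame(rows)


def full_analysis(
    residues: pd.DataFrame,
    mutations: pd.DataFrame,
    usage: CodonUsageTable | None = None,
    fitness: pd.DataFrame | None = None,
    include_mbs: bool = True,
    bias_mode: str = "equiprobability",
) -> dict:
    """Run every statistic of the pipeline; returns a name -> table dict."""
    results: dict = {}

    exp_syn = annotate.expand_events(residues, mutations, include_synonymous=True)
    exp_mis = annotate.expand_events(residues, mutations, include_synonymous=False)
    log.info(
        "expanded %d residues: %d synonymous, %d missense, %d nonsense excluded, %d gaps",
        exp_syn.n_residues, exp_syn.n_synonymous, exp_syn.n_missense,
        exp_syn.n_nonsense, exp_syn.n_gap_dropped,
    )
    ev_syn, ev_mis = exp_syn.events, exp_mis.events
    results["expansion"] = {
        "n_residues": exp_syn.n_residues,
        "n_synonymous": exp_syn.n_synonymous,
        "n_missense": exp_syn.n_missense,
        "n_nonsense": exp_syn.n_nonsense,
        "n_gap_dropped": exp_syn.n_gap_dropped,
        "conserved": exp_syn.conserves_counts(),
    }

    # core/surface summaries of single-base (missense) mutations
    rsa_rows = stats.summarize(ev_mis, "rsa_stratum")
    pooled = stats.summarize(ev_mis.assign(rsa_stratum="all"), "rsa_stratum")
    results["sbs_by_region"] = pd.concat([pooled, rsa_rows], ignore_index=True)

    if include_mbs:
        mbs = annotate.expand_mbs_events(residues, mutations, include_synonymous=False)
        mu_mbs = stats.add_mu_class(mbs.events)
        mu_mbs = mu_mbs[mu_mbs["mu_class"] == "mu_mbs"]
        if not mu_mbs.empty:
            mbs_rows = stats.summarize(mu_mbs, "rsa_stratum")
            mbs_pooled = stats.summarize(mu_mbs.assign(rsa_stratum="all"), "rsa_stratum")
            results["mbs_by_region"] = pd.concat([mbs_pooled, mbs_rows], ignore_index=True)
            results["by_position_set"] = stats.summarize(
                pd.concat(
                    [
                        ev_mis.assign(position_set=ev_mis["codon_position"].map(
                            gc.POSITION_LABELS)),
                        mbs.events,
                    ],
                    ignore_index=True,
                )[["position_set", "ddg"]],
                "position_set",
            )

    # codon-position means under both weighting schemes
    results["position_means_with_syn"] = stats.position_means(
        ev_syn, "with_syn_and_degeneracy")
    results["position_means_without"] = stats.position_means(ev_mis, "without")
    results["class_fractions_random"] = stats.weighted_class_fractions(
        ev_syn, stats.RANDOM_MUTATION_FREQS)
    results["class_fractions_translation"] = stats.weighted_class_fractions(
        ev_syn, stats.TRANSLATION_ERROR_FREQS)

    # correlation of per-position means with translation-error frequencies
    pm = results["position_means_with_syn"]
    results["position_error_correlation"] = stats.pearson(
        [f * 100 for f in stats.TRANSLATION_ERROR_FREQS], pm["mean_ddg"].to_numpy()
    )

    # BLOSUM62 stratification
    bl = stats.add_blosum(ev_mis)
    blosum_table = stats.summarize(bl, "blosum62")
    results["by_blosum"] = blosum_table
    if len(blosum_table) >= 3:
        results["blosum_correlation"] = stats.pearson(
            blosum_table["blosum62"].to_numpy(), blosum_table["mean_ddg"].to_numpy()
        )

    # wild-type base and transition/transversion stratification
    results["by_wt_base"] = stats.summarize(ev_mis, "wt_base")
    results["titv_with_syn"] = stats.titv_means(ev_syn, include_synonymous=True)
    results["titv_without_syn"] = stats.titv_means(ev_mis, include_synonymous=False)

    # hydrophobicity correlations of base content (pure code-level statistic)
    results["base_hydrophobicity"] = pd.DataFrame(
        [
            {"base": b, "r": c.r, "p_value": c.p_value, "n": c.n}
            for b in gc.BASES
            for c in [stats.hydrophobicity_correlation(b)]
        ]
    )

    # RSA, protein length, composition
    results["rsa_profile"] = stats.rsa_profile(ev_mis)
    results["protein_summary"] = stats.protein_summary(ev_mis)
    results["composition"] = stats.composition_profile(residues)

    # used versus synonymous codons
    rows = []
    for name, kwargs in (
        ("I", {"position": 1}),
        ("II", {"position": 2}),
        ("III", {"position": 3}),
        ("random", {"weighting": "random"}),
        ("translation", {"weighting": "translation"}),
    ):
        for stratum in ("all", "core", "surface"):
            d = stats.codon_usage_delta(residues, mutations, stratum=stratum, **kwargs)
            rows.append({"scheme": name, "stratum": stratum, "delta_pct": d.delta_pct,
                         "n_residues": d.n_residues})
    results["codon_usage_delta"] = pd.DataFrame(rows)
    results["gc_delta"] = stats.gc_delta(residues)

    if usage is not None:
        results["bias_labels"] = stats.classify_usage_table(usage, mode=bias_mode)
        results["bias_delta"] = pd.concat(
            [
                bias_stratified_delta(residues, mutations, usage,
                                      weighting=w, mode=bias_mode).assign(scheme=w)
                for w in ("random", "translation")
            ],
            ignore_index=True,
        )

    if fitness is not None:
        labels = stats.fitness_classify_series(
            fitness["fitness"], fitness["wt_score"], fitness["lof_score"]
        )
        frac = labels.value_counts(normalize=True)
        results["fitness_fractions"] = {
            k: float(frac.get(k, 0.0)) for k in ("deleterious", "neutral", "advantageous")
        }

    return results


def code_analysis() -> dict:
    """Pure genetic-code statistics needing no data.

    Reachability of amino-acid mutations per codon position (ordered
    pairs, stop-involving events excluded), the mu-SBS pair count, and the
    per-codon degeneracy/synonymy table.
    """
    reach = {
        gc.POSITION_LABELS[p]: len(gc.reachable_aa_mutations(p)) for p in (1, 2, 3)
    }
    deg_rows = []
    for codon in gc.SENSE_CODONS:
        targets = {}
        for ev in gc.sbs_events(codon):
            if ev.event_class == "missense":
                targets[ev.target_aa] = targets.get(ev.target_aa, 0) + 1
        for aa, k in sorted(targets.items()):
            deg_rows.append(
                {"codon": codon, "wt_aa": gc.CODON_TO_AA[codon], "mut_aa": aa,
                 "degeneracy": k}
            )
    return {
        "reachable_per_position": reach,
        "n_mu_sbs_pairs": len(gc.mu_sbs_pairs()),
        "n_aa_pairs": 20 * 19,
        "degeneracy_table": pd.DataFrame(deg_rows),
        "synonymous_counts": pd.DataFrame(
            [{"codon": c, "aa": gc.CODON_TO_AA[c], "n_synonymous": gc.synonymous_count(c)}
             for c in gc.SENSE_CODONS]
        ),
    }
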