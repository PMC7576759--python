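"""Synthetic structurome generator.

Emulates the statistical structure of a curated X-ray structurome
subjected to exhaustive in silico mutagenesis, so that every stage of the
analysis pipeline can be exercised and checked by parameter recovery:

* protein lengths are log-normal;
* each residue is core (RSA <= 20%) or surface, with the core fraction
  rising with protein length (multi-domain packing);
* RSA within each stratum follows a scaled Beta distribution (buried
  residues concentrated near 0, exposed ones spread over 20-100%);
* core composition is enriched in Val/Ile/Leu/Phe with a length-bin
  dependent hydrophobic fraction (defaults 0.45 / 0.41 / 0.37);
* codons are drawn from biased within-family frequencies (one preferred
  codon per family, bias strength = relative deviation of the
  non-preferred codons from equiprobability);
* ddG of an amino-acid mutation is linear in burial (1 - RSA/100),
  wild-type hydrophobicity (Kyte-Doolittle) and amino-acid dissimilarity
  (negated, rescaled BLOSUM62), plus Gaussian noise.  By default the
  intercept and burial slope are calibrated on the sampled covariates so
  the core and surface mean ddG of single-base-reachable mutations equal
  the 1.09 / 0.49 kcal/mol anchors exactly in the systematic part;
* fitness is a logistic transform of ddG between the loss-of-function
  and wild-type scores.

ddG is generated per amino-acid mutation (not per base-change path) and
every residue carries a ddG row for each of its 19 possible target amino
acids, so single- and multiple-base analyses share one table.  A single
master seed drives independent substreams per table, so adding a table
does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .stats import (
    CodonUsageTable,
    KYTE_DOOLITTLE,
    LENGTH_BIN_LABELS,
    blosum62,
    length_bin,
)

HYDROPHOBIC = ("F", "I", "L", "V")
NON_HYDROPHOBIC = tuple(aa for aa in gc.AMINO_ACIDS if aa not in HYDROPHOBIC)


class ConfigError(ValueError):
    """Infeasible generator configuration, detected before sampling."""


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic structurome (see module docstring)."""

    n_proteins: int = 200
    # log-normal protein length; median 215 with sigma 0.55 gives a mean
    # length near 250, i.e. ~50,000 residues for 200 proteins
    length_median: float = 215.0
    length_sigma: float = 0.55
    length_min: int = 30
    # probability that a residue is core, per protein-length bin
    core_frac_by_bin: dict = field(
        default_factory=lambda: {"<=200": 0.22, "200-400": 0.28, ">400": 0.33}
    )
    # Beta shapes of the RSA mixture components
    rsa_core_shapes: tuple = (1.3, 2.2)  # scaled to [0, 20]
    rsa_surface_shapes: tuple = (1.1, 1.5)  # scaled to [20, 100]
    # P(Val/Ile/Leu/Phe) for core residues per length bin, and for surface
    core_hydrophobic_frac: dict = field(
        default_factory=lambda: {"<=200": 0.45, "200-400": 0.41, ">400": 0.37}
    )
    surface_hydrophobic_frac: float = 0.15
    # relative deviation of non-preferred codons from family equiprobability
    codon_bias: float = 0.25
    # ddG model: beta0 + beta1*burial + beta2*kd(wt) + beta3*dissim(wt,mut)
    beta0: float | None = None  # None -> calibrated to the anchors
    beta1: float | None = None
    beta2: float = 0.06
    beta3: float = 1.5
    noise_sd: float = 1.0  # kcal/mol
    core_mean_anchor: float = 1.09  # kcal/mol, mean ddG of core SBS mutations
    surface_mean_anchor: float = 0.49
    # fitness = wt * logistic(gamma * (midpoint - ddg) + noise)
    wt_score: float = 1.0
    lof_score: float = 0.0
    fitness_gamma: float = 2.5
    fitness_midpoint: float = 0.8  # kcal/mol
    fitness_noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 0 <= self.codon_bias < 1:
            raise ConfigError("codon_bias must be in [0, 1)")
        for name, probs in (
            ("core_frac_by_bin", self.core_frac_by_bin),
            ("core_hydrophobic_frac", self.core_hydrophobic_frac),
        ):
            if set(probs) != set(LENGTH_BIN_LABELS):
                raise ConfigError(f"{name} must have keys {LENGTH_BIN_LABELS}")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ConfigError(f"{name} probabilities must lie in [0, 1]")
        if not 0 <= self.surface_hydrophobic_frac <= 1:
            raise ConfigError("surface_hydrophobic_frac must lie in [0, 1]")
        if self.noise_sd < 0 or self.fitness_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if (self.beta0 is None) != (self.beta1 is None):
            raise ConfigError("beta0 and beta1 must both be set or both be None")


@dataclass
class SyntheticDataset:
    """Generated residue, ddG, fitness and codon-usage tables."""

    residues: pd.DataFrame
    mutations: pd.DataFrame
    fitness: pd.DataFrame
    usage: CodonUsageTable
    provenance: dict

    def checksum(self) -> str:
        """SHA-256 over the canonical TSV serialization of the tables."""
        h = hashlib.sha256()
        for df in (self.residues, self.mutations, self.fitness):
            h.update(df.to_csv(sep="\t", index=False).encode())
        h.update(json.dumps(self.usage.fractions, sort_keys=True).encode())
        return h.hexdigest()


def family_fractions(bias: float) -> dict[str, float]:
    """Within-family codon frequencies of the bias model.

    In a family of k codons the (alphabetically first) preferred codon has
    frequency (1 + bias*(k-1))/k and every other codon (1 - bias)/k, so
    the non-preferred codons deviate from equiprobability by exactly
    ``bias`` in relative terms.
    """
    fractions = {}
    for family in gc.CODONS_FOR_AA.values():
        k = len(family)
        for i, codon in enumerate(sorted(family)):
            fractions[codon] = (1 + bias * (k - 1)) / k if i == 0 else (1 - bias) / k
    return fractions


def _dissimilarity_matrix() -> dict[tuple[str, str], float]:
    """Negated BLOSUM62 rescaled to [0, 1] over the off-diagonal range [-4, 3]."""
    b = blosum62()
    return {
        (wt, mut): (3.0 - b[(wt, mut)]) / 7.0
        for wt in gc.AMINO_ACIDS
        for mut in gc.AMINO_ACIDS
        if wt != mut
    }


def _sbs_reachable_lookup() -> dict[tuple[str, str], bool]:
    """(codon, target aa) -> reachable by a single base substitution."""
    out = {}
    for codon in gc.SENSE_CODONS:
        targets = {
            ev.target_aa for ev in gc.sbs_events(codon) if ev.event_class == "missense"
        }
        for aa in gc.AMINO_ACIDS:
            out[(codon, aa)] = aa in targets
    return out


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Sample a complete synthetic dataset; identical seeds give identical bytes."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_res, rng_ddg, rng_fit = (np.random.default_rng(s) for s in ss.spawn(3))

    # --- proteins ------------------------------------------------------
    lengths = np.maximum(
        config.length_min,
        np.round(
            np.exp(rng_res.normal(np.log(config.length_median), config.length_sigma,
                                  config.n_proteins))
        ).astype(int),
    )
    protein_ids = np.array([f"SYN{i + 1:04d}" for i in range(config.n_proteins)])
    bins = length_bin(lengths)

    # --- residues ------------------------------------------------------
    n_res = int(lengths.sum())
    prot_idx = np.repeat(np.arange(config.n_proteins), lengths)
    position = np.concatenate([np.arange(1, L + 1) for L in lengths])
    p_core = np.repeat([config.core_frac_by_bin[b] for b in bins], lengths)
    is_core = rng_res.random(n_res) < p_core
    a_c, b_c = config.rsa_core_shapes
    a_s, b_s = config.rsa_surface_shapes
    rsa = np.where(
        is_core,
        20.0 * rng_res.beta(a_c, b_c, n_res),
        20.0 + 80.0 * rng_res.beta(a_s, b_s, n_res),
    )
    rsa = np.round(rsa, 2)
    # the core/surface boundary is inclusive at 20%; rounding keeps it exact
    is_core = rsa <= 20.0

    p_hydro = np.where(
        is_core,
        np.repeat([config.core_hydrophobic_frac[b] for b in bins], lengths),
        config.surface_hydrophobic_frac,
    )
    hydro = rng_res.random(n_res) < p_hydro
    aa = np.where(
        hydro,
        np.array(HYDROPHOBIC)[rng_res.integers(0, len(HYDROPHOBIC), n_res)],
        np.array(NON_HYDROPHOBIC)[rng_res.integers(0, len(NON_HYDROPHOBIC), n_res)],
    )

    fractions = family_fractions(config.codon_bias)
    codon = np.empty(n_res, dtype="<U3")
    for amino in gc.AMINO_ACIDS:  # fixed order keeps the stream deterministic
        mask = aa == amino
        family = sorted(gc.CODONS_FOR_AA[amino])
        probs = np.array([fractions[c] for c in family])
        codon[mask] = rng_res.choice(family, size=int(mask.sum()), p=probs)

    residues = pd.DataFrame(
        {
            "protein_id": protein_ids[prot_idx],
            "position": position,
            "wt_aa": aa,
            "wt_codon": codon,
            "rsa": rsa,
            "protein_length": lengths[prot_idx],
        }
    )

    # --- ddG table (all 19 targets per residue) ------------------------
    n_mut = 19 * n_res
    aa_index = {a: i for i, a in enumerate(gc.AMINO_ACIDS)}
    targets = np.array(
        [[m for m in gc.AMINO_ACIDS if m != a] for a in gc.AMINO_ACIDS]
    )  # 20 x 19
    aa_idx = np.array([aa_index[a] for a in aa])
    mut_aa = targets[aa_idx].ravel()
    res_rep = np.repeat(np.arange(n_res), 19)
    burial = 1.0 - rsa[res_rep] / 100.0
    kd_vec = np.array([KYTE_DOOLITTLE[a] for a in gc.AMINO_ACIDS])
    kd_wt = np.repeat(kd_vec[aa_idx], 19)
    dis = _dissimilarity_matrix()
    dissim_mat = np.array(
        [[dis[(a, m)] for m in targets[i]] for i, a in enumerate(gc.AMINO_ACIDS)]
    )
    dissim = dissim_mat[aa_idx].ravel()
    systematic_part = config.beta2 * kd_wt + config.beta3 * dissim

    reach = _sbs_reachable_lookup()
    codon_index = {c: i for i, c in enumerate(gc.SENSE_CODONS)}
    reach_mat = np.array(
        [
            [reach[(c, m)] for m in targets[aa_index[gc.CODON_TO_AA[c]]]]
            for c in gc.SENSE_CODONS
        ]
    )  # 61 x 19, target order matching each codon's amino acid
    codon_ids = pd.Series(codon).map(codon_index).to_numpy()
    sbs_mask = reach_mat[codon_ids].ravel()
    core_mask = (rsa[res_rep] <= 20.0) & sbs_mask
    surf_mask = (rsa[res_rep] > 20.0) & sbs_mask

    if config.beta0 is None:
        # calibrate intercept and burial slope on the realized covariates so
        # the systematic stratum means of SBS-reachable mutations hit the
        # anchors exactly
        if not core_mask.any() or not surf_mask.any():
            raise ConfigError("cannot calibrate anchors: an RSA stratum is empty")
        bc, bs = burial[core_mask].mean(), burial[surf_mask].mean()
        sc, ssm = systematic_part[core_mask].mean(), systematic_part[surf_mask].mean()
        beta1 = (config.core_mean_anchor - config.surface_mean_anchor - (sc - ssm)) / (bc - bs)
        beta0 = config.core_mean_anchor - beta1 * bc - sc
    else:
        beta0, beta1 = config.beta0, config.beta1

    ddg = beta0 + beta1 * burial + systematic_part + rng_ddg.normal(0.0, config.noise_sd, n_mut)
    mutations = pd.DataFrame(
        {
            "protein_id": protein_ids[prot_idx][res_rep],
            "position": position[res_rep],
            "wt_aa": aa[res_rep],
            "mut_aa": mut_aa,
            "ddg": np.round(ddg, 4),
        }
    )

    # --- fitness (SBS-reachable mutations only, DMS-like) ---------------
    fit_noise = rng_fit.normal(0.0, config.fitness_noise_sd, int(sbs_mask.sum()))
    x = config.fitness_gamma * (config.fitness_midpoint - ddg[sbs_mask]) + fit_noise
    score = config.lof_score + (config.wt_score - config.lof_score) / (1.0 + np.exp(-x))
    fitness = pd.DataFrame(
        {
            "protein_id": mutations.loc[sbs_mask, "protein_id"].to_numpy(),
            "position": mutations.loc[sbs_mask, "position"].to_numpy(),
            "wt_aa": mutations.loc[sbs_mask, "wt_aa"].to_numpy(),
            "mut_aa": mutations.loc[sbs_mask, "mut_aa"].to_numpy(),
            "fitness": np.round(score, 4),
            "wt_score": config.wt_score,
            "lof_score": config.lof_score,
        }
    )

    # --- codon usage ----------------------------------------------------
    base_counts = {b: 0 for b in gc.BASES}
    for c, k in zip(*np.unique(codon, return_counts=True)):
        for b in c:
            base_counts[b] += int(k)
    total = sum(base_counts.values())
    usage = CodonUsageTable(
        organism="synthetic",
        fractions=fractions,
        nucleotide_freqs={b: base_counts[b] / total for b in gc.BASES},
    )

    provenance = {
        "config": {k: v for k, v in asdict(config).items()},
        "solved_beta0": float(beta0),
        "solved_beta1": float(beta1),
        "n_residues": n_res,
        "n_mutations": n_mut,
    }
    return SyntheticDataset(
        residues=residues,
        mutations=mutations,
        fitness=fitness,
        usage=usage,
        provenance=provenance,
    )


#: deterministic fixture configurations used throughout the test suite
FIXTURE_CONFIGS = {
    "small": GeneratorConfig(n_proteins=6, length_median=85.0, length_sigma=0.35, seed=101),
    "medium": GeneratorConfig(seed=202),
}

#: frozen SHA-256 checksums of the fixtures (regeneration must match)
FIXTURE_CHECKSUMS: dict[str, str] = {
    "small": "cca01ce8f207bfe02d962a285175c1b1272c5f488f271e2ba82065402f218f6d",
    "medium": "ce0ccc93014038678f7085181423bfbdb92e4a71c41c0af254cf2c212deb689a",
}


def make_fixture(name: str) -> SyntheticDataset:
    """Deterministic packaged datasets: ``small`` (~500 residues) for unit
    tests, ``medium`` (~50,000 residues) for statistical tests."""
    if name not in FIXTURE_CONFIGS:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_CONFIGS)}")
    return generate(FIXTURE_CONFIGS[name])
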