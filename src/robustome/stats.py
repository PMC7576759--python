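"""Stratified robustness statistics over annotated substitution events.

All statistics operate on the tidy event tables produced by
:mod:`robustome.annotate` (one row per single- or multiple-base
substitution event, carrying a ddG in kcal/mol, positive = destabilizing).

The module provides

* the stabilizing / neutral / destabilizing classification (thresholds
  at -0.5 and +0.5 kcal/mol, boundaries neutral),
* per-stratum summaries (count, mean, sd, class fractions) for any
  grouping column,
* per-codon-position means under the two weighting schemes (with or
  without synonymous events and path degeneracy),
* translation-error weighting of class fractions (per-position
  codon-anticodon mispairing frequencies 31.3% / 6.2% / 62.5%),
* transition/transversion means, BLOSUM62 stratification,
* used-versus-synonymous codon comparisons (normalized mean-ddG
  differences and GC-content deltas), codon-usage-bias labelling,
* RSA profiles with the piecewise (quadratic below 20%, linear above)
  fit, per-protein and composition summaries,
* fitness classification for deep-mutational-scanning scores, and
* Pearson correlation with zero-variance flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import stats as _sps

from . import genetic_code as gc
from .annotate import RSA_CORE_THRESHOLD, _sbs_template, rsa_class_series

# ---------------------------------------------------------------------------
# constants

DDG_STABILIZING_THRESHOLD = -0.5  # kcal/mol
DDG_DESTABILIZING_THRESHOLD = 0.5  # kcal/mol

#: per-position codon-anticodon mispairing frequencies (positions I, II, III)
TRANSLATION_ERROR_FREQS = (0.313, 0.062, 0.625)

#: uniform weights of the random-mutation model
RANDOM_MUTATION_FREQS = (1 / 3, 1 / 3, 1 / 3)

#: relative deviation from the expected family frequency above which a
#: codon counts as biased
BIAS_DEVIATION_THRESHOLD = 0.125

#: residues counted as hydrophobic in core-composition profiles
HYDROPHOBIC_CORE_RESIDUES = frozenset("VILF")

CLASS_LABELS = ("stabilizing", "neutral", "destabilizing")

LENGTH_BIN_LABELS = ("<=200", "200-400", ">400")


@lru_cache(maxsize=1)
def blosum62() -> dict[tuple[str, str], int]:
    """BLOSUM62 as a symmetric dict over the 20 standard amino acids."""
    m = substitution_matrices.load("BLOSUM62")
    return {
        (a, b): int(m[a][b])
        for a in gc.AMINO_ACIDS
        for b in gc.AMINO_ACIDS
    }


# ---------------------------------------------------------------------------
# classifications

def classify_ddg(ddg: float) -> str:
    """Stabilizing (< -0.5), neutral ([-0.5, 0.5]) or destabilizing (> 0.5)."""
    if not np.isfinite(ddg):
        raise ValueError(f"ddG must be finite, got {ddg!r}")
    if ddg < DDG_STABILIZING_THRESHOLD:
        return "stabilizing"
    if ddg > DDG_DESTABILIZING_THRESHOLD:
        return "destabilizing"
    return "neutral"


def classify_ddg_series(ddg: pd.Series) -> pd.Series:
    if not np.isfinite(ddg).all():
        raise ValueError("ddG must be finite")
    return pd.Series(
        np.select(
            [ddg < DDG_STABILIZING_THRESHOLD, ddg > DDG_DESTABILIZING_THRESHOLD],
            ["stabilizing", "destabilizing"],
            default="neutral",
        ),
        index=ddg.index,
    )


def fitness_classify(fitness: float, wt_score: float, lof_score: float) -> str:
    """Deleterious / neutral / advantageous for one fitness measurement.

    A mutation is deleterious when its fitness falls below the midpoint of
    the loss-of-function and wild-type scores, advantageous above 1.25x
    the wild-type score, and neutral in between (both boundaries neutral).
    """
    for v in (fitness, wt_score, lof_score):
        if not np.isfinite(v):
            raise ValueError("fitness scores must be finite")
    threshold_low = (lof_score + wt_score) / 2.0
    threshold_high = 1.25 * wt_score
    if threshold_low > threshold_high:
        raise ValueError(
            f"degenerate thresholds: (lof+wt)/2 = {threshold_low} > 1.25*wt = {threshold_high}"
        )
    if fitness < threshold_low:
        return "deleterious"
    if fitness > threshold_high:
        return "advantageous"
    return "neutral"


def fitness_classify_series(fitness: pd.Series, wt_score, lof_score) -> pd.Series:
    low = (np.asarray(lof_score) + np.asarray(wt_score)) / 2.0
    high = 1.25 * np.asarray(wt_score)
    if np.any(low > high):
        raise ValueError("degenerate fitness thresholds")
    return pd.Series(
        np.select([fitness < low, fitness > high], ["deleterious", "advantageous"], "neutral"),
        index=fitness.index,
    )


# ---------------------------------------------------------------------------
# stratum summaries

def summarize(events: pd.DataFrame, by, categories=None) -> pd.DataFrame:
    """Per-stratum count, mean/sd ddG and class fractions.

    *by* is a column name (or list of names) of *events*.  When
    *categories* is given, missing strata are reported as n = 0 rows with
    undefined means rather than silently dropped.
    """
    if events.empty and categories is None:
        raise ValueError("cannot summarize an empty event table")
    df = events.copy()
    df["ddg_class"] = classify_ddg_series(df["ddg"])
    keys = [by] if isinstance(by, str) else list(by)

    def _one(g: pd.DataFrame) -> pd.Series:
        frac = g["ddg_class"].value_counts(normalize=True)
        return pd.Series(
            {
                "n": len(g),
                "mean_ddg": g["ddg"].mean(),
                "sd_ddg": g["ddg"].std(ddof=1),
                "frac_stabilizing": frac.get("stabilizing", 0.0),
                "frac_neutral": frac.get("neutral", 0.0),
                "frac_destabilizing": frac.get("destabilizing", 0.0),
            }
        )

    out = df.groupby(keys, observed=True).apply(_one, include_groups=False)
    if categories is not None:
        out = out.reindex(categories)
        out["n"] = out["n"].fillna(0)
    out["n"] = out["n"].astype(int)
    return out.reset_index()


def class_fractions(events: pd.DataFrame) -> dict[str, float]:
    """Pooled stabilizing/neutral/destabilizing fractions of an event table."""
    frac = classify_ddg_series(events["ddg"]).value_counts(normalize=True)
    return {label: float(frac.get(label, 0.0)) for label in CLASS_LABELS}


def position_means(events: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Mean ddG per codon position under the two weighting schemes.

    mode ``"with_syn_and_degeneracy"`` averages over all non-nonsense
    order-1 events as they stand (synonymous events contribute 0 and
    degenerate paths contribute multiply); it requires an expansion made
    with include_synonymous=True.  mode ``"without"`` averages over
    distinct (residue, amino-acid mutation, position) triples, i.e. drops
    synonymous events and collapses path degeneracy.
    """
    if mode not in ("with_syn_and_degeneracy", "without"):
        raise ValueError(f"unknown mode {mode!r}")
    flag = events.attrs.get("include_synonymous")
    if mode == "with_syn_and_degeneracy" and flag is False:
        raise ValueError("mode 'with_syn_and_degeneracy' needs include_synonymous=True expansion")
    df = events
    if mode == "without":
        df = df[df["event_class"] == "missense"].drop_duplicates(
            ["protein_id", "position", "mut_aa", "codon_position"]
        )
    out = (
        df.groupby("codon_position")["ddg"]
        .agg(n="size", mean_ddg="mean")
        .reindex([1, 2, 3])
    )
    out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()


def weighted_class_fractions(events: pd.DataFrame, weights=TRANSLATION_ERROR_FREQS) -> dict:
    """Class fractions with codon positions weighted by error frequency.

    fraction(c) = sum_p w_p * (class-c events at p / events at p).  With
    equal weights this reduces to the pooled-by-position average.  Empty
    positions with nonzero weight trigger renormalization over the
    populated positions (with a warning).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
        raise ValueError("weights must be 3 nonnegative frequencies summing to 1")
    df = events.copy()
    df["ddg_class"] = classify_ddg_series(df["ddg"])
    populated = [p for p in (1, 2, 3) if (df["codon_position"] == p).any()]
    missing = [p for p in (1, 2, 3) if p not in populated and w[p - 1] > 0]
    if missing:
        warnings.warn(
            f"no events at codon position(s) {missing}; renormalizing weights "
            "over populated positions",
            stacklevel=2,
        )
        keep = np.array([p - 1 for p in populated])
        w = np.zeros(3) + np.where(np.isin(np.arange(3), keep), w, 0.0)
        w = w / w.sum()
    out = {label: 0.0 for label in CLASS_LABELS}
    for p in populated:
        sub = df[df["codon_position"] == p]
        frac = sub["ddg_class"].value_counts(normalize=True)
        for label in CLASS_LABELS:
            out[label] += w[p - 1] * float(frac.get(label, 0.0))
    return out


def titv_means(events: pd.DataFrame, include_synonymous: bool = True) -> pd.DataFrame:
    """Mean ddG of transition versus transversion events (path degeneracy kept)."""
    df = events if include_synonymous else events[events["event_class"] == "missense"]
    out = (
        df.groupby("titv")["ddg"]
        .agg(n="size", mean_ddg="mean")
        .reindex(["transition", "transversion"])
    )
    out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()


# ---------------------------------------------------------------------------
# Pearson correlation

@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int
    valid: bool = True


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation; zero-variance inputs are flagged, not raised."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d vectors with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(r=float("nan"), p_value=float("nan"), n=len(x), valid=False)
    r, p = _sps.pearsonr(x, y)
    return PearsonResult(r=float(r), p_value=float(p), n=len(x))


def hydrophobicity_correlation(base: str) -> PearsonResult:
    """Correlation of a base's count in the 61 sense codons with Kyte-Doolittle.

    T-rich codons preferentially encode hydrophobic amino acids (positive
    r), A-rich codons polar ones (negative r).
    """
    if base not in gc.BASES:
        raise ValueError(f"not a nucleobase: {base!r}")
    counts = [codon.count(base) for codon in gc.SENSE_CODONS]
    scale = [KYTE_DOOLITTLE[gc.CODON_TO_AA[codon]] for codon in gc.SENSE_CODONS]
    return pearson(counts, scale)


# ---------------------------------------------------------------------------
# helper strata

def add_blosum(events: pd.DataFrame) -> pd.DataFrame:
    """Attach the BLOSUM62 score of the amino-acid mutation (missense only)."""
    b = blosum62()
    out = events.copy()
    mis = out["event_class"] == "missense"
    out["blosum62"] = np.nan
    out.loc[mis, "blosum62"] = [
        b[(wt, mut)] for wt, mut in zip(out.loc[mis, "wt_aa"], out.loc[mis, "mut_aa"])
    ]
    return out


def add_mu_class(events: pd.DataFrame) -> pd.DataFrame:
    """Label missense events mu_sbs / mu_mbs by SBS-reachability of the aa pair."""
    reachable = gc.mu_sbs_pairs()
    out = events.copy()
    mis = out["event_class"] == "missense"
    out["mu_class"] = None
    out.loc[mis, "mu_class"] = [
        "mu_sbs" if (wt, mut) in reachable else "mu_mbs"
        for wt, mut in zip(out.loc[mis, "wt_aa"], out.loc[mis, "mut_aa"])
    ]
    return out


def length_bin(length):
    """Protein-length bin: <=200, 200-400 (i.e. (200, 400]), >400.

    Scalar in, scalar out; array-like in, numpy array out (index-free, so
    it can be assigned to any frame).
    """
    arr = np.atleast_1d(np.asarray(length))
    out = np.select([arr <= 200, arr <= 400], LENGTH_BIN_LABELS[:2], LENGTH_BIN_LABELS[2])
    return out.item(0) if np.isscalar(length) else out


def add_length_bin(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["length_bin"] = length_bin(out["protein_length"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# codon usage

class CodonUsageError(ValueError):
    pass


@dataclass
class CodonUsageTable:
    """Within-family codon usage fractions for one organism.

    ``fractions`` maps each sense codon to its frequency among the
    synonymous codons of its amino acid (each family sums to 1).
    ``nucleotide_freqs`` (optional) are organism-wide base frequencies
    used for the nucleotide-frequency bias model.
    """

    organism: str
    fractions: dict[str, float]
    nucleotide_freqs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for aa, family in gc.CODONS_FOR_AA.items():
            missing = [c for c in family if c not in self.fractions]
            if missing:
                raise CodonUsageError(f"usage table missing codons {missing} of {aa}")
            total = sum(self.fractions[c] for c in family)
            if abs(total - 1.0) > 1e-6:
                raise CodonUsageError(
                    f"family of {aa} sums to {total:.8f}, expected 1 within 1e-6"
                )

    @classmethod
    def from_per_thousand(cls, organism: str, per_thousand: dict[str, float],
                          nucleotide_freqs=None) -> "CodonUsageTable":
        """Normalize Kazusa-style per-thousand frequencies within each family."""
        fractions = {}
        for family in gc.CODONS_FOR_AA.values():
            total = sum(per_thousand.get(c, 0.0) for c in family)
            if total <= 0:
                raise CodonUsageError(f"no usage data for family {family}")
            for c in family:
                fractions[c] = per_thousand.get(c, 0.0) / total
        return cls(organism=organism, fractions=fractions, nucleotide_freqs=nucleotide_freqs)

    def family(self, aa: str) -> tuple[str, ...]:
        return gc.CODONS_FOR_AA[aa]

    def expected_fraction(self, codon: str, mode: str = "equiprobability") -> float:
        aa = gc.translate(codon)
        family = self.family(aa)
        if mode == "equiprobability":
            return 1.0 / len(family)
        if mode == "nucleotide_freq":
            if not self.nucleotide_freqs:
                raise CodonUsageError("nucleotide_freq mode needs organism base frequencies")
            weights = {
                c: np.prod([self.nucleotide_freqs[b] for b in c]) for c in family
            }
            total = sum(weights.values())
            return float(weights[codon] / total)
        raise ValueError(f"unknown bias mode {mode!r}")


def bias_classify(codon: str, usage: CodonUsageTable, mode: str = "equiprobability") -> str:
    """Label a codon biased / unbiased by relative deviation from expectation.

    A codon is biased when its observed within-family frequency deviates
    from the expected one by more than 12.5% of the expected value.
    Single-codon families (Met, Trp) are undefined here.
    """
    aa = gc.translate(codon)
    family = gc.CODONS_FOR_AA[aa]
    if len(family) < 2:
        raise CodonUsageError(f"codon {codon} ({aa}) has a single-codon family")
    observed = usage.fractions[codon]
    expected = usage.expected_fraction(codon, mode=mode)
    deviation = abs(observed - expected) / expected
    return "biased" if deviation > BIAS_DEVIATION_THRESHOLD else "unbiased"


def classify_usage_table(usage: CodonUsageTable, mode: str = "equiprobability") -> pd.DataFrame:
    """Bias label for every codon of every multi-codon family."""
    rows = []
    for aa, family in gc.CODONS_FOR_AA.items():
        if len(family) < 2:
            continue
        for c in family:
            rows.append(
                {
                    "codon": c,
                    "aa": aa,
                    "observed": usage.fractions[c],
                    "expected": usage.expected_fraction(c, mode=mode),
                    "label": bias_classify(c, usage, mode=mode),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# used-versus-synonymous codon comparison

@dataclass
class CodonUsageDelta:
    """Normalized used-versus-synonymous mean-ddG difference (percent)."""

    delta_pct: float
    mean_used: float
    mean_syn: float
    sigma: float
    n_residues: int
    n_excluded: int  # residues of single-codon families (Met, Trp)
    n_gap_dropped: int = 0


def _position_weights(weighting) -> np.ndarray:
    if isinstance(weighting, str):
        if weighting == "random":
            return np.asarray(RANDOM_MUTATION_FREQS)
        if weighting == "translation":
            return np.asarray(TRANSLATION_ERROR_FREQS)
        raise ValueError(f"unknown weighting {weighting!r}")
    w = np.asarray(weighting, dtype=float)
    if w.shape != (3,) or abs(w.sum() - 1) > 1e-9:
        raise ValueError("weights must be 3 frequencies summing to 1")
    return w


def _pool_events(res: pd.DataFrame, codon_col: str, mutations: pd.DataFrame,
                 position, w: np.ndarray):
    """Expand events from the codons in *codon_col* and weight them.

    Weighting: within each (residue, source codon) block, positions share
    the per-position frequencies (renormalized over populated positions)
    and the events of one position split it equally; each block then
    carries the residue's per-codon weight ``codon_weight``.
    """
    ev = res.merge(
        _sbs_template().rename(columns={"wt_codon": codon_col}), on=codon_col, how="left"
    )
    ev = ev[ev["event_class"] != "nonsense"].copy()
    ev["ddg"] = np.nan
    # synonymous here means target equals the residue's amino acid, also for
    # events expanded from an alternative codon of the family
    syn = ev["mut_aa"] == ev["wt_aa"]
    ev.loc[syn, "ddg"] = 0.0
    mis = ~syn
    look = ev.loc[mis, ["protein_id", "position", "mut_aa"]].merge(
        mutations[["protein_id", "position", "mut_aa", "ddg"]],
        on=["protein_id", "position", "mut_aa"],
        how="left",
    )
    ev.loc[mis, "ddg"] = look["ddg"].to_numpy()
    n_gap = int(ev["ddg"].isna().sum())
    ev = ev[ev["ddg"].notna()]
    if position is not None:
        ev = ev[ev["codon_position"] == position]
    if ev.empty:
        return ev.assign(weight=1.0), n_gap
    ev["_wp"] = w[ev["codon_position"].to_numpy() - 1]
    block = ["_res_idx", codon_col]
    ev["_np"] = ev.groupby(block + ["codon_position"])["ddg"].transform("size")
    ev["weight"] = ev["_wp"] / ev["_np"]
    ev["weight"] /= ev.groupby(block)["weight"].transform("sum")
    ev["weight"] *= ev["codon_weight"].to_numpy()
    return ev, n_gap


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    w = w / w.sum()
    m = float(np.sum(w * x))
    return m, float(np.sum(w * (x - m) ** 2))


def codon_usage_delta(
    residues: pd.DataFrame,
    mutations: pd.DataFrame,
    weighting="random",
    stratum: str = "all",
    position: int | None = None,
) -> CodonUsageDelta:
    """(<ddG_syn> - <ddG_used>) / sigma for SBS events, as a percentage.

    The used pool expands order-1 events from each residue's actual codon;
    the synonymous pool expands them from every other codon of the same
    amino-acid family, each alternative codon weighted equally per residue
    (a codon-level counterfactual).  ddG is looked up by the target amino
    acid, synonymous events count 0, and sigma**2 is the sum of the two
    pools' (population) variances.  Positive values mean the used codon is
    the more robust one.
    """
    w = _position_weights(weighting)
    res = residues.copy()
    res["rsa_stratum"] = rsa_class_series(res["rsa"])
    if stratum != "all":
        if stratum not in ("core", "surface"):
            raise ValueError(f"unknown stratum {stratum!r}")
        res = res[res["rsa_stratum"] == stratum]
    family_size = res["wt_aa"].map(lambda aa: len(gc.CODONS_FOR_AA[aa]))
    n_excluded = int((family_size < 2).sum())
    res = res[family_size >= 2].reset_index(drop=True)
    if res.empty:
        raise ValueError("no residues from multi-codon families in the requested stratum")
    res["_res_idx"] = np.arange(len(res))
    res["codon_weight"] = 1.0

    used, gap_u = _pool_events(res, "wt_codon", mutations, position, w)

    family_rows = [
        {"wt_aa": aa, "alt_codon": c}
        for aa, fam in gc.CODONS_FOR_AA.items()
        if len(fam) >= 2
        for c in fam
    ]
    alt = res.drop(columns=["codon_weight"]).merge(pd.DataFrame(family_rows), on="wt_aa")
    alt = alt[alt["alt_codon"] != alt["wt_codon"]].copy()
    alt["codon_weight"] = 1.0 / alt.groupby("_res_idx")["alt_codon"].transform("size")
    syn, gap_s = _pool_events(alt, "alt_codon", mutations, position, w)

    if used.empty or syn.empty:
        raise ValueError("empty used or synonymous event pool (check position filter)")
    mean_u, var_u = _weighted_mean_var(used["ddg"].to_numpy(), used["weight"].to_numpy())
    mean_s, var_s = _weighted_mean_var(syn["ddg"].to_numpy(), syn["weight"].to_numpy())
    sigma = float(np.sqrt(var_u + var_s))
    return CodonUsageDelta(
        delta_pct=100.0 * (mean_s - mean_u) / sigma,
        mean_used=mean_u,
        mean_syn=mean_s,
        sigma=sigma,
        n_residues=len(res),
        n_excluded=n_excluded,
        n_gap_dropped=gap_u + gap_s,
    )


# ---------------------------------------------------------------------------
# GC content

_GC_FRACTION = {c: (c.count("G") + c.count("C")) / 3.0 for c in gc.ALL_CODONS}


@dataclass
class GcDelta:
    """Mean (GC_syn - GC_used) over residues, in percentage points."""

    mean_delta_pct: float
    n_residues: int
    n_excluded: int


def gc_delta(residues: pd.DataFrame, usage: CodonUsageTable | None = None) -> GcDelta:
    """Per-residue GC difference between synonymous and used codons.

    For each residue of a multi-codon family: mean GC fraction of the
    *other* codons of its family (usage-weighted when a usage table is
    given) minus the GC fraction of the used codon, averaged over residues
    and reported in percentage points.  Negative values mean the used
    codons are the GC-richer ones.
    """
    family_size = residues["wt_aa"].map(lambda aa: len(gc.CODONS_FOR_AA[aa]))
    n_excluded = int((family_size < 2).sum())
    res = residues[family_size >= 2]
    if res.empty:
        raise ValueError("no residues from multi-codon families")
    syn_mean = {}
    for aa, family in gc.CODONS_FOR_AA.items():
        if len(family) < 2:
            continue
        for c in family:
            others = [o for o in family if o != c]
            if usage is None:
                syn_mean[c] = float(np.mean([_GC_FRACTION[o] for o in others]))
            else:
                wts = np.array([usage.fractions[o] for o in others])
                if wts.sum() <= 0:
                    wts = np.ones_like(wts)
                syn_mean[c] = float(
                    np.average([_GC_FRACTION[o] for o in others], weights=wts)
                )
    delta = res["wt_codon"].map(syn_mean) - res["wt_codon"].map(_GC_FRACTION)
    return GcDelta(
        mean_delta_pct=100.0 * float(delta.mean()),
        n_residues=len(res),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# RSA and protein-level profiles

@dataclass
class RsaProfile:
    """Binned mean ddG versus RSA with the piecewise fit."""

    bins: pd.DataFrame  # bin_left, center, n, mean_ddg
    linear: dict | None  # slope, intercept, r2 on bins with left edge >= 20%
    quadratic: dict | None  # c2, c1, c0, r2 on bins with left edge < 20%
    bin_width: float = 1.0


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def rsa_profile(events: pd.DataFrame, bin_width: float = 1.0) -> RsaProfile:
    """Mean ddG per RSA bin plus the linear/quadratic piecewise fit.

    Bins are half-open [k*w, (k+1)*w) with RSA = 100 folded into the last
    bin.  The linear least-squares fit uses bins at or above the 20% core
    threshold, the second-degree polynomial the bins below it; a fit is
    omitted (None) when its side has fewer populated bins than fit
    parameters + 1.
    """
    rsa = events["rsa"].to_numpy()
    idx = np.minimum(np.floor(rsa / bin_width), np.ceil(100.0 / bin_width) - 1).astype(int)
    df = pd.DataFrame({"bin": idx, "ddg": events["ddg"].to_numpy()})
    bins = df.groupby("bin")["ddg"].agg(n="size", mean_ddg="mean").reset_index()
    bins["bin_left"] = bins["bin"] * bin_width
    bins["center"] = bins["bin_left"] + bin_width / 2.0
    bins = bins[["bin_left", "center", "n", "mean_ddg"]]

    surface = bins[bins["bin_left"] >= RSA_CORE_THRESHOLD]
    core = bins[bins["bin_left"] < RSA_CORE_THRESHOLD]
    linear = None
    if len(surface) >= 3:
        coef = np.polyfit(surface["center"], surface["mean_ddg"], 1)
        yhat = np.polyval(coef, surface["center"])
        linear = {
            "slope": float(coef[0]),
            "intercept": float(coef[1]),
            "r2": _r2(surface["mean_ddg"].to_numpy(), yhat),
        }
    quadratic = None
    if len(core) >= 4:
        coef = np.polyfit(core["center"], core["mean_ddg"], 2)
        yhat = np.polyval(coef, core["center"])
        quadratic = {
            "c2": float(coef[0]),
            "c1": float(coef[1]),
            "c0": float(coef[2]),
            "r2": _r2(core["mean_ddg"].to_numpy(), yhat),
        }
    return RsaProfile(bins=bins, linear=linear, quadratic=quadratic, bin_width=bin_width)


def protein_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Per-protein mean ddG, core-to-length ratio, length bin, surface mean.

    The core-to-length ratio is the number of distinct core residues seen
    in the events over the protein length.
    """
    residues = events.drop_duplicates(["protein_id", "position"])
    per_res = residues.groupby("protein_id").agg(
        n_residues=("position", "size"),
        n_core=("rsa_stratum", lambda s: int((s == "core").sum())),
        protein_length=("protein_length", "first"),
    )
    per_ev = events.groupby("protein_id")["ddg"].mean().rename("mean_ddg")
    surf = (
        events[events["rsa_stratum"] == "surface"]
        .groupby("protein_id")["ddg"]
        .mean()
        .rename("mean_ddg_surface")
    )
    out = per_res.join(per_ev).join(surf)
    out["core_to_length"] = out["n_core"] / out["protein_length"]
    out["length_bin"] = length_bin(out["protein_length"].to_numpy())
    return out.reset_index()


def composition_profile(residues: pd.DataFrame) -> pd.DataFrame:
    """Hydrophobic (Val/Ile/Leu/Phe) fraction of core residues per length bin.

    Bins with no core residues are reported with n_core = 0 and an
    undefined fraction rather than dropped.
    """
    df = residues.copy()
    df["rsa_stratum"] = rsa_class_series(df["rsa"])
    df["length_bin"] = length_bin(df["protein_length"].to_numpy())
    core = df[df["rsa_stratum"] == "core"]
    out = (
        core.groupby("length_bin")
        .agg(
            n_core=("wt_aa", "size"),
            hydrophobic_fraction=("wt_aa", lambda s: s.isin(HYDROPHOBIC_CORE_RESIDUES).mean()),
        )
        .reindex(list(LENGTH_BIN_LABELS))
    )
    out["n_core"] = out["n_core"].fillna(0).astype(int)
    return out.reset_index()
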