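"""Join residue annotations with ddG tables and expand substitution events.

The pipeline's central join: each residue (protein, position, wild-type
codon, RSA) is expanded into its nine single-base substitution events,
nonsense events are excluded, synonymous events carry ddG = 0, and every
missense event is matched to the ddG of its amino-acid mutation.  ddG is
a property of the amino-acid mutation, not of the base-change path, so
the k degenerate paths to the same mutation share one ddG and appear k
times (degeneracy weighting by event multiplicity).

Tables are pandas DataFrames with the column layouts documented in
:mod:`robustome.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import genetic_code as gc

RSA_CORE_THRESHOLD = 20.0  # percent; rsa <= 20 is core
_RSA_CLAMP_TOLERANCE = 0.5  # values marginally above 100% are clamped

RESIDUE_COLUMNS = ["protein_id", "position", "wt_aa", "wt_codon", "rsa", "protein_length"]
MUTATION_COLUMNS = ["protein_id", "position", "wt_aa", "mut_aa", "ddg"]


class AnnotationError(ValueError):
    """Inconsistent residue/mutation annotations (names protein and position)."""


def rsa_class(rsa: float) -> str:
    """Classify an RSA percentage as ``core`` (<= 20%) or ``surface`` (> 20%)."""
    if not np.isfinite(rsa) or rsa < 0 or rsa > 100 + _RSA_CLAMP_TOLERANCE:
        raise ValueError(f"RSA out of range [0, 100]: {rsa!r}")
    return "core" if min(rsa, 100.0) <= RSA_CORE_THRESHOLD else "surface"


def rsa_class_series(rsa: pd.Series) -> pd.Series:
    bad = ~(np.isfinite(rsa) & (rsa >= 0) & (rsa <= 100 + _RSA_CLAMP_TOLERANCE))
    if bad.any():
        raise ValueError(f"RSA out of range [0, 100] for {int(bad.sum())} residues")
    return pd.Series(
        np.where(rsa.clip(upper=100.0) <= RSA_CORE_THRESHOLD, "core", "surface"),
        index=rsa.index,
    )


@lru_cache(maxsize=1)
def _sbs_template() -> pd.DataFrame:
    """61 x 9 table of all single-base events of the sense codons."""
    rows = []
    for codon in gc.SENSE_CODONS:
        for ev in gc.sbs_events(codon):
            rows.append(
                {
                    "wt_codon": ev.source,
                    "mut_codon": ev.target,
                    "codon_position": ev.positions[0],
                    "wt_base": ev.source[ev.positions[0] - 1],
                    "mut_base": ev.target[ev.positions[0] - 1],
                    "mut_aa": ev.target_aa,
                    "event_class": ev.event_class,
                    "titv": ev.titv,
                }
            )
    return pd.DataFrame(rows)


def validate_residues(residues: pd.DataFrame) -> None:
    """Check that every residue's codon translates to its amino acid."""
    trans = residues["wt_codon"].map(gc.CODON_TO_AA)
    if trans.isna().any():
        bad = residues.loc[trans.isna()].iloc[0]
        raise AnnotationError(
            f"invalid codon {bad['wt_codon']!r} at {bad['protein_id']}:{bad['position']}"
        )
    mism = trans != residues["wt_aa"]
    if mism.any():
        bad = residues.loc[mism].iloc[0]
        raise AnnotationError(
            f"codon {bad['wt_codon']} translates to {gc.CODON_TO_AA[bad['wt_codon']]}, "
            f"not {bad['wt_aa']}, at {bad['protein_id']}:{bad['position']}"
        )


@dataclass
class ExpansionResult:
    """Annotated events plus the bookkeeping needed for conservation checks."""

    events: pd.DataFrame
    gaps: pd.DataFrame  # missense events dropped for lack of a ddG row
    n_residues: int = 0
    n_synonymous: int = 0
    n_missense: int = 0
    n_nonsense: int = 0
    n_gap_dropped: int = 0
    include_synonymous: bool = True
    events_per_residue: int = 9  # 9 for SBS, 54 for the MBS position sets

    def conserves_counts(self) -> bool:
        """events/residue x residues = synonymous + missense + nonsense + gaps."""
        return (
            self.events_per_residue * self.n_residues
            == self.n_synonymous + self.n_missense + self.n_nonsense + self.n_gap_dropped
        )


EVENT_COLUMNS = [
    "protein_id", "position", "wt_aa", "wt_codon", "mut_codon", "codon_position",
    "wt_base", "mut_base", "mut_aa", "event_class", "titv", "ddg", "rsa",
    "rsa_stratum", "protein_length",
]


def expand_events(
    residues: pd.DataFrame,
    mutations: pd.DataFrame,
    include_synonymous: bool = True,
) -> ExpansionResult:
    """Expand each residue into its classified, ddG-bearing SBS events.

    Nonsense events are excluded (counted); synonymous events are included
    with ddg = 0 iff *include_synonymous*; missense events look up the ddG
    of their (protein, position, mutant amino acid) and are dropped into
    the gap report when no row exists.
    """
    validate_residues(residues)
    res = residues.copy()
    res["rsa_stratum"] = rsa_class_series(res["rsa"])

    ev = res.merge(_sbs_template(), on="wt_codon", how="left")
    n_nonsense = int((ev["event_class"] == "nonsense").sum())
    ev = ev[ev["event_class"] != "nonsense"]

    syn = ev[ev["event_class"] == "synonymous"].copy()
    syn["ddg"] = 0.0
    n_synonymous = len(syn)

    mis = ev[ev["event_class"] == "missense"].merge(
        mutations[["protein_id", "position", "mut_aa", "ddg"]],
        on=["protein_id", "position", "mut_aa"],
        how="left",
    )
    gap_mask = mis["ddg"].isna()
    gaps = (
        mis.loc[gap_mask, ["protein_id", "position", "wt_aa", "wt_codon", "mut_codon", "mut_aa"]]
        .reset_index(drop=True)
    )
    mis = mis[~gap_mask]

    parts = [mis] if not include_synonymous else [syn, mis]
    nonempty = [p for p in parts if not p.empty]
    if len(nonempty) > 1:
        events = pd.concat(nonempty, ignore_index=True)
    else:
        events = (nonempty[0] if nonempty else parts[0]).reset_index(drop=True)
    events = (
        events[EVENT_COLUMNS]
        .sort_values(["protein_id", "position", "codon_position", "mut_codon"], kind="stable")
        .reset_index(drop=True)
    )
    events.attrs["include_synonymous"] = include_synonymous
    return ExpansionResult(
        events=events,
        gaps=gaps,
        n_residues=len(res),
        n_synonymous=n_synonymous,
        n_missense=len(mis),
        n_nonsense=n_nonsense,
        n_gap_dropped=len(gaps),
        include_synonymous=include_synonymous,
    )


@lru_cache(maxsize=1)
def _mbs_template() -> pd.DataFrame:
    """All 2- and 3-position substitution events of the sense codons.

    Position-set classes I+II, I+III, II+III (9 events each) and I+II+III
    (27 events); every named position changes, keeping the classes
    disjoint from the single-base events.
    """
    rows = []
    for codon in gc.SENSE_CODONS:
        for pos_set in ((1, 2), (1, 3), (2, 3), (1, 2, 3)):
            for ev in gc.mbs_events(codon, pos_set):
                rows.append(
                    {
                        "wt_codon": ev.source,
                        "mut_codon": ev.target,
                        "position_set": ev.position_label,
                        "order": ev.order,
                        "mut_aa": ev.target_aa,
                        "event_class": ev.event_class,
                        "titv": ev.titv,
                    }
                )
    return pd.DataFrame(rows)


MBS_EVENT_COLUMNS = [
    "protein_id", "position", "wt_aa", "wt_codon", "mut_codon", "position_set",
    "order", "mut_aa", "event_class", "titv", "ddg", "rsa", "rsa_stratum",
    "protein_length",
]


def expand_mbs_events(
    residues: pd.DataFrame,
    mutations: pd.DataFrame,
    include_synonymous: bool = True,
) -> ExpansionResult:
    """Expand each residue into its multiple-base substitution events.

    Same contracts as :func:`expand_events` but over the four position-set
    classes I+II, I+III, II+III, I+II+III (54 events per residue before
    exclusions).  ddG is still a property of the amino-acid mutation, so
    an event is matched by its target amino acid regardless of how many
    bases changed.
    """
    validate_residues(residues)
    res = residues.copy()
    res["rsa_stratum"] = rsa_class_series(res["rsa"])

    ev = res.merge(_mbs_template(), on="wt_codon", how="left")
    n_nonsense = int((ev["event_class"] == "nonsense").sum())
    ev = ev[ev["event_class"] != "nonsense"]

    syn = ev[ev["event_class"] == "synonymous"].copy()
    syn["ddg"] = 0.0
    n_synonymous = len(syn)

    mis = ev[ev["event_class"] == "missense"].merge(
        mutations[["protein_id", "position", "mut_aa", "ddg"]],
        on=["protein_id", "position", "mut_aa"],
        how="left",
    )
    gap_mask = mis["ddg"].isna()
    gaps = (
        mis.loc[gap_mask, ["protein_id", "position", "wt_aa", "wt_codon", "mut_codon", "mut_aa"]]
        .reset_index(drop=True)
    )
    mis = mis[~gap_mask]

    parts = [syn, mis] if include_synonymous else [mis]
    nonempty = [p for p in parts if not p.empty]
    if len(nonempty) > 1:
        merged = pd.concat(nonempty, ignore_index=True)
    else:
        merged = (nonempty[0] if nonempty else parts[0]).reset_index(drop=True)
    events = (
        merged[MBS_EVENT_COLUMNS]
        .sort_values(["protein_id", "position", "position_set", "mut_codon"], kind="stable")
        .reset_index(drop=True)
    )
    events.attrs["include_synonymous"] = include_synonymous
    return ExpansionResult(
        events=events,
        gaps=gaps,
        n_residues=len(res),
        n_synonymous=n_synonymous,
        n_missense=len(mis),
        n_nonsense=n_nonsense,
        n_gap_dropped=len(gaps),
        include_synonymous=include_synonymous,
        events_per_residue=54,
    )


@dataclass
class CdsValidation:
    """Result of the gapless CDS-to-protein consistency check."""

    identity: float
    accepted: bool
    codon_map: list = field(default_factory=list)  # codon or None per residue
    mismatches: list = field(default_factory=list)  # 1-based mismatching positions


CDS_IDENTITY_THRESHOLD = 0.95


def validate_cds(protein_seq: str, cds: str) -> CdsValidation:
    """Positionally compare a CDS with a protein sequence.

    The CDS must be exactly 3x the protein length (a trailing stop codon
    is tolerated and ignored); the map is accepted iff at least 95% of
    codons translate to the stated residue.  Mismatching positions carry
    no codon in the returned map.  Gapped alignment is out of scope.
    """
    cds = cds.upper().replace("U", "T")
    protein_seq = protein_seq.upper()
    if len(cds) == 3 * len(protein_seq) + 3 and cds[-3:] in gc.STOP_CODONS:
        cds = cds[:-3]
    if len(cds) != 3 * len(protein_seq):
        raise ValueError(
            f"CDS length {len(cds)} does not match 3 x protein length {len(protein_seq)}"
        )
    codon_map: list = []
    mismatches: list = []
    n_match = 0
    for i, aa in enumerate(protein_seq):
        codon = cds[3 * i: 3 * i + 3]
        if gc.translate(codon) == aa:
            codon_map.append(codon)
            n_match += 1
        else:
            codon_map.append(None)
            mismatches.append(i + 1)
    identity = n_match / len(protein_seq) if protein_seq else 0.0
    return CdsValidation(
        identity=identity,
        accepted=identity >= CDS_IDENTITY_THRESHOLD,
        codon_map=codon_map,
        mismatches=mismatches,
    )
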