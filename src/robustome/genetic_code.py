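"""Combinatorics of the standard genetic code.

Everything here is pure, deterministic enumeration over the standard
(DNA-alphabet) codon table: translation, single- and multiple-base
substitution events, synonymy, degeneracy, transition/transversion
labelling, and position-restricted reachability of amino-acid mutations.

Conventions
-----------
* Codons are 3-letter uppercase DNA strings (``T``, not ``U``).
* Codon positions are 1, 2, 3 (displayed as Roman I, II, III).
* Amino acids are one-letter codes; ``*`` denotes a stop.
* Amino-acid mutations are ORDERED (wt, mut) pairs; this is what makes
  position-restricted reachability counts direction-sensitive.
* Events that create or depart a stop codon are enumerated but labelled
  (``nonsense`` / ``from_stop``) so that downstream robustness statistics
  can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable

from Bio.Data import CodonTable as _CodonTable
from Bio.SeqUtils import seq3 as _seq3

BASES: tuple[str, ...] = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

POSITION_LABELS = {1: "I", 2: "II", 3: "III"}
LABEL_TO_POSITION = {v: k for k, v in POSITION_LABELS.items()}

_STANDARD = _CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, '*' for the three stop codons
CODON_TO_AA: dict[str, str] = {
    **{c: aa for c, aa in _STANDARD.forward_table.items()},
    **{c: "*" for c in _STANDARD.stop_codons},
}

ALL_CODONS: tuple[str, ...] = tuple("".join(b) for b in product(BASES, repeat=3))
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(_STANDARD.forward_table.values())))

#: amino acid -> sorted tuple of its codons (synonymous family)
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa))
    for aa in AMINO_ACIDS
}

assert len(SENSE_CODONS) == 61 and len(STOP_CODONS) == 3
assert len(AMINO_ACIDS) == 20


class InvalidCodonError(ValueError):
    """Raised for strings that are not one of the 64 DNA codons."""


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in BASES for b in codon):
        raise InvalidCodonError(f"not a DNA codon: {codon!r}")
    return codon


def _check_aa(aa: str) -> str:
    if aa not in CODONS_FOR_AA:
        raise ValueError(f"not a standard amino acid: {aa!r}")
    return aa


def translate(codon: str) -> str:
    """Standard-code product of *codon*: a one-letter amino acid or ``'*'``."""
    return CODON_TO_AA[_check_codon(codon)]


def is_transition(b1: str, b2: str) -> bool:
    """True iff the base change b1->b2 conserves the chemical class.

    Transitions interchange purines (A<->G) or pyrimidines (C<->T);
    everything else is a transversion.
    """
    if b1 not in BASES or b2 not in BASES:
        raise ValueError(f"not nucleobases: {b1!r}, {b2!r}")
    if b1 == b2:
        raise ValueError("transition/transversion undefined for identical bases")
    return (b1 in PURINES) == (b2 in PURINES)


@dataclass(frozen=True)
class SubstitutionEvent:
    """One base-level change of a codon.

    ``positions`` is exactly the set of codon positions (1-based) where
    source and target differ; ``order`` is its size.  ``titv`` is
    ``"mixed"`` only for order >= 2 events combining both change types.
    """

    source: str
    target: str
    positions: tuple[int, ...]
    order: int
    source_aa: str
    target_aa: str
    event_class: str  # synonymous | missense | nonsense | from_stop
    titv: str  # transition | transversion | mixed

    @property
    def position_label(self) -> str:
        return "+".join(POSITION_LABELS[p] for p in self.positions)


def _classify(source: str, target: str) -> str:
    saa, taa = CODON_TO_AA[source], CODON_TO_AA[target]
    if saa == "*":
        return "from_stop"
    if taa == "*":
        return "nonsense"
    return "synonymous" if saa == taa else "missense"


def _titv(source: str, target: str, positions: tuple[int, ...]) -> str:
    kinds = {is_transition(source[p - 1], target[p - 1]) for p in positions}
    if kinds == {True}:
        return "transition"
    if kinds == {False}:
        return "transversion"
    return "mixed"


def _make_event(source: str, target: str) -> SubstitutionEvent:
    positions = tuple(i + 1 for i in range(3) if source[i] != target[i])
    return SubstitutionEvent(
        source=source,
        target=target,
        positions=positions,
        order=len(positions),
        source_aa=CODON_TO_AA[source],
        target_aa=CODON_TO_AA[target],
        event_class=_classify(source, target),
        titv=_titv(source, target, positions),
    )


@lru_cache(maxsize=None)
def sbs_events(codon: str) -> tuple[SubstitutionEvent, ...]:
    """All 9 single-base substitution events of *codon* (3 positions x 3 bases)."""
    _check_codon(codon)
    events = []
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            events.append(_make_event(codon, codon[:i] + b + codon[i + 1:]))
    return tuple(events)


def mbs_events(codon: str, positions: Iterable[int]) -> tuple[SubstitutionEvent, ...]:
    """All multiple-base substitution events changing exactly *positions*.

    Every named position must actually change, so a 2-position set yields
    3x3 = 9 events and the 3-position set 27; events in which a named
    position keeps its base belong to a lower-order class and are not
    produced here.
    """
    _check_codon(codon)
    pos = tuple(sorted(set(positions)))
    if len(pos) < 2 or any(p not in (1, 2, 3) for p in pos):
        raise ValueError(f"need a subset of {{1,2,3}} with >=2 positions, got {positions!r}")
    events = []
    alt = [[b for b in BASES if b != codon[p - 1]] for p in pos]
    for combo in product(*alt):
        target = list(codon)
        for p, b in zip(pos, combo):
            target[p - 1] = b
        events.append(_make_event(codon, "".join(target)))
    return tuple(events)


@dataclass(frozen=True)
class AAMutation:
    """An ordered amino-acid mutation and its minimum codon Hamming distance."""

    wt: str
    mut: str
    min_distance: int
    is_mu_sbs: bool


def aa_mutation_distance(wt: str, mut: str) -> AAMutation:
    """Minimum number of base changes between any codon of *wt* and of *mut*.

    Mutations at distance 1 are reachable by a single base substitution
    and form the mu-SBS subset of the 380 ordered amino-acid pairs.
    """
    _check_aa(wt)
    _check_aa(mut)
    if wt == mut:
        raise ValueError("wt and mut amino acids must differ")
    d = min(
        sum(a != b for a, b in zip(c1, c2))
        for c1 in CODONS_FOR_AA[wt]
        for c2 in CODONS_FOR_AA[mut]
    )
    return AAMutation(wt=wt, mut=mut, min_distance=d, is_mu_sbs=d == 1)


@lru_cache(maxsize=None)
def reachable_aa_mutations(position: int) -> frozenset[tuple[str, str]]:
    """Ordered amino-acid mutations reachable by substituting one codon position.

    Enumerates all single-base events at *position* over the 61 sense
    codons and collects the distinct ordered (wt, mut) pairs, dropping
    synonymous and stop-involving events.
    """
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position!r}")
    pairs = set()
    for codon in SENSE_CODONS:
        for ev in sbs_events(codon):
            if ev.positions == (position,) and ev.event_class == "missense":
                pairs.add((ev.source_aa, ev.target_aa))
    return frozenset(pairs)


def degeneracy(codon: str, target_aa: str) -> int:
    """Number of single-base substitutions of *codon* producing *target_aa*.

    0 means the amino-acid mutation is not reachable by any SBS from this
    codon.  For the synonymous count (target equals the codon's own amino
    acid) use :func:`synonymous_count`.
    """
    _check_aa(target_aa)
    if translate(codon) == target_aa:
        raise ValueError("target equals the wild-type amino acid; use synonymous_count")
    return sum(1 for ev in sbs_events(codon) if ev.target_aa == target_aa)


def synonymous_count(codon: str) -> int:
    """Number of synonymous single-base substitutions of a sense codon."""
    return sum(1 for ev in sbs_events(codon) if ev.event_class == "synonymous")


@lru_cache(maxsize=None)
def mu_sbs_pairs() -> frozenset[tuple[str, str]]:
    """All ordered amino-acid mutations reachable by some single base substitution."""
    return reachable_aa_mutations(1) | reachable_aa_mutations(2) | reachable_aa_mutations(3)


def code_table_rows() -> list[dict]:
    """The 64-row standard code table (codon, 3-letter, 1-letter, is_stop)."""
    rows = []
    for codon in ALL_CODONS:
        aa = CODON_TO_AA[codon]
        rows.append(
            {
                "codon": codon,
                "aa3": "Ter" if aa == "*" else _seq3(aa),
                "aa1": aa,
                "is_stop": aa == "*",
            }
        )
    return rows


def export_code_table(path) -> None:
    """Write the standard code table as a 64-row TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("codon\taa3\taa1\tis_stop\n")
        for row in code_table_rows():
            fh.write(f"{row['codon']}\t{row['aa3']}\t{row['aa1']}\t{str(row['is_stop']).lower()}\n")
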