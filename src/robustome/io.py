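"""Readers and writers for the pipeline's tabular formats.

All tables travel as UTF-8 TSV with a header row, '.' decimal separator
and no quoting; floats are serialized with ``repr`` precision so that a
write/read round trip reproduces the frame bit-exactly.  Codon usage is
accepted both as Kazusa-style text (codon, frequency per thousand,
optional count in parentheses) and as plain two-column TSV (codon,
within-family fraction).  Run configuration is YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import genetic_code as gc
from .stats import (
    CodonUsageTable,
    DDG_DESTABILIZING_THRESHOLD,
    DDG_STABILIZING_THRESHOLD,
    TRANSLATION_ERROR_FREQS,
)
from .annotate import MUTATION_COLUMNS, RESIDUE_COLUMNS, RSA_CORE_THRESHOLD

_DTYPES = {"position": int, "protein_length": int, "rsa": float, "ddg": float,
           "fitness": float, "wt_score": float, "lof_score": float}


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col, dt in _DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dt)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_residues(path) -> pd.DataFrame:
    return _read_tsv(path, RESIDUE_COLUMNS)


def read_mutations(path, flip_sign: bool = False) -> pd.DataFrame:
    """Read a ddG table; *flip_sign* converts stability-convention inputs
    (positive = stabilizing) to the folding convention used here."""
    df = _read_tsv(path, MUTATION_COLUMNS)
    if flip_sign:
        df["ddg"] = -df["ddg"]
    return df


def read_fitness(path) -> pd.DataFrame:
    return _read_tsv(path, ["protein_id", "position", "wt_aa", "mut_aa",
                            "fitness", "wt_score", "lof_score"])


def read_events(path) -> pd.DataFrame:
    return _read_tsv(path, ["protein_id", "position", "wt_codon", "mut_codon", "ddg"])


# ---------------------------------------------------------------------------
# codon usage

_KAZUSA_TOKEN = re.compile(
    r"([ACGTUacgtu]{3})\s+([0-9]+(?:\.[0-9]+)?)\s*(?:\(\s*([0-9]+)\s*\))?"
)


def parse_kazusa(text: str, organism: str = "unknown") -> CodonUsageTable:
    """Parse Kazusa-style codon usage text (per-thousand frequencies).

    Accepts both one-entry-per-line layouts and the compact
    ``UUU 17.6(714298)UUC 20.3(...)`` stream; RNA codons are converted to
    the DNA alphabet.  Within-family fractions are renormalized, and
    organism nucleotide frequencies are derived from the per-thousand
    values over all 61 sense codons.
    """
    per_thousand: dict[str, float] = {}
    for m in _KAZUSA_TOKEN.finditer(text):
        codon = m.group(1).upper().replace("U", "T")
        per_thousand[codon] = float(m.group(2))
    sense = {c: v for c, v in per_thousand.items() if c in gc.CODON_TO_AA
             and gc.CODON_TO_AA[c] != "*"}
    if not sense:
        raise ValueError("no codon usage entries found")
    base_weight = {b: 0.0 for b in gc.BASES}
    for c, v in sense.items():
        for b in c:
            base_weight[b] += v
    total = sum(base_weight.values())
    return CodonUsageTable.from_per_thousand(
        organism,
        sense,
        nucleotide_freqs={b: base_weight[b] / total for b in gc.BASES},
    )


def read_codon_usage(path, organism: str | None = None) -> CodonUsageTable:
    """Read codon usage from Kazusa text or a (codon, fraction) TSV."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header = text.splitlines()[0].lower() if text.strip() else ""
    if "codon" in header and ("fraction" in header or "frequency" in header):
        df = pd.read_csv(path, sep="\t")
        col = "fraction" if "fraction" in df.columns else "frequency"
        fractions = {
            str(c).upper().replace("U", "T"): float(v) for c, v in zip(df["codon"], df[col])
        }
        return CodonUsageTable(organism=organism or path.stem, fractions=fractions)
    return parse_kazusa(text, organism=organism or path.stem)


def write_codon_usage(usage: CodonUsageTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("codon\taa\tfraction\n")
        for codon in gc.SENSE_CODONS:
            fh.write(f"{codon}\t{gc.CODON_TO_AA[codon]}\t{usage.fractions[codon]!r}\n")


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path) -> dict[str, str]:
    """FASTA -> {record id: sequence} (protein or CDS)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults are the analysis constants."""

    residues: str | None = None
    mutations: str | None = None
    fitness: str | None = None
    codon_usage: str | None = None
    output_dir: str = "results"
    weighting: str = "random"  # random | translation
    include_synonymous: bool = True
    bias_mode: str = "equiprobability"  # equiprobability | nucleotide_freq
    rsa_threshold: float = RSA_CORE_THRESHOLD
    ddg_thresholds: tuple = (DDG_STABILIZING_THRESHOLD, DDG_DESTABILIZING_THRESHOLD)
    translation_error_freqs: tuple = TRANSLATION_ERROR_FREQS
    seed: int = 0
    flip_ddg_sign: bool = False


def load_run_config(path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown RunConfig key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for tup in ("ddg_thresholds", "translation_error_freqs"):
        setattr(cfg, tup, tuple(getattr(cfg, tup)))
    return cfg


def write_run_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# JSON reports

def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results: dict, path) -> None:
    """Serialize a results dict (DataFrames, dataclasses, scalars) as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
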