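"""Shared fixtures: deterministic synthetic datasets and toy tables."""

import pandas as pd
import pytest

from robustome import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """~600-residue dataset for unit-level pipeline tests."""
    return synthetic.make_fixture("small")


@pytest.fixture(scope="session")
def medium_dataset():
    """~50,000-residue dataset for statistical parameter-recovery tests."""
    return synthetic.make_fixture("medium")


def make_residue(protein_id="P1", position=1, codon="TTA", rsa=50.0, length=100):
    from robustome import genetic_code as gc

    return pd.DataFrame(
        [
            {
                "protein_id": protein_id,
                "position": position,
                "wt_aa": gc.translate(codon),
                "wt_codon": codon,
                "rsa": rsa,
                "protein_length": length,
            }
        ]
    )


def make_mutations(protein_id="P1", position=1, wt_aa="L", ddg_by_target=None):
    columns = ["protein_id", "position", "wt_aa", "mut_aa", "ddg"]
    return pd.DataFrame(
        [
            {
                "protein_id": protein_id,
                "position": position,
                "wt_aa": wt_aa,
                "mut_aa": mut,
                "ddg": ddg,
            }
            for mut, ddg in (ddg_by_target or {}).items()
        ],
        columns=columns,
    )
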