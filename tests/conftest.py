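import numpy as np
import pandas as pd
import pytest

from kiwisat import (
    ErrorModel,
    PopulationSpec,
    default_kiwi_panel,
    simulate_individuals,
    simulate_populations,
    simulate_replicates,
)
from kiwisat.panel import Locus, PanelDefinition


@pytest.fixture(scope="session")
def panel():
    return default_kiwi_panel()


@pytest.fixture(scope="session")
def small_panel():
    """Three autosomal loci + the sex locus, for hand-checkable tests."""
    return PanelDefinition(
        (
            Locus("L1", 2, (100, 120)),
            Locus("L2", 2, (140, 160)),
            Locus("L3", 4, (200, 240)),
            Locus("Z37B", 2, (92, 100), sex_linked=True),
        )
    )


@pytest.fixture(scope="session")
def five_species_specs():
    return [
        PopulationSpec("mantelli", "A. mantelli", "Western"),
        PopulationSpec("haastii", "A. haastii"),
        PopulationSpec("owenii", "A. owenii"),
        PopulationSpec("rowi", "A. rowi"),
        PopulationSpec("australis", "A. australis", "Haast"),
    ]


@pytest.fixture(scope="session")
def noisy_dataset(panel, five_species_specs):
    """A moderate simulated study: 2 populations, fecal-swab-like errors."""
    model = simulate_populations(
        panel,
        five_species_specs[:2],
        n_alleles=5,
        private_allele_plan={"mantelli": ["KMS1", "KMS2"]},
        seed=11,
    )
    truth = simulate_individuals(model, 25, seed=12)
    reps = simulate_replicates(
        truth, ErrorModel(fail_prob=0.06, ado_prob=0.17, fa_prob=0.01), panel, seed=13
    )
    return model, truth, reps


def make_replicate_frame(rows):
    """rows: (sample, locus, replicate, alleles tuple); metadata filled in."""
    return pd.DataFrame(
        [
            {
                "sample": s,
                "population": "pop1",
                "species": "A. mantelli",
                "locus": loc,
                "replicate": rep,
                "alleles": tuple(sorted(alleles)),
            }
            for s, loc, rep, alleles in rows
        ]
    )


def make_genotype_frame(rows):
    """rows: (sample, locus, a, b) with None for missing."""
    df = pd.DataFrame(
        [
            {
                "sample": s,
                "population": "pop1",
                "species": "A. mantelli",
                "locus": loc,
                "allele_a": a,
                "allele_b": b,
            }
            for s, loc, a, b in rows
        ]
    )
    df["allele_a"] = df["allele_a"].astype("Int64")
    df["allele_b"] = df["allele_b"].astype("Int64")
    return df
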