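"""Shared fixtures: small simulated datasets and hand-built site tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import probmsc as pm
from probmsc.sites import DivergentSiteTable, TABLE_COLUMNS


def make_table(rows: list[dict], polarized: bool = True) -> DivergentSiteTable:
    """Build a site table from compact row dicts; genotype defaults are 0
    (ancestral), alleles default A->G."""
    full = []
    for r in rows:
        base = {"locus_id": "L001", "pos": len(full) + 1,
                "allele_anc": "A", "allele_der": "G",
                "F": 0.0, "S": 0.0, "A": 0.0, "M": 0.0, "O": 0.0}
        base.update(r)
        full.append(base)
    return DivergentSiteTable(pd.DataFrame(full, columns=TABLE_COLUMNS), polarized=polarized)


@pytest.fixture(scope="session")
def default_model() -> pm.SpeciesTreeModel:
    return pm.SpeciesTreeModel()


@pytest.fixture(scope="session")
def small_sim() -> pm.SimulatedDataset:
    """60 loci, no mastodon damage: fast, clean substrate for most tests."""
    return pm.simulate_dataset(n_loci=60, seed=101, damage_rate=0.0)


@pytest.fixture(scope="session")
def study_sim() -> pm.SimulatedDataset:
    """Full study-design dataset: 375 loci with mastodon damage."""
    return pm.simulate_dataset(n_loci=375, seed=202, damage_rate=0.05)


@pytest.fixture(scope="session")
def study_table(study_sim) -> pm.DivergentSiteTable:
    """Polarized, recurrence-filtered site table of the study-design dataset."""
    table = pm.call_divergent_sites(study_sim.loci)
    table.meta["n_loci_simulated"] = len(study_sim.loci)
    return pm.filter_recurrent(pm.polarize(table))


@pytest.fixture(scope="session")
def study_polarized(study_sim) -> pm.DivergentSiteTable:
    """Polarized but unfiltered table (the demographic-fit substrate)."""
    return pm.polarize(pm.call_divergent_sites(study_sim.loci))
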