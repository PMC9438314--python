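"""Shared fixtures: toy metagenomes and cached synthetic cohorts."""

import pandas as pd
import pytest

import mucometa as mm


@pytest.fixture(scope="session")
def toy_frames():
    return mm.toy_figs2()


@pytest.fixture(scope="session")
def toy_combined(toy_frames):
    return pd.concat(toy_frames.values(), ignore_index=True)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort (n=41, 500 KOs/community), seed 1."""
    params = mm.CohortParams(seed=1)
    contigs, clinical, totals, truth = mm.generate_cohort(params)
    return {"contigs": contigs, "clinical": clinical, "totals": totals,
            "truth": truth}


@pytest.fixture(scope="session")
def default_tables(default_cohort):
    raw = mm.build_mfa(default_cohort["contigs"], default_cohort["totals"])
    norm = mm.normalize(raw)
    groups = mm.assign_size_groups(default_cohort["clinical"], 14)
    return {"raw": raw, "norm": norm, "groups": groups}


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort (200 KOs/community) for tests that loop over stages."""
    params = mm.CohortParams(seed=3, n_kos_per_community=200)
    contigs, clinical, totals, truth = mm.generate_cohort(params)
    return {"contigs": contigs, "clinical": clinical, "totals": totals,
            "truth": truth}


@pytest.fixture()
def mini_pathway_map():
    """Five tiny pathways over a 10-KO universe (ships as a test map)."""
    return mm.PathwayMap(
        pathways={
            "pw_glycan": frozenset({"K001", "K002", "K003"}),
            "pw_ribosome": frozenset({"K004", "K005"}),
            "pw_galactose": frozenset({"K002", "K006"}),
            "pw_oxphos": frozenset({"K007", "K008", "K009"}),
            "pw_pts": frozenset({"K010"}),
        },
        names={"pw_glycan": "Glycan degradation (synthetic)",
               "pw_ribosome": "Ribosome (synthetic)"},
    )
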