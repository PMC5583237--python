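"""Shared fixtures: hand-built miniature studies and seeded simulations."""

import numpy as np
import pandas as pd
import pytest

from lodemap import (GenotypeMatrix, GenotypeStudy, MarkerDef, PedigreeTable,
                     SimulationConfig, simulate_study)

M = -1  # missing genotype code


def make_study(codes, sample_rows, marker_ids=None, metadata=None):
    """Assemble a GenotypeStudy from a genotype array and pedigree rows.

    ``sample_rows`` is a list of (sample_id, sire, dam, sex, family,
    generation) tuples aligned with the rows of ``codes``.
    """
    codes = np.asarray(codes, dtype=np.int8)
    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(codes.shape[1])]
    ped = PedigreeTable(pd.DataFrame(
        sample_rows,
        columns=["sample_id", "sire_id", "dam_id", "sex", "family_id", "generation"],
    ))
    gm = GenotypeMatrix(codes, [r[0] for r in sample_rows], marker_ids)
    return GenotypeStudy([MarkerDef(m) for m in marker_ids], ped, gm,
                         metadata or {})


def trio_rows(n_progeny, family="F1", with_grandparents=False):
    """Pedigree rows for one full-sib family (optionally grandparent-traced)."""
    rows = []
    if with_grandparents:
        rows += [
            (f"{family}_GSP", "", "", "M", family, "grandparent"),
            (f"{family}_GDP", "", "", "F", family, "grandparent"),
            (f"{family}_GSM", "", "", "M", family, "grandparent"),
            (f"{family}_GDM", "", "", "F", family, "grandparent"),
            (f"{family}_S", f"{family}_GSP", f"{family}_GDP", "M", family, "parent"),
            (f"{family}_D", f"{family}_GSM", f"{family}_GDM", "F", family, "parent"),
        ]
    else:
        rows += [
            (f"{family}_S", "", "", "M", family, "parent"),
            (f"{family}_D", "", "", "F", family, "parent"),
        ]
    rows += [(f"{family}_P{i + 1}", f"{family}_S", f"{family}_D", "U", family,
              "progeny") for i in range(n_progeny)]
    return rows


@pytest.fixture(scope="session")
def small_sim():
    """A fast synthetic study with truth: 2 groups x 15 markers, 8 families."""
    config = SimulationConfig(
        n_lgs=2, markers_per_lg=15, lg_length=30.0, n_families=10,
        progeny_per_family=14, genotype_error_rate=0.0, missing_rate=0.0,
        seed=42,
    )
    return simulate_study(config)


@pytest.fixture(scope="session")
def small_sim_noisy():
    """Like small_sim but with realistic error/missingness and orphans."""
    config = SimulationConfig(
        n_lgs=2, markers_per_lg=15, lg_length=30.0, n_families=8,
        progeny_per_family=12, genotype_error_rate=0.002, missing_rate=0.02,
        orphan_holdout_fraction=0.1, seed=43,
    )
    return simulate_study(config)
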