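"""Shared fixtures: tiny hand-built objects and one seeded reference simulation.

The reference simulation (500-protein paired proteome, benchmark designs,
noise_cv 0.3) is session-scoped so the integration-level tests and the
acceptance tests share one run of each expensive stage.
"""

from __future__ import annotations

import numpy as np
import pytest

import xenoquant as xq
from xenoquant.digestion import IndexEntry, IndexParams, PeptideIndex
from xenoquant.species_assignment import Policy, PolicyView

REF_SEED = 20240901


def make_index(protein_peptides: dict[str, set[str]], species: dict[str, str] | None = None) -> PeptideIndex:
    """Build a PeptideIndex directly from protein -> peptide-key sets."""
    species = species or {p: "human" for p in protein_peptides}
    parents: dict[str, set[str]] = {}
    for pid, peps in protein_peptides.items():
        for k in peps:
            parents.setdefault(k, set()).add(pid)
    entries = {}
    for k, ids in parents.items():
        sp = {species[i] for i in ids}
        cls = (
            "common"
            if sp == {"human", "mouse"}
            else ("human_unique" if sp == {"human"} else "mouse_unique")
        )
        entries[k] = IndexEntry(frozenset(ids), cls)
    return PeptideIndex(
        entries=entries,
        params=IndexParams(),
        protein_peptides={p: tuple(sorted(s)) for p, s in protein_peptides.items()},
        species_of=species,
    )


def view_over(index: PeptideIndex, policy: Policy = Policy.FULL_PEPTIDE) -> PolicyView:
    """A PolicyView exposing every index peptide (for grouping unit tests)."""
    visible = frozenset(index.entries)
    attribution = {
        p: ("shared" if e.species_class == "common" else e.species_class.split("_")[0])
        for p, e in index.entries.items()
    }
    dbs = ("human", "mouse") if policy in (Policy.FULL_PEPTIDE, Policy.UNIQUE_PEPTIDE) else (
        ("human",) if policy is Policy.HUMAN_ONLY else ("mouse",)
    )
    return PolicyView(policy, visible, attribution, dbs)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def ref_pair():
    return xq.generate_paired_proteomes(500, 400, 0.012, seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_index(ref_pair):
    return xq.build_peptide_index(ref_pair)


@pytest.fixture(scope="session")
def cell_design():
    return xq.make_benchmark_designs()[0]


@pytest.fixture(scope="session")
def pdx_design():
    return xq.make_benchmark_designs()[1]


@pytest.fixture(scope="session")
def cell_experiment(ref_pair, ref_index, cell_design):
    return xq.simulate_mixture(ref_pair, ref_index, cell_design, seed=REF_SEED + 1)


@pytest.fixture(scope="session")
def cell_experiment_noise_free(ref_pair, ref_index, cell_design):
    return xq.simulate_mixture(
        ref_pair, ref_index, cell_design, noise_cv=0.0, seed=REF_SEED + 2
    )


@pytest.fixture(scope="session")
def pdx_experiment(ref_pair, ref_index, pdx_design):
    return xq.simulate_mixture(ref_pair, ref_index, pdx_design, seed=REF_SEED + 3)


@pytest.fixture(scope="session")
def cell_quant(ref_index, cell_experiment):
    return {
        p: xq.quantify(cell_experiment, ref_index, p)
        for p in ("full_peptide", "unique_peptide", "human_only")
    }


@pytest.fixture(scope="session")
def cell_thresholds(cell_quant, cell_design):
    return {
        p: xq.calibrate_thresholds(m, cell_design, 0.01) for p, m in cell_quant.items()
    }


@pytest.fixture(scope="session")
def cell_dep_counts(cell_quant, cell_thresholds, cell_design):
    return {
        p: xq.dep_count_matrix(cell_quant[p], cell_design, cell_thresholds[p])
        for p in ("full_peptide", "human_only")
    }


@pytest.fixture(scope="session")
def pdx_quant_full(ref_index, pdx_experiment):
    return xq.quantify(pdx_experiment, ref_index, "full_peptide")


@pytest.fixture(scope="session")
def zero_mouse_pdx(ref_pair, ref_index):
    """Noise-free 4-channel layout: two models, no mouse content anywhere."""
    channels = tuple(
        xq.Channel(xq.TMT16_CHANNELS[i], sid, 1.0, 1, grp)
        for i, (sid, grp) in enumerate(
            [("MA_orig", "MA"), ("MA_demo", "MA"), ("MB_orig", "MB"), ("MB_demo", "MB")]
        )
    )
    design = xq.MixtureDesign(channels)
    experiment = xq.simulate_mixture(
        ref_pair, ref_index, design, noise_cv=0.0, seed=REF_SEED + 4
    )
    matrix = xq.quantify(experiment, ref_index, "full_peptide")
    models = (
        xq.PdxModel("MA", "MA_orig", "MA_demo", 0.0, 0.0),
        xq.PdxModel("MB", "MB_orig", "MB_demo", 0.0, 0.0),
    )
    return matrix, design, models
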