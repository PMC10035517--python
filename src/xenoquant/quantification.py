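"""Protein grouping, unique/razor assignment, abundance roll-up, PSM ratio.

Grouping follows the parsimony style of mainstream search engines: proteins
whose visible peptide set is contained in another protein's set are absorbed
into that protein's group, and a group explaining no peptide beyond what
better-supported groups already explain is merged away (greedy cover).  The
master protein of a group is the member with the largest visible peptide
set; all tie-breaks are deterministic (peptide count, then unique-peptide
count, then lexicographic accession).

Peptides visible in exactly one group are *unique*; peptides shared between
groups become *razor* peptides assigned to the single best-supported group
(or are discarded wholesale under the unique-peptide policy).  Roll-up sums
the observed channel intensities of a group's assigned peptide keys — with
the origins of a peptide summed first, since the instrument cannot split a
reporter intensity between a human and a mouse parent.  That summation is
where the common-peptide artifact enters every policy that keeps common
peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestion import PeptideIndex
from .species_assignment import Policy, PolicyView
from .synthetic_proteome import MixtureExperiment, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ProteinGroup:
    master_id: str
    member_ids: set[str]
    #: union of members' visible peptide keys
    peptides: frozenset[str]
    unique_peptides: set[str] = field(default_factory=set)
    razor_peptides: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class QuantMatrix:
    """Protein x channel abundances plus per-protein PSM bookkeeping.

    ``meta`` columns: ``species`` (of the master), ``n_unique_psm`` (PSMs
    from peptides unique to the master's species), ``n_common_psm`` (PSMs
    from human-mouse common peptides).
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def human_proteins(self) -> pd.Index:
        return self.meta.index[self.meta["species"] == "human"]


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def _order_key(pid: str, pepset: frozenset[str]) -> tuple[int, str]:
    return (-len(pepset), pid)


def group_proteins(view: PolicyView, index: PeptideIndex) -> list[ProteinGroup]:
    """Parsimony protein grouping over the policy's visible peptides."""
    visible_sets: dict[str, frozenset[str]] = {}
    for pid, peps in index.protein_peptides.items():
        if index.species_of[pid] not in view.database_species:
            continue
        vis = frozenset(peps) & view.visible_peptides
        if vis:
            visible_sets[pid] = vis
    if not visible_sets:
        raise ParameterError("no protein has a visible peptide under this view")

    order = sorted(visible_sets, key=lambda p: _order_key(p, visible_sets[p]))

    # phase 1: absorb subset/equal peptide sets into the larger protein
    groups: list[ProteinGroup] = []
    for pid in order:
        pepset = visible_sets[pid]
        hosts = [g for g in groups if pepset <= visible_sets[g.master_id]]
        if hosts:
            host = min(
                hosts, key=lambda g: _order_key(g.master_id, visible_sets[g.master_id])
            )
            host.member_ids.add(pid)
        else:
            groups.append(ProteinGroup(master_id=pid, member_ids={pid}, peptides=pepset))

    # phase 2: greedy cover — accept groups by most still-unexplained
    # peptides; a group left with no unexplained peptide is merged into the
    # accepted group it shares most peptides with
    accepted: list[ProteinGroup] = []
    covered: set[str] = set()
    remaining = list(groups)
    while remaining:
        best = min(
            remaining,
            key=lambda g: (
                -len(visible_sets[g.master_id] - covered),
                -len(visible_sets[g.master_id]),
                g.master_id,
            ),
        )
        remaining.remove(best)
        master_set = visible_sets[best.master_id]
        if master_set <= covered:
            host = max(
                accepted,
                key=lambda a: (
                    len(visible_sets[a.master_id] & master_set),
                    len(visible_sets[a.master_id]),
                    a.master_id,
                ),
            )
            host.member_ids |= best.member_ids
        else:
            covered |= master_set
            accepted.append(best)
    accepted.sort(key=lambda g: _order_key(g.master_id, visible_sets[g.master_id]))

    # group peptide set = union over members (absorbed members may carry
    # peptides outside the master's own set after phase 2)
    for g in accepted:
        g.peptides = frozenset().union(*(visible_sets[m] for m in g.member_ids))
    return accepted


# ---------------------------------------------------------------------------
# peptide assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideAssignment:
    """peptide key -> (master accession or None, role)."""

    roles: dict[str, tuple[str | None, str]]  # role in {"unique","razor","discarded"}
    groups: list[ProteinGroup]
    policy: Policy


def assign_peptides(groups: list[ProteinGroup], view: PolicyView) -> PeptideAssignment:
    """Classify every visible peptide as unique, razor or discarded."""
    containing: dict[str, list[ProteinGroup]] = {}
    for g in groups:
        g.unique_peptides = set()
        g.razor_peptides = set()
        for p in g.peptides:
            containing.setdefault(p, []).append(g)

    # first pass: group-level unique peptides (needed for razor tie-breaks)
    for p, gs in containing.items():
        if len(gs) == 1:
            gs[0].unique_peptides.add(p)

    roles: dict[str, tuple[str | None, str]] = {}
    for p, gs in containing.items():
        if len(gs) == 1:
            roles[p] = (gs[0].master_id, "unique")
        elif view.policy is Policy.UNIQUE_PEPTIDE:
            roles[p] = (None, "discarded")
        else:
            best = min(
                gs,
                key=lambda g: (
                    -len(g.peptides),
                    -len(g.unique_peptides),
                    g.master_id,  # lexicographically smaller accession on full tie
                ),
            )
            best.razor_peptides.add(p)
            roles[p] = (best.master_id, "razor")
    return PeptideAssignment(roles=roles, groups=groups, policy=view.policy)


# ---------------------------------------------------------------------------
# abundance roll-up and normalization
# ---------------------------------------------------------------------------

def rollup_abundance(
    experiment: MixtureExperiment,
    assignment: PeptideAssignment,
    index: PeptideIndex,
) -> QuantMatrix:
    """Sum assigned peptide intensities into master-protein abundances."""
    channels = list(experiment.design.channel_labels)
    intensities = experiment.channel_intensities()  # peptide key x channel
    psm_counts = experiment.peptide_psm_counts()

    assigned = pd.DataFrame(
        [
            (pep, master)
            for pep, (master, role) in assignment.roles.items()
            if role != "discarded"
        ],
        columns=["peptide", "master"],
    )
    if assigned.empty:
        idx = pd.Index([], name="protein")
        return QuantMatrix(
            data=pd.DataFrame(columns=channels, index=idx),
            meta=pd.DataFrame(
                columns=["species", "n_unique_psm", "n_common_psm"], index=idx
            ),
        )
    assigned = assigned[assigned["peptide"].isin(intensities.index)]
    assigned["species"] = assigned["master"].map(index.species_of)
    assigned["cls"] = assigned["peptide"].map(
        lambda p: index.species_class(p)
    )
    assigned["psm"] = assigned["peptide"].map(psm_counts)

    joined = assigned.join(intensities, on="peptide")
    data = joined.groupby("master", sort=True)[channels].sum()
    # a peptide unique to the other species assigned here (possible only
    # through cross-species group merges) counts toward neither PSM tally
    is_unique = assigned["cls"] == assigned["species"] + "_unique"
    is_common = assigned["cls"] == "common"
    meta = pd.DataFrame(
        {
            "species": assigned.groupby("master", sort=True)["species"].first(),
            "n_unique_psm": assigned.assign(u=assigned["psm"].where(is_unique, 0))
            .groupby("master", sort=True)["u"]
            .sum()
            .astype(int),
            "n_common_psm": assigned.assign(c=assigned["psm"].where(is_common, 0))
            .groupby("master", sort=True)["c"]
            .sum()
            .astype(int),
        }
    )
    quantified = data.sum(axis=1) > 0
    data, meta = data[quantified], meta[quantified]
    data.index.name = meta.index.name = "protein"
    return QuantMatrix(data=data, meta=meta)


def normalize_human_total(matrix: QuantMatrix, constant: float = 1e6) -> QuantMatrix:
    """Scale each channel so its summed human-protein abundance = constant."""
    if constant <= 0:
        raise ParameterError("normalization constant must be > 0")
    human = matrix.human_proteins()
    if len(human) == 0:
        raise ParameterError("matrix has no human proteins to normalize on")
    totals = matrix.data.loc[human].sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ParameterError(f"zero human total in channel(s) {bad}")
    scaled = matrix.data * (constant / totals)
    return QuantMatrix(data=scaled, meta=matrix.meta.copy())


# ---------------------------------------------------------------------------
# PSM ratio
# ---------------------------------------------------------------------------

def psm_ratio(matrix: QuantMatrix, species: str = "human") -> pd.Series:
    """Per-protein fraction of PSMs from species-unique peptides.

    ratio = n_unique_psm / (n_unique_psm + n_common_psm); 1 for proteins
    quantified entirely by species-unique peptides, 0 for proteins
    quantified only by human-mouse common peptides.  Proteins with zero
    total PSMs are excluded.
    """
    meta = matrix.meta[matrix.meta["species"] == species]
    total = meta["n_unique_psm"] + meta["n_common_psm"]
    meta = meta[total > 0]
    ratio = meta["n_unique_psm"] / (meta["n_unique_psm"] + meta["n_common_psm"])
    ratio.name = "psm_ratio"
    return ratio


# ---------------------------------------------------------------------------
# convenience: one call from experiment to normalized matrix
# ---------------------------------------------------------------------------

def quantify(
    experiment: MixtureExperiment,
    index: PeptideIndex,
    policy: Policy | str,
    normalization_constant: float = 1e6,
) -> QuantMatrix:
    """Run apply_policy -> grouping -> assignment -> roll-up -> normalization."""
    from .species_assignment import apply_policy

    view = apply_policy(index, experiment, policy)
    groups = group_proteins(view, index)
    assignment = assign_peptides(groups, view)
    matrix = rollup_abundance(experiment, assignment, index)
    if Policy(policy) is Policy.MOUSE_ONLY:
        # a mouse-only search has no human proteins; normalize on mouse total
        totals = matrix.data.sum(axis=0)
        matrix = QuantMatrix(
            data=matrix.data * (normalization_constant / totals), meta=matrix.meta
        )
        return matrix
    return normalize_human_total(matrix, normalization_constant)


def write_quant_tsv(matrix: QuantMatrix, data_path, meta_path) -> None:
    matrix.data.to_csv(data_path, sep="\t", float_format="%.10g")
    matrix.meta.to_csv(meta_path, sep="\t")


def read_quant_tsv(data_path, meta_path) -> QuantMatrix:
    data = pd.read_csv(data_path, sep="\t", index_col=0)
    data.columns = [str(c) for c in data.columns]
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return QuantMatrix(data=data, meta=meta)
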