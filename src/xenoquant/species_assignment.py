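"""The four database-search policies' view of the observed peptide universe.

* ``full_peptide`` — combined human+mouse database, unique and razor
  peptides used; common peptides stay visible and are attributed by protein
  grouping downstream.
* ``unique_peptide`` — combined database, human-mouse common peptides
  discarded before quantification.
* ``human_only`` / ``mouse_only`` — single-species database: the other
  species' unique peptides are invisible, and common peptides are attributed
  wholesale to the database species (a mouse-origin common peptide is
  treated as human under ``human_only``).

Identification noise is not modelled: every peptide present in the
experiment is seen by any policy whose database contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .digestion import PeptideIndex
from .synthetic_proteome import MixtureExperiment, ParameterError


class Policy(str, Enum):
    FULL_PEPTIDE = "full_peptide"
    UNIQUE_PEPTIDE = "unique_peptide"
    HUMAN_ONLY = "human_only"
    MOUSE_ONLY = "mouse_only"


#: species of the search database(s) per policy
DATABASE_SPECIES = {
    Policy.FULL_PEPTIDE: ("human", "mouse"),
    Policy.UNIQUE_PEPTIDE: ("human", "mouse"),
    Policy.HUMAN_ONLY: ("human",),
    Policy.MOUSE_ONLY: ("mouse",),
}


@dataclass(frozen=True)
class PolicyView:
    policy: Policy
    visible_peptides: frozenset[str]
    #: peptide -> species-of-record; "shared" marks combined-database common
    #: peptides whose attribution is resolved by protein grouping downstream
    attribution: Mapping[str, str]
    database_species: tuple[str, ...]


def apply_policy(
    index: PeptideIndex, experiment: MixtureExperiment, policy: Policy | str
) -> PolicyView:
    """Restrict the experiment's peptides to what ``policy`` can see."""
    try:
        policy = Policy(policy)
    except ValueError as exc:
        raise ParameterError(f"unknown policy {policy!r}") from exc

    present = experiment.peptides
    missing = present - set(index.entries)
    if missing:
        raise ParameterError(
            f"{len(missing)} experiment peptides absent from the index"
        )

    cls = {p: index.species_class(p) for p in present}
    if policy is Policy.FULL_PEPTIDE:
        visible = present
        attribution = {
            p: ("shared" if cls[p] == "common" else cls[p].split("_")[0])
            for p in visible
        }
    elif policy is Policy.UNIQUE_PEPTIDE:
        visible = frozenset(p for p in present if cls[p] != "common")
        attribution = {p: cls[p].split("_")[0] for p in visible}
    elif policy is Policy.HUMAN_ONLY:
        visible = frozenset(p for p in present if cls[p] != "mouse_unique")
        attribution = {p: "human" for p in visible}
    else:  # MOUSE_ONLY
        visible = frozenset(p for p in present if cls[p] != "human_unique")
        attribution = {p: "mouse" for p in visible}

    return PolicyView(
        policy=policy,
        visible_peptides=frozenset(visible),
        attribution=attribution,
        database_species=DATABASE_SPECIES[policy],
    )
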