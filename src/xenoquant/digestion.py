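"""In-silico trypsin/P digestion and the peptide -> protein index.

Trypsin/P cleaves after every K or R, including before proline.  The index
collects all peptides of both proteomes (up to a missed-cleavage budget,
within a length window) and classifies each peptide key as human-unique,
mouse-unique or human-mouse common.  Because mass spectrometry cannot
distinguish leucine from isoleucine, keys are I/L-collapsed by default, so
two sequences differing only at I/L positions count as the same peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from pyteomics import parser as _pyt_parser

from .synthetic_proteome import AMINO_ACIDS, ParameterError, ProteomePair

#: cleave after K or R, no proline exception
TRYPSIN_P_RULE = r"[KR]"

_VALID_SEQ = re.compile(f"^[{AMINO_ACIDS}]+$")


class InputError(ValueError):
    """Invalid sequence or proteome input."""


def digest_protein(
    sequence: str,
    missed_cleavages: int = 2,
    min_length: int = 7,
    max_length: int = 45,
) -> set[str]:
    """All trypsin/P peptides of ``sequence`` within the length window.

    Peptides span at most ``missed_cleavages`` internal cleavage sites; the
    C-terminal fragment is included.  Raises :class:`InputError` on residues
    outside the 20-letter alphabet.
    """
    if not _VALID_SEQ.match(sequence):
        raise InputError("sequence must be non-empty uppercase 20-letter amino acids")
    if missed_cleavages < 0:
        raise ParameterError("missed_cleavages must be >= 0")
    peptides = _pyt_parser.cleave(
        sequence, TRYPSIN_P_RULE, missed_cleavages=missed_cleavages,
        min_length=min_length,
    )
    return {p for p in peptides if len(p) <= max_length}


@dataclass(frozen=True)
class IndexParams:
    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 45
    collapse_IL: bool = True


@dataclass(frozen=True)
class IndexEntry:
    protein_ids: frozenset[str]
    species_class: str  # "human_unique" | "mouse_unique" | "common"


@dataclass(frozen=True)
class PeptideIndex:
    """Digested peptide key -> parent proteins, with species classification."""

    entries: Mapping[str, IndexEntry]
    params: IndexParams
    #: protein id -> sorted tuple of its peptide keys (post length filter)
    protein_peptides: Mapping[str, tuple[str, ...]]
    #: protein id -> species
    species_of: Mapping[str, str]

    def species_class(self, peptide: str) -> str:
        return self.entries[peptide].species_class

    @property
    def common_fraction(self) -> float:
        """Fraction of index keys shared between the two species."""
        n = len(self.entries)
        if n == 0:
            return float("nan")
        return sum(e.species_class == "common" for e in self.entries.values()) / n

    def class_counts(self) -> dict[str, int]:
        counts = {"human_unique": 0, "mouse_unique": 0, "common": 0}
        for e in self.entries.values():
            counts[e.species_class] += 1
        return counts


def peptide_key(peptide: str, collapse_IL: bool = True) -> str:
    return peptide.replace("I", "L") if collapse_IL else peptide


def build_peptide_index(pair: ProteomePair, params: IndexParams = IndexParams()) -> PeptideIndex:
    """Digest both proteomes and classify every peptide key.

    A key is ``common`` iff its parent set spans both species; otherwise
    ``human_unique`` / ``mouse_unique``.
    """
    seen_ids: set[str] = set()
    parents: dict[str, set[str]] = {}
    protein_peptides: dict[str, tuple[str, ...]] = {}
    species_of: dict[str, str] = {}

    for rec in pair.records():
        if rec.id in seen_ids:
            raise InputError(f"duplicate protein id {rec.id}")
        seen_ids.add(rec.id)
        species_of[rec.id] = rec.species
        keys = sorted(
            {
                peptide_key(p, params.collapse_IL)
                for p in digest_protein(
                    rec.sequence,
                    params.missed_cleavages,
                    params.min_length,
                    params.max_length,
                )
            }
        )
        protein_peptides[rec.id] = tuple(keys)
        for k in keys:
            parents.setdefault(k, set()).add(rec.id)

    entries: dict[str, IndexEntry] = {}
    for key, ids in parents.items():
        species = {species_of[i] for i in ids}
        if species == {"human", "mouse"}:
            cls = "common"
        elif species == {"human"}:
            cls = "human_unique"
        else:
            cls = "mouse_unique"
        entries[key] = IndexEntry(protein_ids=frozenset(ids), species_class=cls)

    return PeptideIndex(
        entries=entries,
        params=params,
        protein_peptides=protein_peptides,
        species_of=species_of,
    )


def write_index_tsv(index: PeptideIndex, path) -> None:
    frame = pd.DataFrame(
        {
            "peptide": sorted(index.entries),
            "species_class": [index.entries[k].species_class for k in sorted(index.entries)],
            "protein_ids": [
                ";".join(sorted(index.entries[k].protein_ids)) for k in sorted(index.entries)
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
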