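"""Paired human/mouse proteome generation and TMT-style mixture simulation.

The generator emulates the situation in xenograft proteomics: two closely
related proteomes whose tryptic peptides are partly shared, mixed in known
human/mouse proportions across the 16 channels of a TMTpro plex.  Mouse
orthologs are derived from human sequences by independent per-residue
substitution, so the shared-peptide fraction of the digested index is a
smooth, monotone function of the substitution rate and can be placed in the
~40-50% regime observed for real human/mouse samples.

Simulated quantities per (peptide, origin protein) row:

* expected reporter intensity per channel
  = (species fraction of the channel) x (protein base abundance)
    x (biological expression-group factor) x (peptide response factor)
* technical noise: multiplicative log-normal with coefficient of variation
  ``noise_cv``, independent per channel
* PSM count: Poisson with mean ``psm_rate`` x expected total signal of the
  row; rows with zero PSMs are unobserved and dropped.

"Fraction" always means fraction of total protein signal in the channel, for
both the cell-line design (mixed by protein mass) and the PDX design (the
measured cell percentages stand in for protein percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: TMTpro 16-plex reporter channels in plex order.
TMT16_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)

#: Human-cell percentages of the eight cell-line mixtures (two technical
#: replicates each).
CELL_LINE_HUMAN_PCT = (100.0, 98.0, 95.0, 92.0, 85.0, 75.0, 65.0, 55.0)

#: Measured mouse-cell percentage per PDX tumor sample.  "A" samples are
#: original xenograft tumors, "B" samples the same tumor after mouse-cell
#: depletion.  Three A/B pairs carry two technical replicates each.
PDX_MOUSE_PCT = {
    "LI6663A": 7.8, "LI6650A": 15.6, "LI6674A": 51.3, "LI6675A": 17.3,
    "LI1057A": 90.7, "LI6663B": 0.2, "LI6650B": 0.3, "LI6674B": 0.8,
    "LI6675B": 0.4, "LI1057B": 4.9,
}

_PDX_CHANNEL_LAYOUT = (
    ("126", "LI6663A", 1), ("127N", "LI6663A", 2),
    ("127C", "LI6650A", 1), ("128N", "LI6650A", 2),
    ("128C", "LI6674A", 1), ("129N", "LI6674A", 2),
    ("129C", "LI6675A", 1), ("130N", "LI1057A", 1),
    ("130C", "LI6663B", 1), ("131N", "LI6663B", 2),
    ("131C", "LI6650B", 1), ("132N", "LI6650B", 2),
    ("132C", "LI6674B", 1), ("133N", "LI6674B", 2),
    ("133C", "LI6675B", 1), ("134N", "LI1057B", 1),
)


class ParameterError(ValueError):
    """Invalid generator or simulator parameter."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a ground-truth base abundance."""

    id: str
    species: str  # "human" | "mouse"
    sequence: str
    base_abundance: float

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ParameterError(f"unknown species {self.species!r}")
        if not self.sequence or not set(self.sequence) <= set(AMINO_ACIDS):
            raise ParameterError(
                f"protein {self.id}: sequence must be non-empty uppercase "
                "20-letter amino-acid string"
            )
        if not self.base_abundance > 0:
            raise ParameterError(f"protein {self.id}: base_abundance must be > 0")


@dataclass(frozen=True)
class ProteomePair:
    """Species-labelled proteomes with ground-truth orthology links."""

    human: tuple[ProteinRecord, ...]
    mouse: tuple[ProteinRecord, ...]
    ortholog_map: Mapping[str, str]  # human id -> mouse id (partial)
    mutation_rate: float
    seed: int

    def __post_init__(self) -> None:
        ids = [r.id for r in self.human] + [r.id for r in self.mouse]
        if len(ids) != len(set(ids)):
            raise ParameterError("protein ids must be unique within and across species")

    def records(self) -> Iterable[ProteinRecord]:
        yield from self.human
        yield from self.mouse

    @property
    def abundance(self) -> dict[str, float]:
        return {r.id: r.base_abundance for r in self.records()}

    @property
    def species_of(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records()}


@dataclass(frozen=True)
class Channel:
    channel_label: str
    sample_id: str
    human_fraction: float
    replicate_id: int
    #: biological expression profile shared by channels of the same material;
    #: PDX original/demoused pairs share one, all cell-line mixtures share one.
    expression_group: str = "default"


@dataclass(frozen=True)
class MixtureDesign:
    """Ordered channel layout of one 16-plex (or smaller) experiment."""

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        labels = [c.channel_label for c in self.channels]
        if len(labels) != len(set(labels)):
            raise ParameterError("channel labels must be unique")
        for c in self.channels:
            if not 0.0 <= c.human_fraction <= 1.0:
                raise ParameterError(
                    f"channel {c.channel_label}: human_fraction {c.human_fraction} "
                    "outside [0, 1]"
                )
        by_sample: dict[str, set[float]] = {}
        groups: dict[str, set[str]] = {}
        for c in self.channels:
            by_sample.setdefault(c.sample_id, set()).add(c.human_fraction)
            groups.setdefault(c.sample_id, set()).add(c.expression_group)
        for sid, fracs in by_sample.items():
            if len(fracs) > 1 or len(groups[sid]) > 1:
                raise ParameterError(
                    f"replicates of sample {sid} must share human_fraction "
                    "and expression_group"
                )

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(c.channel_label for c in self.channels)

    @property
    def samples(self) -> tuple[str, ...]:
        """Sample ids in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.channels:
            seen.setdefault(c.sample_id, None)
        return tuple(seen)

    def channels_of(self, sample_id: str) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.sample_id == sample_id)

    def human_fraction_of(self, sample_id: str) -> float:
        chans = self.channels_of(sample_id)
        if not chans:
            raise KeyError(sample_id)
        return chans[0].human_fraction

    def replicate_pairs(self) -> tuple[tuple[str, str, str], ...]:
        """(sample_id, channel_a, channel_b) for every technical-replicate pair."""
        pairs = []
        for sid in self.samples:
            chans = self.channels_of(sid)
            if len(chans) == 2:
                pairs.append((sid, chans[0].channel_label, chans[1].channel_label))
            elif len(chans) > 2:
                raise ParameterError(f"sample {sid}: more than two replicates")
        return tuple(pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel_labels,
                "sample": [c.sample_id for c in self.channels],
                "human_fraction": [c.human_fraction for c in self.channels],
                "replicate": [c.replicate_id for c in self.channels],
                "expression_group": [c.expression_group for c in self.channels],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MixtureDesign":
        return cls(
            tuple(
                Channel(
                    str(row["channel"]),
                    str(row["sample"]),
                    float(row["human_fraction"]),
                    int(row["replicate"]),
                    str(row.get("expression_group", "default")),
                )
                for _, row in frame.iterrows()
            )
        )


@dataclass(frozen=True)
class MixtureExperiment:
    """Simulated per-(peptide, origin protein) PSM counts and intensities.

    ``psm_table`` columns: ``peptide`` (index key), ``origin_protein_id``,
    ``origin_species``, ``psm_count``, then one intensity column per channel
    label.  Only rows with at least one PSM are present (unobserved rows are
    dropped, emulating peptides that were never identified).
    """

    design: MixtureDesign
    psm_table: pd.DataFrame
    noise_cv: float
    seed: int

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(self.psm_table["peptide"])

    def channel_intensities(self) -> pd.DataFrame:
        """Observed intensity per peptide key per channel (origins summed).

        This is what the instrument reports: reporter intensities of a
        peptide cannot be split between its human and mouse origins.
        """
        cols = list(self.design.channel_labels)
        return self.psm_table.groupby("peptide", sort=True)[cols].sum()

    def peptide_psm_counts(self) -> pd.Series:
        return self.psm_table.groupby("peptide", sort=True)["psm_count"].sum()


# ---------------------------------------------------------------------------
# proteome generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))

def _draw_lengths(rng: np.random.Generator, n: int, mean_length: int) -> np.ndarray:
    # gamma with shape 16 -> CV 0.25, floored so every protein digests
    lengths = rng.gamma(shape=16.0, scale=mean_length / 16.0, size=n)
    return np.maximum(30, np.rint(lengths)).astype(int)


def generate_paired_proteomes(
    n_proteins: int,
    mean_length: int = 400,
    mutation_rate: float = 0.012,
    seed: int = 0,
    *,
    ortholog_fraction: float = 0.8,
    abundance_log10_sd: float = 0.5,
    ortholog_abundance_log10_sd: float = 0.4,
) -> ProteomePair:
    """Generate a human proteome and a mouse proteome derived from it.

    A fraction ``ortholog_fraction`` of human proteins get a mouse ortholog
    obtained by substituting each residue independently with probability
    ``mutation_rate`` (uniformly to one of the 19 other residues); the rest
    of each proteome is species-exclusive with independently drawn sequences.
    Ortholog base abundances are the human abundance perturbed by a
    log10-normal factor (sd ``ortholog_abundance_log10_sd``), so cross-species
    expression is correlated but not identical.  Deterministic given ``seed``.
    """
    if n_proteins < 1:
        raise ParameterError("n_proteins must be >= 1")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ParameterError("mutation_rate must be in [0, 1]")
    if not 0.0 <= ortholog_fraction <= 1.0:
        raise ParameterError("ortholog_fraction must be in [0, 1]")
    if mean_length < 1:
        raise ParameterError("mean_length must be positive")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_proteins)))

    lengths = _draw_lengths(rng, n_proteins, mean_length)
    human = []
    for i in range(n_proteins):
        human.append(
            ProteinRecord(
                id=f"HUM{i:0{width}d}",
                species="human",
                sequence=_random_sequence(rng, lengths[i]),
                base_abundance=float(10.0 ** rng.normal(0.0, abundance_log10_sd)),
            )
        )

    n_orth = int(round(ortholog_fraction * n_proteins))
    orth_idx = np.sort(rng.permutation(n_proteins)[:n_orth])
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    mouse: list[ProteinRecord] = []
    ortholog_map: dict[str, str] = {}
    for i in orth_idx:
        seq = np.frombuffer(human[i].sequence.encode(), dtype=np.uint8).copy()
        hit = rng.random(seq.size) < mutation_rate
        if hit.any():
            # shift by 1..19 positions within the alphabet: always a new residue
            pos = np.searchsorted(alphabet, seq[hit])
            shift = rng.integers(1, len(AMINO_ACIDS), size=int(hit.sum()))
            seq[hit] = alphabet[(pos + shift) % len(AMINO_ACIDS)]
        mid = f"MUS{i:0{width}d}"
        mouse.append(
            ProteinRecord(
                id=mid,
                species="mouse",
                sequence=seq.tobytes().decode(),
                base_abundance=float(
                    human[i].base_abundance
                    * 10.0 ** rng.normal(0.0, ortholog_abundance_log10_sd)
                ),
            )
        )
        ortholog_map[human[i].id] = mid

    n_excl = n_proteins - n_orth
    excl_lengths = _draw_lengths(rng, n_excl, mean_length)
    for j in range(n_excl):
        mouse.append(
            ProteinRecord(
                id=f"MUS{n_proteins + j:0{width}d}",
                species="mouse",
                sequence=_random_sequence(rng, excl_lengths[j]),
                base_abundance=float(10.0 ** rng.normal(0.0, abundance_log10_sd)),
            )
        )

    return ProteomePair(
        human=tuple(human),
        mouse=tuple(mouse),
        ortholog_map=ortholog_map,
        mutation_rate=mutation_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# benchmark designs (Table-1-style layouts)
# ---------------------------------------------------------------------------

def make_benchmark_designs() -> tuple[MixtureDesign, MixtureDesign]:
    """The two 16-channel benchmark layouts.

    Returns ``(cell_line, pdx)``: the human/mouse cell-line titration
    (human % 100/98/95/92/85/75/65/55, two technical replicates each, one
    shared expression profile) and the five-PDX-model layout (original "A"
    and demoused "B" tumor per model, six replicated samples, measured mouse
    percentages, one expression profile per model).
    """
    cell_channels = []
    for i, pct in enumerate(CELL_LINE_HUMAN_PCT):
        for rep in (1, 2):
            cell_channels.append(
                Channel(
                    channel_label=TMT16_CHANNELS[2 * i + rep - 1],
                    sample_id=f"{pct:g}",
                    human_fraction=round(pct / 100.0, 6),
                    replicate_id=rep,
                    expression_group="celline",
                )
            )
    cell_line = MixtureDesign(tuple(cell_channels))

    pdx_channels = tuple(
        Channel(
            channel_label=label,
            sample_id=sample,
            human_fraction=round(1.0 - PDX_MOUSE_PCT[sample] / 100.0, 6),
            replicate_id=rep,
            expression_group=sample[:-1],  # model id: strip A/B suffix
        )
        for label, sample, rep in _PDX_CHANNEL_LAYOUT
    )
    return cell_line, MixtureDesign(pdx_channels)


# ---------------------------------------------------------------------------
# mixture simulation
# ---------------------------------------------------------------------------

def simulate_mixture(
    pair: ProteomePair,
    index,  # PeptideIndex; untyped to avoid circular import
    design: MixtureDesign,
    noise_cv: float = 0.3,
    psm_rate: float = 0.2,
    seed: int = 0,
    *,
    response_log_sd: float = 1.0,
    group_log10_sd: float = 0.3,
) -> MixtureExperiment:
    """Simulate reporter intensities and PSM counts for one plex.

    Every (peptide key, parent protein) pair is one potential row; its
    expected intensity in a channel is the product of the channel's species
    fraction, the protein's base abundance, the channel's expression-group
    factor for that protein and a per-peptide ionization response factor.
    ``noise_cv`` applies independent multiplicative log-normal noise (unit
    mean) per cell; ``psm_rate`` scales the Poisson mean of the row's PSM
    count.  Rows drawing zero PSMs are unobserved.
    """
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    if psm_rate <= 0:
        raise ParameterError("psm_rate must be > 0")

    rng = np.random.default_rng(seed)
    species_of = pair.species_of
    abundance = pair.abundance

    # stable row order: proteins in pair order, peptides in index order per protein
    rows_pep: list[str] = []
    rows_prot: list[str] = []
    for rec in pair.records():
        for key in index.protein_peptides[rec.id]:
            rows_pep.append(key)
            rows_prot.append(rec.id)
    n_rows = len(rows_pep)
    if n_rows == 0:
        raise ParameterError("peptide index is empty for this proteome pair")

    rows_species = np.array([species_of[p] for p in rows_prot])
    base = np.array([abundance[p] for p in rows_prot])

    # one response factor per distinct peptide key, shared across parents
    keys = sorted(set(rows_pep))
    key_pos = {k: i for i, k in enumerate(keys)}
    response_by_key = np.exp(rng.normal(0.0, response_log_sd, size=len(keys)))
    response = response_by_key[np.fromiter((key_pos[k] for k in rows_pep), int, n_rows)]

    # per-(expression group, protein) biological factors
    group_names = sorted({c.expression_group for c in design.channels})
    prot_ids = [r.id for r in pair.records()]
    prot_pos = {p: i for i, p in enumerate(prot_ids)}
    group_factors = 10.0 ** rng.normal(
        0.0, group_log10_sd, size=(len(group_names), len(prot_ids))
    )
    group_row = {g: i for i, g in enumerate(group_names)}

    frac = np.empty((n_rows, len(design.channels)))
    is_human = rows_species == "human"
    prot_col = np.fromiter((prot_pos[p] for p in rows_prot), int, n_rows)
    for j, ch in enumerate(design.channels):
        f = np.where(is_human, ch.human_fraction, 1.0 - ch.human_fraction)
        frac[:, j] = f * group_factors[group_row[ch.expression_group], prot_col]

    expected = (base * response)[:, None] * frac

    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=expected.shape))
        intensities = expected * noise
    else:
        intensities = expected

    psm = rng.poisson(psm_rate * expected.sum(axis=1))
    observed = psm > 0

    table = pd.DataFrame(
        {
            "peptide": np.array(rows_pep)[observed],
            "origin_protein_id": np.array(rows_prot)[observed],
            "origin_species": rows_species[observed],
            "psm_count": psm[observed],
        }
    )
    for j, label in enumerate(design.channel_labels):
        table[label] = intensities[observed, j]
    table = table.reset_index(drop=True)
    return MixtureExperiment(design=design, psm_table=table, noise_cv=noise_cv, seed=seed)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as multi-FASTA; base abundance kept in the description."""
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"species={r.species} abundance={r.base_abundance:.10g}",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[ProteinRecord]:
    """Read back FASTA written by :func:`write_fasta`."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        out.append(
            ProteinRecord(
                id=rec.id,
                species=fields.get("species", "human"),
                sequence=str(rec.seq),
                base_abundance=float(fields.get("abundance", 1.0)),
            )
        )
    return out


def write_design_tsv(design: MixtureDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_design_tsv(path) -> MixtureDesign:
    return MixtureDesign.from_frame(pd.read_csv(path, sep="\t", dtype={"channel": str, "sample": str}))


def write_psm_tsv(experiment: MixtureExperiment, path) -> None:
    experiment.psm_table.to_csv(path, sep="\t", index=False, float_format="%.10g")
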