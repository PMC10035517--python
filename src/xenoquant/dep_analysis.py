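"""Replicate-calibrated DEP thresholds, DEP calling, power-law fit, overlaps.

Thresholds for differential expression are calibrated from technical
replicates: the abundance ratio of every protein between the two replicates
of a sample is computed in two rounds (each replicate once as the
denominator), all ratios are pooled, and the thresholds are the fdr/2 and
1 - fdr/2 quantiles of the pooled distribution.  Quantiles are taken on the
log-ratio scale with linear interpolation; since the two-round pool is
symmetric under log-negation this makes ``low == 1/high`` exact.

DEP calls use strict inequalities (a ratio exactly at a threshold is not a
DEP), replicate-averaged sample abundances, and only human proteins
quantified in every channel of the design.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import QuantMatrix
from .synthetic_proteome import MixtureDesign, ParameterError

logger = logging.getLogger(__name__)

#: relative tolerance for threshold comparisons (boundary ties are not DEPs)
_REL_TOL = 1e-12


@dataclass(frozen=True)
class DepThresholds:
    low: float
    high: float
    degenerate: bool = False
    n_pooled: int = 0


@dataclass(frozen=True)
class DepCallSet:
    sample_a: str
    sample_b: str
    #: index: protein; columns: ratio (a/b), direction ("up"/"down")
    calls: pd.DataFrame

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.calls.index)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class PowerFit:
    a: float
    b: float
    r_squared: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def complete_human_matrix(matrix: QuantMatrix) -> pd.DataFrame:
    """Human proteins with positive abundance in every channel."""
    human = matrix.data.loc[matrix.human_proteins()]
    return human[(human > 0).all(axis=1)]


def sample_means(matrix: QuantMatrix, design: MixtureDesign) -> pd.DataFrame:
    """Replicate-averaged abundance per sample (complete human proteins)."""
    human = complete_human_matrix(matrix)
    out = {}
    for sid in design.samples:
        labels = [c.channel_label for c in design.channels_of(sid)]
        out[sid] = human[labels].mean(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_thresholds(
    matrix: QuantMatrix, design: MixtureDesign, fdr: float = 0.01
) -> DepThresholds:
    """Two-round replicate-ratio calibration of DEP thresholds."""
    if not 0.0 < fdr < 1.0:
        raise ParameterError("fdr must be in (0, 1)")
    pairs = design.replicate_pairs()
    if not pairs:
        raise ParameterError("design has no technical-replicate pairs")
    human = complete_human_matrix(matrix)
    log_ratios = []
    for _sid, ch_a, ch_b in pairs:
        r = np.log(human[ch_a].to_numpy() / human[ch_b].to_numpy())
        log_ratios.append(r)
        log_ratios.append(-r)  # second round: other replicate as denominator
    pooled = np.concatenate(log_ratios)
    lo, hi = np.quantile(pooled, [fdr / 2.0, 1.0 - fdr / 2.0])
    low, high = float(np.exp(lo)), float(np.exp(hi))
    degenerate = not (low < 1.0 < high)
    if degenerate:
        logger.warning(
            "degenerate calibration: thresholds (%.6g, %.6g) do not straddle 1",
            low, high,
        )
    return DepThresholds(low=low, high=high, degenerate=degenerate, n_pooled=pooled.size)


# ---------------------------------------------------------------------------
# DEP calling
# ---------------------------------------------------------------------------

def _call_from_columns(
    values_a: pd.Series, values_b: pd.Series, thresholds: DepThresholds
) -> pd.DataFrame:
    ok = values_b > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("%d proteins skipped: zero denominator", n_skipped)
    ratio = values_a[ok] / values_b[ok]
    # strict inequalities with a relative guard band so float rounding of a
    # mathematically-equal ratio (e.g. noise-free data) never creates a call
    up = ratio > thresholds.high * (1.0 + _REL_TOL)
    down = ratio < thresholds.low * (1.0 - _REL_TOL)
    calls = pd.DataFrame({"ratio": ratio[up | down]})
    calls["direction"] = np.where(up[up | down], "up", "down")
    return calls


def call_deps(
    matrix: QuantMatrix,
    design: MixtureDesign,
    sample_a: str,
    sample_b: str,
    thresholds: DepThresholds,
) -> DepCallSet:
    """DEPs between two samples (replicate-averaged, strict thresholds)."""
    means = sample_means(matrix, design)
    for s in (sample_a, sample_b):
        if s not in means.columns:
            raise ParameterError(f"unknown sample {s!r}")
    calls = _call_from_columns(means[sample_a], means[sample_b], thresholds)
    return DepCallSet(sample_a=sample_a, sample_b=sample_b, calls=calls)


def replicate_dep_count(
    matrix: QuantMatrix, design: MixtureDesign, sample_id: str, thresholds: DepThresholds
) -> int:
    """DEP count between the two technical replicates of one sample."""
    chans = design.channels_of(sample_id)
    if len(chans) != 2:
        return 0
    human = complete_human_matrix(matrix)
    calls = _call_from_columns(
        human[chans[0].channel_label], human[chans[1].channel_label], thresholds
    )
    return len(calls)


def dep_count_matrix(
    matrix: QuantMatrix, design: MixtureDesign, thresholds: DepThresholds
) -> pd.DataFrame:
    """Symmetric sample x sample DEP-count table.

    Off-diagonal entries count DEPs between replicate-averaged samples; the
    diagonal counts DEPs between a sample's two technical replicates (0 for
    unreplicated samples).
    """
    samples = design.samples
    counts = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for a, b in itertools.combinations(samples, 2):
        n = len(call_deps(matrix, design, a, b, thresholds))
        counts.loc[a, b] = counts.loc[b, a] = n
    for s in samples:
        counts.loc[s, s] = replicate_dep_count(matrix, design, s, thresholds)
    return counts


# ---------------------------------------------------------------------------
# power-law fit
# ---------------------------------------------------------------------------

def fit_power_law(points: list[tuple[float, float]]) -> PowerFit:
    """Least-squares fit of n = a * x^b on the log-log scale."""
    kept = [(x, n) for x, n in points if n > 0]
    dropped = len(points) - len(kept)
    if dropped:
        logger.warning("%d zero-count points dropped from power-law fit", dropped)
    if len(kept) < 3:
        raise ParameterError("power-law fit needs >= 3 points with positive counts")
    x = np.array([p[0] for p in kept], dtype=float)
    n = np.array([p[1] for p in kept], dtype=float)
    if (x <= 0).any():
        raise ParameterError("power-law fit needs positive x")
    if np.unique(x).size < 2:
        raise ParameterError("degenerate design: all x identical")
    res = stats.linregress(np.log(x), np.log(n))
    return PowerFit(a=float(np.exp(res.intercept)), b=float(res.slope),
                    r_squared=float(res.rvalue**2))


# ---------------------------------------------------------------------------
# overlap analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    #: region key: frozenset of set names the region belongs to exclusively
    region_counts: dict[frozenset, int]
    #: containment.loc[a, b] = |A ∩ B| / |A|
    containment: pd.DataFrame
    shared: frozenset

    def exclusive(self, name: str) -> int:
        return self.region_counts.get(frozenset([name]), 0)


def overlap_analysis(named_sets: dict[str, set]) -> OverlapResult:
    """Full inclusion-exclusion region counts for up to 4 named sets."""
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ParameterError("overlap analysis takes 2-4 named sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    universe = set().union(*sets.values())

    region_counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for c in combo:
                inside &= sets[c]
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            region_counts[frozenset(combo)] = len(inside)

    containment = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            containment.loc[a, b] = (
                len(sets[a] & sets[b]) / len(sets[a]) if sets[a] else np.nan
            )
    shared = frozenset(set.intersection(*sets.values()))
    return OverlapResult(region_counts=region_counts, containment=containment, shared=shared)
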