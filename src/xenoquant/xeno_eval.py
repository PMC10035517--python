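"""Intra- and inter-PDX evaluation of quantification policies.

*Intra-PDX*: DEPs between a model's original xenograft tumor and its
demoused (mouse-depleted) pair, correlated against the original tumor's
mouse-cell percentage.

*Inter-PDX*: for a pair of models, DEPs between the two demoused tumors
define the truth set T, DEPs between the two original tumors (same minimal
TMT ratio) the observed set O; then TP = |O ∩ T|, FP = |O \\ T|,
FN = |T \\ O|, FDR = FP/(FP+TP) and TPR = TP/(TP+FN).  "Beyond the minimal
TMT ratio" is two-sided: max(r, 1/r) >= min_ratio, so down-regulation counts
the same as up-regulation.  The sweep repeats this over a ratio grid
(default 1.2 to 3.0) and reports medians over all model pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dep_analysis import DepThresholds, call_deps, sample_means
from .quantification import QuantMatrix
from .synthetic_proteome import MixtureDesign, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PdxModel:
    name: str
    original_sample: str
    demoused_sample: str
    mouse_pct_original: float
    mouse_pct_demoused: float


def benchmark_pdx_models() -> tuple[PdxModel, ...]:
    """The five liver PDX models of the benchmark design."""
    from .synthetic_proteome import PDX_MOUSE_PCT

    models = []
    for name in ("LI1057", "LI6650", "LI6663", "LI6674", "LI6675"):
        models.append(
            PdxModel(
                name=name,
                original_sample=f"{name}A",
                demoused_sample=f"{name}B",
                mouse_pct_original=PDX_MOUSE_PCT[f"{name}A"],
                mouse_pct_demoused=PDX_MOUSE_PCT[f"{name}B"],
            )
        )
    return tuple(models)


@dataclass(frozen=True)
class EvalResult:
    min_ratio: float
    tp: int
    fp: int
    fn: int
    fdr: float  # NaN when fp + tp == 0
    tpr: float  # NaN when tp + fn == 0
    n_dep: int

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.fdr) or math.isnan(self.tpr))


@dataclass(frozen=True)
class SweepResult:
    #: columns: min_ratio, median_fdr, median_tpr, median_ndep
    summary: pd.DataFrame
    #: (model_a, model_b, min_ratio) -> EvalResult
    per_pair: dict[tuple[str, str, float], EvalResult]


# ---------------------------------------------------------------------------
# intra-PDX
# ---------------------------------------------------------------------------

def intra_pdx_deps(
    matrix: QuantMatrix,
    design: MixtureDesign,
    models: tuple[PdxModel, ...],
    thresholds: DepThresholds,
) -> tuple[pd.DataFrame, float, float]:
    """DEP count original-vs-demoused per model, and its Pearson correlation
    with the original tumor's mouse percentage.

    Returns ``(counts_frame, r, p)``; ``r``/``p`` are NaN with a warning for
    fewer than three models or a constant count vector.
    """
    rows = []
    for m in models:
        n = len(call_deps(matrix, design, m.original_sample, m.demoused_sample, thresholds))
        rows.append((m.name, m.mouse_pct_original, n))
    frame = pd.DataFrame(rows, columns=["model", "mouse_pct", "n_dep"])

    r = p = float("nan")
    if len(frame) < 3:
        logger.warning("fewer than 3 models: correlation omitted")
    elif frame["n_dep"].nunique() == 1:
        logger.warning("constant DEP counts: correlation undefined")
    else:
        res = stats.pearsonr(frame["mouse_pct"], frame["n_dep"])
        r, p = float(res.statistic), float(res.pvalue)
    return frame, r, p


# ---------------------------------------------------------------------------
# inter-PDX
# ---------------------------------------------------------------------------

def _beyond_ratio_set(
    means: pd.DataFrame, sample_a: str, sample_b: str, min_ratio: float
) -> frozenset[str]:
    a, b = means[sample_a], means[sample_b]
    ok = (a > 0) & (b > 0)
    r = a[ok] / b[ok]
    hit = np.maximum(r, 1.0 / r) >= min_ratio
    return frozenset(r.index[hit])


def inter_pdx_eval(
    matrix: QuantMatrix,
    design: MixtureDesign,
    model_a: PdxModel,
    model_b: PdxModel,
    min_ratio: float,
) -> EvalResult:
    """TP/FP/FN bookkeeping for one model pair at one minimal TMT ratio."""
    if min_ratio < 1.0:
        raise ParameterError("min_ratio must be >= 1")
    means = sample_means(matrix, design)
    truth = _beyond_ratio_set(means, model_a.demoused_sample, model_b.demoused_sample, min_ratio)
    observed = _beyond_ratio_set(means, model_a.original_sample, model_b.original_sample, min_ratio)

    tp = len(observed & truth)
    fp = len(observed - truth)
    fn = len(truth - observed)
    fdr = fp / (fp + tp) if fp + tp > 0 else float("nan")
    tpr = tp / (tp + fn) if tp + fn > 0 else float("nan")
    if not truth and not observed:
        logger.warning(
            "empty truth and observed sets for %s vs %s at min_ratio %.2f",
            model_a.name, model_b.name, min_ratio,
        )
    return EvalResult(min_ratio=min_ratio, tp=tp, fp=fp, fn=fn, fdr=fdr, tpr=tpr,
                      n_dep=tp + fp)


def sweep_min_ratio(
    matrix: QuantMatrix,
    design: MixtureDesign,
    models: tuple[PdxModel, ...],
    grid: np.ndarray | None = None,
) -> SweepResult:
    """inter_pdx_eval over all model pairs at each grid value, medianized."""
    if len(models) < 2:
        raise ParameterError("sweep needs >= 2 models")
    if grid is None:
        grid = np.round(np.arange(1.2, 3.0 + 1e-9, 0.2), 10)
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ParameterError("grid must be strictly ascending")

    per_pair: dict[tuple[str, str, float], EvalResult] = {}
    rows = []
    for mr in grid:
        fdrs, tprs, ndeps = [], [], []
        for a, b in itertools.combinations(models, 2):
            res = inter_pdx_eval(matrix, design, a, b, float(mr))
            per_pair[(a.name, b.name, float(mr))] = res
            fdrs.append(res.fdr)
            tprs.append(res.tpr)
            ndeps.append(res.n_dep)
        rows.append(
            (
                float(mr),
                float(np.nanmedian(fdrs)),
                float(np.nanmedian(tprs)),
                float(np.median(ndeps)),
            )
        )
    summary = pd.DataFrame(rows, columns=["min_ratio", "median_fdr", "median_tpr", "median_ndep"])
    return SweepResult(summary=summary, per_pair=per_pair)


def write_sweep_tsv(sweep: SweepResult, path) -> None:
    sweep.summary.to_csv(path, sep="\t", index=False, float_format="%.10g")
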