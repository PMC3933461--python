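"""Probe-level quality control and normalization.

The chain mirrors standard bead-array practice for a background-corrected
intensity matrix: (1) drop probes whose detection p-value fails a threshold
in too few samples, (2) quantile-normalize columns, (3) floor non-positive
values to the smallest positive intensity and take log2, (4) collapse
probes to genes by averaging probes that share a gene annotation.

Flooring covers zeros as well as negatives: the purpose of the floor is to
make the log2 transform well defined, and log2(0) is as undefined as
log2 of a negative number.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, ProbeMatrix

__all__ = [
    "detection_filter",
    "quantile_normalize",
    "floor_log2",
    "collapse_probes",
    "preprocess_chain",
    "default_min_samples",
]


def default_min_samples(n_samples: int) -> int:
    """Generalize 'at least 5 of the 12 samples' to ceil(5/12 * n)."""
    return math.ceil(5 * n_samples / 12)


def detection_filter(
    m: ProbeMatrix, p_thresh: float = 0.05, min_samples: int | None = None
) -> ProbeMatrix:
    """Keep probes detected (p strictly below ``p_thresh``) in >= ``min_samples`` samples."""
    if m.detection_p is None:
        raise ValueError(
            "no detection p-value matrix present; skip the detection-filter stage"
        )
    if not 0.0 < p_thresh <= 1.0:
        raise ValueError("p_thresh must be in (0, 1]")
    if min_samples is None:
        min_samples = default_min_samples(m.n_samples)
    if not 1 <= min_samples <= m.n_samples:
        raise ValueError(f"min_samples must be in [1, {m.n_samples}]")
    n_detected = (m.detection_p.to_numpy() < p_thresh).sum(axis=1)
    keep = m.values.index[n_detected >= min_samples]
    return ProbeMatrix(
        values=m.values.loc[keep],
        detection_p=m.detection_p.loc[keep],
        probe2gene=None if m.probe2gene is None else m.probe2gene.copy(),
        groups=None if m.groups is None else m.groups.copy(),
    )


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Force every column onto the mean empirical distribution.

    The reference distribution is the across-column mean of the sorted
    columns; values are mapped back by rank, with tied values receiving
    the mean of the reference quantiles they span (average ranks).
    """
    x = m.values.to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    if np.isnan(x).any():
        raise ValueError("missing values not supported by quantile normalization")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(x.shape[0], dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average") - 1.0
        # average ranks are half-integers at ties; interpolate the reference
        out[:, j] = np.interp(ranks, grid, ref)
    return m.replace_values(out)


def floor_log2(m: ProbeMatrix) -> ProbeMatrix:
    """Replace non-positive values with the global minimum positive value, then log2."""
    x = m.values.to_numpy(dtype=float)
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive value; cannot take log2")
    floor = positive.min()
    return m.replace_values(np.log2(np.where(x <= 0, floor, x)))


def collapse_probes(m: ProbeMatrix) -> ExpressionMatrix:
    """Drop unannotated probes; average probes mapping to the same gene.

    Averaging happens on whatever scale the matrix currently is (the
    pipeline calls this after the log2 step).  Requires group labels on the
    matrix so the result is a ready-to-test :class:`ExpressionMatrix`.
    """
    if m.probe2gene is None or len(m.probe2gene) == 0:
        raise ValueError("no probe->gene annotation present")
    if m.groups is None:
        raise ValueError("sample group labels required to emit an ExpressionMatrix")
    annotated = m.values.index.intersection(m.probe2gene.index)
    vals = m.values.loc[annotated]
    genes = m.probe2gene.loc[annotated]
    collapsed = vals.groupby(genes.to_numpy()).mean()
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(values=collapsed, groups=m.groups.copy())


def preprocess_chain(
    m: ProbeMatrix,
    p_thresh: float = 0.05,
    min_samples: int | None = None,
    skip_detection: bool = False,
) -> tuple[ExpressionMatrix, dict]:
    """Full chain: detection filter -> quantile normalize -> floor+log2 -> collapse.

    Returns the gene-level matrix plus a stage log (probe counts before and
    after filtering, the expressed fraction, gene count).
    """
    n0 = m.n_probes
    if not skip_detection and m.detection_p is not None:
        m = detection_filter(m, p_thresh=p_thresh, min_samples=min_samples)
    n1 = m.n_probes
    m = quantile_normalize(m)
    m = floor_log2(m)
    expr = collapse_probes(m)
    log = {
        "probes_total": n0,
        "probes_detected": n1,
        "detected_fraction": n1 / n0 if n0 else float("nan"),
        "genes": int(expr.values.shape[0]),
    }
    return expr, log
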