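"""Dynamic-time-warping latency statistic (DTW direction).

The individual waveform and a reference (the grand average) are cropped
to a component window and aligned by classic boundary-to-boundary DTW
with steps (1,0), (0,1), (1,1). The *direction* statistic is the signed
area between the warping path and the main diagonal of the cost matrix,
normalized by the area under the diagonal:

    direction = sum over path vertices of (j - i) / (N (N - 1) / 2)

where i indexes the reference and j the individual waveform. Identical
waveforms give exactly 0; a positive value means the individual waveform
lags the reference (longer latency), a negative value that it leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .erp_features import ERPWaveform


@dataclass(frozen=True)
class DTWResult:
    direction: float
    path: tuple  # ((i_ref, j_ind), ...) from (0,0) to (N-1,N-1)
    cost: float
    window_ms: tuple | None = None


def dtw_align(ref: np.ndarray, ind: np.ndarray, metric: str = "abs") -> DTWResult:
    """Align two equal-length segments and compute the direction statistic.

    Local cost is |ref[i] - ind[j]| (or squared with ``metric="sq"``). On
    accumulated-cost ties the diagonal step is preferred, then the step
    advancing j, which keeps the identity path unique for identical
    inputs.
    """
    ref = np.asarray(ref, dtype=float)
    ind = np.asarray(ind, dtype=float)
    if ref.ndim != 1 or ind.ndim != 1 or len(ref) != len(ind):
        raise ValueError("segments must be 1-D and of equal length")
    n = len(ref)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(ind))):
        raise ValueError("non-finite values in input")
    if metric == "abs":
        local = np.abs(ref[:, None] - ind[None, :])
    elif metric == "sq":
        local = (ref[:, None] - ind[None, :]) ** 2
    else:
        raise ValueError(f"unknown DTW metric {metric!r}")

    big = np.inf
    acc = np.full((n + 1, n + 1), big)
    acc[0, 0] = 0.0
    # predecessor choice encoded for deterministic backtracking:
    # 0 = diagonal (i-1, j-1), 1 = advance j (i, j-1), 2 = advance i (i-1, j)
    choice = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        row_prev = acc[i]
        row_cur = acc[i + 1]
        for j in range(n):
            c_diag = row_prev[j]
            c_left = row_cur[j]
            c_up = row_prev[j + 1]
            best, pick = c_diag, 0
            if c_left < best:
                best, pick = c_left, 1
            if c_up < best:
                best, pick = c_up, 2
            row_cur[j + 1] = local[i, j] + best
            choice[i, j] = pick

    path = []
    i, j = n - 1, n - 1
    while True:
        path.append((i, j))
        if i == 0 and j == 0:
            break
        pick = choice[i, j]
        if pick == 0 and i > 0 and j > 0:
            i, j = i - 1, j - 1
        elif pick == 1 and j > 0:
            j -= 1
        else:
            i -= 1
    path.reverse()

    signed_area = sum(j - i for i, j in path)
    direction = signed_area / (n * (n - 1) / 2.0)
    return DTWResult(direction=float(direction), path=tuple(path), cost=float(acc[n, n]))


def dtw_direction_feature(
    individual: ERPWaveform,
    reference: ERPWaveform,
    window_ms: tuple,
    metric: str = "abs",
) -> float:
    """Direction statistic over a component window.

    Both waveforms are cropped to ``window_ms`` (inclusive); they must
    share the sampling grid.
    """
    if len(individual.time_ms) != len(reference.time_ms) or not np.allclose(
        individual.time_ms, reference.time_ms
    ):
        raise ValueError("individual and reference must share a time axis")
    mask = (individual.time_ms >= window_ms[0]) & (individual.time_ms <= window_ms[1])
    if mask.sum() < 2:
        raise ValueError(f"window {window_ms} outside the epoch")
    res = dtw_align(reference.data[mask], individual.data[mask], metric=metric)
    return res.direction
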