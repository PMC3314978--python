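"""Internal-reliability estimates: split-half LIs and Cronbach's alpha.

Split-half reliability asks whether half the trials yield the same LI as
the other half: the epochs are partitioned odd/even (by accepted order) or
by a seeded random split, the halves are averaged separately, and the LI
computed on each. Cronbach's alpha generalises this across all split-half
iterations: with per-epoch LIs as items (columns) and files/participants
as cases (rows),

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total))

using sample variances (ddof=1) and total = row sums.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError
from .events import TimingSpec
from .laterality import Epoch, average_epochs, compute_li

__all__ = ["split_half", "cronbach_alpha", "complete_case_matrix"]


def split_half(
    epochs: list[Epoch],
    spec: TimingSpec,
    mode: str = "odd-even",
    seed: int | None = None,
    li_mode: str = "mean",
    peak_mode: str = "abs",
) -> tuple[float, float, list[int], list[int]]:
    """LI of each half of the accepted epochs.

    ``mode="odd-even"`` puts the 1st, 3rd, ... accepted epoch in half A and
    the 2nd, 4th, ... in half B; ``mode="random"`` shuffles the accepted
    order with the given seed before halving (halves differ in size by at
    most one). Each half is averaged and its LI computed exactly as for
    the full set. Returns ``(li_a, li_b, indices_a, indices_b)``.
    """
    acc = [e for e in epochs if e.accepted]
    if len(acc) < 2:
        raise InsufficientDataError("split-half needs >= 2 accepted epochs")
    order = np.arange(len(acc))
    if mode == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(order)
        half = (len(acc) + 1) // 2
        idx_a, idx_b = sorted(order[:half]), sorted(order[half:])
    elif mode == "odd-even":
        idx_a, idx_b = list(order[::2]), list(order[1::2])
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    def half_li(idx: list[int]) -> float:
        avg = average_epochs([acc[i] for i in idx])
        li, _, _ = compute_li(
            avg.difference,
            acc[0].poi,
            spec.activation_window,
            acc[0].sample_rate,
            offset=acc[0].offset,
            li_mode=li_mode,
            peak_mode=peak_mode,
        )
        return li

    return half_li(idx_a), half_li(idx_b), [int(i) for i in idx_a], [int(i) for i in idx_b]


def cronbach_alpha(per_epoch_li_matrix: np.ndarray) -> float:
    """Cronbach's alpha of a files x epochs matrix of per-epoch LIs.

    Requires >= 2 files and >= 2 epochs with no missing entries (see
    :func:`complete_case_matrix` for ragged inputs). Zero variance of the
    item sums leaves alpha undefined; NaN is returned.
    """
    m = np.asarray(per_epoch_li_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InsufficientDataError(
            f"alpha needs a >=2 x >=2 complete matrix, got shape {m.shape}"
        )
    if np.isnan(m).any():
        raise InsufficientDataError("alpha requires a complete matrix (no NaN)")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def complete_case_matrix(per_file_lis: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Stack ragged per-file LI lists into a complete files x k matrix.

    Files reject different epochs, so per-epoch LI lists differ in length;
    alpha is computed over the first k epochs present in every file, with
    k reported alongside.
    """
    if not per_file_lis:
        raise InsufficientDataError("no files")
    k = min(len(x) for x in per_file_lis)
    if k < 2:
        raise InsufficientDataError("fewer than 2 epochs common to all files")
    return np.vstack([np.asarray(x, dtype=float)[:k] for x in per_file_lis]), k
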