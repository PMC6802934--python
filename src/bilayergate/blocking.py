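"""Blocking-transform standard errors for correlated time series.

Iterated pairwise averaging (Flyvbjerg & Petersen): each transform halves the
series by averaging neighbours; for uncorrelated data the naive standard
error of the mean, sqrt(c0 / (n - 1)) with c0 the biased sample variance, is
invariant under the transform, while for positively correlated data it grows
until the block length exceeds the correlation time and the estimate
plateaus.  The plateau value is the autocorrelation-robust standard error of
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

__all__ = ["BlockingResult", "blocking_stderr"]


@dataclass
class BlockingResult:
    """Plateau standard error plus the full per-level estimate curve."""

    stderr: float
    block_curve: np.ndarray  # SEM estimate at each blocking level
    block_sizes: np.ndarray  # samples per block at each level
    plateau_level: int | None
    plateau_found: bool

    def __iter__(self):  # allows `stderr, curve = blocking_stderr(x)`
        yield self.stderr
        yield self.block_curve


def blocking_stderr(
    series, rel_tol: float = 0.05, min_blocks: int = 4
) -> BlockingResult:
    """Standard error of the mean of a (possibly autocorrelated) series.

    Parameters
    ----------
    series : 1-D numeric sequence, length >= 8
    rel_tol : float
        Plateau criterion: the first level whose estimate changes by less
        than the tolerance over each of the next two levels is taken as the
        plateau.  The tolerance per comparison is the larger of ``rel_tol``
        and the sampling noise of the later level's estimate,
        ``1/sqrt(2 (n_blocks - 1))`` — without this allowance the late,
        few-block levels could never register as flat.  Without a plateau
        the maximum-level estimate is reported and ``plateau_found`` is
        False.
    min_blocks : int
        Blocking stops once fewer than this many blocks remain.

    Returns
    -------
    BlockingResult
        Unpacks as ``(stderr, block_curve)``.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 8:
        raise InsufficientDataError("blocking analysis needs >= 8 samples")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("series contains non-finite values")

    sems = []
    sizes = []
    nblocks = []
    block = 1
    while x.size >= max(min_blocks, 2):
        n = x.size
        c0 = np.var(x)  # biased sample variance at this level
        sems.append(np.sqrt(c0 / (n - 1)))
        sizes.append(block)
        nblocks.append(n)
        if x.size // 2 < max(min_blocks, 2):
            break
        m = (n // 2) * 2
        x = 0.5 * (x[0:m:2] + x[1:m:2])
        block *= 2

    curve = np.asarray(sems)
    sizes = np.asarray(sizes)
    nblocks = np.asarray(nblocks)

    plateau_level = None
    for i in range(len(curve) - 2):
        if curve[i] == 0.0:
            # constant series: zero stays zero under blocking
            plateau_level = i
            break
        tol1 = max(rel_tol, 1.0 / np.sqrt(2.0 * (nblocks[i + 1] - 1)))
        tol2 = max(rel_tol, 1.0 / np.sqrt(2.0 * (nblocks[i + 2] - 1)))
        d1 = abs(curve[i + 1] - curve[i]) / curve[i]
        d2 = abs(curve[i + 2] - curve[i + 1]) / max(curve[i + 1], 1e-300)
        if d1 < tol1 and d2 < tol2:
            plateau_level = i
            break
    if plateau_level is not None:
        return BlockingResult(
            stderr=float(curve[plateau_level]),
            block_curve=curve,
            block_sizes=sizes,
            plateau_level=plateau_level,
            plateau_found=True,
        )
    return BlockingResult(
        stderr=float(curve[-1]),
        block_curve=curve,
        block_sizes=sizes,
        plateau_level=None,
        plateau_found=False,
    )
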