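"""Iterative proportional fitting (raking) of sample weights to marginal targets.

Used both to emulate a cross-sectional calibration weight on the synthetic
baseline and to standardize a respondent sample to a reference composition.
Margins are marginal distributions only; no joint cell structure is imposed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import RakingError

__all__ = ["rake"]


def _check_margins(frame: pd.DataFrame, margins: Mapping[str, Mapping[str, float]]) -> None:
    for dim, levels in margins.items():
        if dim not in frame.columns:
            raise RakingError(f"raking dimension {dim!r} not present in the sample")
        total = float(sum(levels.values()))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise RakingError(f"margin for {dim!r} sums to {total}, expected 1")
        present = set(frame[dim].dropna().unique())
        for level, share in levels.items():
            if share > 0 and level not in present:
                raise RakingError(
                    f"margin cell {dim!r}={level!r} has target share {share} "
                    "but no sample members; raking cannot converge"
                )


def rake(
    frame: pd.DataFrame,
    margins: Mapping[str, Mapping[str, float]],
    *,
    base_weights: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Return mean-1 weights whose weighted margins match ``margins``.

    Parameters
    ----------
    frame : sample with one categorical column per raking dimension.
    margins : ``{dimension: {level: population share}}``; shares sum to 1.
    base_weights : starting weights (defaults to 1).
    tol : maximum absolute margin discrepancy at convergence.
    max_iter : cycles over all dimensions before giving up.
    """
    _check_margins(frame, margins)
    n = len(frame)
    if n == 0:
        raise RakingError("cannot rake an empty sample")
    w = np.ones(n) if base_weights is None else np.asarray(base_weights, dtype=float).copy()
    if np.any(w <= 0):
        raise RakingError("base weights must be positive")

    dims = list(margins)
    level_masks = {
        dim: {level: (frame[dim] == level).to_numpy() for level in margins[dim]}
        for dim in dims
    }

    # convergence is checked before each update cycle, so an already
    # standardized sample passes through unchanged (idempotence)
    for _ in range(max_iter + 1):
        total = w.sum()
        worst = 0.0
        for dim in dims:
            for level, target in margins[dim].items():
                worst = max(worst, abs(w[level_masks[dim][level]].sum() / total - target))
        if worst < tol:
            return w / w.mean()
        for dim in dims:
            total = w.sum()
            for level, target in margins[dim].items():
                mask = level_masks[dim][level]
                current = w[mask].sum() / total
                if current > 0:
                    w[mask] *= target / current
    raise RakingError(f"raking did not converge within {max_iter} iterations (worst discrepancy {worst:.2e})")
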