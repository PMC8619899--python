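"""Dietary-pattern extraction from food-frequency intakes.

Food-item intakes are summed into 29 predefined food groups; patterns are
principal components of the standardized (correlation-matrix) group intakes.
Components with eigenvalue > 1.5 are retained, varimax-rotated
(Kaiser-normalized), and scored per subject; groups with |rotated loading|
>= 0.40 label each pattern, and subjects at or above the 70th percentile of
a pattern score form its "high" group.

Standardized PCA is used because intake scales differ by orders of
magnitude, which would otherwise make the eigenvalue rule meaningless.
Quantiles use linear interpolation between order statistics; ties at the
cutoff all go to the high side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DietaryPatternResult",
    "aggregate_food_groups",
    "extract_patterns",
    "varimax",
    "dichotomize_scores",
]


def aggregate_food_groups(
    item_intake: pd.DataFrame,
    mapping: Mapping[str, str],
) -> pd.DataFrame:
    """Sum per-item daily intakes into food groups.

    ``mapping`` sends every item column to exactly one group name; any
    unmapped item is a configuration error.
    """
    unmapped = [c for c in item_intake.columns if c not in mapping]
    if unmapped:
        raise ValueError(f"items without a food-group mapping: {unmapped}")
    groups = sorted(set(mapping[c] for c in item_intake.columns))
    out = pd.DataFrame(
        {g: item_intake.loc[:, [c for c in item_intake.columns if mapping[c] == g]]
            .sum(axis=1) for g in groups},
        index=item_intake.index,
    )
    return out


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix; returns (rotated, rotation).

    The rotation matrix is orthonormal, so communalities (row sums of
    squared loadings) are preserved.  A single-column input is returned
    unchanged (the rotation is the 1x1 identity).
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    Ln = L / h[:, None] if kaiser_normalize else L.copy()
    R = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        Lr = Ln @ R
        grad = Ln.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        new_obj = s.sum()
        if new_obj < obj * (1.0 + tol):
            break
        obj = new_obj
    rotated = (Ln @ R) * (h[:, None] if kaiser_normalize else 1.0)
    return rotated, R


@dataclass
class DietaryPatternResult:
    """Retained, rotated dietary patterns with scores and labels."""

    loadings: pd.DataFrame          # groups x components, rotated
    eigenvalues: np.ndarray         # pre-rotation, for retained components
    all_eigenvalues: np.ndarray     # full spectrum, descending
    scores: pd.DataFrame            # subjects x components
    labels: dict[str, list[str]]    # component -> salient groups
    high_flags: pd.DataFrame        # subjects x components, bool
    rotation: np.ndarray

    @property
    def n_patterns(self) -> int:
        return self.loadings.shape[1]


def extract_patterns(
    group_intake: pd.DataFrame,
    eigen_threshold: float = 1.5,
    loading_threshold: float = 0.40,
    percentile: float = 70.0,
    n_components: int | None = None,
) -> DietaryPatternResult:
    """PCA + varimax dietary patterns from a subjects x groups intake table.

    ``n_components`` overrides the eigenvalue rule with a fixed count.
    Zero-variance group columns are dropped with a warning.  Component signs
    are fixed so the largest-|loading| group loads positively.
    """
    if len(group_intake) <= group_intake.shape[1]:
        raise ValueError("need more subjects than food groups")
    x = group_intake.astype(float)
    sd = x.std(ddof=1)
    dead = list(sd.index[sd == 0.0])
    if dead:
        warnings.warn(f"zero-variance group columns dropped: {dead}")
        x = x.drop(columns=dead)
        sd = sd.drop(index=dead)
    z = (x - x.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if n_components is None:
        n_keep = int((eigval > eigen_threshold).sum())
    else:
        n_keep = int(n_components)
    names = [f"pattern{i + 1}" for i in range(n_keep)]
    if n_keep == 0:
        empty = pd.DataFrame(index=x.columns)
        return DietaryPatternResult(
            loadings=empty, eigenvalues=np.empty(0), all_eigenvalues=eigval,
            scores=pd.DataFrame(index=x.index), labels={},
            high_flags=pd.DataFrame(index=x.index), rotation=np.empty((0, 0)),
        )

    raw_loadings = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    rotated, rotation = varimax(raw_loadings)
    # sign convention: dominant group of each component loads positively
    for j in range(n_keep):
        i_max = np.argmax(np.abs(rotated[:, j]))
        if rotated[i_max, j] < 0:
            rotated[:, j] *= -1.0
            rotation[:, j] *= -1.0

    loadings = pd.DataFrame(rotated, index=x.columns, columns=names)
    # regression-method factor scores from the rotated solution
    coef = np.linalg.solve(corr, rotated)
    score_arr = z.to_numpy() @ coef
    score_arr /= score_arr.std(axis=0, ddof=1)
    scores = pd.DataFrame(score_arr, index=x.index, columns=names)

    labels = {
        name: list(loadings.index[np.abs(loadings[name]) >= loading_threshold])
        for name in names
    }
    high = pd.DataFrame(
        {name: dichotomize_scores(scores[name], percentile) for name in names},
        index=x.index,
    )
    return DietaryPatternResult(
        loadings=loadings, eigenvalues=eigval[:n_keep], all_eigenvalues=eigval,
        scores=scores, labels=labels, high_flags=high, rotation=rotation,
    )


def dichotomize_scores(scores: pd.Series | np.ndarray, percentile: float = 70.0) -> pd.Series:
    """True where the score is at or above the empirical percentile cutoff.

    Uses the linear-interpolation quantile; equal scores land on the same
    side (>= cutoff is high).  Constant scores yield all-low with a warning.
    """
    s = pd.Series(scores).astype(float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if s.nunique() == 1:
        warnings.warn("constant scores: no high group")
        return pd.Series(False, index=s.index)
    cutoff = float(np.quantile(s.to_numpy(), percentile / 100.0))
    return s >= cutoff
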