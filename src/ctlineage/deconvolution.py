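"""Non-negative stepwise deconvolution of ctDNA into per-lesion parts.

ctDNA is a mixture of DNA shed by different tumour deposits (plus normal
cell-free DNA).  Given a features × tissue-samples design matrix ``X``
(feature values are per-sample mutation CCFs or methylation-haplotype
frequencies) and the matching ctDNA feature vector ``y``, the mixture is
modelled through the origin as ``y ≈ X β`` with ``β >= 0``.

Model selection follows a two-phase scheme:

1. **Forward**: starting from the empty model, repeatedly add the tissue
   sample whose non-negative least-squares (NNLS) refit maximises
   adjusted R²; stop at the first non-improving addition.
2. **Backward**: compute per-coefficient p-values from an ordinary
   least-squares refit on the selected support and recursively remove
   the least significant variable while any p > alpha (default 0.05).

Per-organ contributions are the sums of the coefficients of each organ's
samples (e.g. the summed liver coefficients quantify how much the plasma
reflects liver disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls as _scipy_nnls

logger = logging.getLogger(__name__)


@dataclass
class ContributionModel:
    """A selected set of tissue samples with non-negative coefficients."""

    samples: tuple[str, ...]
    beta: dict[str, float]
    adjusted_r2: float | None
    pvalues: dict[str, float]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.beta.values()):
            raise ValueError("coefficients must be non-negative")

    @property
    def is_empty(self) -> bool:
        return len(self.samples) == 0


def nnls_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve ``min ||X b - y||_2`` subject to ``b >= 0``.

    Returns ``(beta, residual norm)``.  At the solution the active-set
    KKT conditions hold: the gradient component is ~0 for positive
    coefficients and non-negative for zero ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("rows of X must match length of y")
    if X.shape[0] < X.shape[1]:
        logger.warning("NNLS with fewer features (%d) than samples (%d)",
                       X.shape[0], X.shape[1])
    beta, rnorm = _scipy_nnls(X, y)
    return beta, rnorm


def adjusted_r2(y: np.ndarray, fitted: np.ndarray, k: int) -> float:
    """Adjusted R²: ``1 - (1 - R²)(n - 1)/(n - k - 1)``.

    R² is computed against the mean of ``y``.  Requires ``n > k + 1``.
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = y.shape[0]
    if n <= k + 1:
        raise ValueError(f"adjusted R2 undefined for n={n}, k={k}")
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def stepwise_nnls(X: pd.DataFrame, y, alpha: float = 0.05
                  ) -> ContributionModel:
    """Forward-by-adjusted-R² NNLS selection with p > alpha pruning.

    ``X`` is features × candidate tissue samples; ``y`` the ctDNA feature
    vector on the same index.  Zero-variance feature rows across tissues
    are dropped before fitting (logged).  Backward-phase p-values come
    from an unconstrained OLS refit (no intercept) on the selected
    support; after pruning, the final coefficients are the NNLS solution
    on the surviving support.

    When every candidate is rejected the returned model is empty (with a
    diagnostic), not an error.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a features × samples DataFrame")
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate column")
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if X.shape[1] >= 2:
        keep_rows = X.var(axis=1, ddof=0) > 0
    else:  # the across-tissue variance filter is meaningless for one column
        keep_rows = pd.Series(True, index=X.index)
    n_dropped = int((~keep_rows).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance features", n_dropped)
    Xv = X.loc[keep_rows]
    yv = y.loc[keep_rows]
    diagnostics = {"n_features": int(keep_rows.sum()),
                   "n_zero_variance_dropped": n_dropped,
                   "forward_path": []}
    n = Xv.shape[0]
    candidates = list(Xv.columns)
    selected: list[str] = []
    # the empty mixture model predicts 0 for every feature
    best_adj = adjusted_r2(yv.to_numpy(), np.zeros(n), 0) if n > 1 else 0.0
    while candidates and n > len(selected) + 2:
        scores = []
        for c in candidates:
            cols = selected + [c]
            beta, _ = nnls_fit(Xv[cols].to_numpy(), yv.to_numpy())
            fitted = Xv[cols].to_numpy() @ beta
            scores.append((adjusted_r2(yv.to_numpy(), fitted, len(cols)), c))
        step_best, step_col = max(scores)
        if step_best <= best_adj:
            break
        selected.append(step_col)
        candidates.remove(step_col)
        best_adj = step_best
        diagnostics["forward_path"].append((step_col, step_best))
    if not selected:
        diagnostics["reason"] = "no candidate improved adjusted R2"
        return ContributionModel(samples=(), beta={}, adjusted_r2=None,
                                 pvalues={}, diagnostics=diagnostics)
    # backward pruning on OLS-refit p-values
    pvalues: dict[str, float] = {}
    while selected:
        ols = sm.OLS(yv.to_numpy(), Xv[selected].to_numpy()).fit()
        pvalues = dict(zip(selected, ols.pvalues))
        worst = max(selected, key=lambda c: pvalues[c])
        if pvalues[worst] > alpha:
            selected.remove(worst)
            diagnostics.setdefault("pruned", []).append(
                (worst, float(pvalues[worst])))
            pvalues.pop(worst)
        else:
            break
    if not selected:
        diagnostics["reason"] = "all variables pruned at alpha"
        return ContributionModel(samples=(), beta={}, adjusted_r2=None,
                                 pvalues={}, diagnostics=diagnostics)
    beta, _ = nnls_fit(Xv[selected].to_numpy(), yv.to_numpy())
    fitted = Xv[selected].to_numpy() @ beta
    adj = adjusted_r2(yv.to_numpy(), fitted, len(selected))
    return ContributionModel(
        samples=tuple(selected),
        beta={c: float(b) for c, b in zip(selected, beta)},
        adjusted_r2=float(adj),
        pvalues={c: float(pvalues[c]) for c in selected},
        diagnostics=diagnostics)


def summarize_contributions(model: ContributionModel,
                            organ_map: Mapping[str, str]
                            ) -> dict[str, dict[str, float]]:
    """Per-organ coefficient sums and normalised shares.

    ``organ_map`` assigns every selected sample to an organ; organs that
    appear in the map but received no selected sample report 0.  Raises
    ``KeyError`` for an unmapped selected sample.
    """
    for s in model.samples:
        if s not in organ_map:
            raise KeyError(f"sample {s!r} has no organ assignment")
    organs = sorted(set(organ_map.values()))
    sums = {o: 0.0 for o in organs}
    for s, b in model.beta.items():
        sums[organ_map[s]] += b
    total = sum(model.beta.values())
    shares = {o: (sums[o] / total if total > 0 else 0.0) for o in organs}
    return {"sums": sums, "shares": shares}
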