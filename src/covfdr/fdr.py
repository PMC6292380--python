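"""Plug-in false discovery rate estimation.

The covariate-adjusted FDR is the elementwise product of the BH-adjusted
p-values with the estimated null proportion pi0(x_i); the classical
scalar-pi0 q-value style estimator is the same product with a single pi0.
Because pi0 varies with x, the covariate product is deliberately NOT
re-monotonized in p: the plug-in is a plain product, and a feature with a
slightly larger p-value but a much smaller pi0(x) may legitimately have a
smaller estimated FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .pi0 import PValueSet, Pi0Fit, _as_pvalues

__all__ = ["FdrResults", "bh_adjust", "plugin_fdr", "storey_qvalue"]


@dataclass(frozen=True)
class FdrResults:
    """Per-feature adjusted quantities for one analysis."""

    bh_adjusted: np.ndarray
    fdr_covariate: np.ndarray
    fdr_storey: np.ndarray | None = None

    def discoveries(self, nominal: float = 0.05) -> np.ndarray:
        """Boolean vector: covariate-adjusted FDR at or below the nominal level."""
        if not 0.0 < nominal < 1.0:
            raise ValueError("nominal level must lie in (0, 1)")
        return self.fdr_covariate <= nominal


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} m p_(j) / j on the sorted scale, capped at 1.
    """
    pv = p.p if isinstance(p, PValueSet) else np.asarray(p, dtype=float)
    if pv.ndim != 1 or pv.size == 0:
        raise ValueError("p-values must form a non-empty vector")
    if not np.all((pv >= 0.0) & (pv <= 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    if pv.size == 1:
        return pv.copy()
    return multipletests(pv, method="fdr_bh")[1]


def plugin_fdr(pi0, bh_adjusted: np.ndarray) -> np.ndarray:
    """Covariate-adjusted plug-in FDR(x_i) = pi0(x_i) * BH_i, capped at 1."""
    pi0 = pi0.pi0 if isinstance(pi0, Pi0Fit) else np.asarray(pi0, dtype=float)
    bh = np.asarray(bh_adjusted, dtype=float)
    if pi0.shape != bh.shape:
        raise ValueError(
            f"pi0 and adjusted p-value vectors differ in shape: {pi0.shape} vs {bh.shape}"
        )
    return np.clip(pi0 * bh, 0.0, 1.0)


def storey_qvalue(p, pi0_scalar: float) -> np.ndarray:
    """Scalar-pi0 plug-in: pi0 * BH-adjusted p-values, capped at 1."""
    if not 0.0 < pi0_scalar <= 1.0:
        raise ValueError("pi0_scalar must lie in (0, 1]")
    return np.clip(pi0_scalar * bh_adjust(p), 0.0, 1.0)


def analyse(p, pi0_fit: Pi0Fit, pi0_scalar: float | None = None) -> FdrResults:
    """Convenience wrapper assembling FdrResults for one p-value set."""
    if isinstance(p, PValueSet):
        pv = p.p
    else:
        pv = _as_pvalues(p)
    bh = bh_adjust(pv)
    cov = plugin_fdr(pi0_fit, bh)
    storey = storey_qvalue(pv, pi0_scalar) if pi0_scalar is not None else None
    return FdrResults(bh_adjusted=bh, fdr_covariate=cov, fdr_storey=storey)
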