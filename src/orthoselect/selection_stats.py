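"""Likelihood-ratio tests and FDR control for the model-comparison schedule.

The pipeline runs a fixed schedule of nested comparisons: the site-model
pairs M0-vs-M3, M1a-vs-M2a, M7-vs-M8 and M8a-vs-M8, plus per-foreground
branch (two-ratio vs one-ratio) and branch-site (Model A vs its omega2=1
null) tests. 2*delta-lnL is compared to a chi-square distribution with the
schedule's degrees of freedom, and Benjamini-Hochberg FDR is applied within
each comparison family across clusters. For the two boundary comparisons
(M8a-vs-M8, branch-site) the plain chi-square(1) is conservative; a 50:50
chi0:chi1 mixture is available via ``boundary_mixture=True``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .codon_engine import ModelFit

log = logging.getLogger(__name__)

#: comparison -> (null model, alternative model, degrees of freedom)
SCHEDULE: dict[str, tuple[str, str, int]] = {
    "M0_vs_M3": ("M0", "M3k3", 4),
    "M1a_vs_M2a": ("M1a", "M2a", 2),
    "M7_vs_M8": ("M7", "M8", 2),
    "M8a_vs_M8": ("M8a", "M8", 1),
    "BR2_vs_M0": ("M0", "BR2", 1),
    "BSA_vs_BSA0": ("BSA0", "BSA", 1),
}

BOUNDARY_COMPARISONS = ("M8a_vs_M8", "BSA_vs_BSA0")


@dataclass(frozen=True)
class LRTResult:
    ogc_id: str
    comparison: str
    lnl_null: float
    lnl_alt: float
    np_null: int
    np_alt: int
    two_delta_lnl: float
    dof: int
    p_value: float
    q_value: float | None = None
    foreground: str | None = None

    @property
    def significant(self) -> bool:
        return self.q_value is not None and self.q_value < 0.05


def dof_for(comparison: str, null: ModelFit | None = None,
            alt: ModelFit | None = None) -> int:
    """Degrees of freedom for a scheduled comparison.

    When fits are supplied, their free-parameter difference must agree with
    the schedule constant — a disagreement means the models were wired wrong.
    """
    if comparison not in SCHEDULE:
        raise ValueError(f"unknown comparison {comparison!r}")
    dof = SCHEDULE[comparison][2]
    if null is not None and alt is not None:
        observed = alt.np_params - null.np_params
        if observed != dof:
            raise RuntimeError(
                f"{comparison}: np(alt) - np(null) = {observed}, expected {dof}")
    return dof


def lrt(null: ModelFit, alt: ModelFit, comparison: str, ogc_id: str = "",
        foreground: str | None = None,
        boundary_mixture: bool = False) -> LRTResult:
    """One likelihood-ratio test; negative 2*delta-lnL is clamped to 0.

    A deficit worse than -0.01 triggers a warning (optimizer-failure signal).
    """
    dof = dof_for(comparison, null, alt)
    delta = 2.0 * (alt.lnL - null.lnL)
    if delta < -0.01:
        warnings.warn(
            f"{ogc_id or '<?>'} {comparison}: 2dlnL = {delta:.4f} < 0 — "
            "alternative fit worse than null, likely optimizer failure",
            RuntimeWarning, stacklevel=2)
    delta = max(delta, 0.0)
    p = float(chi2.sf(delta, dof))
    if boundary_mixture and comparison in BOUNDARY_COMPARISONS:
        # 50:50 mixture of a point mass at 0 and chi-square(1)
        p = 1.0 if delta == 0.0 else 0.5 * float(chi2.sf(delta, dof))
    return LRTResult(ogc_id=ogc_id, comparison=comparison,
                     lnl_null=null.lnL, lnl_alt=alt.lnL,
                     np_null=null.np_params, np_alt=alt.np_params,
                     two_delta_lnl=delta, dof=dof, p_value=p,
                     foreground=foreground)


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values."""
    if not p_values:
        return []
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(x) for x in q]


def fdr_adjust(results: list[LRTResult], pooled: bool = False) -> list[LRTResult]:
    """Attach q-values: BH within each comparison family (default) or pooled.

    Returns results in the input order with ``q_value`` filled in.
    """
    if not results:
        return []
    if pooled:
        families = {"all": list(range(len(results)))}
    else:
        families: dict[str, list[int]] = {}
        for i, r in enumerate(results):
            families.setdefault(r.comparison, []).append(i)
    out: list[LRTResult | None] = [None] * len(results)
    for idx in families.values():
        qs = bh_adjust([results[i].p_value for i in idx])
        for i, q in zip(idx, qs):
            out[i] = replace(results[i], q_value=q)
    return out
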