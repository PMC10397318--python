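"""Conditional tissue-enrichment analysis.

Given a vector of per-tissue enrichment Z-scores and the tissue-tissue
correlation matrix, the top tissue is conditioned out by

    z'_s = (z_s - rho_ts * z_t) / sqrt(1 - rho_ts^2)

and the step is repeated on the updated panel until the maximum Z drops
below a significance stop (2.585, the lowest Z with FDR < 0.05 in the
upstream enrichment engine).  Each iteration reveals whether the remaining
tissues carry signal independent of the ones already conditioned on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class TissueZPanel:
    """Tissue enrichment Z-scores plus their correlation matrix."""

    labels: list[str]
    z: np.ndarray
    corr: np.ndarray

    def __post_init__(self):
        self.labels = list(self.labels)
        self.z = np.asarray(self.z, float)
        self.corr = np.asarray(self.corr, float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("tissue labels must be unique")
        if self.z.shape != (n,) or self.corr.shape != (n, n):
            raise ValueError("shape mismatch between labels, z and corr")
        if not np.allclose(self.corr, self.corr.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @classmethod
    def read_tsv(cls, z_path, corr_path) -> "TissueZPanel":
        zdf = pd.read_csv(z_path, sep="\t")
        cdf = pd.read_csv(corr_path, sep="\t", index_col=0)
        labels = list(zdf.iloc[:, 0].astype(str))
        corr = cdf.loc[labels, labels].to_numpy(float)
        return cls(labels, zdf.iloc[:, 1].to_numpy(float), corr)


@dataclass
class ConditionalStep:
    tissue: str
    z_before: pd.Series
    z_after: pd.Series
    max_z_after: float
    collinear_removed: list[str] = field(default_factory=list)


@dataclass
class ConditionalTrace:
    steps: list[ConditionalStep]
    final: TissueZPanel

    def __len__(self):
        return len(self.steps)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(iteration=i + 1, conditioned=s.tissue, max_z_after=s.max_z_after)
             for i, s in enumerate(self.steps)]
        )


def conditional_z(panel: TissueZPanel, t: int, update_corr: bool = True) -> TissueZPanel:
    """Condition the panel on tissue index ``t``.

    Every remaining tissue's Z becomes (z_s - rho_ts z_t)/sqrt(1 - rho_ts^2);
    the conditioned tissue leaves the panel.  Tissues perfectly correlated
    with it (|rho| = 1) are removed with a logged reason.  With
    ``update_corr`` the remaining correlations are replaced by partial
    correlations given the conditioned tissue, so repeated conditioning does
    not double-count shared signal; the raw-correlation behaviour is kept
    behind the flag for comparison.
    """
    n = len(panel.labels)
    rho = panel.corr[t]
    keep = [s for s in range(n) if s != t and abs(rho[s]) < 1 - 1e-12]
    dropped = [panel.labels[s] for s in range(n) if s != t and abs(rho[s]) >= 1 - 1e-12]
    for lab in dropped:
        log.info("conditional_z: tissue %s perfectly collinear with %s; removed",
                 lab, panel.labels[t])
    r = rho[keep]
    z_new = (panel.z[keep] - r * panel.z[t]) / np.sqrt(1 - r**2)
    sub = panel.corr[np.ix_(keep, keep)]
    if update_corr:
        denom = np.sqrt(np.outer(1 - r**2, 1 - r**2))
        sub = (sub - np.outer(r, r)) / denom
        np.fill_diagonal(sub, 1.0)
        sub = np.clip(sub, -1.0, 1.0)
    return TissueZPanel([panel.labels[s] for s in keep], z_new, sub)


def iterate_conditioning(
    panel: TissueZPanel,
    z_stop: float = 2.585,
    max_iter: int | None = None,
    update_corr: bool = True,
) -> ConditionalTrace:
    """Repeatedly condition on the current maximum-Z tissue while that
    maximum is at or above ``z_stop`` (signed maximum; ties broken by label
    order).  Returns the full trace."""
    max_iter = max_iter if max_iter is not None else len(panel.labels)
    steps: list[ConditionalStep] = []
    current = panel
    for _ in range(max_iter):
        if len(current.labels) == 0 or current.z.max(initial=-np.inf) < z_stop:
            break
        zs = pd.Series(current.z, index=current.labels)
        order = np.lexsort((current.labels, -current.z))
        t = int(order[0])
        before_labels = set(current.labels)
        nxt = conditional_z(current, t, update_corr=update_corr)
        removed = sorted(before_labels - set(nxt.labels) - {current.labels[t]})
        steps.append(
            ConditionalStep(
                tissue=current.labels[t],
                z_before=zs,
                z_after=pd.Series(nxt.z, index=nxt.labels),
                max_z_after=float(nxt.z.max(initial=-np.inf)),
                collinear_removed=removed,
            )
        )
        current = nxt
    return ConditionalTrace(steps, current)
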