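"""Module eigengenes and their relationships to sample traits.

The module eigengene (ME) is the first principal component of a module's
standardized probe x sample submatrix — a representative expression profile
per sample.  Correlating an eigengene with a sample trait (strain, tissue)
gives the eigengene significance; correlating every probe with an eigengene
gives module membership (kME).  A per-probe linear model with a
strain x tissue interaction term screens for probes whose regional effect
depends on genetic background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexnet.network import GREY

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Eigengene:
    module: str
    scores: pd.Series  # per-sample, zero mean, unit variance
    explained_variance: float


@dataclass(frozen=True)
class EigengeneSignificance:
    module: str
    trait: str
    r: float
    p: float


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return (x - mu) / sd


def _encode_trait(trait: pd.Series) -> np.ndarray:
    t = pd.Series(trait)
    if t.dtype == object or t.dtype.name in ("category", "bool"):
        levels = sorted(t.unique())
        if len(levels) != 2:
            raise ValueError(f"non-numeric trait must be binary, got levels {levels}")
        return (t == levels[1]).to_numpy(dtype=float)
    return t.to_numpy(dtype=float)


def module_eigengene(expr: pd.DataFrame, assignment: pd.Series) -> list[Eigengene]:
    """First principal component per module, sign-oriented.

    Each probe is standardized across samples; the eigengene is the first
    right-singular vector of the module submatrix, scaled to unit variance
    and oriented so that it correlates non-negatively with the module's
    average standardized profile.  Grey probes are excluded; zero-variance
    probes are dropped with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    out: list[Eigengene] = []
    for module in _module_order(assignment):
        members = assignment.index[assignment == module]
        sub = expr.loc[expr.index.intersection(members)]
        sd = sub.to_numpy().std(axis=1)
        if (sd == 0).any():
            log.warning("module %s: dropping %d zero-variance probes", module, int((sd == 0).sum()))
            sub = sub.loc[sd > 0]
        if len(sub) < 2:
            raise ValueError(f"module {module} has fewer than 2 usable probes")
        x = _standardize_rows(sub.to_numpy(dtype=float))
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        scores = vt[0]
        mean_profile = x.mean(axis=0)
        if mean_profile.std() > 0 and np.corrcoef(scores, mean_profile)[0, 1] < 0:
            scores = -scores
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        out.append(
            Eigengene(
                module=module,
                scores=pd.Series(scores, index=expr.columns, name=module),
                explained_variance=float(s[0] ** 2 / (s**2).sum()),
            )
        )
    return out


def _module_order(assignment: pd.Series) -> list[str]:
    sizes = assignment[assignment != GREY].value_counts()
    return sorted(sizes.index, key=lambda m: (-sizes[m], m))


def eigengene_significance(eg: Eigengene, trait: pd.Series, trait_name: str | None = None) -> EigengeneSignificance:
    """Pearson correlation between an eigengene and a sample trait.

    Binary traits are encoded 0/1 (point-biserial correlation); the p-value
    comes from the t-distribution with n - 2 degrees of freedom.
    """
    y = _encode_trait(trait)
    if len(y) != len(eg.scores):
        raise ValueError("trait length does not match number of samples")
    if np.std(y) == 0:
        raise ValueError("constant trait has undefined correlation")
    n = len(y)
    r = float(np.corrcoef(eg.scores.to_numpy(), y)[0, 1])
    if 1.0 - r**2 < 1e-15:  # |r| numerically 1: p underflows to the floor
        t = np.inf
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    name = trait_name if trait_name is not None else (trait.name or "trait")
    return EigengeneSignificance(module=eg.module, trait=str(name), r=r, p=max(p, np.finfo(float).tiny))


def module_membership(expr: pd.DataFrame, eigengenes: list[Eigengene]) -> pd.DataFrame:
    """kME table: Pearson correlation of every probe with every eigengene.

    Defined for all probes, including those outside the network subset.
    Zero-variance probes get NaN.
    """
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    cols = {}
    for eg in eigengenes:
        e = eg.scores.reindex(expr.columns).to_numpy()
        ec = e - e.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = (xc @ ec) / (xn * np.linalg.norm(ec))
        kme[xn == 0] = np.nan
        cols[eg.module] = kme
    return pd.DataFrame(cols, index=expr.index)


def interaction_scan(
    expr: pd.DataFrame,
    strain: pd.Series,
    tissue: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-probe OLS of expression ~ strain + tissue + strain:tissue.

    Returns a table with the interaction estimate, its two-sided t-test
    p-value, the Benjamini-Hochberg adjusted p-value, and a boolean
    ``significant`` column (adjusted p < ``alpha``).  Both factors must be
    binary with at least two samples per design cell.
    """
    s = _encode_trait(strain.reindex(expr.columns))
    t = _encode_trait(tissue.reindex(expr.columns))
    cells = pd.crosstab(s, t)
    if cells.shape != (2, 2) or (cells.to_numpy() < 2).any():
        raise ValueError("need at least 2 samples in every strain x tissue cell")

    design = np.column_stack([np.ones_like(s), s, t, s * t])
    y = expr.to_numpy(dtype=float).T  # samples x probes
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = design.shape[0] - design.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[3, 3])
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta[3] / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    p = np.where(np.isnan(p), 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "estimate": beta[3],
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=expr.index,
    )
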