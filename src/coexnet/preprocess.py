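"""Probe filtering, intensity transformation/normalization, variance selection.

Bead arrays report a per-probe, per-sample detection p-value against
negative-control background; probes never reliably detected carry no signal
and are removed before network construction.  Intensities are then put on a
variance-stabilized scale (log2 with floor 1 by default, asinh as an
alternative), optionally quantile-normalized across samples, and reduced to
the most variable probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    detection_alpha: float = 0.01
    detection_rule: str = "any_sample"  # or "min_fraction"
    min_fraction: float = 0.5
    transform: str = "log2"  # "asinh", or "none" for already-transformed input
    normalization: str = "quantile"  # or "none"
    top_k: int = 5000

    def validate(self) -> None:
        if not 0.0 < self.detection_alpha < 1.0:
            raise ValueError("detection_alpha must be in (0, 1)")
        if self.detection_rule not in ("any_sample", "min_fraction"):
            raise ValueError(f"unknown detection_rule {self.detection_rule!r}")
        if self.transform not in ("log2", "asinh", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.normalization not in ("quantile", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")


def detection_filter(
    expr: pd.DataFrame, detection: pd.DataFrame, cfg: PreprocessConfig
) -> pd.DataFrame:
    """Keep probes whose detection p-values pass the configured rule.

    ``any_sample`` keeps a probe detected (p < alpha) in at least one sample;
    ``min_fraction`` requires detection in at least ``min_fraction`` of
    samples.  Probe order is preserved.
    """
    cfg.validate()
    if not expr.index.equals(detection.index):
        raise ValueError("expression and detection matrices disagree on the probe axis")
    if not expr.columns.equals(detection.columns):
        raise ValueError("expression and detection matrices disagree on the sample axis")
    detected = (detection.to_numpy() < cfg.detection_alpha).mean(axis=1)
    if cfg.detection_rule == "any_sample":
        keep = detected > 0
    else:
        keep = detected >= cfg.min_fraction
    out = expr.loc[keep]
    log.info("detection filter kept %d of %d probes", len(out), len(expr))
    return out


def transform_normalize(expr: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """Variance-stabilize each sample, then optionally quantile-normalize.

    log2 floors values at 1 (a warning counts floored cells); asinh accepts
    any real input.  Quantile normalization replaces each sample's sorted
    values by the across-sample mean at that rank, so afterwards every sample
    shares one value multiset; ties receive the mean of their rank range.
    """
    cfg.validate()
    x = expr.to_numpy(dtype=float)
    if cfg.transform == "log2":
        n_floored = int((x < 1.0).sum())
        if n_floored:
            log.warning("log2 transform floored %d values below 1", n_floored)
        x = np.log2(np.maximum(x, 1.0))
    elif cfg.transform == "asinh":
        x = np.arcsinh(x)

    if cfg.normalization == "quantile":
        order = np.sort(x, axis=0)
        ref = order.mean(axis=1)
        ranks = np.apply_along_axis(rankdata, 0, x)  # average ranks for ties
        x = np.interp(ranks, np.arange(1, x.shape[0] + 1), ref)
    return pd.DataFrame(x, index=expr.index, columns=expr.columns)


def select_top_variance(expr: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Return the ``top_k`` probes with the largest across-sample variance.

    Ties at the cutoff are broken in favour of the lexicographically smaller
    probe ID, making the selection invariant to input row order.
    """
    if top_k > len(expr):
        raise ValueError(f"top_k={top_k} exceeds the {len(expr)} available probes")
    var = expr.var(axis=1, ddof=1)
    ranked = var.sort_index().sort_values(ascending=False, kind="stable")
    chosen = ranked.index[:top_k]
    return expr.loc[expr.index.isin(chosen)]
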