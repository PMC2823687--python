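"""Module preservation across sample subsets.

A module defined on all samples is preserved in a subset (one strain, one
tissue) if its internal wiring persists there.  Two checks are provided:
recomputing eigengene-trait significance inside the subset with the reference
module labels, and the connectivity-based preservation statistic — the
Pearson correlation of intramodular connectivities (kIM) computed separately
in the two subsets — with a permutation p-value against random same-size
probe sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexnet.network import GREY
from coexnet.traits import EigengeneSignificance, eigengene_significance, module_eigengene

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreservationResult:
    module: str
    subsets: str
    kim_correlation: float
    permutation_p: float
    n_permutations: int
    seed: int


def subset_eigengene_significance(
    expr_subset: pd.DataFrame,
    reference_assignment: pd.Series,
    trait: pd.Series,
    trait_name: str | None = None,
) -> list[EigengeneSignificance]:
    """Eigengene significance recomputed inside a sample subset.

    Module labels come from the reference (all-sample) network; eigengenes
    are recomputed over the subset samples only and correlated with the
    within-subset trait.  Modules left with fewer than 2 probes are skipped.
    """
    assignment = reference_assignment.loc[reference_assignment.index.intersection(expr_subset.index)]
    usable = assignment[assignment != GREY].value_counts()
    keep = usable.index[usable >= 2]
    skipped = set(usable.index) - set(keep)
    if skipped:
        log.warning("skipping modules with < 2 probes in subset: %s", sorted(skipped))
    assignment = assignment[assignment.isin(keep) | (assignment == GREY)]
    egs = module_eigengene(expr_subset.loc[assignment.index], assignment)
    trait_sub = trait.reindex(expr_subset.columns)
    return [eigengene_significance(eg, trait_sub, trait_name) for eg in egs]


def _intramodular_connectivity(expr: pd.DataFrame, beta: int) -> np.ndarray:
    r = np.corrcoef(expr.to_numpy(dtype=float))
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def connectivity_preservation(
    expr_subset_1: pd.DataFrame,
    expr_subset_2: pd.DataFrame,
    reference_assignment: pd.Series,
    module: str,
    beta: int = 8,
) -> float:
    """Correlation of intramodular connectivities between two sample subsets.

    Within each subset the adjacency among the module's probes alone is
    rebuilt at the same soft-threshold power and kIM_i = sum_j a_ij; the
    statistic is the Pearson correlation of the two kIM vectors.  High values
    mean the module's connectivity pattern is preserved across the subsets.
    """
    members = reference_assignment.index[reference_assignment == module]
    members = members.intersection(expr_subset_1.index).intersection(expr_subset_2.index)
    if len(members) < 3:
        raise ValueError(f"module {module!r} has fewer than 3 probes present in both subsets")
    k1 = _intramodular_connectivity(expr_subset_1.loc[members], beta)
    k2 = _intramodular_connectivity(expr_subset_2.loc[members], beta)
    if np.std(k1) == 0 or np.std(k2) == 0:
        raise ValueError("degenerate: constant intramodular connectivity vector")
    return float(np.corrcoef(k1, k2)[0, 1])


def preservation_permutation_p(
    expr_subset_1: pd.DataFrame,
    expr_subset_2: pd.DataFrame,
    assignment: pd.Series,
    module: str,
    n_perm: int = 1000,
    seed: int = 0,
    beta: int = 8,
    null_universe=None,
) -> PreservationResult:
    """Permutation p-value for the kIM-correlation preservation statistic.

    The null draws ``n_perm`` random probe sets of the module's size and
    recomputes the statistic; the one-sided empirical p is
    ``(1 + #{null >= observed}) / (n_perm + 1)`` (preservation is
    directional: the alternative is "more preserved than random").

    Null sets are drawn from the probes present in both expression subsets,
    excluding members of any detected (non-grey) module: probes belonging to
    other modules carry genuinely preserved connectivity, and a null set
    mixing module and background probes inherits a preserved high-vs-low
    connectivity split, which would make the null all but impossible to
    beat.  Pass ``null_universe`` to override.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = expr_subset_1.index.intersection(expr_subset_2.index)
    members = assignment.index[assignment == module].intersection(universe)
    size = len(members)
    if null_universe is not None:
        universe = pd.Index(null_universe).intersection(universe)
    else:
        unassigned = {GREY, "none"}  # detected networks use grey; planted truth uses none
        assigned = assignment.index[assignment.isin(set(assignment.unique()) - unassigned)]
        universe = universe.difference(assigned)
    if size > len(universe):
        raise ValueError("module size exceeds the probe universe")
    observed = connectivity_preservation(expr_subset_1, expr_subset_2, assignment, module, beta)

    rng = np.random.default_rng(seed)
    x1 = expr_subset_1.loc[universe].to_numpy(dtype=float)
    x2 = expr_subset_2.loc[universe].to_numpy(dtype=float)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(len(universe), size=size, replace=False)
        k1 = _intramodular_connectivity(pd.DataFrame(x1[idx]), beta)
        k2 = _intramodular_connectivity(pd.DataFrame(x2[idx]), beta)
        if np.std(k1) == 0 or np.std(k2) == 0:
            null[b] = np.nan
            continue
        null[b] = np.corrcoef(k1, k2)[0, 1]
    valid = null[~np.isnan(null)]
    p = (1.0 + float((valid >= observed).sum())) / (len(valid) + 1.0)
    return PreservationResult(
        module=module,
        subsets="subset1|subset2",
        kim_correlation=observed,
        permutation_p=p,
        n_permutations=n_perm,
        seed=seed,
    )
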