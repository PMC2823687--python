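"""Synthetic expression datasets with planted co-expression module structure.

The generator emulates a two-strain (A/J vs C57BL/6J), two-brain-region
(amygdala vs hippocampus) bead-array study: block-correlated modules driven by
a shared latent factor, tissue-driven modules with both up- and down-regulated
probes, and one strain-driven "artifact" module whose probes are
systematically attenuated in a single strain because their targets are
polymorphic (only a fraction of the polymorphisms being known to the SNP
catalog) — the signature of a hybridization artifact rather than a
biological strain effect.  A matching
synthetic genome (gene intervals, 50-bp probe intervals, positioned SNP
catalog, cis-eQTL status labels) feeds the downstream enrichment diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENE_LENGTH = 20_000
GENE_SPACING = 30_000  # start-to-start distance on a chromosome
PROBE_LENGTH = 50
PROBE_OFFSET = 5_000  # probe start relative to gene start

DRIVERS = ("tissue", "strain_artifact", "none")
# per-probe factor loadings are Uniform(LOADING_LO, LOADING_HI); the wide
# range gives modules a realistic membership gradient (kME roughly 0.5-0.95)
# and hence hub structure in intramodular connectivity
LOADING_LO = 0.5
LOADING_HI = 1.0
EQTL_STATUSES = ("real_cis", "false_cis", "none", "unknown")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: its size, what drives it, and its effect geometry.

    ``direction_mix`` is the fraction of probes with a positive sign; tissue
    modules at 0.5 contain both up- and down-regulated probes, while the
    strain-artifact module is one-directional (all probes attenuated the same
    way in the affected strain).  ``trait_share`` is the fraction of a driver
    module's shared signal variance contributed by the trait effect itself;
    the remainder comes from a module-specific latent factor, so lower values
    give a module whose eigengene tracks the trait less tightly while staying
    internally coherent and distinct from other modules.
    """

    name: str
    size: int
    driver: str = "none"
    effect: float = 1.0
    direction_mix: float = 0.5
    trait_share: float = 0.9


@dataclass(frozen=True)
class SyntheticDesign:
    """Full parameterisation of a synthetic dataset.

    Defaults reproduce the study geometry this package is built around:
    35 samples (17 amygdala: 8 A/J + 9 C57BL/6J; 18 hippocampus: 9 + 9),
    2000 probes with two tissue-driven modules (200 and 80 probes) and one
    80-probe strain-artifact module whose probes lose ``effect`` log2 units
    of intensity in A/J; known-SNP flags cover 0.4 of its probes versus a
    0.02 background rate.
    """

    n_probes: int = 2000
    sample_plan: tuple = (
        ("A/J", "amygdala", 8),
        ("C57BL/6J", "amygdala", 9),
        ("A/J", "hippocampus", 9),
        ("C57BL/6J", "hippocampus", 9),
    )
    module_specs: tuple = (
        ModuleSpec("tissue_major", 200, "tissue", 1.0, 0.5, trait_share=0.93),
        ModuleSpec("tissue_minor", 80, "tissue", 1.0, 0.5, trait_share=0.65),
        ModuleSpec("strain_artifact", 80, "strain_artifact", 1.0, 1.0, trait_share=0.95),
    )
    within_module_cor: float = 0.7
    noise_sd: float = 0.2
    baseline_mean: float = 9.0
    snp_flag_rate_artifact: float = 0.4
    snp_flag_rate_background: float = 0.02
    undetected_fraction: float = 0.05
    snp_density: float = 1.0 / 1500.0  # SNPs per bp of gene region
    nonsyn_frac_artifact: float = 0.008
    nonsyn_frac_background: float = 0.002
    synonymous_frac: float = 0.01
    seed: int = 11

    def validate(self) -> None:
        if sum(m.size for m in self.module_specs) > self.n_probes:
            raise ValueError("invalid design: sum of module sizes exceeds n_probes")
        for m in self.module_specs:
            if m.driver not in DRIVERS:
                raise ValueError(f"invalid design: unknown driver {m.driver!r}")
            if not 0.0 <= m.direction_mix <= 1.0:
                raise ValueError("invalid design: direction_mix outside [0, 1]")
            if not 0.0 < m.trait_share <= 1.0:
                raise ValueError("invalid design: trait_share outside (0, 1]")
        for name in (
            "snp_flag_rate_artifact",
            "snp_flag_rate_background",
            "undetected_fraction",
            "nonsyn_frac_artifact",
            "nonsyn_frac_background",
            "synonymous_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid design: {name} outside [0, 1]")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("invalid design: within_module_cor outside (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("invalid design: noise_sd must be > 0")
        if any(n < 2 for _, _, n in self.sample_plan):
            raise ValueError("invalid design: fewer than 2 samples in a (strain, tissue) cell")
        if self.snp_density < 0:
            raise ValueError("invalid design: snp_density must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated expression data plus the ground truth it was planted with."""

    expression: pd.DataFrame  # probes x samples, log2-like scale
    detection: pd.DataFrame  # same shape, detection p-values in [0, 1]
    traits: pd.DataFrame  # sample x (strain, tissue)
    truth: pd.Series  # probe -> planted module name ("none" = background)
    probe_records: pd.DataFrame  # probe annotation incl. snp_in_probe, eqtl_status
    snp_catalog: pd.DataFrame  # chrom, pos (1-based), cls
    factors: pd.DataFrame | None = None  # planted module factors (module x sample)


def _sample_frame(plan) -> pd.DataFrame:
    rows = []
    for strain, tissue, n in plan:
        tag = f"{strain.split('/')[0].replace('57BL', '')}_{tissue[:3]}"
        for i in range(n):
            rows.append((f"{tag}_{i + 1:02d}", strain, tissue))
    df = pd.DataFrame(rows, columns=["sample", "strain", "tissue"]).set_index("sample")
    if df.index.has_duplicates:
        raise ValueError("invalid design: duplicate sample IDs")
    return df


def _probe_annotation(design: SyntheticDesign, truth: pd.Series) -> pd.DataFrame:
    """Lay genes on one chromosome per module (plus one for background)."""
    labels = list(dict.fromkeys(truth))
    chrom_of = {lab: f"chr{i + 1}" for i, lab in enumerate(labels)}
    idx_within: dict[str, int] = {}
    rows = []
    for probe, lab in truth.items():
        i = idx_within.get(lab, 0)
        idx_within[lab] = i + 1
        gene_start = 1 + i * GENE_SPACING
        gene_end = gene_start + GENE_LENGTH - 1
        probe_start = gene_start + PROBE_OFFSET
        rows.append(
            (
                probe,
                lab,
                chrom_of[lab],
                gene_start,
                gene_end,
                probe_start,
                probe_start + PROBE_LENGTH - 1,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["probe", "module_truth", "chrom", "gene_start", "gene_end", "probe_start", "probe_end"],
    ).set_index("probe")


def generate_dataset(design: SyntheticDesign) -> SyntheticDataset:
    """Draw a complete synthetic dataset from a validated design.

    Module probe *i* in sample *s* follows the latent-factor model
    ``x_is = baseline + loading_i * f_s + group effects + eps`` with
    ``eps ~ N(0, noise_sd)``.  For driver modules the factor variance is set
    from ``trait_share`` (the balance of the shared signal not explained by
    the trait effect); for background-driver modules it is calibrated so the
    expected pairwise within-module correlation equals ``within_module_cor``.
    Tissue-driver modules add ``±effect`` in hippocampus (sign per probe,
    fraction positive = ``direction_mix``); strain-artifact modules subtract
    ``effect`` in A/J for every module probe — the attenuation is physical,
    while the SNP catalog only *flags* the known fraction.  Identical designs
    (same seed) give identical output.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    traits = _sample_frame(design.sample_plan)
    n_samples = len(traits)
    probes = pd.Index([f"probe_{i:04d}" for i in range(design.n_probes)], name="probe")

    truth = pd.Series("none", index=probes, name="module_truth")
    pos = 0
    for m in design.module_specs:
        truth.iloc[pos : pos + m.size] = m.name
        pos += m.size

    strains = list(dict.fromkeys(traits["strain"]))
    tissues = list(dict.fromkeys(traits["tissue"]))
    attenuated_strain = strains[0]  # A/J under the default plan
    shifted_tissue = tissues[-1]  # hippocampus under the default plan
    in_attenuated = (traits["strain"] == attenuated_strain).to_numpy()
    in_shifted = (traits["tissue"] == shifted_tissue).to_numpy()

    x = design.baseline_mean + rng.normal(0.0, design.noise_sd, size=(design.n_probes, n_samples))

    # the factor variance is scaled by E[l^2] of the loading distribution so
    # pairwise correlations land where intended
    lo, hi = LOADING_LO, LOADING_HI
    mean_sq_loading = (hi**3 - lo**3) / (3.0 * (hi - lo))
    mean_loading = (hi + lo) / 2.0
    c = design.within_module_cor
    background_factor_var = design.noise_sd**2 * c / ((1.0 - c) * mean_sq_loading)

    snp_flag = rng.random(design.n_probes) < design.snp_flag_rate_background
    factors: dict[str, np.ndarray] = {}
    pos = 0
    for m in design.module_specs:
        sl = slice(pos, pos + m.size)
        pos += m.size
        if m.driver == "tissue":
            group = in_shifted.astype(float)
        elif m.driver == "strain_artifact":
            group = in_attenuated.astype(float)
        else:
            group = np.zeros(n_samples)
        # driver modules: the factor supplies the (1 - trait_share) balance of
        # the shared signal variance; background modules: within_module_cor
        effect_var = m.effect**2 * group.var()
        if m.driver != "none" and effect_var > 0:
            factor_var = effect_var * (1.0 - m.trait_share) / (m.trait_share * mean_sq_loading)
        else:
            factor_var = background_factor_var
        factor = rng.normal(0.0, np.sqrt(factor_var), size=n_samples)
        loadings = rng.uniform(lo, hi, size=m.size)
        signs = np.where(rng.random(m.size) < m.direction_mix, 1.0, -1.0)
        x[sl] += np.outer(signs * loadings, factor)
        factors[m.name] = factor
        # per-probe response magnitudes follow the loadings (normalized to
        # mean 1 so the average planted shift equals `effect`): high-loading
        # probes are module hubs in every sample subset, giving modules the
        # intramodular-connectivity heterogeneity real networks show
        probe_effect = m.effect * loadings / mean_loading
        if m.driver == "tissue":
            x[sl] += np.outer(signs * probe_effect, group)
        elif m.driver == "strain_artifact":
            # hybridization artifact: every module probe hybridizes worse in
            # the non-reference strain (probes harbour polymorphisms whether
            # or not the SNP catalog knows them); the catalog flags only the
            # snp_flag_rate_artifact fraction as known SNPs
            snp_flag[sl] = rng.random(m.size) < design.snp_flag_rate_artifact
            x[sl] -= np.outer(signs * probe_effect, group)

    expression = pd.DataFrame(x, index=probes, columns=traits.index)

    # detection p-values: tight for expressed probes, diffuse for a fraction
    # of background probes declared "undetected" in every sample
    detection = pd.DataFrame(
        rng.uniform(0.0, 0.005, size=x.shape), index=probes, columns=traits.index
    )
    background = np.flatnonzero((truth == "none").to_numpy())
    n_undetected = min(int(round(design.undetected_fraction * design.n_probes)), background.size)
    if n_undetected:
        undetected = rng.choice(background, size=n_undetected, replace=False)
        detection.iloc[undetected] = rng.uniform(0.1, 1.0, size=(n_undetected, n_samples))

    records = _probe_annotation(design, truth)
    records["snp_in_probe"] = snp_flag

    # cis-eQTL status: flagged artifact probes skew towards apparent ("false")
    # cis signals, unflagged ones towards real cis effects
    artifact_names = {m.name for m in design.module_specs if m.driver == "strain_artifact"}
    status = np.full(design.n_probes, "unknown", dtype=object)
    in_artifact = truth.isin(artifact_names).to_numpy()
    u = rng.random(design.n_probes)
    flagged = in_artifact & snp_flag
    unflagged = in_artifact & ~snp_flag
    status[flagged] = np.select([u[flagged] < 0.40, u[flagged] < 0.50], ["false_cis", "real_cis"], "none")
    status[unflagged] = np.select(
        [u[unflagged] < 0.35, u[unflagged] < 0.50], ["real_cis", "false_cis"], "none"
    )
    records["eqtl_status"] = status

    catalog = generate_snp_catalog(design, records)

    return SyntheticDataset(
        expression=expression,
        detection=detection,
        traits=traits,
        truth=truth,
        probe_records=records,
        snp_catalog=catalog,
        factors=pd.DataFrame(factors, index=traits.index).T,
    )


def generate_snp_catalog(design: SyntheticDesign, probe_records: pd.DataFrame) -> pd.DataFrame:
    """Position SNPs on the synthetic genome described by ``probe_records``.

    Background SNPs fall as a Poisson process of rate ``snp_density`` per bp
    over each gene interval, avoiding un-flagged probe intervals so that the
    probe flags in ``probe_records`` stay authoritative; every SNP-flagged
    probe receives one SNP inside its 50-bp interval.  Genes of
    strain-artifact modules draw their SNP classes with the elevated
    non-synonymous fraction.
    """
    if (probe_records["gene_start"] < 1).any():
        raise ValueError("negative or zero gene coordinates are not allowed")
    rng = np.random.default_rng(None if design.seed is None else design.seed + 1)

    artifact_names = {m.name for m in design.module_specs if m.driver == "strain_artifact"}
    chroms, positions, classes = [], [], []

    def draw_class(n: int, nonsyn_frac: float) -> np.ndarray:
        u = rng.random(n)
        return np.select(
            [u < nonsyn_frac, u < nonsyn_frac + design.synonymous_frac],
            ["non_synonymous", "synonymous"],
            "other",
        )

    for probe, rec in probe_records.iterrows():
        nonsyn_frac = (
            design.nonsyn_frac_artifact
            if rec["module_truth"] in artifact_names
            else design.nonsyn_frac_background
        )
        length = rec["gene_end"] - rec["gene_start"] + 1
        n_snps = rng.poisson(design.snp_density * length)
        if n_snps:
            p = rng.integers(rec["gene_start"], rec["gene_end"] + 1, size=n_snps)
            if not rec["snp_in_probe"]:
                p = p[(p < rec["probe_start"]) | (p > rec["probe_end"])]
            chroms.append(np.full(p.size, rec["chrom"], dtype=object))
            positions.append(p)
            classes.append(draw_class(p.size, nonsyn_frac))
        if rec["snp_in_probe"]:
            chroms.append(np.array([rec["chrom"]], dtype=object))
            positions.append(rng.integers(rec["probe_start"], rec["probe_end"] + 1, size=1))
            classes.append(draw_class(1, nonsyn_frac))

    if not positions:
        return pd.DataFrame(columns=["chrom", "pos", "cls"])
    catalog = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions).astype(np.int64),
            "cls": np.concatenate(classes),
        }
    )
    return catalog.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
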