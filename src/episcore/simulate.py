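"""Synthetic cohorts with full ground truth.

The generator emulates a targeted-bisulfite kidney-transplant cohort: a
reference panel of immune cell-type methylomes with planted hypomethylated
marker blocks, Dirichlet cell-type mixtures per blood sample, additive
per-CpG trait effects (induction immunosuppression, infection risk,
transplant, serostatus, sex, age), exponential/Weibull infection times whose
hazard follows a latent infection propensity, and optionally a gene
expression matrix anticorrelated with methylation at mapped sites.

Every generator is a pure function of (config, root seed): streams are
derived per component (see :mod:`episcore._seeds`) so outputs are
bit-reproducible and adding a generator never perturbs existing streams.
Effects are injected additively and recorded exactly in :class:`GroundTruth`,
so expected group differences can be recomputed without the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .io import ValidationError, site_key

__all__ = [
    "SimulationConfig",
    "ReferencePanel",
    "GroundTruth",
    "simulate_reference_panel",
    "simulate_cohort",
    "simulate_survival",
    "simulate_expression",
    "make_site_gene_mapping",
    "simulate_epiage_moderation",
]

_DEFAULT_CELLTYPES = ("CD4T", "CD8T", "Bcell", "NK", "naiveT", "mono")
# PBMC-like skew: CD4 > naive T > CD8 ~ mono > B ~ NK
_DEFAULT_ALPHA6 = (9.0, 4.0, 3.0, 3.0, 6.0, 5.0)


def _default_trait_effects() -> dict:
    # trait -> (n affected sites, per-site effect on the methylation fraction);
    # binary effects are hypermethylating, the age slope is per year with
    # random sign per site.
    return {
        "atg": (100, 0.15),
        "infection_risk": (100, 0.10),
        "transplant": (100, 0.10),
        "cmv": (50, 0.10),
        "sex": (50, 0.10),
        "age": (200, 0.002),
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.  Defaults mirror the emulated design:
    ~90 subjects sampled pre/post transplant, an 8,000-site targeted panel,
    six reference cell types, and a 365-day infection follow-up window."""

    n_subjects: int = 90
    paired: bool = True
    n_sites: int = 8000
    n_celltypes: int = 6
    replicates_per_celltype: int = 4
    site_spacing_bp: int = 100
    chrom: str = "chrS"
    dmr_blocks_per_celltype: int = 5
    dmr_block_length_bp: int = 600
    dmr_delta: float = -0.40
    dmr_background: float = 0.90
    replicate_concentration: float = 300.0
    trait_effects: dict = field(default_factory=_default_trait_effects)
    noise_sd: float = 0.05
    dirichlet_alpha: tuple | None = None
    age_range: tuple = (25.0, 70.0)
    atg_prevalence: float = 0.5
    cmv_prevalence: float = 0.6
    male_prevalence: float = 0.5
    n_ancestry_pcs: int = 2
    risk_quantile: float = 0.70
    propensity_weights: dict = field(
        default_factory=lambda: {"age": 0.8, "atg": 1.0, "cmv": 0.8}
    )
    propensity_noise_sd: float = 1.0
    survival_model: str = "exponential"
    weibull_shape: float = 1.5
    baseline_rate: float = 0.002
    log_hazard: float = float(np.log(2.0))
    censor_day: int = 365
    expr_intercept: float = 8.0
    expr_slope: float = 4.0
    expr_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sites", "n_celltypes", "replicates_per_celltype",
                     "site_spacing_bp", "dmr_block_length_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.dmr_blocks_per_celltype < 0:  # 0 = null panel, no planted markers
            raise ValidationError("dmr_blocks_per_celltype must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not -1.0 < self.dmr_delta < 0.0:
            raise ValidationError("dmr_delta must be a negative fraction in (-1, 0)")
        if not 0.0 < self.dmr_background + self.dmr_delta:
            raise ValidationError("dmr_background + dmr_delta must stay in (0, 1)")

    @property
    def celltype_names(self) -> list[str]:
        if self.n_celltypes == len(_DEFAULT_CELLTYPES):
            return list(_DEFAULT_CELLTYPES)
        return [f"CT{i + 1}" for i in range(self.n_celltypes)]

    @property
    def alpha(self) -> np.ndarray:
        if self.dirichlet_alpha is not None:
            a = np.asarray(self.dirichlet_alpha, dtype=float)
            if a.shape != (self.n_celltypes,):
                raise ValidationError("dirichlet_alpha length must equal n_celltypes")
            return a
        if self.n_celltypes == 6:
            return np.asarray(_DEFAULT_ALPHA6)
        return np.full(self.n_celltypes, 5.0)


@dataclass
class ReferencePanel:
    """Cell-type methylomes with replicates, aligned to matrix site keys.

    ``profiles``: sites x (celltype, replicate) MultiIndex DataFrame of
    methylation fractions; ``base_profiles``: the noise-free per-type means.
    """

    profiles: pd.DataFrame
    base_profiles: pd.DataFrame

    @property
    def site_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def celltypes(self) -> list[str]:
        return list(self.profiles.columns.get_level_values(0).unique())

    @property
    def n_replicates(self) -> int:
        ct = self.celltypes[0]
        return self.profiles[ct].shape[1]

    def mean_profiles(self) -> pd.DataFrame:
        """Replicate-mean methylome per cell type (sites x celltypes)."""
        return self.profiles.T.groupby(level=0).mean().T[self.celltypes]


@dataclass
class GroundTruth:
    """Exact record of everything the generator injected."""

    cell_fractions: pd.DataFrame          # samples x celltypes, rows sum to 1
    effect_sites: dict                    # trait -> Series site_key -> signed effect
    trait_indicator: pd.DataFrame         # samples x traits, value multiplied by effects
    propensity: pd.Series                 # per subject latent infection propensity
    log_hazard: float
    marker_sites: list                    # site keys inside planted DMR blocks


def _site_positions(config: SimulationConfig) -> np.ndarray:
    return 1 + np.arange(config.n_sites) * config.site_spacing_bp


def simulate_reference_panel(config: SimulationConfig):
    """Simulate cell-type reference methylomes with planted marker blocks.

    Each cell type receives ``dmr_blocks_per_celltype`` hypomethylated blocks
    spanning ``dmr_block_length_bp`` where its mean sits ``dmr_delta`` below
    the (shared) background of all other types.  Elsewhere the methylome is a
    shared bimodal baseline (masses near 0.05 and 0.95).  Replicates add
    beta-distributed noise around the type mean.

    Returns
    -------
    (ReferencePanel, DataFrame)
        The panel and the true marker regions (chrom/start/end/label/score,
        BED convention, score = planted delta).
    """
    if config.n_celltypes < 2:
        raise ValidationError("need at least 2 cell types")
    if config.replicates_per_celltype < 2:
        raise ValidationError("need >= 2 replicates per cell type (region testing)")

    rng = rng_for(config.seed, "reference_panel")
    positions = _site_positions(config)
    sites = [site_key(config.chrom, p) for p in positions]
    names = config.celltype_names

    block_len = config.dmr_block_length_bp // config.site_spacing_bp + 1
    n_blocks = config.n_celltypes * config.dmr_blocks_per_celltype
    stride = config.n_sites // (n_blocks + 1) if n_blocks else config.n_sites
    # keep blocks separated by more than the caller's run gap
    if n_blocks and stride < block_len + 8:
        raise ValidationError(
            "configured marker blocks exceed n_sites (blocks would overlap)"
        )

    # bimodal bulk (masses near 0.05 / 0.95) plus a partially-methylated
    # intermediate fraction, as in real CpG methylomes
    comp = rng.choice(3, size=config.n_sites, p=(0.4, 0.4, 0.2))
    low = rng.beta(2.0, 38.0, size=config.n_sites)
    high = rng.beta(38.0, 2.0, size=config.n_sites)
    mid = rng.beta(8.0, 8.0, size=config.n_sites)
    baseline = np.select([comp == 0, comp == 1], [low, high], default=mid)

    base = np.tile(baseline[:, None], (1, config.n_celltypes))
    assignments = [(ct, b) for ct in range(config.n_celltypes)
                   for b in range(config.dmr_blocks_per_celltype)]
    order = rng.permutation(len(assignments))
    regions = []
    marker_sites: list[str] = []
    for slot, idx in enumerate(order):
        ct, _ = assignments[idx]
        start_i = (slot + 1) * stride
        sl = slice(start_i, start_i + block_len)
        base[sl, :] = config.dmr_background
        base[sl, ct] = config.dmr_background + config.dmr_delta
        first, last = positions[start_i], positions[start_i + block_len - 1]
        regions.append((config.chrom, int(first) - 1, int(last), names[ct],
                        float(config.dmr_delta)))
        marker_sites.extend(sites[sl])

    conc = config.replicate_concentration
    means = np.clip(base, 0.005, 0.995)
    cols = pd.MultiIndex.from_product(
        [names, [f"rep{r + 1}" for r in range(config.replicates_per_celltype)]],
        names=["celltype", "replicate"],
    )
    reps = np.empty((config.n_sites, len(cols)))
    for j, ct in enumerate(names):
        m = means[:, j]
        for r in range(config.replicates_per_celltype):
            reps[:, j * config.replicates_per_celltype + r] = rng.beta(
                m * conc, (1.0 - m) * conc
            )
    panel = ReferencePanel(
        profiles=pd.DataFrame(reps, index=pd.Index(sites, name="site"), columns=cols),
        base_profiles=pd.DataFrame(base, index=pd.Index(sites, name="site"), columns=names),
    )
    true_dmrs = pd.DataFrame(regions, columns=["chrom", "start", "end", "label", "score"])
    panel._marker_sites = marker_sites  # noqa: SLF001 - carried into GroundTruth
    return panel, true_dmrs


def _assign_effect_sites(config: SimulationConfig, sites: list[str],
                         marker_sites: set, expected_mean: pd.Series,
                         rng: np.random.Generator) -> dict:
    """Disjoint random per-trait effect-site sets, excluding marker blocks.

    Effects are planted only where the shift fits inside [0, 1] with margin
    (hypermethylation needs headroom below 1; the signed age slope needs a
    mid-range baseline), so the injected group difference survives clipping
    and stays exactly recomputable from GroundTruth.
    """
    candidates = [s for s in sites if s not in marker_sites]
    rng.shuffle(candidates)
    taken: set[str] = set()
    out = {}
    # assign the signed age slope first: it has the tightest headroom window
    order = sorted(config.trait_effects, key=lambda t: t != "age")
    for trait in order:
        n, eff = config.trait_effects[trait]
        if trait == "age":
            span = abs(eff) * (config.age_range[1] - config.age_range[0]) / 2
            ok = lambda m: span + 0.05 <= m <= 0.95 - span  # noqa: E731
        elif eff >= 0:
            ok = lambda m: 0.02 <= m <= 0.95 - eff  # noqa: E731
        else:
            ok = lambda m: 0.05 - eff <= m <= 0.98  # noqa: E731
        chosen = []
        for s in candidates:
            if s in taken or not ok(expected_mean[s]):
                continue
            chosen.append(s)
            taken.add(s)
            if len(chosen) == n:
                break
        if len(chosen) < n:
            raise ValidationError(
                f"trait {trait!r} requests {n} effect sites; only {len(chosen)} "
                "candidates satisfy the headroom constraint"
            )
        if trait == "age":
            signs = rng.choice([-1.0, 1.0], size=n)
        else:
            signs = np.ones(n)
        out[trait] = pd.Series(signs * eff, index=pd.Index(chosen, name="site"))
    return out


def simulate_cohort(config: SimulationConfig, panel: ReferencePanel):
    """Simulate a mixed-cell-type methylation cohort with injected effects.

    Per sample: cell fractions ~ Dirichlet(alpha); the pre-noise methylome is
    the fraction-weighted average of the cell-type mean profiles; trait
    effects are added at their recorded sites; Gaussian noise (sd
    ``noise_sd``) is added and values are clipped to [0, 1].

    In paired mode each subject contributes a pre- and a post-transplant
    sample; the metadata ``atg`` field is the subject's induction arm and the
    ATG methylation effect is applied to post samples of ATG subjects only.
    In unpaired mode each subject contributes one sample and the ATG effect
    applies wherever ``atg == yes``.

    Returns ``(matrix, metadata, truth)`` with the matrix sites x samples.
    """
    t_rng = rng_for(config.seed, "cohort_traits")
    f_rng = rng_for(config.seed, "cohort_fractions")
    n_rng = rng_for(config.seed, "cohort_noise")
    e_rng = rng_for(config.seed, "effect_sites")

    names = config.celltype_names
    ref_means = panel.mean_profiles()[names]
    sites = list(ref_means.index)

    n_sub = config.n_subjects
    subjects = [f"S{i + 1:03d}" for i in range(n_sub)]
    age = t_rng.uniform(*config.age_range, size=n_sub)
    sex = np.where(t_rng.random(n_sub) < config.male_prevalence, "M", "F")
    cmv = np.where(t_rng.random(n_sub) < config.cmv_prevalence, "positive", "negative")
    atg = np.where(t_rng.random(n_sub) < config.atg_prevalence, "yes", "no")
    ancestry = t_rng.standard_normal((n_sub, config.n_ancestry_pcs))

    if config.paired:
        rows = [(s, f"{s}_{tp}", tp) for s in subjects for tp in ("pre", "post")]
    else:
        timepoints = np.where(t_rng.random(n_sub) < 0.5, "pre", "post")
        rows = [(s, f"{s}_x", tp) for s, tp in zip(subjects, timepoints)]
    subj_of = {sid: s for s, sid, _ in rows}
    sample_ids = [sid for _, sid, _ in rows]
    tp_of = {sid: tp for _, sid, tp in rows}
    sub_idx = {s: i for i, s in enumerate(subjects)}

    # latent infection propensity (subject level)
    zage = (age - age.mean()) / age.std()
    w = config.propensity_weights
    prop = (w.get("age", 0.0) * zage
            + w.get("atg", 0.0) * (atg == "yes")
            + w.get("cmv", 0.0) * (cmv == "positive")
            + t_rng.standard_normal(n_sub) * config.propensity_noise_sd)
    thresh = np.quantile(prop, config.risk_quantile)
    risk = np.where(prop >= thresh, "yes", "no")

    meta = pd.DataFrame({
        "subject_id": [subj_of[s] for s in sample_ids],
        "sample_id": sample_ids,
        "age": [age[sub_idx[subj_of[s]]] for s in sample_ids],
        "sex": [sex[sub_idx[subj_of[s]]] for s in sample_ids],
        "cmv": [cmv[sub_idx[subj_of[s]]] for s in sample_ids],
        "transplant": [tp_of[s] for s in sample_ids],
        "atg": [atg[sub_idx[subj_of[s]]] for s in sample_ids],
        "infection_risk": [risk[sub_idx[subj_of[s]]] for s in sample_ids],
    })
    for k in range(config.n_ancestry_pcs):
        meta[f"ancestry_pc{k + 1}"] = [ancestry[sub_idx[subj_of[s]], k] for s in sample_ids]

    fractions = f_rng.dirichlet(config.alpha, size=len(sample_ids))
    mixture = ref_means.to_numpy() @ fractions.T  # sites x samples

    marker_sites = set(getattr(panel, "_marker_sites", []))
    expected_frac = config.alpha / config.alpha.sum()
    expected_mean = pd.Series(ref_means.to_numpy() @ expected_frac, index=sites)
    effect_sites = _assign_effect_sites(config, sites, marker_sites,
                                        expected_mean, e_rng)
    site_pos = {s: i for i, s in enumerate(sites)}

    # numeric indicator actually multiplied into the additive effects
    indicator = pd.DataFrame(0.0, index=sample_ids, columns=list(config.trait_effects))
    atg_sample = meta["atg"].eq("yes").to_numpy()
    if config.paired:
        atg_sample &= meta["transplant"].eq("post").to_numpy()
    for trait in config.trait_effects:
        if trait == "atg":
            indicator[trait] = atg_sample.astype(float)
        elif trait == "transplant":
            indicator[trait] = meta["transplant"].eq("post").astype(float).to_numpy()
        elif trait == "infection_risk":
            indicator[trait] = meta["infection_risk"].eq("yes").astype(float).to_numpy()
        elif trait == "cmv":
            indicator[trait] = meta["cmv"].eq("positive").astype(float).to_numpy()
        elif trait == "sex":
            indicator[trait] = meta["sex"].eq("M").astype(float).to_numpy()
        elif trait == "age":
            indicator[trait] = (meta["age"] - np.mean(config.age_range)).to_numpy()
        else:
            raise ValidationError(f"no indicator rule for trait {trait!r}")

    values = mixture.copy()
    for trait, effs in effect_sites.items():
        idx = [site_pos[s] for s in effs.index]
        values[idx, :] += np.outer(effs.to_numpy(), indicator[trait].to_numpy())

    if config.noise_sd > 0:
        values += n_rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    matrix = pd.DataFrame(values, index=pd.Index(sites, name="site"), columns=sample_ids)
    truth = GroundTruth(
        cell_fractions=pd.DataFrame(fractions, index=sample_ids, columns=names),
        effect_sites=effect_sites,
        trait_indicator=indicator,
        propensity=pd.Series(prop, index=subjects),
        log_hazard=config.log_hazard,
        marker_sites=sorted(marker_sites, key=lambda s: site_pos[s]),
    )
    return matrix, meta, truth


def simulate_survival(metadata: pd.DataFrame, truth: GroundTruth,
                      config: SimulationConfig) -> pd.DataFrame:
    """Draw infection times whose hazard follows the latent propensity.

    Hazard is ``baseline_rate * exp(log_hazard * z)`` with ``z`` the
    standardized propensity; times beyond ``censor_day`` are censored there.
    Returns the metadata with ``days_to_infection``/``event_observed`` filled
    (subject-level; both paired samples share the outcome).
    """
    if config.baseline_rate <= 0:
        raise ValidationError("baseline_rate must be positive")
    rng = rng_for(config.seed, "survival")
    prop = truth.propensity
    z = (prop - prop.mean()) / prop.std()
    scale = np.exp(config.log_hazard * z.to_numpy())
    e = rng.exponential(1.0, size=len(prop))
    if config.survival_model == "exponential":
        t = e / (config.baseline_rate * scale)
    elif config.survival_model == "weibull":
        # cumulative hazard (rate*t)^shape * exp(beta z)
        t = (e / scale) ** (1.0 / config.weibull_shape) / config.baseline_rate
    else:
        raise ValidationError(f"unknown survival_model {config.survival_model!r}")
    day = np.maximum(1, np.ceil(t)).astype(int)
    event = day <= config.censor_day
    day = np.minimum(day, config.censor_day)

    out = metadata.copy()
    per_subject = pd.DataFrame({"days_to_infection": day, "event_observed":
                                np.where(event, "yes", "no")}, index=prop.index)
    out["days_to_infection"] = out["subject_id"].map(per_subject["days_to_infection"]).astype(float)
    out["event_observed"] = out["subject_id"].map(per_subject["event_observed"])
    return out


def make_site_gene_mapping(truth: GroundTruth, trait: str = "atg",
                           n_sites: int | None = None) -> dict:
    """Map a subset of a trait's effect sites onto synthetic gene names."""
    sites = list(truth.effect_sites[trait].index)
    if n_sites is not None:
        sites = sites[:n_sites]
    return {s: f"GENE_{s.replace(':', '_')}" for s in sites}


def simulate_expression(matrix: pd.DataFrame, mapping: dict,
                        config: SimulationConfig, n_noise_genes: int = 50) -> pd.DataFrame:
    """Log-scale expression anticorrelated with methylation at mapped sites.

    For each mapped gene, expression = intercept - slope * methylation +
    Gaussian noise; unmapped genes are pure noise around the intercept.
    Returns genes x samples.
    """
    rng = rng_for(config.seed, "expression")
    rows, names = [], []
    for site, gene in mapping.items():
        if site not in matrix.index:
            raise ValidationError(f"mapped site {site!r} not in matrix")
        m = matrix.loc[site].to_numpy()
        rows.append(config.expr_intercept - config.expr_slope * m
                    + rng.normal(0.0, config.expr_noise_sd, size=matrix.shape[1]))
        names.append(gene)
    for g in range(n_noise_genes):
        rows.append(config.expr_intercept
                    + rng.normal(0.0, config.expr_noise_sd, size=matrix.shape[1]))
        names.append(f"NOISE_{g + 1}")
    return pd.DataFrame(rows, index=pd.Index(names, name="gene"), columns=matrix.columns)


def simulate_epiage_moderation(n: int, base_slope: float, interaction: float,
                               noise_sd: float, seed: int,
                               age_range: tuple = (25.0, 70.0)):
    """Toy predicted-age data with a planted age x moderator interaction.

    EpiAge = age * base_slope + moderator * age * interaction + noise; the
    moderator is balanced 0/1.  Returns (epiage, age, moderator) arrays.
    """
    rng = rng_for(seed, "moderation")
    age = rng.uniform(*age_range, size=n)
    moderator = (np.arange(n) % 2).astype(float)
    rng.shuffle(moderator)
    epiage = age * base_slope + moderator * age * interaction + rng.normal(0, noise_sd, n)
    return epiage, age, moderator
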