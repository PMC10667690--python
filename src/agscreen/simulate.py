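"""Synthetic anaerobic-germination screening trials with known ground truth.

The generator emulates a two-season screenhouse study: 200 test entries plus
8 replicated checks laid out in a 14 x 16 alpha lattice with 2 replications,
grown under a flooded (anaerobic) and a control (aerobic) condition in each
of two calendar experiments, phenotyped for eight traits, and genotyped on a
~1000-SNP amplicon panel.

Trait values follow a latent-Gaussian model: per plot,

    value = condition mean + experiment offset + replication offset
            + block effect + true breeding value (TBV) + residual,

where TBVs are linear in centred marker dosages (so GBLUP can recover them)
and residual variance is back-solved from the configured plot-basis
heritability, h2 = var(TBV) / (var(TBV) + sigma2_e).  Germination is turned
into a count of seeds out of ``seeds_per_plot`` by rounding the latent
percentage and truncating to the valid range; dry matter and length traits
are floored at zero.  Default condition means, heritabilities and spreads
are calibrated to a published flooded-vs-control rice screening of this
design, with the flooded means strongly degraded relative to control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputDataError
from .markers import MarkerPanel
from .phenotypes import TRAITS

__all__ = [
    "SimConfig",
    "TrueGenetics",
    "simulate_markers",
    "simulate_breeding_values",
    "generate_trial_design",
    "simulate_phenotypes",
    "TrialSimulator",
    "SimResult",
    "default_genetic_correlation",
]

CONDITIONS = ("anaerobic", "aerobic")

#: Across-experiment condition means (anaerobic, aerobic) per trait.
DEFAULT_TRAIT_MEANS: dict[str, dict[str, float]] = {
    "germ14_pct": {"anaerobic": 29.4, "aerobic": 98.3},
    "germ21_pct": {"anaerobic": 53.7, "aerobic": 98.4},
    "height14": {"anaerobic": 15.6, "aerobic": 28.8},
    "height21": {"anaerobic": 32.4, "aerobic": 44.1},
    "culm": {"anaerobic": 1.7, "aerobic": 2.7},
    "rootlen": {"anaerobic": 6.5, "aerobic": 9.0},
    "shootdm": {"anaerobic": 0.025, "aerobic": 0.071},
    "rootdm": {"anaerobic": 0.007, "aerobic": 0.014},
}

#: Plot-basis heritabilities (means of the two flooded experiments).
DEFAULT_HERITABILITIES: dict[str, float] = {
    "germ14_pct": 0.71,
    "germ21_pct": 0.65,
    "height14": 0.50,
    "height21": 0.68,
    "culm": 0.40,
    "rootlen": 0.36,
    "shootdm": 0.56,
    "rootdm": 0.46,
}

#: Plot-level phenotypic standard deviations (trait units).
DEFAULT_PHENOTYPIC_SD: dict[str, float] = {
    "germ14_pct": 20.0,
    "germ21_pct": 20.0,
    "height14": 4.0,
    "height21": 6.0,
    "culm": 0.35,
    "rootlen": 1.8,
    "shootdm": 0.009,
    "rootdm": 0.0035,
}

_GERM_TRAITS = ("germ14_pct", "germ21_pct")
_COUNT_COLUMN = {"germ14_pct": "germ14_count", "germ21_pct": "germ21_count"}
_MEASUREMENT_COLUMN = {
    "height14": "height14_cm",
    "height21": "height21_cm",
    "culm": "culm_mm",
    "rootlen": "rootlen_cm",
    "shootdm": "shootdm_g",
    "rootdm": "rootdm_g",
}


def default_genetic_correlation() -> np.ndarray:
    """Moderate positive genetic correlations: germination timepoints tightly
    coupled, growth traits moderately, culm diameter nearly independent."""
    r = np.array([
        # g14   g21   h14   h21   culm  rtln  sdm   rdm
        [1.00, 0.85, 0.50, 0.60, 0.15, 0.25, 0.50, 0.30],
        [0.85, 1.00, 0.50, 0.60, 0.15, 0.25, 0.50, 0.30],
        [0.50, 0.50, 1.00, 0.60, 0.15, 0.25, 0.50, 0.30],
        [0.60, 0.60, 0.60, 1.00, 0.15, 0.25, 0.50, 0.30],
        [0.15, 0.15, 0.15, 0.15, 1.00, 0.15, 0.15, 0.15],
        [0.25, 0.25, 0.25, 0.25, 0.15, 1.00, 0.25, 0.25],
        [0.50, 0.50, 0.50, 0.50, 0.15, 0.25, 1.00, 0.50],
        [0.30, 0.30, 0.30, 0.30, 0.15, 0.25, 0.50, 1.00],
    ])
    return r


@dataclass
class SimConfig:
    """Study conditions for one synthetic screening trial."""

    n_entries: int = 200
    n_checks: int = 8
    check_reps_within_replication: int = 3
    n_markers: int = 1000
    n_replications: int = 2
    blocks_per_replication: int = 16
    plots_per_block: int = 14
    n_experiments: int = 2  # two experiments x two conditions = 4 environments
    seeds_per_plot: int = 30
    missing_rate: float = 0.06
    maf_range: tuple[float, float] = (0.05, 0.95)
    inbreeding: float = 0.95  # F; rice lines are near-fully inbred
    trait_heritabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HERITABILITIES))
    trait_means_by_condition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(m) for t, m in DEFAULT_TRAIT_MEANS.items()})
    trait_phenotypic_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPIC_SD))
    trait_genetic_correlation: np.ndarray = field(
        default_factory=default_genetic_correlation)
    block_variance: float = 0.05  # fraction of phenotypic variance
    replication_effect_size: float = 0.05  # offset in phenotypic SDs
    environment_effect_size: float = 0.10  # offset in phenotypic SDs
    rng_seed: int = 0

    # -------------------------------------------------------------- #
    @property
    def n_genotypes(self) -> int:
        return self.n_entries + self.n_checks

    @property
    def entry_ids(self) -> list[str]:
        return [f"ENT{i + 1:03d}" for i in range(self.n_entries)]

    @property
    def check_ids(self) -> list[str]:
        return [f"CHK{i + 1:02d}" for i in range(self.n_checks)]

    @property
    def genotype_ids(self) -> list[str]:
        return self.entry_ids + self.check_ids

    def validate(self) -> None:
        if self.n_entries <= 0 and self.n_checks <= 0:
            raise ConfigurationError("need at least one entry or check")
        if self.n_markers <= 0 or self.n_genotypes <= 0:
            raise ConfigurationError("marker and genotype counts must be positive")
        lhs = self.n_entries + self.n_checks * self.check_reps_within_replication
        rhs = self.blocks_per_replication * self.plots_per_block
        if lhs != rhs:
            raise ConfigurationError(
                "lattice count identity violated: "
                f"{self.n_entries} entries + {self.n_checks} checks x "
                f"{self.check_reps_within_replication} = {lhs}, but "
                f"{self.blocks_per_replication} blocks x "
                f"{self.plots_per_block} plots = {rhs}"
            )
        for t, h in self.trait_heritabilities.items():
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(f"heritability of {t} must be in [0,1], got {h}")
        corr = np.asarray(self.trait_genetic_correlation, float)
        if corr.shape != (len(TRAITS), len(TRAITS)):
            raise ConfigurationError("genetic correlation must be 8x8 in trait order")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigurationError("genetic correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConfigurationError("genetic correlation matrix needs a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("genetic correlation matrix is not positive semi-definite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0,1)")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ConfigurationError("inbreeding coefficient must be in [0,1]")
        for name in ("block_variance", "replication_effect_size", "environment_effect_size"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.rng_seed), spawn_key=(stream,))
        )

    def genetic_sd(self, trait: str) -> float:
        return float(
            np.sqrt(self.trait_heritabilities[trait]) * self.trait_phenotypic_sd[trait]
        )

    def residual_sd(self, trait: str) -> float:
        h = self.trait_heritabilities[trait]
        return float(np.sqrt(1.0 - h) * self.trait_phenotypic_sd[trait])


@dataclass
class TrueGenetics:
    """Ground truth: allele frequencies, marker effects and breeding values."""

    allele_frequencies: np.ndarray
    marker_effects: pd.DataFrame  # trait x marker
    true_breeding_values: pd.DataFrame  # genotype x trait, zero column means


# ---------------------------------------------------------------------- #
# stages
# ---------------------------------------------------------------------- #
def simulate_markers(cfg: SimConfig) -> MarkerPanel:
    """Draw per-marker dosages with allele frequency p_j ~ U(maf_range).

    Genotypes follow the inbred-line model with inbreeding coefficient F:
    P(2) = p^2 + F p(1-p), P(1) = 2 p (1-p) (1-F), P(0) = (1-p)^2 + F p(1-p).
    F = 0 recovers the Hardy-Weinberg binomial(2, p) draw; the default
    F = 0.95 yields the low residual heterozygosity typical of rice lines
    (so the panel survives a 10% heterozygosity QC ceiling).  Allele
    frequencies are preserved for any F.
    """
    cfg.validate()
    rng = cfg._rng(0)
    lo, hi = cfg.maf_range
    p = rng.uniform(lo, hi, size=cfg.n_markers)
    f = cfg.inbreeding
    p2 = p ** 2 + f * p * (1.0 - p)
    p1 = 2.0 * p * (1.0 - p) * (1.0 - f)
    draw = rng.random(size=(cfg.n_genotypes, cfg.n_markers))
    dosages = np.where(draw < p2, 2.0, np.where(draw < p2 + p1, 1.0, 0.0))
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        # never blank out an entire marker
        full_cols = miss.all(axis=0)
        miss[0, full_cols] = False
        dosages[miss] = np.nan
    marker_ids = [f"M{j + 1:04d}" for j in range(cfg.n_markers)]
    return MarkerPanel(cfg.genotype_ids, marker_ids, dosages)


def simulate_breeding_values(panel: MarkerPanel, cfg: SimConfig) -> TrueGenetics:
    """True breeding values linear in centred dosages, correlated across traits.

    Raw marker effects are i.i.d. normal per trait and mixed through the
    Cholesky factor of the genetic correlation matrix; each trait's TBV
    column is then rescaled so its sample variance equals the genetic
    variance implied by the configured heritability and phenotypic SD.
    """
    cfg.validate()
    if panel.has_missing:
        from .markers import impute_missing

        panel = impute_missing(panel)
    rng = cfg._rng(1)
    n_traits = len(TRAITS)
    corr = np.asarray(cfg.trait_genetic_correlation, float)
    # PSD-safe Cholesky (allows singular correlation targets)
    w, v = np.linalg.eigh(corr)
    L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    raw = L @ rng.standard_normal((n_traits, panel.n_markers))

    p = panel.allele_frequencies
    z = panel.dosages - 2.0 * p
    tbv = z @ raw.T  # genotype x trait, zero column means by centring
    effects = raw.copy()
    for t_idx, trait in enumerate(TRAITS):
        target_sd = cfg.genetic_sd(trait)
        col_sd = float(np.std(tbv[:, t_idx], ddof=1)) if panel.n_genotypes > 1 else 0.0
        scale = 0.0 if target_sd == 0.0 or col_sd == 0.0 else target_sd / col_sd
        tbv[:, t_idx] *= scale
        effects[t_idx, :] *= scale
    return TrueGenetics(
        allele_frequencies=p,
        marker_effects=pd.DataFrame(effects, index=list(TRAITS), columns=panel.marker_ids),
        true_breeding_values=pd.DataFrame(
            tbv, index=panel.genotype_ids, columns=list(TRAITS)
        ),
    )


def generate_trial_design(cfg: SimConfig) -> pd.DataFrame:
    """Randomized alpha-lattice allocation for every environment.

    Within each (experiment, condition, replication) the pool of plots —
    every entry once, every check ``check_reps_within_replication`` times —
    is randomly permuted and chunked into ``blocks_per_replication`` blocks
    of ``plots_per_block``.  No concurrence optimisation is attempted.
    """
    cfg.validate()
    rng = cfg._rng(2)
    pool = cfg.entry_ids + [
        c for c in cfg.check_ids for _ in range(cfg.check_reps_within_replication)
    ]
    rows = []
    for e in range(1, cfg.n_experiments + 1):
        for condition in CONDITIONS:
            for r in range(1, cfg.n_replications + 1):
                order = rng.permutation(len(pool))
                for idx, slot in enumerate(order):
                    rows.append(
                        (
                            f"exp{e}",
                            condition,
                            f"r{r}",
                            f"b{idx // cfg.plots_per_block + 1:02d}",
                            idx % cfg.plots_per_block + 1,
                            pool[slot],
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["experiment", "condition", "replication", "block", "plot", "genotype"],
    )


def simulate_phenotypes(design: pd.DataFrame, genetics: TrueGenetics,
                        cfg: SimConfig) -> pd.DataFrame:
    """Plot records for every design row (wide phenotype CSV dialect)."""
    cfg.validate()
    tbv = genetics.true_breeding_values
    unknown = set(design["genotype"].astype(str)) - set(tbv.index.astype(str))
    if unknown:
        raise InputDataError(
            f"design references genotypes without breeding values: {sorted(unknown)[:5]}"
        )
    rng = cfg._rng(3)
    n = len(design)
    out = design[["experiment", "condition", "replication", "block", "genotype"]].copy()
    out["seeds_sown"] = cfg.seeds_per_plot

    exp_sign = np.where(design["experiment"].astype(str) == "exp1", -0.5, 0.5)
    rep_sign = np.where(design["replication"].astype(str) == "r1", -0.5, 0.5)
    block_key = design[["experiment", "condition", "replication", "block"]].astype(
        str).agg(":".join, axis=1)
    block_levels = sorted(block_key.unique())
    block_index = block_key.map({b: i for i, b in enumerate(block_levels)}).to_numpy()

    for trait in TRAITS:
        sd_p = cfg.trait_phenotypic_sd[trait]
        means = design["condition"].map(cfg.trait_means_by_condition[trait]).to_numpy(float)
        env_off = exp_sign * cfg.environment_effect_size * sd_p
        rep_off = rep_sign * cfg.replication_effect_size * sd_p
        block_effects = rng.normal(
            0.0, np.sqrt(cfg.block_variance) * sd_p, size=len(block_levels)
        )
        noise_sd = cfg.residual_sd(trait)
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        g = tbv.loc[design["genotype"], trait].to_numpy(float)
        latent = means + env_off + rep_off + block_effects[block_index] + g + noise
        if trait in _GERM_TRAITS:
            counts = np.rint(latent / 100.0 * cfg.seeds_per_plot)
            counts = np.clip(counts, 0, cfg.seeds_per_plot)
            out[_COUNT_COLUMN[trait]] = counts.astype(int)
        else:
            out[_MEASUREMENT_COLUMN[trait]] = np.maximum(latent, 0.0)
    return out


@dataclass
class SimResult:
    config: SimConfig
    panel: MarkerPanel
    genetics: TrueGenetics
    design: pd.DataFrame
    plots: pd.DataFrame

    def write_fixtures(self, out_dir, vcf: bool = False) -> dict[str, Path]:
        """Write phenotype CSV, marker dosage CSV, TBV truth TSV (and VCF)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        pheno = out_dir / "phenotypes.csv"
        self.plots.to_csv(pheno, index=False, float_format="%.6g")
        paths["phenotypes"] = pheno
        markers = out_dir / "markers.csv"
        self.panel.to_csv(markers)
        paths["markers"] = markers
        truth = out_dir / "true_breeding_values.tsv"
        self.genetics.true_breeding_values.rename_axis("genotype").to_csv(
            truth, sep="\t", float_format="%.10g"
        )
        paths["truth"] = truth
        if vcf:
            vcf_path = out_dir / "markers.vcf"
            self.panel.to_vcf(vcf_path)
            paths["vcf"] = vcf_path
        return paths


class TrialSimulator:
    """Run all generator stages for one configuration.

    Deterministic: the same :class:`SimConfig` (including ``rng_seed``)
    reproduces identical markers, designs and phenotypes.
    """

    def __init__(self, config: SimConfig | None = None):
        self.config = config or SimConfig()

    def run(self) -> SimResult:
        cfg = self.config
        panel = simulate_markers(cfg)
        genetics = simulate_breeding_values(panel, cfg)
        design = generate_trial_design(cfg)
        plots = simulate_phenotypes(design, genetics, cfg)
        return SimResult(cfg, panel, genetics, design, plots)
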