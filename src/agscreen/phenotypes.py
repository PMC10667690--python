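"""Plot-level phenotype preparation for germination-stress screening trials.

Raw plot records (counts and measurements from a flooded/control crate
experiment) are converted into a long-format trait table, screened for
outliers with a Bonferroni test on externally studentized residuals, and
summarised as stress-impact percentage reductions and Pearson trait
correlations.

Germination is expressed per plot as

    percentage germination = germinated / sown * 100,

where "germinated" counts seedlings that emerged above the water surface.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .exceptions import InputDataError

logger = logging.getLogger(__name__)

__all__ = [
    "TRAITS",
    "PLOT_COLUMNS",
    "percent_germination",
    "plots_to_traits",
    "BonferroniOutlierFilter",
    "bonferroni_outlier_filter",
    "stress_impact",
    "trait_correlations",
]

#: The eight analysis traits, in reporting order.
TRAITS = (
    "germ14_pct",
    "germ21_pct",
    "height14",
    "height21",
    "culm",
    "rootlen",
    "shootdm",
    "rootdm",
)

#: Plot-record columns of the phenotype CSV dialect.
PLOT_COLUMNS = [
    "experiment",
    "condition",
    "replication",
    "block",
    "genotype",
    "seeds_sown",
    "germ14_count",
    "germ21_count",
    "height14_cm",
    "height21_cm",
    "culm_mm",
    "rootlen_cm",
    "shootdm_g",
    "rootdm_g",
]

_MEASUREMENT_FOR_TRAIT = {
    "height14": "height14_cm",
    "height21": "height21_cm",
    "culm": "culm_mm",
    "rootlen": "rootlen_cm",
    "shootdm": "shootdm_g",
    "rootdm": "rootdm_g",
}

KEY_COLUMNS = ["experiment", "condition", "replication", "block", "genotype"]


def percent_germination(germinated: int, sown: int) -> float:
    """Percentage of sown seeds that germinated (emerged), in [0, 100]."""
    if sown <= 0:
        raise InputDataError("seeds sown must be positive to compute a germination percentage")
    if germinated < 0 or germinated > sown:
        raise InputDataError(
            f"germinated count {germinated} outside [0, {sown}]"
        )
    return (germinated * 100) / sown


def plots_to_traits(plots: pd.DataFrame) -> pd.DataFrame:
    """Melt wide plot records into the long trait table.

    Returns one row per plot per trait with columns
    ``experiment, condition, replication, block, genotype, trait, value``;
    germination counts become percentages of seeds sown.  Missing
    measurements stay as NaN so downstream models can drop and count them.
    """
    missing_cols = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing_cols:
        raise InputDataError(f"plot table lacks columns {missing_cols}")
    sown = plots["seeds_sown"].to_numpy(dtype=float)
    if (sown <= 0).any():
        raise InputDataError("every plot must have seeds_sown > 0")
    for col in ("germ14_count", "germ21_count"):
        counts = plots[col].to_numpy(dtype=float)
        ok = np.isnan(counts) | ((counts >= 0) & (counts <= sown))
        if not ok.all():
            raise InputDataError(f"{col} outside [0, seeds_sown] in some plots")

    out = plots[KEY_COLUMNS].copy()
    out["germ14_pct"] = plots["germ14_count"] / plots["seeds_sown"] * 100.0
    out["germ21_pct"] = plots["germ21_count"] / plots["seeds_sown"] * 100.0
    for trait, col in _MEASUREMENT_FOR_TRAIT.items():
        out[trait] = plots[col].astype(float)
    long = out.melt(id_vars=KEY_COLUMNS, value_vars=list(TRAITS),
                    var_name="trait", value_name="value")
    return long.reset_index(drop=True)


# ---------------------------------------------------------------------- #
# Bonferroni outlier screen
# ---------------------------------------------------------------------- #
def _lmm_studentized(work: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int] | None:
    """Externally studentized conditional residuals of the per-experiment
    mixed model (replication and block fixed, genotype random).

    The conditional residual is e = y - Xb - Zu from Henderson's equations,
    with Cov(e) = sigma2_e (I - H) and H the hat matrix A M^-1 A' of the
    full system.  The genotype effect is shrunken, so a single aberrant plot
    keeps the largest residual instead of splitting it symmetrically with
    its replicate (the masking failure of a genotype-fixed screen).
    Internally studentized residuals r are mapped to the external scale with
    the exact leave-one-out relation t = r sqrt((df - 1) / (df - r^2)).

    Returns (t, bonferroni_p, df) or None when there are not enough residual
    degrees of freedom.
    """
    from .lmm import VAR_FLOOR, build_design, reml_fit

    design = build_design(work, scope="sea")
    n, p = design.X.shape
    df = n - p
    if df - 1 < 1 or n <= p + 1:
        return None
    varcomp = reml_fit(design.X, design.Z, design.y, tol=1e-6, max_iter=200)
    A = np.hstack([design.X, design.Z])
    lam = varcomp.sigma2_e / max(varcomp.sigma2_g, VAR_FLOOR)
    M = A.T @ A
    M[p:, p:] += lam * np.eye(design.Z.shape[1])
    cho = cho_factor(M, lower=True)
    sol = cho_solve(cho, A.T @ design.y)
    resid = design.y - A @ sol
    hat = np.einsum("ij,ji->i", A, cho_solve(cho, A.T))
    one_minus_h = np.clip(1.0 - hat, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = resid / np.sqrt(varcomp.sigma2_e * one_minus_h)
        r2 = np.minimum(r**2, df - 1e-12)
        t = r * np.sqrt((df - 1) / (df - r2))
    t[~np.isfinite(t)] = np.nan
    pvals = 2.0 * stats.t.sf(np.abs(t), df - 1)
    bonf = np.minimum(pvals * n, 1.0)
    return t, bonf, df


class BonferroniOutlierFilter(BaseEstimator):
    """Iterative Bonferroni outlier screen on externally studentized
    conditional residuals of the per-experiment mixed model.

    Within each (experiment, condition, trait) cell the screening model
    (replication and block-within-replication fixed, genotype random) is
    fitted; the observation with the largest |studentized residual| is
    removed when its Bonferroni-adjusted two-sided p-value falls below
    ``alpha``, and the model is refitted until nothing is flagged.  The
    procedure is idempotent by construction.  ``alpha <= 0`` disables the
    filter.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, table: pd.DataFrame, y=None) -> "BonferroniOutlierFilter":
        removed_idx: list = []
        removed_rows: list[pd.DataFrame] = []
        if self.alpha > 0:
            groups = table.groupby(["experiment", "condition", "trait"], sort=True)
            for _, group in groups:
                removed = self._screen_group(group)
                if removed is not None and len(removed):
                    removed_rows.append(removed)
                    removed_idx.extend(removed.index.tolist())
        if removed_rows:
            self.outliers_ = pd.concat(removed_rows).sort_index()
        else:
            self.outliers_ = pd.DataFrame(
                columns=list(table.columns) + ["student_resid", "bonferroni_p"]
            )
        self.removed_index_ = pd.Index(removed_idx)
        return self

    def _screen_group(self, group: pd.DataFrame) -> pd.DataFrame | None:
        work = group.dropna(subset=["value"])
        flagged: list[tuple] = []
        while True:
            if len(work) < 3:
                break
            screened = _lmm_studentized(work)
            if screened is None:
                logger.warning(
                    "outlier screen skipped for a cell with too few residual df"
                )
                break
            student, bonf_p, _ = screened
            finite = np.isfinite(student)
            if not finite.any():
                break
            worst = int(np.nanargmax(np.where(finite, np.abs(student), -np.inf)))
            if not np.isfinite(bonf_p[worst]) or bonf_p[worst] >= self.alpha:
                break
            label = work.index[worst]
            flagged.append((label, float(student[worst]), float(bonf_p[worst])))
            work = work.drop(index=label)
        if not flagged:
            return None
        labels = [f[0] for f in flagged]
        removed = group.loc[labels].copy()
        removed["student_resid"] = [f[1] for f in flagged]
        removed["bonferroni_p"] = [f[2] for f in flagged]
        return removed

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table.drop(index=self.removed_index_, errors="ignore")

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)


def bonferroni_outlier_filter(table: pd.DataFrame, alpha: float = 0.05
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper; returns (cleaned table, report of removed rows)."""
    flt = BonferroniOutlierFilter(alpha=alpha)
    cleaned = flt.fit_transform(table)
    return cleaned, flt.outliers_


# ---------------------------------------------------------------------- #
# summaries
# ---------------------------------------------------------------------- #
def stress_impact(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait percentage reduction of the stressed condition vs control.

    Means are taken at the genotype level first (so unequal replication does
    not weight genotypes unevenly), then averaged per condition:

        reduction = (mean_aerobic - mean_anaerobic) / mean_aerobic * 100.

    Negative values (traits that increased under stress) are reported as-is.
    A trait whose aerobic mean is zero is flagged undefined.
    """
    rows = []
    for trait, sub in table.groupby("trait", sort=False):
        by_cond = (
            sub.groupby(["condition", "genotype"])["value"].mean()
            .groupby("condition").mean()
        )
        m_aer = by_cond.get("aerobic", np.nan)
        m_ana = by_cond.get("anaerobic", np.nan)
        if m_aer == 0 or np.isnan(m_aer) or np.isnan(m_ana):
            rows.append((trait, m_ana, m_aer, np.nan, True))
        else:
            rows.append((trait, m_ana, m_aer, (m_aer - m_ana) / m_aer * 100.0, False))
    return pd.DataFrame(
        rows,
        columns=["trait", "mean_anaerobic", "mean_aerobic", "reduction_pct", "undefined"],
    )


def trait_correlations(values: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlations between traits on genotype-level values.

    ``values`` is genotype-by-trait (e.g. BLUPs per condition).  Pairs with
    fewer than ``min_pairs`` complete observations are NaN; the diagonal is
    exactly 1 for any trait with at least one observation.
    """
    corr = values.corr(method="pearson", min_periods=min_pairs)
    observed = values.notna().any(axis=0)
    for trait in values.columns:
        if observed[trait]:
            corr.loc[trait, trait] = 1.0
    return corr
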