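"""Genomic estimated breeding values, the weighted selection index and donor lists.

GEBVs come from the same mixed-model engine with the genotype covariance set
to the genomic relationship matrix; predictions are recentred by the model
intercept so that, for example, germination GEBVs live on the 0-100
percentage scale.  Per environment the eight trait GEBVs are standardized
(mean 0, SD 1 over genotypes) and combined into the selection index

    I_g = sum_t w_t * x_gt

with fixed economic weights emphasising germination.  Donor lists keep
genotypes passing both an index threshold and a phenotypic germination-BLUP
threshold at 21 days after seeding, sorted by index.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InputDataError
from .lmm import MixedModel
from .markers import GenomicRelationshipMatrix
from .phenotypes import TRAITS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_INDEX_WEIGHTS",
    "DEFAULT_SELECTION_RULES",
    "ENVIRONMENTS",
    "gblup_gebvs",
    "SelectionIndexScorer",
    "standardize_gebvs",
    "selection_index",
    "select_donors",
    "donor_report",
]

#: Economic weights for the eight traits (germination dominates).
DEFAULT_INDEX_WEIGHTS: dict[str, float] = {
    "germ14_pct": 10.0,
    "germ21_pct": 8.0,
    "height14": 5.0,
    "height21": 4.0,
    "shootdm": 7.0,
    "rootdm": 4.0,
    "culm": 3.0,
    "rootlen": 5.0,
}

#: (index_min, germ21_blup_min) per selection rule.
DEFAULT_SELECTION_RULES: dict[str, tuple[float, float]] = {
    "anaerobic": (25.0, 70.0),
    "aerobic": (25.0, 80.0),
    "across": (25.0, 80.0),
}

ENVIRONMENTS = ("anaerobic", "aerobic", "across")

#: Tolerated fraction of phenotyped genotypes missing from the marker panel.
MAX_PANEL_MISMATCH = 0.10


def _environment_subset(table: pd.DataFrame, environment: str) -> tuple[pd.DataFrame, str]:
    if environment == "across":
        return table, "mea"
    if environment in ("anaerobic", "aerobic"):
        return table[table["condition"] == environment], "across"
    raise InputDataError(f"environment must be one of {ENVIRONMENTS}, got {environment!r}")


def gblup_gebvs(table: pd.DataFrame, grm: GenomicRelationshipMatrix,
                environment: str = "anaerobic", blocks: str = "fixed",
                traits: tuple[str, ...] = TRAITS, tol: float = 1e-8,
                max_iter: int = 500, return_fits: bool = False):
    """Fit GBLUP per trait and return the GEBV table for one environment.

    Every genotype of the marker panel appears exactly once; phenotyped
    genotypes missing from the panel are excluded with a log message, but
    more than 10% missing is treated as a panel/phenotype mismatch and
    raises.
    """
    subset, scope = _environment_subset(table, environment)
    phenotyped = set(subset["genotype"].astype(str).unique())
    panel = set(grm.genotype_ids)
    missing = phenotyped - panel
    if phenotyped and len(missing) / len(phenotyped) > MAX_PANEL_MISMATCH:
        raise InputDataError(
            f"{len(missing)}/{len(phenotyped)} phenotyped genotypes absent from the "
            "marker panel; check that phenotype and genotype files match"
        )
    if missing:
        logger.warning("excluding %d unpanelled genotypes: %s",
                       len(missing), sorted(missing)[:5])
        subset = subset[~subset["genotype"].astype(str).isin(missing)]

    gebvs = {}
    fits = {}
    for trait in traits:
        model = MixedModel(scope=scope, kinship=grm, blocks=blocks,
                           tol=tol, max_iter=max_iter)
        model.fit(subset[subset["trait"] == trait])
        gebvs[trait] = model.predict()
        fits[trait] = model
    out = pd.DataFrame(gebvs).rename_axis("genotype")
    out.attrs["environment"] = environment
    if return_fits:
        return out, fits
    return out


class SelectionIndexScorer(BaseEstimator):
    """Standardize trait GEBVs and combine them into a weighted index.

    ``fit`` learns per-trait means and standard deviations over genotypes
    (within one environment); ``transform`` returns standardized GEBVs and
    ``predict`` the index values.  A zero-variance trait standardizes to all
    zeros and is recorded in ``zero_variance_traits_``.  With
    ``standardize=False`` the weights act on the raw GEBV scale.
    """

    def __init__(self, weights: dict[str, float] | None = None,
                 standardize: bool = True, ddof: int = 1):
        self.weights = weights
        self.standardize = standardize
        self.ddof = ddof

    def _weights(self) -> dict[str, float]:
        w = DEFAULT_INDEX_WEIGHTS if self.weights is None else self.weights
        if any(v < 0 for v in w.values()):
            raise InputDataError("selection-index weights must be nonnegative")
        if not any(v > 0 for v in w.values()):
            raise InputDataError("at least one selection-index weight must be positive")
        return w

    def fit(self, gebvs: pd.DataFrame, y=None) -> "SelectionIndexScorer":
        if len(gebvs) < 2:
            raise InputDataError("standardization needs at least 2 genotypes")
        self.means_ = gebvs.mean(axis=0)
        self.stds_ = gebvs.std(axis=0, ddof=self.ddof)
        self.zero_variance_traits_ = [
            t for t in gebvs.columns if not np.isfinite(self.stds_[t]) or self.stds_[t] == 0
        ]
        return self

    def transform(self, gebvs: pd.DataFrame) -> pd.DataFrame:
        if not self.standardize:
            return gebvs.copy()
        out = (gebvs - self.means_) / self.stds_
        for t in self.zero_variance_traits_:
            out[t] = 0.0
        return out

    def fit_transform(self, gebvs: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(gebvs).transform(gebvs)

    def predict(self, gebvs: pd.DataFrame) -> pd.Series:
        """Weighted index per genotype; NaN where a weighted trait is missing."""
        std = self.transform(gebvs)
        w = self._weights()
        traits = [t for t in std.columns if w.get(t, 0.0) != 0.0]
        weights = np.array([w[t] for t in traits])
        values = std[traits].to_numpy(dtype=float) @ weights
        index = pd.Series(values, index=std.index, name="selection_index")
        incomplete = std[traits].isna().any(axis=1)
        if incomplete.any():
            logger.warning("%d genotypes missing a weighted trait; index flagged NaN",
                           int(incomplete.sum()))
            index[incomplete] = np.nan
        return index


def standardize_gebvs(gebvs: pd.DataFrame, ddof: int = 1
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Per-trait standardization over genotypes; returns (table, zero-variance flags)."""
    scorer = SelectionIndexScorer(ddof=ddof).fit(gebvs)
    return scorer.transform(gebvs), scorer.zero_variance_traits_


def selection_index(standardized_gebvs: pd.DataFrame,
                    weights: dict[str, float] | None = None) -> pd.Series:
    """Weighted sum of (already standardized) trait values per genotype."""
    scorer = SelectionIndexScorer(weights=weights, standardize=False)
    return scorer.predict(standardized_gebvs)


def select_donors(index: pd.Series, germ21_blups: pd.Series, rule: str,
                  index_min: float | None = None, germ_min: float | None = None,
                  checks: set[str] | frozenset[str] = frozenset()) -> pd.DataFrame:
    """Apply one selection rule and rank the surviving genotypes.

    Keeps genotypes with ``index >= index_min`` and ``germ21 >= germ_min``
    (strict conjunction), sorted by index descending with ties broken by
    germination then genotype label.  Checks are flagged but retained.  An
    empty result is valid.
    """
    if rule not in DEFAULT_SELECTION_RULES:
        raise InputDataError(f"rule must be one of {tuple(DEFAULT_SELECTION_RULES)}")
    default_idx, default_germ = DEFAULT_SELECTION_RULES[rule]
    index_min = default_idx if index_min is None else index_min
    germ_min = default_germ if germ_min is None else germ_min

    merged = pd.DataFrame({"selection_index": index}).join(
        pd.DataFrame({"germ21_blup_pct": germ21_blups}), how="inner"
    )
    keep = merged[
        (merged["selection_index"] >= index_min) & (merged["germ21_blup_pct"] >= germ_min)
    ].copy()
    keep["genotype"] = keep.index.astype(str)
    keep["is_check"] = keep["genotype"].isin({str(c) for c in checks})
    keep = keep.reset_index(drop=True)
    keep = keep.sort_values(
        by=["selection_index", "germ21_blup_pct", "genotype"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    out = keep[["genotype", "selection_index", "germ21_blup_pct", "is_check"]]
    out = out.reset_index(drop=True)
    out.attrs["rule"] = rule
    out.attrs["thresholds"] = (index_min, germ_min)
    return out


def donor_report(donor_lists: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write one TSV per selection rule plus a combined summary.

    Columns follow the reporting shape Genotype / Condition / SelectionIndex /
    Germination21DAS / Remarks (Entry or Check).  Byte-identical on identical
    inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    combined = []
    for rule in sorted(donor_lists):
        table = donor_lists[rule]
        report = pd.DataFrame(
            {
                "Genotype": table["genotype"],
                "Condition": rule,
                "SelectionIndex": table["selection_index"].round(2),
                "Germination21DAS": table["germ21_blup_pct"].round(1),
                "Remarks": np.where(table["is_check"], "Check", "Entry"),
            }
        )
        path = out_dir / f"donors_{rule}.tsv"
        report.to_csv(path, sep="\t", index=False)
        paths.append(path)
        combined.append(report)
    summary = pd.concat(combined, ignore_index=True) if combined else pd.DataFrame(
        columns=["Genotype", "Condition", "SelectionIndex", "Germination21DAS", "Remarks"]
    )
    summary_path = out_dir / "donors_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    paths.append(summary_path)
    return paths
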