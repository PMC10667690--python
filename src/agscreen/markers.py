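"""SNP dosage panels: containers, quality control, imputation and the
genomic relationship matrix.

Dosages count copies of the alternate allele, so each cell is 0, 1 or 2;
missing calls are stored as NaN.  The genomic relationship matrix (GRM)
follows VanRaden's first estimator,

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),

where ``Z`` is the dosage matrix centred marker-wise by twice the sample
allele frequency ``2 p_j``.  Under Hardy-Weinberg-like panels the diagonal
of ``G`` averages about 1.  A small ridge is added to the diagonal so the
matrix stays invertible inside the mixed-model equations.

Quality control removes poor samples first (call rate, heterozygosity) and
poor markers second (call rate, minor allele frequency), mirroring how
amplicon panels for inbred rice are routinely cleaned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import EmptyPanelError, InputDataError

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanel",
    "MarkerQCReport",
    "GenomicRelationshipMatrix",
    "MarkerQC",
    "MarkerImputer",
    "GenomicRelationship",
    "qc_markers",
    "impute_missing",
    "compute_grm",
]


@dataclass
class MarkerPanel:
    """A genotype-by-marker dosage matrix with missingness tracked as NaN."""

    genotype_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float array, shape (n_genotypes, n_markers)

    def __post_init__(self) -> None:
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.genotype_ids) or m != len(self.marker_ids):
            raise InputDataError(
                f"dosage matrix is {n}x{m} but there are "
                f"{len(self.genotype_ids)} genotype ids and {len(self.marker_ids)} marker ids"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise InputDataError(f"dosages must be 0, 1, 2 or missing; found {bad[:5]}")

    # ------------------------------------------------------------------ #
    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per marker from non-missing cells only."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies
        return np.minimum(p, 1.0 - p)

    @property
    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    @property
    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    @property
    def sample_heterozygosity(self) -> np.ndarray:
        """Fraction of a sample's non-missing calls that are heterozygous."""
        het = (self.dosages == 1.0).sum(axis=1)
        called = (~np.isnan(self.dosages)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, het / called, np.nan)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset(self, genotypes=None, markers=None) -> "MarkerPanel":
        gi = np.arange(self.n_genotypes) if genotypes is None else np.asarray(genotypes, dtype=int)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers, dtype=int)
        return MarkerPanel(
            [self.genotype_ids[i] for i in gi],
            [self.marker_ids[j] for j in mi],
            self.dosages[np.ix_(gi, mi)].copy(),
        )

    # ------------------------------ I/O ------------------------------- #
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.genotype_ids, columns=self.marker_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerPanel":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        """Write the dosage dialect: rows are genotypes, cells 0/1/2/NA."""
        frame = self.to_frame()
        frame.index.name = "genotype"
        frame.to_csv(path, na_rep="NA", float_format="%.0f")

    @classmethod
    def from_csv(cls, path) -> "MarkerPanel":
        frame = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls.from_frame(frame.astype(float))

    def to_vcf(self, path, chrom: str = "1") -> None:
        """Export as a minimal diploid VCF (one contig, 1-based positions)."""
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.genotype_ids)
                + "\n"
            )
            for j, marker in enumerate(self.marker_ids):
                gts = [
                    "./." if np.isnan(d) else code[d] for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{chrom}\t{j + 1}\t{marker}\tA\tT\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "MarkerPanel":
        """Read a diploid VCF; multiallelic records are skipped with a logged count."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        genotype_ids = list(vcf.samples)
        marker_ids: list[str] = []
        rows: list[np.ndarray] = []
        n_skipped = 0
        for variant in vcf:
            if len(variant.ALT) != 1:
                n_skipped += 1
                continue
            gt = variant.gt_types.astype(float)  # 0/1/2, 3 = unknown
            gt[gt == 3] = np.nan
            marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
            rows.append(gt)
        vcf.close()
        if n_skipped:
            logger.info("skipped %d multiallelic VCF records", n_skipped)
        dosages = np.column_stack(rows) if rows else np.empty((len(genotype_ids), 0))
        return cls(genotype_ids, marker_ids, dosages)


@dataclass
class MarkerQCReport:
    """Outcome of panel quality control; kept + dropped always reconciles."""

    n_samples_in: int
    n_markers_in: int
    dropped_samples: pd.DataFrame  # columns: genotype, reason, value
    dropped_markers: pd.DataFrame  # columns: marker, reason, value
    mean_sample_call_rate: float
    mean_marker_call_rate: float
    mean_heterozygosity: float

    @property
    def n_samples_kept(self) -> int:
        return self.n_samples_in - len(self.dropped_samples)

    @property
    def n_markers_kept(self) -> int:
        return self.n_markers_in - len(self.dropped_markers)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_kept", self.n_samples_kept),
            ("markers_in", self.n_markers_in),
            ("markers_kept", self.n_markers_kept),
            ("mean_sample_call_rate", self.mean_sample_call_rate),
            ("mean_marker_call_rate", self.mean_marker_call_rate),
            ("mean_heterozygosity", self.mean_heterozygosity),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GenomicRelationshipMatrix:
    """VanRaden genomic relationship matrix with its scaling denominator."""

    genotype_ids: list[str]
    values: np.ndarray
    denominator: float
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotype_ids),) * 2:
            raise InputDataError("GRM must be square over genotype_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise InputDataError("GRM is not symmetric within 1e-10")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.genotype_ids)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "genotype"
        frame.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "GenomicRelationshipMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy(dtype=float)
        values = (values + values.T) / 2.0  # round-trip symmetrisation
        return cls(list(frame.index), values, denominator=np.nan)


# ---------------------------------------------------------------------- #
# estimators
# ---------------------------------------------------------------------- #
class MarkerQC(BaseEstimator):
    """Quality-control filter for a :class:`MarkerPanel`.

    Samples are screened before markers: a sample is dropped when its call
    rate falls below ``sample_call_min`` (primary reason ``call_rate``) or its
    heterozygosity exceeds ``het_max`` (reason ``heterozygosity``).  Markers
    are then dropped for call rate below ``marker_call_min`` (``call_rate``)
    or minor allele frequency below ``maf_min`` (``maf``), both computed on
    the retained samples.

    Defaults reflect common practice for amplicon panels on inbred rice:
    a 66% sample pass bar, 90% marker call rate, MAF 1% and a 10%
    heterozygosity ceiling.
    """

    def __init__(self, sample_call_min: float = 0.66, marker_call_min: float = 0.90,
                 maf_min: float = 0.01, het_max: float = 0.10):
        self.sample_call_min = sample_call_min
        self.marker_call_min = marker_call_min
        self.maf_min = maf_min
        self.het_max = het_max

    def fit(self, panel: MarkerPanel, y=None) -> "MarkerQC":
        if panel.n_genotypes == 0 or panel.n_markers == 0:
            raise InputDataError("cannot QC an empty marker panel")

        call = panel.sample_call_rate
        het = panel.sample_heterozygosity
        dropped_samples = []
        keep_samples = []
        for i, g in enumerate(panel.genotype_ids):
            if call[i] < self.sample_call_min:
                dropped_samples.append((g, "call_rate", call[i]))
            elif not np.isnan(het[i]) and het[i] > self.het_max:
                dropped_samples.append((g, "heterozygosity", het[i]))
            else:
                keep_samples.append(i)
        if not keep_samples:
            raise EmptyPanelError(
                "quality control removed all samples "
                f"(sample_call_min={self.sample_call_min}, het_max={self.het_max})"
            )

        trimmed = panel.subset(genotypes=keep_samples)
        mcall = trimmed.marker_call_rate
        maf = trimmed.minor_allele_frequencies
        dropped_markers = []
        keep_markers = []
        for j, m in enumerate(panel.marker_ids):
            if mcall[j] < self.marker_call_min:
                dropped_markers.append((m, "call_rate", mcall[j]))
            elif np.isnan(maf[j]) or maf[j] < self.maf_min:
                dropped_markers.append((m, "maf", maf[j]))
            else:
                keep_markers.append(j)

        self.keep_samples_ = keep_samples
        self.keep_markers_ = keep_markers
        self.report_ = MarkerQCReport(
            n_samples_in=panel.n_genotypes,
            n_markers_in=panel.n_markers,
            dropped_samples=pd.DataFrame(
                dropped_samples, columns=["genotype", "reason", "value"]
            ),
            dropped_markers=pd.DataFrame(
                dropped_markers, columns=["marker", "reason", "value"]
            ),
            mean_sample_call_rate=float(np.mean(call)),
            mean_marker_call_rate=float(np.mean(panel.marker_call_rate)),
            mean_heterozygosity=float(np.nanmean(het)) if len(het) else np.nan,
        )
        return self

    def transform(self, panel: MarkerPanel) -> MarkerPanel:
        return panel.subset(genotypes=self.keep_samples_, markers=self.keep_markers_)

    def fit_transform(self, panel: MarkerPanel, y=None) -> MarkerPanel:
        return self.fit(panel).transform(panel)


class MarkerImputer(BaseEstimator):
    """Mean-dosage imputation: a missing cell becomes the marker mean 2p_j.

    Imputing with the observed mean leaves every marker's allele frequency
    unchanged, which keeps the GRM centring consistent.
    """

    def fit(self, panel: MarkerPanel, y=None) -> "MarkerImputer":
        all_missing = np.isnan(panel.dosages).all(axis=0)
        if all_missing.any():
            bad = [panel.marker_ids[j] for j in np.flatnonzero(all_missing)]
            raise InputDataError(
                f"markers with no observed genotype cannot be imputed: {bad[:10]}"
            )
        self.marker_means_ = np.nanmean(panel.dosages, axis=0)
        return self

    def transform(self, panel: MarkerPanel) -> MarkerPanel:
        filled = panel.dosages.copy()
        miss = np.isnan(filled)
        if miss.any():
            filled[miss] = np.broadcast_to(self.marker_means_, filled.shape)[miss]
        out = MarkerPanel.__new__(MarkerPanel)  # bypass {0,1,2} validation
        out.genotype_ids = list(panel.genotype_ids)
        out.marker_ids = list(panel.marker_ids)
        out.dosages = filled
        return out

    def fit_transform(self, panel: MarkerPanel, y=None) -> MarkerPanel:
        return self.fit(panel).transform(panel)


class GenomicRelationship(BaseEstimator):
    """Compute the VanRaden GRM from a complete dosage panel.

    Parameters
    ----------
    ridge : float
        Added to the diagonal so downstream mixed-model equations can invert
        the matrix; the default 1e-6 is negligible relative to diagonal
        values near 1.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, panel: MarkerPanel, y=None) -> "GenomicRelationship":
        if panel.n_genotypes < 2 or panel.n_markers < 2:
            raise InputDataError("GRM needs at least 2 genotypes and 2 markers")
        if panel.has_missing:
            raise InputDataError("GRM requires a complete panel; impute first")
        p = panel.allele_frequencies
        denom = float(2.0 * np.sum(p * (1.0 - p)))
        if denom <= 0.0:
            raise InputDataError(
                "all markers are monomorphic: VanRaden denominator 2*sum p(1-p) is zero"
            )
        z = panel.dosages - 2.0 * p
        values = z @ z.T / denom
        values = (values + values.T) / 2.0
        values[np.diag_indices_from(values)] += self.ridge
        self.grm_ = GenomicRelationshipMatrix(
            list(panel.genotype_ids), values, denominator=denom, ridge=self.ridge
        )
        self.denominator_ = denom
        return self

    def transform(self, panel: MarkerPanel) -> GenomicRelationshipMatrix:
        return self.grm_

    def fit_transform(self, panel: MarkerPanel, y=None) -> GenomicRelationshipMatrix:
        return self.fit(panel).grm_


# ---------------------------------------------------------------------- #
# thin functional wrappers
# ---------------------------------------------------------------------- #
def qc_markers(panel: MarkerPanel, sample_call_min: float = 0.66,
               marker_call_min: float = 0.90, maf_min: float = 0.01,
               het_max: float = 0.10) -> tuple[MarkerPanel, MarkerQCReport]:
    qc = MarkerQC(sample_call_min, marker_call_min, maf_min, het_max)
    cleaned = qc.fit_transform(panel)
    return cleaned, qc.report_


def impute_missing(panel: MarkerPanel) -> MarkerPanel:
    return MarkerImputer().fit_transform(panel)


def compute_grm(panel: MarkerPanel, ridge: float = 1e-6) -> GenomicRelationshipMatrix:
    return GenomicRelationship(ridge=ridge).fit_transform(panel)
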