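"""Cross-cohort expression screen, CLIP quantification filters, polysome summaries.

The screen reproduces a meta-analysis pattern used for prioritising
RNA-modifying proteins (RMPs) across tumour expression cohorts: per-cohort
Z-scores of tumour classes against the normal reference group, a per-gene
one-way ANOVA across the N (normal) / P (primary) / M (metastasis) groups, and
a "coherence" summary — the percentage of cohorts in which the gene's ANOVA is
significant among cohorts that contain the gene.  A gene is a hit when it is
significant in at least ``min_datasets`` cohorts AND its coherence reaches
``min_coherence`` percent.

Also housed here: RPM/RPKM quantification with log2 IP-vs-control enrichment
and the replicate coefficient-of-variation peak filter used for CLIP peak sets,
and per-fraction polysome-profile summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LABELS = ("N", "P", "M")

__all__ = [
    "ExpressionCohort",
    "PolysomeProfile",
    "cohort_zscore",
    "cohort_anova",
    "rmp_screen",
    "parclip_quant",
    "class_median_log2_rpm",
    "cv_filter",
    "polysome_proportions",
    "polysome_fc",
]


@dataclass
class ExpressionCohort:
    """One expression dataset: genes x samples log2 expression with group labels.

    ``labels`` holds one of ``N`` (normal reference), ``P`` (primary tumour) or
    ``M`` (metastasis) per sample, aligned with the matrix columns.  At least
    two N samples are required so a reference standard deviation exists.
    """

    name: str
    expr: pd.DataFrame
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) != self.expr.shape[1]:
            raise ValueError(
                f"cohort {self.name!r}: {len(self.labels)} labels for "
                f"{self.expr.shape[1]} samples"
            )
        bad = set(self.labels) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"cohort {self.name!r}: unknown group labels {sorted(bad)}")
        if self.labels.count("N") < 2:
            raise ValueError(f"cohort {self.name!r}: need >=2 N samples")

    def group_columns(self, group: str) -> list:
        return [c for c, g in zip(self.expr.columns, self.labels) if g == group]

    @property
    def genes(self) -> pd.Index:
        return self.expr.index


def cohort_zscore(cohort: ExpressionCohort, gene: str, tumour_class: str) -> float:
    """Z = (mean(class) - mean(N)) / sd(N), sd with n-1 denominator.

    Expresses the class mean as a number of reference-population standard
    deviations from the normal-group mean.  Returns NaN (with a warning) when
    the N-group SD is zero, and NaN silently when the gene or class is absent.
    """
    if tumour_class not in ("P", "M"):
        raise ValueError(f"tumour_class must be 'P' or 'M', got {tumour_class!r}")
    if gene not in cohort.expr.index:
        return float("nan")
    normals = cohort.expr.loc[gene, cohort.group_columns("N")].to_numpy(float)
    cls = cohort.expr.loc[gene, cohort.group_columns(tumour_class)].to_numpy(float)
    if cls.size == 0 or normals.size < 2:
        return float("nan")
    sd = normals.std(ddof=1)
    if sd == 0:
        warnings.warn(f"cohort {cohort.name!r}, gene {gene!r}: zero N-group SD")
        return float("nan")
    return float((cls.mean() - normals.mean()) / sd)


def cohort_anova(cohort: ExpressionCohort, gene: str) -> float:
    """One-way fixed-effects ANOVA p-value across the N/P/M groups present.

    Groups with fewer than two samples are dropped; with fewer than two usable
    groups the result is NaN.
    """
    if gene not in cohort.expr.index:
        return float("nan")
    groups = []
    for g in GROUP_LABELS:
        cols = cohort.group_columns(g)
        if len(cols) >= 2:
            groups.append(cohort.expr.loc[gene, cols].to_numpy(float))
    if len(groups) < 2:
        return float("nan")
    return float(stats.f_oneway(*groups).pvalue)


def _anova_matrix(cohort: ExpressionCohort) -> pd.Series:
    """Vectorised per-gene ANOVA over all genes of a cohort."""
    arrays = []
    for g in GROUP_LABELS:
        cols = cohort.group_columns(g)
        if len(cols) >= 2:
            arrays.append(cohort.expr[cols].to_numpy(float))
    if len(arrays) < 2:
        return pd.Series(np.nan, index=cohort.expr.index)
    res = stats.f_oneway(*arrays, axis=1)
    return pd.Series(res.pvalue, index=cohort.expr.index)


def _zscore_matrix(cohort: ExpressionCohort, tumour_class: str) -> pd.Series:
    normals = cohort.expr[cohort.group_columns("N")].to_numpy(float)
    cols = cohort.group_columns(tumour_class)
    if not cols:
        return pd.Series(np.nan, index=cohort.expr.index)
    cls = cohort.expr[cols].to_numpy(float)
    sd = normals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (cls.mean(axis=1) - normals.mean(axis=1)) / sd
    z[sd == 0] = np.nan
    return pd.Series(z, index=cohort.expr.index)


def rmp_screen(
    cohorts: Sequence[ExpressionCohort],
    gene_list: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    min_datasets: int = 3,
    min_coherence: float = 75.0,
) -> pd.DataFrame:
    """Multi-cohort differential-expression screen.

    For every gene: per-cohort ANOVA significance (p < ``alpha``), per-cohort
    Z_P and Z_M, coherence = 100 * n_significant / n_present over cohorts that
    contain the gene, and average Z per tumour class over cohorts where it is
    defined.  ``hit`` requires both ``n_significant >= min_datasets`` and
    ``coherence >= min_coherence``.  Output is ranked by \\|avg Z\\| (largest
    class-average magnitude first).  Per-cohort values are kept in columns
    ``p_<cohort>``, ``Z_P_<cohort>``, ``Z_M_<cohort>``; non-significant cohort
    Z values are reported, flagged by their accompanying p-value.
    """
    if len(cohorts) == 0:
        raise ValueError("need at least one cohort")
    if gene_list is None:
        genes: list[str] = []
        for c in cohorts:
            genes.extend(g for g in c.genes if g not in genes)
    else:
        genes = list(gene_list)

    per_cohort_p = {c.name: _anova_matrix(c) for c in cohorts}
    per_cohort_zp = {c.name: _zscore_matrix(c, "P") for c in cohorts}
    per_cohort_zm = {c.name: _zscore_matrix(c, "M") for c in cohorts}

    rows = []
    for gene in genes:
        n_present = 0
        n_sig = 0
        zps, zms = [], []
        rec: dict = {"gene": gene}
        for c in cohorts:
            present = gene in c.expr.index
            p = per_cohort_p[c.name].get(gene, np.nan) if present else np.nan
            zp = per_cohort_zp[c.name].get(gene, np.nan) if present else np.nan
            zm = per_cohort_zm[c.name].get(gene, np.nan) if present else np.nan
            rec[f"p_{c.name}"] = p
            rec[f"Z_P_{c.name}"] = zp
            rec[f"Z_M_{c.name}"] = zm
            if present:
                n_present += 1
                if np.isfinite(p) and p < alpha:
                    n_sig += 1
            if np.isfinite(zp):
                zps.append(zp)
            if np.isfinite(zm):
                zms.append(zm)
        coherence = 100.0 * n_sig / n_present if n_present else 0.0
        avg_zp = float(np.mean(zps)) if zps else np.nan
        avg_zm = float(np.mean(zms)) if zms else np.nan
        rec.update(
            n_present=n_present,
            n_significant=n_sig,
            coherence=coherence,
            avg_Z_P=avg_zp,
            avg_Z_M=avg_zm,
            hit=bool(n_sig >= min_datasets and coherence >= min_coherence),
        )
        rows.append(rec)

    out = pd.DataFrame(rows).set_index("gene")
    rank = out[["avg_Z_P", "avg_Z_M"]].abs().max(axis=1).fillna(-np.inf)
    return out.loc[rank.sort_values(ascending=False).index]


def parclip_quant(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    gene_lengths: pd.Series,
    ip: str,
    control: str,
    pseudo_rpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene RPM/RPKM and log2 IP-vs-control enrichment.

    RPM = 1e6 * count / library size; RPKM = 1e3 * RPM / length (nt);
    enrichment = log2((RPM_IP + c) / (RPM_control + c)) with c = ``pseudo_rpm``.
    """
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for every gene")
    rpm = 1e6 * counts.div(library_sizes, axis=1)
    rpkm = 1e3 * rpm.div(lengths, axis=0)
    out = pd.DataFrame(index=counts.index)
    for s in counts.columns:
        out[f"rpm_{s}"] = rpm[s]
        out[f"rpkm_{s}"] = rpkm[s]
    out["log2_enrichment"] = np.log2(
        (rpm[ip] + pseudo_rpm) / (rpm[control] + pseudo_rpm)
    )
    return out


def class_median_log2_rpm(rpm: pd.Series, classes: pd.Series) -> pd.Series:
    """Median log2(RPM) per RNA class (tRNA, rRNA, mRNA, ...); zero RPM is dropped."""
    log2rpm = np.log2(rpm[rpm > 0])
    return log2rpm.groupby(classes.reindex(log2rpm.index)).median()


def cv_filter(cpm: pd.DataFrame, max_cv_percent: float = 30.0) -> pd.DataFrame:
    """Retain peaks reproducible across replicates.

    Peaks present (CPM > 0) in fewer than two replicates are removed first;
    survivors are kept when CV = 100 * sd / mean (n-1 sd) is below
    ``max_cv_percent``.  Peaks with zero mean are removed.
    """
    if cpm.shape[1] < 2:
        raise ValueError("need >=2 replicates for the CV filter")
    present = (cpm > 0).sum(axis=1) >= 2
    kept = cpm.loc[present]
    mean = kept.mean(axis=1)
    sd = kept.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    ok = (mean > 0) & (cv < max_cv_percent)
    return kept.loc[ok]


@dataclass
class PolysomeProfile:
    """Transcripts x sucrose-gradient fractions abundance table.

    ``polysome_mask`` marks the fractions containing polysome-engaged mRNAs;
    at least one polysome and one non-polysome fraction are required.
    """

    abundance: pd.DataFrame
    polysome_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.polysome_mask = np.asarray(self.polysome_mask, dtype=bool)
        if self.polysome_mask.shape != (self.abundance.shape[1],):
            raise ValueError("polysome_mask length must match number of fractions")
        if not (self.polysome_mask.any() and (~self.polysome_mask).any()):
            raise ValueError("need >=1 polysome and >=1 non-polysome fraction")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")


def polysome_proportions(profile: PolysomeProfile) -> pd.DataFrame:
    """Per-transcript fraction shares: abundance normalized to the transcript total.

    Transcripts with zero total are dropped (missing, not zero).
    """
    total = profile.abundance.sum(axis=1)
    kept = profile.abundance.loc[total > 0]
    return kept.div(kept.sum(axis=1), axis=0)


def polysome_fc(profile: PolysomeProfile) -> pd.Series:
    """Polysome/non-polysome share ratio per transcript.

    FC = (sum of polysome-fraction shares) / (sum of non-polysome shares).
    Transcripts with all mass in polysome fractions report ``inf`` (degenerate,
    flagged by the caller via ``np.isinf``); zero-total transcripts are absent.
    """
    shares = polysome_proportions(profile)
    poly = shares.loc[:, profile.polysome_mask].sum(axis=1)
    nonpoly = shares.loc[:, ~profile.polysome_mask].sum(axis=1)
    with np.errstate(divide="ignore"):
        fc = poly / nonpoly
    return fc
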