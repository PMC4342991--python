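"""Microarray-style sex-biased differential expression.

Pipeline: probe intensities -> log2 (with a positivity floor) -> quantile
normalization across samples -> per-gene probe summarization -> two-sample
t-test male vs female -> multiple-testing adjustment -> significance and
bias classification. The fold-change direction is fixed as
``log2_fc = mean(male) - mean(female)``, i.e. log2(male/female).

A transcript is called differentially expressed (a DET) when its adjusted
p-value falls below ``alpha``; it is additionally classed as strongly
male- or female-biased when |log2_fc| exceeds ``strong_lfc``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from os import PathLike
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: -log10(p_adj) rendered for p_adj == 0 in volcano tables.
NEG_LOG10_CAP = 320.0

SEXES = ("male", "female")
BIAS_CLASSES = ("male_strong", "female_strong", "not_strong", "not_significant")


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and method switches for the differential-expression stage.

    ``alpha`` applies to the *adjusted* p-value; ``strong_lfc`` is the
    absolute log2 fold-change bound separating strongly biased DETs from
    the rest. Repeat hybridizations are included as ordinary samples by
    default; ``average_into_parent`` collapses each repeat into its parent
    column before testing.
    """

    alpha: float = 0.05
    strong_lfc: float = 2.0
    summarization: str = "median"
    test: str = "student"
    adjust: str = "bonferroni"
    include_repeats: str = "as_samples"
    log2_floor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.strong_lfc < 0:
            raise ValueError("strong_lfc must be >= 0")
        if self.summarization not in ("median", "mean"):
            raise ValueError("summarization must be 'median' or 'mean'")
        if self.test not in ("student", "welch"):
            raise ValueError("test must be 'student' or 'welch'")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValueError("adjust must be 'bonferroni' or 'bh'")
        if self.include_repeats not in ("as_samples", "average_into_parent"):
            raise ValueError(
                "include_repeats must be 'as_samples' or 'average_into_parent'"
            )
        if self.log2_floor <= 0:
            raise ValueError("log2_floor must be > 0")


@dataclass
class ExpressionStudy:
    """Probe x sample intensity matrix plus sample sheet and probe->gene map.

    ``intensities``: DataFrame indexed by probe id, columns = sample ids,
    raw (positive) scale. ``samples``: DataFrame with columns sample_id,
    sex in {male, female}, repeat_of (empty string or NaN for unique
    samples). ``probe_to_gene``: Series mapping probe id -> gene id.
    """

    intensities: pd.DataFrame
    probe_to_gene: pd.Series
    samples: pd.DataFrame

    def validate(self) -> None:
        missing = self.intensities.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} matrix probes absent from probe_to_gene map "
                f"(first: {missing[0]!r})"
            )
        if set(self.samples["sample_id"]) != set(self.intensities.columns):
            raise ValueError("sample sheet ids do not match matrix columns")
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        for sex in SEXES:
            if (self.samples["sex"] == sex).sum() < 2:
                raise ValueError(f"need >=2 samples per sex, got too few {sex}")

    @classmethod
    def from_files(
        cls,
        intensities_tsv: Union[str, PathLike],
        samples_tsv: Union[str, PathLike],
        probe_map_tsv: Union[str, PathLike],
    ) -> "ExpressionStudy":
        intensities = pd.read_csv(intensities_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(samples_tsv, sep="\t", dtype=str).fillna({"repeat_of": ""})
        pmap = pd.read_csv(probe_map_tsv, sep="\t", index_col=0)
        study = cls(intensities, pmap.iloc[:, 0], samples)
        study.validate()
        return study

    def to_files(self, intensities_tsv, samples_tsv, probe_map_tsv) -> None:
        self.intensities.to_csv(intensities_tsv, sep="\t", index_label="probe_id")
        self.samples.to_csv(samples_tsv, sep="\t", index=False)
        self.probe_to_gene.rename("gene_id").to_csv(
            probe_map_tsv, sep="\t", index_label="probe_id"
        )


def log2_transform(intensities: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """log2 of intensities after flooring at ``floor`` (> 0)."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    values = intensities.to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2(np.maximum(values, floor)),
        index=intensities.index,
        columns=intensities.columns,
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common rank-wise mean distribution.

    Each column is sorted, the reference distribution is the row-wise mean
    of the sorted columns, and each value is replaced by the reference
    value at its rank. Ties within a column receive the mean of the
    reference values at the tied ranks, so the map is well defined and
    idempotent. Missing values are rejected.
    """
    a = matrix.to_numpy(dtype=float)
    if a.ndim != 2 or a.shape[1] < 1:
        raise ValueError("need a matrix with at least one column")
    if np.isnan(a).any():
        raise ValueError("missing values are not supported")
    reference = np.sort(a, axis=0).mean(axis=1)
    out = np.empty_like(a)
    for j in range(a.shape[1]):
        col = a[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # contiguous tie groups in sorted order share the mean reference value
        new_group = np.r_[True, sorted_col[1:] != sorted_col[:-1]]
        group_id = np.cumsum(new_group) - 1
        sums = np.bincount(group_id, weights=reference)
        counts = np.bincount(group_id)
        out[order, j] = (sums / counts)[group_id]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def summarize_probes(
    matrix: pd.DataFrame,
    probe_to_gene: Union[pd.Series, Mapping[str, str]],
    method: str = "median",
) -> pd.DataFrame:
    """Collapse probe rows to one row per gene (median or mean per sample)."""
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    pmap = pd.Series(probe_to_gene)
    unmapped = matrix.index.difference(pmap.index)
    if len(unmapped):
        raise ValueError(f"{len(unmapped)} probes missing from probe_to_gene map")
    empty_genes = set(pmap.unique()) - set(pmap.loc[matrix.index].unique())
    if empty_genes:
        logger.warning(
            "%d genes have no probes in the matrix and are excluded (e.g. %r)",
            len(empty_genes),
            sorted(empty_genes)[0],
        )
    genes = pmap.loc[matrix.index]
    grouped = matrix.groupby(genes.to_numpy())
    summarized = grouped.median() if method == "median" else grouped.mean()
    summarized.index.name = "gene_id"
    return summarized.sort_index()


def _resolve_sample_groups(
    samples: pd.DataFrame, cfg: DEConfig
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Sample sheet after repeat handling, plus repeat->parent groupings."""
    samples = samples.copy()
    if "repeat_of" not in samples.columns:
        samples["repeat_of"] = ""
    samples["repeat_of"] = samples["repeat_of"].fillna("")
    if cfg.include_repeats == "as_samples":
        return samples, {}
    groups: dict[str, list[str]] = {}
    for _, row in samples.iterrows():
        parent = row["repeat_of"] or row["sample_id"]
        groups.setdefault(parent, []).append(row["sample_id"])
    kept = samples[samples["repeat_of"] == ""].reset_index(drop=True)
    return kept, groups


def t_test_per_gene(
    gene_matrix: pd.DataFrame, samples: pd.DataFrame, cfg: DEConfig = DEConfig()
) -> pd.DataFrame:
    """Two-sided two-sample t-test per gene, male minus female.

    Student's pooled-variance test by default (Welch optional). When the
    pooled variance degenerates to zero the convention is p=1 for equal
    group means and p=0 otherwise. Requires >=2 samples per sex after
    repeat handling.
    """
    samples, groups = _resolve_sample_groups(samples, cfg)
    if groups:
        gene_matrix = pd.DataFrame(
            {
                parent: gene_matrix[members].mean(axis=1)
                for parent, members in groups.items()
            }
        )
    sex_of = dict(zip(samples["sample_id"], samples["sex"]))
    male_cols = [s for s in gene_matrix.columns if sex_of.get(s) == "male"]
    female_cols = [s for s in gene_matrix.columns if sex_of.get(s) == "female"]
    if len(male_cols) < 2 or len(female_cols) < 2:
        raise ValueError(
            f"need >=2 samples per sex after repeat handling, got "
            f"{len(male_cols)} male / {len(female_cols)} female"
        )
    m = gene_matrix[male_cols].to_numpy(dtype=float)
    f = gene_matrix[female_cols].to_numpy(dtype=float)
    mean_m = m.mean(axis=1)
    mean_f = f.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger a scipy precision warning; the
        # degenerate-variance convention below handles them explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(m, f, axis=1, equal_var=(cfg.test == "student"))
        p = np.asarray(result.pvalue, dtype=float)
    degenerate = (m.var(axis=1) == 0) & (f.var(axis=1) == 0)
    p[degenerate & (mean_m == mean_f)] = 1.0
    p[degenerate & (mean_m != mean_f)] = 0.0
    return pd.DataFrame(
        {
            "mean_male": mean_m,
            "mean_female": mean_f,
            "log2_fc": mean_m - mean_f,
            "p_raw": p,
        },
        index=gene_matrix.index,
    )


def adjust_pvalues(p_raw: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (min(1, p*m)) or Benjamini-Hochberg adjustment."""
    p = np.asarray(p_raw, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError("method must be 'bonferroni' or 'bh'")


def classify_bias(
    results: pd.DataFrame, cfg: DEConfig = DEConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach is_det and bias_class; return summary counts.

    male_strong: significant and log2_fc > strong_lfc; female_strong:
    significant and log2_fc < -strong_lfc; not_strong: significant but
    within the band; not_significant otherwise.
    """
    results = results.copy()
    is_det = results["p_adj"] < cfg.alpha
    bias = np.where(
        ~is_det,
        "not_significant",
        np.where(
            results["log2_fc"] > cfg.strong_lfc,
            "male_strong",
            np.where(results["log2_fc"] < -cfg.strong_lfc, "female_strong", "not_strong"),
        ),
    )
    results["is_det"] = is_det
    results["bias_class"] = bias
    summary = {
        "n_genes": int(len(results)),
        "n_det": int(is_det.sum()),
        "n_male_strong": int((bias == "male_strong").sum()),
        "n_female_strong": int((bias == "female_strong").sum()),
    }
    return results, summary


def volcano_table(
    results: pd.DataFrame, path: Optional[Union[str, PathLike]] = None
) -> pd.DataFrame:
    """Volcano-plot table: gene, log2_fc, -log10(p_adj), bias_class.

    p_adj of exactly zero is rendered as the documented cap
    ``NEG_LOG10_CAP``.
    """
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(results["p_adj"].to_numpy(dtype=float))
    neg_log10 = np.where(np.isinf(neg_log10), NEG_LOG10_CAP, neg_log10)
    table = pd.DataFrame(
        {
            "gene_id": results.index,
            "log2_fc": results["log2_fc"].to_numpy(),
            "neg_log10_p_adj": neg_log10,
            "bias_class": results["bias_class"].to_numpy(),
        }
    )
    if path is not None:
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return table


def run_de(
    study: ExpressionStudy, cfg: DEConfig = DEConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full stage: log2 -> quantile normalize -> summarize -> test -> classify."""
    study.validate()
    logged = log2_transform(study.intensities, floor=cfg.log2_floor)
    normalized = quantile_normalize(logged)
    gene_matrix = summarize_probes(normalized, study.probe_to_gene, cfg.summarization)
    results = t_test_per_gene(gene_matrix, study.samples, cfg)
    results["p_adj"] = adjust_pvalues(results["p_raw"].to_numpy(), cfg.adjust)
    return classify_bias(results, cfg)
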