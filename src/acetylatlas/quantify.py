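"""Abundance-matrix construction, normalization, imputation, summarization.

The sites x runs intensity matrix is detection-filtered (a site counts as
detected in a tissue when at least ``min_replicates`` replicates of one sex
quantified it there), log2 transformed, median-normalized at the tissue
level, and then missing values are imputed feature-wise with a left-shifted
Gaussian (the standard Perseus approach for left-censored, missing-not-at-
random DIA data): draws from Normal(mu - downshift*sigma, (width*sigma)^2)
where mu/sigma are each row's observed mean and sd.  Finally replicate
values are summarized to one column per tissue x sex, preferring observed
over imputed values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .ingest import IntegrityError, SampleDesign, SiteRecord

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Sites x runs abundances with design metadata and imputation mask.

    ``values`` is a DataFrame indexed by collapse key with one column per
    run; missing cells are NaN.  ``imputed_mask`` marks cells filled by
    imputation (False everywhere until imputation runs).
    """

    values: pd.DataFrame
    design: list[SampleDesign]
    imputed_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise IntegrityError("duplicate row keys in abundance matrix")
        design_runs = [d.run_id for d in self.design]
        if list(self.values.columns) != design_runs:
            raise IntegrityError("matrix columns do not match design run order")

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), list(self.design), self.imputed_mask.copy()
        )

    @property
    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_id": [d.run_id for d in self.design],
                "tissue": [d.tissue for d in self.design],
                "sex": [d.sex for d in self.design],
                "replicate": [d.replicate for d in self.design],
            }
        ).set_index("run_id")


@dataclass
class DetectionPattern:
    """Per-site, per-tissue detection calls and tissue counts."""

    detected: pd.DataFrame          # sites x tissues, boolean
    n_tissues_detected: pd.Series   # per site

    def tissues_for_site(self, key: str) -> list[str]:
        row = self.detected.loc[key]
        return list(row.index[row])


def build_matrix(
    records: list[SiteRecord], design: list[SampleDesign]
) -> AbundanceMatrix:
    """Place raw per-run intensities into a sites x runs matrix.

    Zero intensities are treated as missing: DIA reports use 0 and blank
    interchangeably for non-quantified cells, and 0 is not a valid log2
    input.
    """
    run_ids = [d.run_id for d in design]
    run_set = set(run_ids)
    for rec in records:
        extra = set(rec.intensities) - run_set
        if extra:
            raise IntegrityError(
                f"site {rec.collapse_key!r} quantified in run(s) absent "
                f"from the design: {sorted(extra)}"
            )
    values = pd.DataFrame(
        np.nan,
        index=pd.Index([r.collapse_key for r in records], name="collapse_key"),
        columns=run_ids,
        dtype=float,
    )
    for rec in records:
        for run, v in rec.intensities.items():
            if v != 0:
                values.at[rec.collapse_key, run] = v
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return AbundanceMatrix(values, list(design), mask)


def compute_detection_pattern(
    matrix: AbundanceMatrix, cfg: PipelineConfig
) -> DetectionPattern:
    """Detected(site, tissue) iff some sex has >= min_replicates observations."""
    observed = matrix.values.notna() & ~matrix.imputed_mask
    tissues = sorted({d.tissue for d in matrix.design})
    cols = {}
    for tissue in tissues:
        per_sex = []
        sexes = sorted({d.sex for d in matrix.design if d.tissue == tissue})
        for sex in sexes:
            runs = [
                d.run_id
                for d in matrix.design
                if d.tissue == tissue and d.sex == sex
            ]
            per_sex.append(observed[runs].sum(axis=1) >= cfg.min_replicates)
        cols[tissue] = np.logical_or.reduce(per_sex) if per_sex else False
    detected = pd.DataFrame(cols, index=matrix.values.index)
    return DetectionPattern(detected, detected.sum(axis=1))


def detection_filter(
    matrix: AbundanceMatrix, cfg: PipelineConfig | None = None
) -> tuple[AbundanceMatrix, DetectionPattern]:
    """Drop sites never seen in >= min_replicates replicates of one tissue x sex."""
    cfg = cfg or PipelineConfig()
    pattern = compute_detection_pattern(matrix, cfg)
    keep = pattern.n_tissues_detected > 0
    logger.info("detection_filter: kept %d/%d sites", int(keep.sum()), len(keep))
    filtered = AbundanceMatrix(
        matrix.values.loc[keep].copy(),
        list(matrix.design),
        matrix.imputed_mask.loc[keep].copy(),
    )
    return filtered, DetectionPattern(
        pattern.detected.loc[keep], pattern.n_tissues_detected.loc[keep]
    )


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2 each observed intensity; missing cells stay missing."""
    vals = matrix.values
    observed = vals.notna()
    if (vals[observed] <= 0).any().any():
        raise ValueError("nonpositive observed intensity; cannot log2 transform")
    out = matrix.copy()
    out.values = np.log2(vals)
    return out


def median_normalize(
    matrix: AbundanceMatrix, cfg: PipelineConfig | None = None
) -> AbundanceMatrix:
    """Shift each run so its observed median matches its tissue's pooled median.

    The pooled median is taken over all observed values in the tissue's runs
    (both sexes); with ``median_norm_target='global'`` all runs are aligned
    to the whole matrix's pooled median instead.  Pure per-run shifts, so
    within-run differences are untouched.
    """
    cfg = cfg or PipelineConfig()
    out = matrix.copy()
    vals = out.values
    global_target = float(np.nanmedian(vals.to_numpy())) if (
        cfg.median_norm_target == "global"
    ) else None
    for tissue in sorted({d.tissue for d in matrix.design}):
        runs = [d.run_id for d in matrix.design if d.tissue == tissue]
        pooled = vals[runs].to_numpy().ravel()
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            warnings.warn(f"tissue {tissue!r} has no observed values; shift 0")
            continue
        target = global_target if global_target is not None else float(
            np.median(pooled)
        )
        for run in runs:
            col = vals[run]
            if col.notna().sum() == 0:
                warnings.warn(f"run {run!r} has no observed values; shift 0")
                continue
            vals[run] = col + (target - float(col.median()))
    return out


def impute_left_shifted(
    matrix: AbundanceMatrix,
    cfg: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AbundanceMatrix:
    """Fill missing cells with left-shifted Gaussian draws, feature-wise.

    For each row with observed mean mu and sample sd sigma, missing cells
    become independent draws from Normal(mu - downshift*sigma,
    (width*sigma)^2).  Rows with sigma == 0 fall back to the matrix-wide
    median of positive row sds.  Observed cells are untouched and the
    imputed mask records every filled cell.
    """
    cfg = cfg or PipelineConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    out = matrix.copy()
    vals = out.values.to_numpy()
    missing = np.isnan(vals)
    n_obs = (~missing).sum(axis=1)
    assert (n_obs >= 2).all(), (
        "rows with <2 observations must be removed by detection_filter first"
    )
    mu = np.nanmean(vals, axis=1)
    sigma = np.nanstd(vals, axis=1, ddof=1)
    positive = sigma[sigma > 0]
    fallback = float(np.median(positive)) if positive.size else 1.0
    sigma = np.where(sigma > 0, sigma, fallback)
    shift_mu = mu - cfg.impute_downshift * sigma
    width = cfg.impute_width * sigma
    for i in np.flatnonzero(missing.any(axis=1)):
        idx = np.flatnonzero(missing[i])
        vals[i, idx] = rng.normal(shift_mu[i], width[i], size=idx.size)
    out.values = pd.DataFrame(
        vals, index=matrix.values.index, columns=matrix.values.columns
    )
    out.imputed_mask = pd.DataFrame(
        missing, index=matrix.values.index, columns=matrix.values.columns
    )
    return out


def group_columns(design: list[SampleDesign]) -> dict[str, list[str]]:
    """Map 'tissue|sex' labels to their run columns, in design order."""
    groups: dict[str, list[str]] = {}
    for d in design:
        groups.setdefault(f"{d.tissue}|{d.sex}", []).append(d.run_id)
    return groups


def summarize_tissue_sex(
    detected: AbundanceMatrix, imputed: AbundanceMatrix
) -> pd.DataFrame:
    """Collapse replicates to one column per tissue x sex.

    Each cell is the mean of observed replicate values when any exist for
    that tissue x sex; otherwise the mean of the imputed draws, leaving no
    missing cells.
    """
    if detected.values.shape != imputed.values.shape:
        raise IntegrityError("detected and imputed matrices differ in shape")
    groups = group_columns(detected.design)
    out = {}
    for label, runs in groups.items():
        obs_mean = detected.values[runs].mean(axis=1)        # skips NaN
        imp_mean = imputed.values[runs].mean(axis=1)
        out[label] = obs_mean.fillna(imp_mean)
    summary = pd.DataFrame(out, index=detected.values.index)
    assert not summary.isna().any().any()
    return summary


def standardize_rows(summary: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-score each row; constant rows become all-zero with a warning."""
    values = summary.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) standardized to 0")
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        (values - mean) / sd, index=summary.index, columns=summary.columns
    )


def site_mean_abundance(
    matrix: AbundanceMatrix, detection: DetectionPattern | None = None
) -> pd.Series:
    """Mean of detected (non-imputed) log2 values per site.

    With a detection pattern, only runs belonging to tissues where the
    site passes the detection rule contribute, so stray single
    observations in off-tissues cannot drag the estimate; without one,
    all observed values count.
    """
    observed = matrix.values.where(~matrix.imputed_mask)
    if detection is None:
        return observed.mean(axis=1)
    run_tissue = {d.run_id: d.tissue for d in matrix.design}
    keep = pd.DataFrame(
        {
            run: detection.detected[run_tissue[run]]
            for run in observed.columns
        },
        index=observed.index,
    )
    return observed.where(keep).mean(axis=1)
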