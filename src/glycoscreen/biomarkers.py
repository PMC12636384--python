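"""Per-feature differential statistics, volcano classification and the
reproducibility-constrained biomarker screen.

Group comparison uses the equal-variance two-sided Student t-test on
relative levels with missing values imputed as zeros; effect size is the
mean-fold ratio (MFR), cancer mean over healthy mean.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VOLCANO_P = 1e-10
VOLCANO_MFR_BOUND = 2.0 ** 0.5
SCREEN_P = 1e-10
SCREEN_FC = 1.5
SCREEN_CV_MAX = 15.0


def egp_stats(
    values: pd.DataFrame,
    groups: pd.Series,
    cancer_group: str,
    healthy_group: str = "healthy",
    cv_intra: Optional[pd.Series] = None,
    cv_inter: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-feature t-test and mean-fold ratio, cancer vs healthy.

    ``values`` is features x samples; ``groups`` maps sample id -> group.
    Features whose healthy mean is zero get mfr NaN and are flagged
    ``excluded`` rather than dropped silently.
    """
    groups = groups.reindex(values.columns)
    a_cols = groups.index[groups == cancer_group]
    b_cols = groups.index[groups == healthy_group]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    a = values[a_cols].to_numpy(float)
    b = values[b_cols].to_numpy(float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mfr = np.where(mean_b > 0, mean_a / mean_b, np.nan)
        log2_mfr = np.where(np.isfinite(mfr) & (mfr > 0), np.log2(mfr), np.nan)
    out = pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "mfr": mfr,
            "log2_mfr": log2_mfr,
            "excluded": ~np.isfinite(mfr),
        },
        index=values.index,
    )
    out.index.name = "feature_id"
    n_excl = int(out.excluded.sum())
    if n_excl:
        logger.info("%d features with zero healthy mean excluded from MFR", n_excl)
    out["cv_intra_pct"] = (cv_intra.reindex(out.index) if cv_intra is not None
                           else np.nan)
    out["cv_inter_pct"] = (cv_inter.reindex(out.index) if cv_inter is not None
                           else np.nan)
    return out


def volcano_classify(
    stats_df: pd.DataFrame,
    p_thresh: float = VOLCANO_P,
    mfr_bound: float = VOLCANO_MFR_BOUND,
) -> pd.Series:
    """Label each feature up / down / ns from p-value and MFR thresholds."""
    p = stats_df.p_value
    mfr = stats_df.mfr
    up = (p < p_thresh) & (mfr > mfr_bound)
    down = (p < p_thresh) & (mfr < 1.0 / mfr_bound)
    labels = pd.Series("ns", index=stats_df.index, name="volcano_class")
    labels[up.fillna(False)] = "up"
    labels[down.fillna(False)] = "down"
    return labels


def screen_biomarkers(
    stats_df: pd.DataFrame,
    p_max: float = SCREEN_P,
    fc_min: float = SCREEN_FC,
    cv_max: float = SCREEN_CV_MAX,
) -> pd.DataFrame:
    """Candidate screen: very low p, |fold change| beyond fc_min in either
    direction, and intra- AND inter-day CV at or below cv_max.

    Returns the stats rows with ``screen_pass`` and a failure ``reason``
    column ('' when passing; missing CV is an explicit failure reason).
    """
    out = stats_df.copy()
    p_ok = out.p_value < p_max
    fc_ok = (out.mfr > fc_min) | (out.mfr < 1.0 / fc_min)
    cv_known = out.cv_intra_pct.notna() & out.cv_inter_pct.notna()
    cv_ok = cv_known & (out.cv_intra_pct <= cv_max) & (out.cv_inter_pct <= cv_max)
    out["screen_pass"] = (p_ok & fc_ok.fillna(False) & cv_ok).to_numpy()
    reasons = []
    for i in out.index:
        if out.screen_pass.loc[i]:
            reasons.append("")
        elif not cv_known.loc[i]:
            reasons.append("missing_cv")
        elif not p_ok.loc[i]:
            reasons.append("p_value")
        elif not bool(fc_ok.fillna(False).loc[i]):
            reasons.append("fold_change")
        else:
            reasons.append("cv")
    out["reason"] = reasons
    return out


def volcano_table(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready columns: -log10 p and log2 MFR alongside the class label."""
    out = stats_df.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out.p_value)
    out["volcano_class"] = volcano_classify(stats_df)
    return out
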