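"""Peak alignment, QC filtering and normalization.

Aligns per-sample LC-MS peak lists into a feature matrix at fixed m/z and
retention-time tolerances, then applies the three-step feature selection:
(i) drop irreproducible features (QC replicate CV > 50 %),
(ii) drop unreliable features (signal-to-noise < 5),
(iii) drop isotope, adduct and fragment satellite features;
finally expresses surviving features as ratios to the QC standard.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import constants
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

DEFAULT_TOL_MZ = 0.06
DEFAULT_TOL_RT = 0.3
DEFAULT_CV_MAX = 50.0
DEFAULT_SNR_MIN = 5.0
COELUTION_RT = 0.1  # min; satellite co-elution window
FRAGMENT_CORR_MIN = 0.95

REQUIRED_COLUMNS = ("sample_id", "rt_min", "mz", "area")


@dataclass
class FeatureMatrix:
    """Aligned features x samples.

    ``features`` holds one row per feature (feature_id, rt, mz) with
    intensity-weighted consensus coordinates; ``values`` is indexed by
    feature_id with one column per sample (absent entries are 0);
    ``provenance`` records which source peak fed each cell.
    """

    features: pd.DataFrame
    values: pd.DataFrame
    provenance: pd.DataFrame  # feature_id, sample_id, peak_id, area

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def subset(self, feature_ids: Sequence[int]) -> "FeatureMatrix":
        ids = list(feature_ids)
        feats = self.features[self.features.feature_id.isin(ids)].reset_index(drop=True)
        vals = self.values.loc[ids]
        prov = self.provenance[self.provenance.feature_id.isin(ids)]
        return FeatureMatrix(features=feats, values=vals, provenance=prov.reset_index(drop=True))

    def drop_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        keep = [c for c in self.values.columns if c not in set(sample_ids)]
        prov = self.provenance[~self.provenance.sample_id.isin(set(sample_ids))]
        return FeatureMatrix(
            features=self.features.copy(),
            values=self.values[keep],
            provenance=prov.reset_index(drop=True),
        )


def _check_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"peak table missing columns {missing}")
    if "peak_id" not in df.columns:
        df = df.copy()
        df["peak_id"] = [f"pk{i}" for i in range(len(df))]
    return df


def align_peaks(
    table: pd.DataFrame,
    tol_mz: float = DEFAULT_TOL_MZ,
    tol_rt: float = DEFAULT_TOL_RT,
) -> FeatureMatrix:
    """Cluster peaks from all samples into consensus features.

    Greedy seeded clustering: peaks are visited in descending area order
    (ties broken by m/z, RT, sample id, so the result does not depend on row
    or sample order); each unclaimed peak opens a feature and claims, per
    sample, the nearest unclaimed peak within both tolerances (nearest by
    |dmz| then |drt|). Consensus coordinates are the intensity-weighted
    means of the member peaks.
    """
    if tol_mz <= 0 or tol_rt <= 0:
        raise ConfigurationError("alignment tolerances must be > 0")
    table = _check_table(table)
    n = len(table)
    if n == 0:
        return FeatureMatrix(
            features=pd.DataFrame(columns=["feature_id", "rt", "mz"]),
            values=pd.DataFrame(),
            provenance=pd.DataFrame(columns=["feature_id", "sample_id", "peak_id", "area"]),
        )

    mz = table["mz"].to_numpy(float)
    rt = table["rt_min"].to_numpy(float)
    area = table["area"].to_numpy(float)
    sample = table["sample_id"].to_numpy(str)
    peak_id = table["peak_id"].to_numpy(str)
    if (area <= 0).any() or (mz <= 0).any() or (rt < 0).any():
        raise ConfigurationError("peaks require area > 0, mz > 0, rt >= 0")

    # deterministic seed order: by area desc, then coordinates, then ids
    seed_order = np.lexsort((peak_id, sample, rt, mz, -area))
    # mz-sorted view for windowed candidate lookup
    mz_order = np.argsort(mz, kind="stable")
    mz_sorted = mz[mz_order]

    claimed = np.zeros(n, dtype=bool)
    feat_rows: List[tuple] = []
    prov_rows: List[tuple] = []
    fid = 0
    for seed in seed_order:
        if claimed[seed]:
            continue
        lo = np.searchsorted(mz_sorted, mz[seed] - tol_mz, side="left")
        hi = np.searchsorted(mz_sorted, mz[seed] + tol_mz, side="right")
        cand = mz_order[lo:hi]
        cand = cand[~claimed[cand]]
        cand = cand[np.abs(rt[cand] - rt[seed]) <= tol_rt]
        cand = cand[np.abs(mz[cand] - mz[seed]) <= tol_mz]  # guard fp edge
        # nearest per sample: sort by (sample, |dmz|, |drt|) and take first
        dmz = np.abs(mz[cand] - mz[seed])
        drt = np.abs(rt[cand] - rt[seed])
        order = np.lexsort((peak_id[cand], drt, dmz, sample[cand]))
        members = []
        last = None
        for idx in order:
            s = sample[cand[idx]]
            if s != last:
                members.append(cand[idx])
                last = s
        members = np.asarray(members)
        claimed[members] = True
        w = area[members]
        feat_rows.append(
            (fid, float(np.average(rt[members], weights=w)),
             float(np.average(mz[members], weights=w)))
        )
        for m in members:
            prov_rows.append((fid, sample[m], peak_id[m], area[m]))
        fid += 1

    features = pd.DataFrame(feat_rows, columns=["feature_id", "rt", "mz"])
    provenance = pd.DataFrame(prov_rows, columns=["feature_id", "sample_id", "peak_id", "area"])
    all_samples = sorted(set(sample))
    values = (
        provenance.pivot_table(index="feature_id", columns="sample_id",
                               values="area", aggfunc="first")
        .reindex(index=features.feature_id, columns=all_samples)
        .fillna(0.0)
    )
    values.columns.name = None
    return FeatureMatrix(features=features, values=values, provenance=provenance)


def compute_cv(replicate_areas: Sequence[float]) -> float:
    """Percent coefficient of variation (sample sd / mean * 100).

    Returns NaN (undefined; the feature fails the CV filter) for fewer than
    two replicates or a non-positive mean.
    """
    x = np.asarray(list(replicate_areas), dtype=float)
    if len(x) < 2:
        return float("nan")
    m = x.mean()
    if m <= 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass
class NoiseFloorModel:
    """Local noise-floor estimator built from known noise peaks.

    The floor at a retention time is the median area of noise peaks within
    +/- ``window`` minutes, falling back to the global median when no noise
    peak is nearby.
    """

    noise_rt: np.ndarray
    noise_area: np.ndarray
    window: float = 0.5
    _global: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.noise_rt)
        self.noise_rt = np.asarray(self.noise_rt, float)[order]
        self.noise_area = np.asarray(self.noise_area, float)[order]
        if len(self.noise_area) == 0 or np.median(self.noise_area) <= 0:
            raise ConfigurationError("noise floor model requires positive noise areas")
        self._global = float(np.median(self.noise_area))

    @classmethod
    def from_peaks(cls, table: pd.DataFrame, window: float = 0.5) -> "NoiseFloorModel":
        return cls(noise_rt=table["rt_min"].to_numpy(float),
                   noise_area=table["area"].to_numpy(float), window=window)

    @classmethod
    def constant(cls, floor: float) -> "NoiseFloorModel":
        return cls(noise_rt=np.array([0.0]), noise_area=np.array([floor]), window=np.inf)

    def floor_at(self, rt: float) -> float:
        lo = np.searchsorted(self.noise_rt, rt - self.window, side="left")
        hi = np.searchsorted(self.noise_rt, rt + self.window, side="right")
        if hi <= lo:
            logger.debug("no local noise peaks at rt=%.2f; global fallback", rt)
            return self._global
        return float(np.median(self.noise_area[lo:hi]))


def estimate_snr(matrix: FeatureMatrix, noise_model: NoiseFloorModel,
                 sample_ids: Optional[Sequence[str]] = None) -> pd.Series:
    """Signal-to-noise per feature: median area across samples / local floor.

    Median is taken over the (zero-imputed) sample columns, so features
    present in under half the samples get snr 0 and fail the filter.
    """
    cols = list(sample_ids) if sample_ids is not None else list(matrix.values.columns)
    med = matrix.values[cols].median(axis=1)
    floors = matrix.features.set_index("feature_id").rt.map(noise_model.floor_at)
    return med / floors


def flag_artifacts(
    matrix: FeatureMatrix,
    tol_mz: float = DEFAULT_TOL_MZ,
    coelution_rt: float = COELUTION_RT,
    fragment_corr_min: float = FRAGMENT_CORR_MIN,
) -> pd.DataFrame:
    """Flag isotope, adduct and fragment satellite features.

    A feature is an isotope if a more intense feature sits at
    -1.00335/z Da (z in 1..3) within tol_mz/2 and co-elutes within 0.1 min;
    an adduct if a more intense feature sits at -(Na-H) or -(K-H);
    a fragment if a more intense higher-m/z co-eluting feature has
    per-sample areas correlating at r >= ``fragment_corr_min``.
    """
    feats = matrix.features
    nf = len(feats)
    flags = pd.DataFrame(
        {
            "is_isotope": np.zeros(nf, bool),
            "is_adduct": np.zeros(nf, bool),
            "is_fragment": np.zeros(nf, bool),
        },
        index=feats.feature_id,
    )
    if nf == 0:
        return flags
    rt = feats.rt.to_numpy()
    mz = feats.mz.to_numpy()
    fid = feats.feature_id.to_numpy()
    intensity = matrix.values.median(axis=1).reindex(fid).to_numpy()
    vals = matrix.values.reindex(fid).to_numpy()

    rt_order = np.argsort(rt)
    rt_sorted = rt[rt_order]
    iso_offsets = [constants.ISOTOPE_SPACING / z for z in (1, 2, 3)]
    add_offsets = [constants.ADDUCT_NA_MINUS_H, constants.ADDUCT_K_MINUS_H]
    half_tol = tol_mz / 2.0

    for i in range(nf):
        lo = np.searchsorted(rt_sorted, rt[i] - coelution_rt, side="left")
        hi = np.searchsorted(rt_sorted, rt[i] + coelution_rt, side="right")
        neigh = rt_order[lo:hi]
        neigh = neigh[(neigh != i) & (intensity[neigh] > intensity[i])]
        if len(neigh) == 0:
            continue
        dmz = mz[i] - mz[neigh]  # positive when neighbour is the lower-mz parent
        if any(np.abs(dmz - off).min() <= half_tol for off in iso_offsets):
            flags.iloc[i, 0] = True
        if any(np.abs(dmz - off).min() <= half_tol for off in add_offsets):
            flags.iloc[i, 1] = True
        higher = neigh[mz[neigh] > mz[i]]
        if len(higher) > 0:
            x = vals[i]
            if x.std() > 0:
                for j in higher:
                    y = vals[j]
                    if y.std() == 0:
                        continue
                    r = np.corrcoef(x, y)[0, 1]
                    if r >= fragment_corr_min:
                        flags.iloc[i, 2] = True
                        break
    return flags


def build_flags(
    matrix: FeatureMatrix,
    cv_pct: pd.Series,
    snr: pd.Series,
    artifact_flags: pd.DataFrame,
    cv_max: float = DEFAULT_CV_MAX,
    snr_min: float = DEFAULT_SNR_MIN,
) -> pd.DataFrame:
    """Combine filter inputs into one flags table with the pass decision.

    Removal is strict: cv > cv_max or snr < snr_min or any satellite bit.
    An undefined (NaN) CV fails the reproducibility step.
    """
    idx = matrix.features.feature_id
    out = pd.DataFrame(index=idx)
    out["cv_pct"] = cv_pct.reindex(idx).to_numpy()
    out["snr"] = snr.reindex(idx).to_numpy()
    for c in ("is_isotope", "is_adduct", "is_fragment"):
        out[c] = artifact_flags[c].reindex(idx).fillna(False).to_numpy()
    fail_cv = out.cv_pct.isna() | (out.cv_pct > cv_max)
    fail_snr = out.snr < snr_min
    fail_art = out.is_isotope | out.is_adduct | out.is_fragment
    out["pass_egp"] = ~(fail_cv | fail_snr | fail_art)
    return out


def select_egps(
    matrix: FeatureMatrix, flags: pd.DataFrame,
    cv_max: float = DEFAULT_CV_MAX, snr_min: float = DEFAULT_SNR_MIN,
) -> Tuple[FeatureMatrix, Dict[str, int]]:
    """Apply the three selection steps sequentially; report removal counts."""
    idx = matrix.features.feature_id
    f = flags.reindex(idx)
    fail_cv = f.cv_pct.isna() | (f.cv_pct > cv_max)
    after_cv = ~fail_cv
    fail_snr = after_cv & (f.snr < snr_min)
    after_snr = after_cv & ~fail_snr
    fail_art = after_snr & (f.is_isotope | f.is_adduct | f.is_fragment)
    keep = after_snr & ~fail_art
    report = {
        "input": int(len(idx)),
        "removed_cv": int(fail_cv.sum()),
        "removed_snr": int(fail_snr.sum()),
        "removed_artifact": int(fail_art.sum()),
        "output": int(keep.sum()),
    }
    return matrix.subset(idx[keep.to_numpy()].tolist()), report


def normalize_to_qc(
    matrix: FeatureMatrix, qc_values: pd.DataFrame
) -> Tuple[FeatureMatrix, List[int]]:
    """Express sample areas as ratios to the mean QC area per feature.

    ``qc_values`` is indexed by feature_id with one column per QC injection.
    Features absent from QC (zero mean) are excluded and returned.
    """
    qc_mean = qc_values.reindex(matrix.features.feature_id).fillna(0.0).mean(axis=1)
    excluded = qc_mean.index[qc_mean <= 0].tolist()
    if excluded:
        logger.warning("%d features have no QC signal; excluded", len(excluded))
    kept = [f for f in matrix.features.feature_id if f not in set(excluded)]
    sub = matrix.subset(kept)
    ratios = sub.values.div(qc_mean.reindex(sub.values.index), axis=0)
    return (
        FeatureMatrix(features=sub.features, values=ratios, provenance=sub.provenance),
        excluded,
    )


@dataclass
class PipelineResult:
    """Output of the full peaks stage."""

    egp_matrix: FeatureMatrix  # relative levels, cohort samples only
    flags: pd.DataFrame
    report: Dict[str, int]
    cv_intra: pd.Series
    cv_inter: pd.Series
    aligned: FeatureMatrix  # all features, raw areas, incl. QC columns


def run_pipeline(
    sample_table: pd.DataFrame,
    qc_intra: pd.DataFrame,
    qc_inter: pd.DataFrame,
    noise_model: Optional[NoiseFloorModel] = None,
    tol_mz: float = DEFAULT_TOL_MZ,
    tol_rt: float = DEFAULT_TOL_RT,
    cv_max: float = DEFAULT_CV_MAX,
    snr_min: float = DEFAULT_SNR_MIN,
) -> PipelineResult:
    """Align samples + QC injections jointly, filter, and QC-normalize.

    QC injections are aligned together with the cohort samples so replicate
    CVs and normalization ratios refer to the same consensus features. The
    step-(i) CV pools all QC injections; intra-/inter-day CVs are also kept
    separately for downstream reproducibility screening. Without an explicit
    noise model the floor defaults to the 5th percentile of all peak areas.
    """
    qc_i = _check_table(qc_intra)
    qc_d = _check_table(qc_inter)
    samp = _check_table(sample_table)
    qc_ids = set(qc_i.sample_id) | set(qc_d.sample_id)
    overlap = qc_ids & set(samp.sample_id)
    if overlap:
        raise ConfigurationError(f"QC sample ids collide with cohort ids: {sorted(overlap)[:3]}")
    combined = pd.concat([samp, qc_i, qc_d], ignore_index=True)
    aligned = align_peaks(combined, tol_mz=tol_mz, tol_rt=tol_rt)

    qc_intra_cols = sorted(set(qc_i.sample_id) & set(aligned.values.columns))
    qc_inter_cols = sorted(set(qc_d.sample_id) & set(aligned.values.columns))
    cohort_cols = [c for c in aligned.values.columns if c not in qc_ids]

    def cv_over(cols: List[str]) -> pd.Series:
        return aligned.values[cols].apply(lambda r: compute_cv(r.to_numpy()), axis=1)

    cv_intra = cv_over(qc_intra_cols)
    cv_inter = cv_over(qc_inter_cols)
    cv_all = cv_over(qc_intra_cols + qc_inter_cols)

    if noise_model is None:
        floor = float(np.percentile(combined["area"].to_numpy(), 5))
        noise_model = NoiseFloorModel.constant(max(floor, np.finfo(float).tiny))
        logger.info("no noise model supplied; constant floor %.3g", floor)
    snr = estimate_snr(aligned, noise_model, sample_ids=cohort_cols)
    art = flag_artifacts(aligned, tol_mz=tol_mz)
    flags = build_flags(aligned, cv_all, snr, art, cv_max=cv_max, snr_min=snr_min)
    selected, report = select_egps(aligned, flags, cv_max=cv_max, snr_min=snr_min)
    qc_vals = selected.values[qc_intra_cols + qc_inter_cols]
    normalized, _ = normalize_to_qc(selected, qc_vals)
    egp = normalized.drop_samples(sorted(qc_ids))
    return PipelineResult(
        egp_matrix=egp, flags=flags, report=report,
        cv_intra=cv_intra, cv_inter=cv_inter, aligned=aligned,
    )


def matrix_to_frame(matrix: FeatureMatrix) -> pd.DataFrame:
    """Feature matrix as one flat frame (rt/mz columns + sample columns)."""
    out = matrix.features.set_index("feature_id")[["rt", "mz"]].copy()
    return out.join(matrix.values)
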