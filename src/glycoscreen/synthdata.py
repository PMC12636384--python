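"""Synthetic cohort, tumor-marker and LC-MS peak-table simulator.

Generates four-group cohorts (healthy plus three cancer types) with stage
structure, log-normal tumor-marker panels, and long-format peak tables with
planted glycopeptide species, satellite peaks (isotope / adduct / fragment),
noise peaks, below-detection dropout and coordinate jitter — all with a
ground-truth registry so every downstream stage can be tested against known
answers.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import constants
from .exceptions import ConfigurationError

GROUPS = ("healthy", "CRC", "GC", "EC")
CANCER_GROUPS = ("CRC", "GC", "EC")
STAGES = ("I", "II", "III", "IV")
MARKER_NAMES = (
    "CEA",
    "CA19-9",
    "CYFRA",
    "NCC-ST-439",
    "CA125",
    "PSA",
    "CA15-3",
    "AFP",
    "SCCA",
)

_GROUP_PREFIX = {"healthy": "HE", "CRC": "CRC", "GC": "GC", "EC": "EC"}

LN2 = math.log(2.0)

# per-marker baseline of log10(level): (mean, sd) in native units
DEFAULT_MARKER_BASELINES: Dict[str, Tuple[float, float]] = {
    "CEA": (0.20, 0.30),
    "CA19-9": (0.90, 0.40),
    "CYFRA": (0.10, 0.25),
    "NCC-ST-439": (0.30, 0.35),
    "CA125": (1.00, 0.30),
    "PSA": (-0.10, 0.45),
    "CA15-3": (1.00, 0.25),
    "AFP": (0.50, 0.30),
    "SCCA": (0.00, 0.30),
}


def shift_for_auc(auc: float, sd_healthy: float, sd_cancer: float) -> float:
    """Mean shift giving a target two-Gaussian AUC.

    For X ~ N(mu, s1^2) vs N(mu + d, s2^2), AUC = Phi(d / sqrt(s1^2 + s2^2)),
    so d = Phi^-1(auc) * sqrt(s1^2 + s2^2).
    """
    if not 0.0 < auc < 1.0:
        raise ConfigurationError(f"target AUC must be in (0, 1), got {auc}")
    return float(norm.ppf(auc) * math.hypot(sd_healthy, sd_cancer))


def default_marker_shifts() -> Dict[str, Dict[str, float]]:
    """log10 mean shifts per marker and cancer group.

    Calibrated so that the informative single markers reach their published
    single-marker AUCs; all other marker/group pairs are null.
    """
    targets = {
        "CEA": {"CRC": 0.805},
        "CYFRA": {"CRC": 0.834, "GC": 0.836},
        "CA19-9": {"CRC": 0.613},
        "SCCA": {"EC": 0.794},
    }
    shifts: Dict[str, Dict[str, float]] = {
        m: {g: 0.0 for g in CANCER_GROUPS} for m in MARKER_NAMES
    }
    for marker, per_group in targets.items():
        sd = DEFAULT_MARKER_BASELINES[marker][1]
        for group, auc in per_group.items():
            shifts[marker][group] = shift_for_auc(auc, sd, sd)
    return shifts


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort and peak simulator."""

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"healthy": 590, "CRC": 296, "GC": 180, "EC": 42}
    )
    # per cancer group, proportions over stages I..IV
    stage_weights: Dict[str, Sequence[float]] = field(
        default_factory=lambda: {
            "CRC": (76 / 289, 96 / 289, 79 / 289, 38 / 289),
            "GC": (73 / 180, 47 / 180, 39 / 180, 21 / 180),
            "EC": (5 / 42, 18 / 42, 15 / 42, 4 / 42),
        }
    )
    n_true_egps: int = 300
    frac_differential: float = 0.15
    effect_log2fc: float = 1.0
    # fraction of a group's differential species shifted DOWN (rest up)
    down_frac: Dict[str, float] = field(
        default_factory=lambda: {"CRC": 0.5, "GC": 0.8, "EC": 0.5}
    )
    # multiplies effect sizes by stage (I, II, III, IV)
    stage_factors: Tuple[float, float, float, float] = (0.5, 1.0, 1.1, 1.2)
    marker_shifts: Dict[str, Dict[str, float]] = field(
        default_factory=default_marker_shifts
    )
    marker_baselines: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_BASELINES)
    )
    # two designated strong glycopeptide species, informative in every cancer
    n_sentinels: int = 2
    sentinel_log2fc: float = 1.2
    lod: float = 0.0
    noise_sd: float = 0.3  # sd of natural-log multiplicative noise
    per_sample_scale_sd: float = 0.0  # global per-sample scale (natural-log sd)
    jitter_rt_sd: float = 0.05  # min
    jitter_mz_sd: float = 0.01  # Da
    satellite_rates: Dict[str, float] = field(
        default_factory=lambda: {"isotope": 0.0, "adduct": 0.0, "fragment": 0.0}
    )
    n_noise_peaks: int = 0  # random noise peaks per sample
    noise_floor: float = 50.0  # typical noise-peak area
    base_area: float = 2000.0  # typical parent-peak area
    n_qc_replicates: Tuple[int, int] = (6, 6)  # intra-day, inter-day
    qc_cv_intra_pct: float = 8.0
    qc_cv_inter_pct: float = 10.0
    frac_high_cv: float = 0.0  # species planted with irreproducible QC areas
    rt_range: Tuple[float, float] = (1.0, 14.0)
    mz_range: Tuple[float, float] = (800.0, 2400.0)
    seed: int = 0

    def validate(self) -> None:
        for g in GROUPS:
            if g not in self.n_per_group:
                raise ConfigurationError(f"n_per_group missing group {g!r}")
            if self.n_per_group[g] < 0:
                raise ConfigurationError("group counts must be >= 0")
        for g, w in self.stage_weights.items():
            if len(w) != 4 or any(x < 0 for x in w):
                raise ConfigurationError(f"stage_weights[{g!r}] must be 4 non-negatives")
            if abs(sum(w) - 1.0) > 1e-6:
                raise ConfigurationError(f"stage_weights[{g!r}] must sum to 1")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigurationError("frac_differential must be in [0, 1]")
        if self.n_true_egps < 0 or self.n_noise_peaks < 0 or self.n_sentinels < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.lod < 0:
            raise ConfigurationError("lod must be >= 0")
        # jitter must stay well inside the alignment tolerances (0.06 Da, 0.3 min)
        if self.jitter_rt_sd >= 0.15 or self.jitter_mz_sd >= 0.03:
            raise ConfigurationError(
                "jitter SDs must be below half the alignment tolerances "
                "(0.15 min, 0.03 Da)"
            )
        for role, rate in self.satellite_rates.items():
            if role not in ("isotope", "adduct", "fragment"):
                raise ConfigurationError(f"unknown satellite role {role!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("satellite rates must be in [0, 1]")


@dataclass
class Subject:
    id: str
    group: str
    stage: str  # "none" for healthy
    markers: Dict[str, float]


@dataclass
class GroundTruth:
    """Registry of everything the simulator planted."""

    species: pd.DataFrame  # species_id, rt, mz, log_base_area, flags
    effects: pd.DataFrame  # species_id, group, log2fc (signed)
    satellites: pd.DataFrame  # species_id, role, mz_offset, rel_area
    peak_roles: Dict[str, str] = field(default_factory=dict)

    @property
    def registry(self) -> pd.DataFrame:
        """(rt, mz, species_id) for every planted parent species."""
        return self.species[["species_id", "rt", "mz"]].copy()

    @property
    def sentinel_ids(self) -> List[int]:
        return self.species.loc[self.species.is_sentinel, "species_id"].tolist()

    @property
    def anchor_id(self) -> int:
        return int(self.species.loc[self.species.is_anchor, "species_id"].iloc[0])

    def differential_ids(self, group: str) -> Dict[int, float]:
        sel = self.effects[self.effects.group == group]
        return dict(zip(sel.species_id.astype(int), sel.log2fc))

    def effect_lookup(self, group: str) -> np.ndarray:
        """Signed log2 fold-change per species (0 where null) for a group."""
        out = np.zeros(len(self.species))
        sel = self.effects[self.effects.group == group]
        out[sel.species_id.to_numpy(int)] = sel.log2fc.to_numpy()
        return out


@dataclass
class PeakTables:
    """Long-format peak tables for cohort samples and QC injections."""

    samples: pd.DataFrame  # sample_id, rt_min, mz, area, peak_id
    qc_intra: pd.DataFrame
    qc_inter: pd.DataFrame


def _stage_factor(stage: str, config: CohortConfig) -> float:
    if stage == "none":
        return 0.0
    return config.stage_factors[STAGES.index(stage)]


def generate_marker_panel(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> Dict[str, float]:
    """Draw the nine-marker panel for one subject (log-normal per marker)."""
    values = {}
    for m in MARKER_NAMES:
        mu, sd = config.marker_baselines[m]
        shift = 0.0 if group == "healthy" else config.marker_shifts[m].get(group, 0.0)
        values[m] = float(10.0 ** (mu + shift + sd * rng.standard_normal()))
    return values


def _plant_species(config: CohortConfig, rng: np.random.Generator) -> GroundTruth:
    n = config.n_true_egps
    rt = rng.uniform(*config.rt_range, n)
    mz = rng.uniform(*config.mz_range, n)
    log_base = np.log(config.base_area) + 0.5 * rng.standard_normal(n)
    species = pd.DataFrame(
        {
            "species_id": np.arange(n),
            "rt": rt,
            "mz": mz,
            "log_base_area": log_base,
            "is_anchor": False,
            "is_sentinel": False,
            "is_differential": False,
            "is_high_cv": False,
        }
    )

    effects: List[dict] = []
    if n > 0:
        species.loc[0, "is_anchor"] = True  # stable normalizer, never differential
        sentinel_ids = list(range(1, min(1 + config.n_sentinels, n)))
        species.loc[sentinel_ids, "is_sentinel"] = True
        species.loc[sentinel_ids, "is_differential"] = True
        for sid in sentinel_ids:
            for g in CANCER_GROUPS:
                effects.append(
                    {"species_id": sid, "group": g, "log2fc": config.sentinel_log2fc}
                )

        eligible = np.arange(1 + len(sentinel_ids), n)
        n_diff = int(round(config.frac_differential * n))
        n_diff = min(max(n_diff - len(sentinel_ids), 0), len(eligible))
        diff_ids = rng.choice(eligible, size=n_diff, replace=False) if n_diff else []
        species.loc[list(diff_ids), "is_differential"] = True
        for sid in diff_ids:
            for g in CANCER_GROUPS:
                down = rng.random() < config.down_frac.get(g, 0.5)
                sign = -1.0 if down else 1.0
                effects.append(
                    {"species_id": int(sid), "group": g, "log2fc": sign * config.effect_log2fc}
                )

        if config.frac_high_cv > 0:
            n_hc = int(round(config.frac_high_cv * n))
            null_ids = species.loc[~species.is_differential & ~species.is_anchor,
                                   "species_id"].to_numpy()
            hc = rng.choice(null_ids, size=min(n_hc, len(null_ids)), replace=False)
            species.loc[hc, "is_high_cv"] = True

    effects_df = pd.DataFrame(effects, columns=["species_id", "group", "log2fc"])

    sats: List[dict] = []
    for sid in range(n):
        if rng.random() < config.satellite_rates.get("isotope", 0.0):
            z = int(rng.choice([1, 2]))
            sats.append(
                {
                    "species_id": sid,
                    "role": "isotope",
                    "mz_offset": constants.ISOTOPE_SPACING / z,
                    "rel_area": 0.4,
                }
            )
        if rng.random() < config.satellite_rates.get("adduct", 0.0):
            off = float(rng.choice([constants.ADDUCT_NA_MINUS_H, constants.ADDUCT_K_MINUS_H]))
            sats.append(
                {"species_id": sid, "role": "adduct", "mz_offset": off, "rel_area": 0.3}
            )
        if rng.random() < config.satellite_rates.get("fragment", 0.0):
            sats.append(
                {
                    "species_id": sid,
                    "role": "fragment",
                    "mz_offset": -constants.NEUAC,
                    "rel_area": 0.5,
                }
            )
    sat_df = pd.DataFrame(sats, columns=["species_id", "role", "mz_offset", "rel_area"])
    return GroundTruth(species=species, effects=effects_df, satellites=sat_df)


def generate_cohort(
    config: CohortConfig,
) -> Tuple[List[Subject], GroundTruth]:
    """Generate subjects (with markers and stages) plus the planted truth.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects: List[Subject] = []
    for group in GROUPS:
        n = config.n_per_group[group]
        for i in range(n):
            sid = f"{_GROUP_PREFIX[group]}{i + 1:04d}"
            if group == "healthy":
                stage = "none"
            else:
                w = np.asarray(config.stage_weights[group], float)
                stage = str(rng.choice(STAGES, p=w / w.sum()))
            markers = generate_marker_panel(group, config, rng)
            subjects.append(Subject(id=sid, group=group, stage=stage, markers=markers))
    truth = _plant_species(config, rng)
    return subjects, truth


def subjects_frame(subjects: Sequence[Subject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"id": s.id, "group": s.group, "stage": s.stage}
        row.update(s.markers)
        rows.append(row)
    cols = ["id", "group", "stage", *MARKER_NAMES]
    return pd.DataFrame(rows, columns=cols)


def _sample_log_levels(
    subject: Subject, truth: GroundTruth, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Natural-log areas of every planted species for one sample draw."""
    base = truth.species.log_base_area.to_numpy()
    eff = truth.effect_lookup(subject.group) * _stage_factor(subject.stage, config)
    noise = config.noise_sd * rng.standard_normal(len(base))
    return base + eff * LN2 + noise


def generate_peak_tables(
    subjects: Sequence[Subject],
    truth: GroundTruth,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> PeakTables:
    """Emit long-format peak tables (parents, satellites, noise) plus QC tables.

    Fills ``truth.peak_roles`` with the role of every emitted peak id.
    Areas below ``config.lod`` are dropped (downstream imputes zeros).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_sp = len(truth.species)
    sp_rt = truth.species.rt.to_numpy()
    sp_mz = truth.species.mz.to_numpy()
    sat = truth.satellites
    roles = truth.peak_roles

    rows: List[tuple] = []

    def emit_sample(sample_id: str, log_levels: np.ndarray, scale: float,
                    with_noise_peaks: bool) -> None:
        areas = np.exp(log_levels) * scale
        rt_j = sp_rt + config.jitter_rt_sd * rng.standard_normal(n_sp)
        mz_j = sp_mz + config.jitter_mz_sd * rng.standard_normal(n_sp)
        keep = areas >= config.lod
        for sid in np.flatnonzero(keep):
            pid = f"{sample_id}:p{sid}"
            rows.append((sample_id, rt_j[sid], mz_j[sid], areas[sid], pid))
            roles[pid] = "parent"
        for k, srow in enumerate(sat.itertuples()):
            sid = int(srow.species_id)
            a = srow.rel_area * areas[sid]
            if a < config.lod:
                continue
            rt_s = rt_j[sid] + 0.01 * rng.standard_normal()
            mz_s = sp_mz[sid] + srow.mz_offset + config.jitter_mz_sd * rng.standard_normal()
            pid = f"{sample_id}:{srow.role[0]}{k}"
            rows.append((sample_id, rt_s, mz_s, a, pid))
            roles[pid] = srow.role
        if with_noise_peaks and config.n_noise_peaks > 0:
            m = config.n_noise_peaks
            rt_n = rng.uniform(*config.rt_range, m)
            mz_n = rng.uniform(*config.mz_range, m)
            a_n = np.exp(np.log(config.noise_floor) + 0.5 * rng.standard_normal(m))
            for k in np.flatnonzero(a_n >= config.lod):
                pid = f"{sample_id}:n{k}"
                rows.append((sample_id, rt_n[k], mz_n[k], a_n[k], pid))
                roles[pid] = "noise"

    for subject in subjects:
        scale = (
            math.exp(config.per_sample_scale_sd * rng.standard_normal())
            if config.per_sample_scale_sd > 0
            else 1.0
        )
        emit_sample(subject.id, _sample_log_levels(subject, truth, config, rng),
                    scale, with_noise_peaks=True)
    samples_df = pd.DataFrame(rows, columns=["sample_id", "rt_min", "mz", "area", "peak_id"])

    def qc_tables(n_reps: int, cv_pct: float, prefix: str) -> pd.DataFrame:
        nonlocal rows
        rows = []
        sigma = cv_pct / 100.0
        sigma_vec = np.where(truth.species.is_high_cv.to_numpy(), 1.0, sigma)
        base = truth.species.log_base_area.to_numpy()
        for r in range(n_reps):
            log_levels = base + sigma_vec * rng.standard_normal(n_sp)
            emit_sample(f"{prefix}{r + 1}", log_levels, 1.0, with_noise_peaks=False)
        return pd.DataFrame(rows, columns=["sample_id", "rt_min", "mz", "area", "peak_id"])

    qc_intra = qc_tables(config.n_qc_replicates[0], config.qc_cv_intra_pct, "QCI")
    qc_inter = qc_tables(config.n_qc_replicates[1], config.qc_cv_inter_pct, "QCD")
    return PeakTables(samples=samples_df, qc_intra=qc_intra, qc_inter=qc_inter)


def generate_egp_matrix(
    subjects: Sequence[Subject],
    truth: GroundTruth,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Directly generate the relative-level matrix (samples x species).

    Shortcut past peak emission and alignment: levels are areas divided by
    the per-species QC level, with below-detection values set to zero.
    Useful for testing the statistics and model stages in isolation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    qc_level = np.exp(truth.species.log_base_area.to_numpy())
    data = np.empty((len(subjects), len(truth.species)))
    for i, subject in enumerate(subjects):
        scale = (
            math.exp(config.per_sample_scale_sd * rng.standard_normal())
            if config.per_sample_scale_sd > 0
            else 1.0
        )
        areas = np.exp(_sample_log_levels(subject, truth, config, rng)) * scale
        areas[areas < config.lod] = 0.0
        data[i] = areas / qc_level
    cols = [f"egp_{i:04d}" for i in range(len(truth.species))]
    return pd.DataFrame(data, index=[s.id for s in subjects], columns=cols)


def species_column(species_id: int) -> str:
    """Column name used for a planted species in the direct matrix."""
    return f"egp_{species_id:04d}"


@dataclass
class SimulatedCohort:
    config: CohortConfig
    subjects: List[Subject]
    truth: GroundTruth
    tables: PeakTables


def simulate(config: CohortConfig) -> SimulatedCohort:
    """Run the full simulator: cohort, truth, peak and QC tables."""
    subjects, truth = generate_cohort(config)
    rng = np.random.default_rng(config.seed + 1)
    tables = generate_peak_tables(subjects, truth, config, rng)
    return SimulatedCohort(config=config, subjects=subjects, truth=truth, tables=tables)


def write_outputs(sim: SimulatedCohort, outdir: str | Path) -> None:
    """Write subject CSV, peak CSVs and ground-truth JSON to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    subjects_frame(sim.subjects).to_csv(out / "subjects.csv", index=False)
    sim.tables.samples.to_csv(out / "peaks_samples.csv", index=False)
    sim.tables.qc_intra.to_csv(out / "peaks_qc_intra.csv", index=False)
    sim.tables.qc_inter.to_csv(out / "peaks_qc_inter.csv", index=False)
    truth = {
        "species": sim.truth.species.to_dict(orient="records"),
        "effects": sim.truth.effects.to_dict(orient="records"),
        "satellites": sim.truth.satellites.to_dict(orient="records"),
        "peak_roles": sim.truth.peak_roles,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def config_from_dict(d: dict) -> CohortConfig:
    """Build a config from a (YAML/JSON-loaded) mapping, validating keys."""
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = CohortConfig(**d)
    cfg.validate()
    return cfg
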