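"""Glycopeptide candidate enumeration and neutral-mass assignment.

Digests protein sequences in silico (trypsin + Lys-C behaviour: cleavage
C-terminal to K/R except before P), keeps peptides carrying an
N-glycosylation sequon (N-X-S/T, X != P), enumerates glycan compositions on
a configurable grid, and assigns observed negative-mode features whose
deconvoluted neutral mass matches a candidate within tolerance.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import (
    CARBAMIDOMETHYL,
    FUC,
    HEX,
    HEXNAC,
    NEUAC,
    PROTON,
    RESIDUE_MASSES,
    WATER,
)
from .exceptions import ConfigurationError, InputDataError

DEFAULT_GLYCAN_RANGES: Dict[str, Tuple[int, int]] = {
    # bi- to tetra-antennary sialylated N-glycans, incl. Hex5HexNAc4NeuAc2
    "hex": (3, 9),
    "hexnac": (2, 6),
    "neuac": (0, 4),
    "fuc": (0, 2),
}
DEFAULT_TOL = 0.03
DEFAULT_CHARGES = (1, 2, 3, 4)

GLYCAN_UNIT_MASSES = {"hex": HEX, "hexnac": HEXNAC, "neuac": NEUAC, "fuc": FUC}


@dataclass(frozen=True)
class SequonPeptide:
    protein_id: str
    peptide: str
    start: int  # 1-based position of the peptide in the protein
    site: int  # 1-based asparagine position in the protein
    missed_cleavages: int

    @property
    def mass(self) -> float:
        return peptide_mass(self.peptide)


@dataclass(frozen=True)
class GlycoPeptideCandidate:
    protein_id: str
    peptide: str
    site: int
    glycan: Tuple[int, int, int, int]  # (hex, hexnac, neuac, fuc)
    neutral_mass: float

    @property
    def composition_label(self) -> str:
        h, n, s, f = self.glycan
        return f"Hex{h}HexNAc{n}NeuAc{s}Fuc{f}"


def peptide_mass(peptide: str) -> float:
    """Monoisotopic peptide mass with fixed carbamidomethyl on Cys."""
    try:
        m = sum(RESIDUE_MASSES[aa] for aa in peptide)
    except KeyError as e:
        raise InputDataError(f"illegal residue {e.args[0]!r}") from None
    return m + WATER + peptide.count("C") * CARBAMIDOMETHYL


def glycan_mass(glycan: Sequence[int]) -> float:
    h, n, s, f = glycan
    return h * HEX + n * HEXNAC + s * NEUAC + f * FUC


def _cleavage_sites(sequence: str) -> List[int]:
    """Indices after which cleavage occurs (K/R not followed by P)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    return sites


def _sequon_positions(peptide: str) -> List[int]:
    """0-based positions within the peptide of N in an N-X-S/T (X != P) motif."""
    out = []
    for i in range(len(peptide) - 2):
        if peptide[i] == "N" and peptide[i + 1] != "P" and peptide[i + 2] in "ST":
            out.append(i)
    return out


def cleave(sequence: str, max_missed: int = 0) -> List[Tuple[str, int]]:
    """All proteolytic peptides (peptide, 1-based start), sequon or not."""
    if max_missed < 0:
        raise ConfigurationError("max_missed must be >= 0")
    bounds = [0, *_cleavage_sites(sequence), len(sequence)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            out.append((sequence[bounds[i]:bounds[j]], bounds[i] + 1))
    return out


def digest(
    sequence: str, protein_id: str = "protein", max_missed: int = 2
) -> List[SequonPeptide]:
    """Proteolytic peptides carrying at least one N-glycosylation sequon.

    Cleaves C-terminal to K/R (not before P) with up to ``max_missed``
    missed cleavages; returns one entry per (peptide, sequon site).
    """
    sequence = sequence.strip().upper()
    bad = set(sequence) - set(RESIDUE_MASSES)
    if bad:
        raise InputDataError(f"illegal residues in sequence: {sorted(bad)}")
    if max_missed < 0:
        raise ConfigurationError("max_missed must be >= 0")
    bounds = [0, *_cleavage_sites(sequence), len(sequence)]
    out: List[SequonPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            pep = sequence[start:end]
            for pos in _sequon_positions(pep):
                out.append(
                    SequonPeptide(
                        protein_id=protein_id,
                        peptide=pep,
                        start=start + 1,
                        site=start + pos + 1,
                        missed_cleavages=j - i - 1,
                    )
                )
    return out


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Minimal FASTA reader returning {record_id: sequence}."""
    records: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise InputDataError(f"no FASTA records in {path}")
    return records


def enumerate_candidates(
    peptides: Iterable[SequonPeptide],
    glycan_ranges: Optional[Dict[str, Tuple[int, int]]] = None,
) -> List[GlycoPeptideCandidate]:
    """Cartesian product of sequon peptides and glycan compositions."""
    ranges = dict(DEFAULT_GLYCAN_RANGES if glycan_ranges is None else glycan_ranges)
    for key in ("hex", "hexnac", "neuac", "fuc"):
        lo, hi = ranges.get(key, (0, -1))
        if hi < lo:
            return []
    grids = [
        range(ranges[k][0], ranges[k][1] + 1) for k in ("hex", "hexnac", "neuac", "fuc")
    ]
    out: List[GlycoPeptideCandidate] = []
    for p in peptides:
        pmass = p.mass
        for comp in itertools.product(*grids):
            out.append(
                GlycoPeptideCandidate(
                    protein_id=p.protein_id,
                    peptide=p.peptide,
                    site=p.site,
                    glycan=comp,
                    neutral_mass=pmass + glycan_mass(comp),
                )
            )
    return out


def observed_neutral_mass(mz: float, charge: int) -> float:
    """Neutral mass of a negative-mode ion [M - zH]^z-."""
    return charge * mz + charge * PROTON


@dataclass(frozen=True)
class Assignment:
    feature_id: int
    candidate: GlycoPeptideCandidate
    charge: int
    delta_mass: float  # observed neutral - theoretical


def match_features(
    features: pd.DataFrame,
    candidates: Sequence[GlycoPeptideCandidate],
    charges: Sequence[int] = DEFAULT_CHARGES,
    tol: float = DEFAULT_TOL,
) -> List[Assignment]:
    """All (feature, candidate, charge) with |observed - theoretical| <= tol.

    ``features`` needs feature_id and mz columns. Matches are returned
    sorted by |delta|; ambiguous assignments are all reported.
    """
    if tol <= 0:
        raise ConfigurationError("tolerance must be > 0")
    if any(z < 1 for z in charges):
        raise ConfigurationError("charges must be positive")
    masses = np.array([c.neutral_mass for c in candidates])
    order = np.argsort(masses)
    sorted_masses = masses[order]
    out: List[Assignment] = []
    for row in features.itertuples():
        for z in charges:
            obs = observed_neutral_mass(float(row.mz), z)
            lo = np.searchsorted(sorted_masses, obs - tol, side="left")
            hi = np.searchsorted(sorted_masses, obs + tol, side="right")
            for k in order[lo:hi]:
                delta = obs - masses[k]
                if abs(delta) <= tol:
                    out.append(
                        Assignment(
                            feature_id=int(row.feature_id),
                            candidate=candidates[int(k)],
                            charge=z,
                            delta_mass=float(delta),
                        )
                    )
    out.sort(key=lambda a: (abs(a.delta_mass), a.feature_id, a.charge))
    return out


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        c = a.candidate
        rows.append(
            {
                "feature_id": a.feature_id,
                "protein_id": c.protein_id,
                "peptide": c.peptide,
                "site": c.site,
                "composition": c.composition_label,
                "charge": a.charge,
                "delta_mDa": a.delta_mass * 1000.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "protein_id", "peptide", "site", "composition",
                 "charge", "delta_mDa"],
    )


def normalize_to_transferrin(
    values: pd.DataFrame, transferrin_feature_id
) -> Tuple[pd.DataFrame, List[str]]:
    """Divide every feature level by the sample's anchor-protein level.

    ``values`` is features x samples. Samples whose anchor level is zero are
    excluded from the result and returned for reporting.
    """
    if transferrin_feature_id not in values.index:
        raise InputDataError(f"anchor feature {transferrin_feature_id!r} not in matrix")
    anchor = values.loc[transferrin_feature_id]
    bad = anchor.index[anchor <= 0].tolist()
    kept = [c for c in values.columns if c not in set(bad)]
    normalized = values[kept].div(anchor[kept], axis=1)
    return normalized, bad
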