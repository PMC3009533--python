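"""Fixed-length sequence featurization.

A sequence maps to 104 numbers laid out as::

    [charge, hydro_sum, helix_sum, sheet_sum, composition(20), local_env(80)]

``composition`` counts the 20 standard amino acids (alphabetical one-letter
order ``ACDEFGHIKLMNPQRSTVWY``). ``local_env`` crosses residue identity with
one of four secondary-structure environment regimes derived from windowed
helix/sheet propensity means, giving 4 x 20 slots. Ambiguity codes
(B, Z, X, U, O) are excluded from every count and from window means.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datasets import STANDARD_AA, SequenceRecord

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: side-chain charge at neutral pH (His treated as neutral)
DEFAULT_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CHOU_FASMAN_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

CHOU_FASMAN_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

#: environment regime labels in slot order (helix regime x sheet regime)
ENV_CATEGORIES = ("loH_loS", "loH_hiS", "hiH_loS", "hiH_hiS")


@dataclass(frozen=True)
class PropensityScale:
    """A named map from each of the 20 standard amino acids to a real value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise ValueError(f"scale {self.name!r} must cover exactly the 20 standard amino acids")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[a] for a in STANDARD_AA], dtype=float)


@dataclass(frozen=True)
class FeatureConfig:
    """Scales, window and thresholds for the feature encoder.

    The environment of a residue is the mean helix/sheet propensity over a
    centered window of ``env_window`` residues (truncated at the ends,
    ambiguity codes ignored), split into high/low at the thresholds.
    """

    charge_map: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CHARGE))
    hydrophobicity: PropensityScale = field(
        default_factory=lambda: PropensityScale("kyte-doolittle", KYTE_DOOLITTLE)
    )
    helix: PropensityScale = field(
        default_factory=lambda: PropensityScale("chou-fasman-helix", CHOU_FASMAN_HELIX)
    )
    sheet: PropensityScale = field(
        default_factory=lambda: PropensityScale("chou-fasman-sheet", CHOU_FASMAN_SHEET)
    )
    env_window: int = 7
    env_threshold_helix: float = 1.0
    env_threshold_sheet: float = 1.0
    normalize_composition: bool = True

    def __post_init__(self) -> None:
        if self.env_window < 1 or self.env_window % 2 == 0:
            raise ValueError(f"env_window must be odd and >= 1, got {self.env_window}")


@dataclass(frozen=True)
class FeatureVector:
    charge: float
    hydro_sum: float
    helix_sum: float
    sheet_sum: float
    composition: np.ndarray  # (20,)
    local_env: np.ndarray  # (80,)
    effective_length: int

    def to_array(self) -> np.ndarray:
        """Concatenate into the documented 104-feature layout."""
        return np.concatenate(
            [
                [self.charge, self.hydro_sum, self.helix_sum, self.sheet_sum],
                self.composition,
                self.local_env,
            ]
        )


def feature_names() -> list[str]:
    names = ["charge", "hydro_sum", "helix_sum", "sheet_sum"]
    names += [f"comp_{a}" for a in STANDARD_AA]
    names += [f"env_{a}_{c}" for a in STANDARD_AA for c in ENV_CATEGORIES]
    return names


def _standard_indices(seq: str) -> np.ndarray:
    """Per-position index into STANDARD_AA, -1 for ambiguity codes."""
    return np.array([AA_INDEX.get(ch, -1) for ch in seq], dtype=int)


def net_charge(seq: str, charge_map: Mapping[str, float] | None = None) -> float:
    """Sum of per-residue charge contributions; unmapped residues contribute 0."""
    cmap = DEFAULT_CHARGE if charge_map is None else charge_map
    return float(sum(cmap.get(ch, 0.0) for ch in seq))

def scale_sum(seq: str, scale: PropensityScale) -> float:
    """Sum of scale values over standard residues; ambiguity codes skipped."""
    return float(sum(scale.values[ch] for ch in seq if ch in scale.values))


def aa_composition(seq: str, normalize: bool = True) -> np.ndarray:
    """Per-amino-acid counts over standard residues, optionally as fractions.

    An all-ambiguous (or empty) sequence yields the all-zeros vector even
    when ``normalize`` is set.
    """
    idx = _standard_indices(seq)
    counts = np.bincount(idx[idx >= 0], minlength=20).astype(float)
    if normalize:
        n = counts.sum()
        if n > 0:
            counts /= n
    return counts


def _window_means(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Mean of ``values`` over valid positions in a centered window.

    The window is truncated at the sequence ends; positions flagged invalid
    contribute neither to the numerator nor the denominator.
    """
    n = len(values)
    half = window // 2
    pos = np.arange(n)
    lo = np.maximum(0, pos - half)
    hi = np.minimum(n, pos + half + 1)
    vsum = np.concatenate([[0.0], np.cumsum(np.where(valid, values, 0.0))])
    csum = np.concatenate([[0.0], np.cumsum(valid.astype(float))])
    sums = vsum[hi] - vsum[lo]
    counts = csum[hi] - csum[lo]
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def local_env_composition(seq: str, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Count residues by (identity x helix/sheet environment regime): 80 slots.

    Slot layout: index ``4*a + c`` where ``a`` indexes STANDARD_AA and
    ``c = 2*[helix_mean >= threshold] + [sheet_mean >= threshold]``.
    """
    if cfg is None:
        cfg = FeatureConfig()
    idx = _standard_indices(seq)
    valid = idx >= 0
    counts = np.zeros(80, dtype=float)
    if valid.any():
        helix_vals = np.where(valid, cfg.helix.as_array()[np.where(valid, idx, 0)], 0.0)
        sheet_vals = np.where(valid, cfg.sheet.as_array()[np.where(valid, idx, 0)], 0.0)
        h_mean = _window_means(helix_vals, valid, cfg.env_window)
        s_mean = _window_means(sheet_vals, valid, cfg.env_window)
        cat = 2 * (h_mean >= cfg.env_threshold_helix) + (s_mean >= cfg.env_threshold_sheet)
        slots = 4 * idx[valid] + cat[valid]
        counts = np.bincount(slots, minlength=80).astype(float)
    if cfg.normalize_composition:
        n = valid.sum()
        if n > 0:
            counts /= n
    return counts


def featurize(seq: str, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Assemble the full feature vector for one sequence."""
    if cfg is None:
        cfg = FeatureConfig()
    eff_len = int(sum(1 for ch in seq if ch in AA_INDEX))
    return FeatureVector(
        charge=net_charge(seq, cfg.charge_map),
        hydro_sum=scale_sum(seq, cfg.hydrophobicity),
        helix_sum=scale_sum(seq, cfg.helix),
        sheet_sum=scale_sum(seq, cfg.sheet),
        composition=aa_composition(seq, cfg.normalize_composition),
        local_env=local_env_composition(seq, cfg),
        effective_length=eff_len,
    )


def featurize_records(
    records: Sequence[SequenceRecord], cfg: FeatureConfig | None = None
) -> tuple[list[str], np.ndarray]:
    """Featurize many records into (ids, matrix of shape (n, 104))."""
    if cfg is None:
        cfg = FeatureConfig()
    ids = [r.id for r in records]
    X = np.vstack([featurize(r.seq, cfg).to_array() for r in records]) if records else np.empty((0, 104))
    return ids, X


def write_feature_table(
    records: Iterable[SequenceRecord], path: str | Path, cfg: FeatureConfig | None = None
) -> None:
    """Write a TSV feature matrix with a header row (id + 104 named columns)."""
    if cfg is None:
        cfg = FeatureConfig()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id"] + feature_names())
        for rec in records:
            vec = featurize(rec.seq, cfg).to_array()
            writer.writerow([rec.id] + [format(v, ".10g") for v in vec])
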