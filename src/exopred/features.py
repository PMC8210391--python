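"""Fixed-length sequence encodings.

Five schemes are supported, all computable from the sequence alone:

* ``AA`` — amino-acid composition: 20 residue frequencies.
* ``DP`` — dipeptide composition: frequencies of the 400 ordered residue
  pairs over the N−1 overlapping windows of the sequence.
* ``PCP`` — 11 physico-chemical properties, each the sequence mean of a
  min–max-normalized per-residue scale:  P_i = (1/N) Σ_n p_i(a_n).
* ``PCP_AA`` (33) and ``PCP_AA_DP`` (433) — concatenations of the blocks
  above, PCP first.

Residues are ordered alphabetically (ACDEFGHIKLMNPQRSTVWY) and dipeptides
row-major over that order; the order is part of the feature contract.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteinRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
DIPEPTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)

SCHEMES = ("PCP", "AA", "PCP_AA", "DP", "PCP_AA_DP")
# Combined schemes are exact concatenations of their blocks: 11 + 20 = 31 and
# 11 + 20 + 400 = 431. (Published descriptions of this feature family
# sometimes quote 33/433 for the combined vectors, which is not consistent
# with 11 named properties; the concatenation arithmetic is authoritative
# here.)
SCHEME_LENGTHS = {"PCP": 11, "AA": 20, "PCP_AA": 31, "DP": 400, "PCP_AA_DP": 431}


class EncodingError(ValueError):
    """Sequence cannot be encoded under the requested scheme."""


def _check_sequence(sequence: str, min_length: int = 1) -> None:
    if len(sequence) < min_length:
        raise EncodingError(
            f"sequence of length {len(sequence)} (minimum {min_length})"
        )
    bad = set(sequence) - set(ALPHABET)
    if bad:
        raise EncodingError(f"non-canonical residue(s) {sorted(bad)}")


@dataclasses.dataclass(frozen=True)
class PropertyScale:
    """One named per-residue numeric scale with min–max normalization."""

    name: str
    raw_values: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        if set(self.raw_values) != set(ALPHABET):
            raise ValueError(
                f"scale {self.name!r}: must define exactly the 20 canonical residues"
            )

    @property
    def normalized_values(self) -> dict[str, float]:
        vals = np.array([self.raw_values[a] for a in ALPHABET], dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            norm = (vals - lo) / (hi - lo)
        else:  # constant scale: keep the value if already in [0,1], else collapse
            norm = np.clip(vals, 0.0, 1.0)
        return dict(zip(ALPHABET, norm))

    def normalized_array(self) -> np.ndarray:
        nv = self.normalized_values
        return np.array([nv[a] for a in ALPHABET], dtype=float)


@dataclasses.dataclass(frozen=True)
class ScaleSet:
    """Ordered set of exactly 11 property scales; order defines feature order."""

    scales: tuple[PropertyScale, ...]
    version: str = "bundled-1"

    def __post_init__(self) -> None:
        if len(self.scales) != 11:
            raise ValueError(f"a ScaleSet holds exactly 11 scales, got {len(self.scales)}")
        names = [s.name for s in self.scales]
        if len(set(names)) != len(names):
            raise ValueError("scale names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.scales)

    def matrix(self) -> np.ndarray:
        """11 × 20 array of normalized values, residue order = ALPHABET."""
        return np.vstack([s.normalized_array() for s in self.scales])


def read_scale_table(path: str | Path, version: Optional[str] = None) -> ScaleSet:
    """Read a scale TSV (columns: scale, 20 residues, source)."""
    df = pd.read_csv(path, sep="\t")
    missing = [aa for aa in ALPHABET if aa not in df.columns]
    if missing:
        raise ValueError(f"scale table {path}: missing residue columns {missing}")
    scales = tuple(
        PropertyScale(
            name=str(row["scale"]),
            raw_values={aa: float(row[aa]) for aa in ALPHABET},
            source=str(row.get("source", "")),
        )
        for _, row in df.iterrows()
    )
    return ScaleSet(scales=scales, version=version or Path(path).stem)


_default_scale_set: Optional[ScaleSet] = None


def default_scale_set() -> ScaleSet:
    """The 11 bundled scales: flexibility, volume, mutability, net charge,
    side-chain interaction, polarity, designed helix/sheet propensities,
    amphiphilicity, modified Kyte–Doolittle hydrophobicity, aromaticity."""
    global _default_scale_set
    if _default_scale_set is None:
        ref = resources.files("exopred.data").joinpath("property_scales.tsv")
        with resources.as_file(ref) as path:
            _default_scale_set = read_scale_table(path, version="bundled-1")
    return _default_scale_set


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    scheme: str
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_LENGTHS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(self.values) != SCHEME_LENGTHS[self.scheme]:
            raise ValueError(
                f"scheme {self.scheme}: expected {SCHEME_LENGTHS[self.scheme]} "
                f"values, got {len(self.values)}"
            )
        if len(self.feature_names) != len(self.values):
            raise ValueError("feature_names/values length mismatch")


AA_FEATURE_NAMES = tuple(f"AA_{a}" for a in ALPHABET)
DP_FEATURE_NAMES = tuple(f"DP_{d}" for d in DIPEPTIDES)


def aa_composition(sequence: str) -> FeatureVector:
    """20 residue proportions; components sum to 1."""
    _check_sequence(sequence, 1)
    counts = np.zeros(20)
    for ch in sequence:
        counts[_INDEX[ch]] += 1
    return FeatureVector("AA", counts / len(sequence), AA_FEATURE_NAMES)


def dipeptide_composition(sequence: str) -> FeatureVector:
    """400 ordered-pair proportions over the N−1 overlapping windows."""
    _check_sequence(sequence, 2)
    counts = np.zeros(400)
    for i in range(len(sequence) - 1):
        counts[_INDEX[sequence[i]] * 20 + _INDEX[sequence[i + 1]]] += 1
    return FeatureVector("DP", counts / (len(sequence) - 1), DP_FEATURE_NAMES)


def pcp_features(sequence: str, scale_set: Optional[ScaleSet] = None) -> FeatureVector:
    """11 sequence means of normalized per-residue properties."""
    _check_sequence(sequence, 1)
    scale_set = scale_set or default_scale_set()
    idx = np.fromiter((_INDEX[ch] for ch in sequence), dtype=int, count=len(sequence))
    values = scale_set.matrix()[:, idx].mean(axis=1)
    names = tuple(f"PCP_{name}" for name in scale_set.names)
    return FeatureVector("PCP", values, names)


def encode(
    sequence: str, scheme: str, scale_set: Optional[ScaleSet] = None
) -> FeatureVector:
    """Encode one sequence under any of the five schemes.

    Combined schemes are exact concatenations of their standalone blocks,
    PCP block first, then AA, then DP.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    blocks: list[FeatureVector] = []
    if "PCP" in scheme:
        blocks.append(pcp_features(sequence, scale_set))
    if "AA" in scheme:
        blocks.append(aa_composition(sequence))
    if "DP" in scheme:
        blocks.append(dipeptide_composition(sequence))
    if len(blocks) == 1:
        return blocks[0]
    return FeatureVector(
        scheme,
        np.concatenate([b.values for b in blocks]),
        tuple(n for b in blocks for n in b.feature_names),
    )


def feature_names(scheme: str, scale_set: Optional[ScaleSet] = None) -> tuple[str, ...]:
    scale_set = scale_set or default_scale_set()
    names: tuple[str, ...] = ()
    if "PCP" in scheme:
        names += tuple(f"PCP_{n}" for n in scale_set.names)
    if "AA" in scheme:
        names += AA_FEATURE_NAMES
    if "DP" in scheme:
        names += DP_FEATURE_NAMES
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    return names


def encode_dataset(
    records: Sequence[ProteinRecord],
    scheme: str,
    scale_set: Optional[ScaleSet] = None,
    require_labels: bool = False,
) -> tuple[pd.DataFrame, Optional[np.ndarray]]:
    """Encode records into a feature matrix (rows follow record order).

    Returns ``(features, labels)``; labels is None when any record is
    unlabeled and ``require_labels`` is false.
    """
    scale_set = scale_set or default_scale_set()
    rows = []
    for rec in records:
        try:
            rows.append(encode(rec.sequence, scheme, scale_set).values)
        except EncodingError as exc:
            raise EncodingError(f"record {rec.id!r}: {exc}") from None
    matrix = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, SCHEME_LENGTHS[scheme])),
        index=[r.id for r in records],
        columns=list(feature_names(scheme, scale_set)),
    )
    labels_list = [r.label for r in records]
    if any(lab is None for lab in labels_list):
        if require_labels:
            missing = [r.id for r in records if r.label is None][:5]
            raise ValueError(f"unlabeled records (e.g. {missing}) in training mode")
        return matrix, None
    return matrix, np.array(labels_list, dtype=int)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
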