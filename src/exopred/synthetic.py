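"""Seeded two-class synthetic protein datasets.

Real exosome-cargo training data must be downloaded; this generator stands
in for it so every stage of the package — encoding, curation, CV, gating —
is exercisable offline. Two signal constructions are offered:

* ``aa_bias`` — each class draws residues i.i.d. from its own Dirichlet-
  perturbed distribution; the distance between the class distributions grows
  with ``bias_strength`` (0 = identical, 1 = near-disjoint preferred
  alphabets), so amino-acid composition carries the signal.
* ``dipeptide_bias`` — both classes share the uniform marginal residue
  distribution but differ in first-order transition probabilities (Markov
  chains with matched stationary distributions), so dipeptide composition
  carries signal that amino-acid composition cannot see.

Sequences are 50–400 residues by default, roughly protein-like and long
enough for dipeptide vectors to be well populated.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .features import ALPHABET
from .io_formats import AnnotationEntry, AnnotationTable, ProteinRecord

_N_RES = 20


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (50, 400)
    bias_strength: float = 0.7
    signal_mode: Literal["aa_bias", "dipeptide_bias"] = "aa_bias"
    annotation_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one record per class")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length_range must satisfy 30 <= lo <= hi")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must be in [0, 1]")
        if not 0.0 <= self.annotation_noise <= 1.0:
            raise ValueError("annotation_noise must be in [0, 1]")
        if self.signal_mode not in ("aa_bias", "dipeptide_bias"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")


def _aa_bias_distributions(
    bias: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class residue distributions at the requested separation.

    A shared Dirichlet base is blended with class-preferred halves of the
    alphabet; at bias 1 the classes use near-disjoint alphabets, at bias 0
    they are identical.
    """
    base = rng.dirichlet(np.full(_N_RES, 5.0))
    pref_pos = np.zeros(_N_RES)
    pref_pos[: _N_RES // 2] = 1.0
    pref_pos /= pref_pos.sum()
    pref_neg = np.zeros(_N_RES)
    pref_neg[_N_RES // 2 :] = 1.0
    pref_neg /= pref_neg.sum()
    p_pos = (1.0 - bias) * base + bias * pref_pos
    p_neg = (1.0 - bias) * base + bias * pref_neg
    return p_pos, p_neg


def _dipeptide_bias_transitions(bias: float) -> tuple[np.ndarray, np.ndarray]:
    """Doubly-stochastic transition matrices with uniform stationary law.

    The positive class blends the uniform matrix with a cyclic-shift
    permutation, the negative class with the opposite shift; both remain
    doubly stochastic, so the marginal residue frequencies of the two
    classes match while their transition structures diverge with bias.
    """
    uniform = np.full((_N_RES, _N_RES), 1.0 / _N_RES)
    shift_fwd = np.roll(np.eye(_N_RES), 1, axis=1)
    shift_bwd = np.roll(np.eye(_N_RES), -1, axis=1)
    t_pos = (1.0 - bias) * uniform + bias * shift_fwd
    t_neg = (1.0 - bias) * uniform + bias * shift_bwd
    return t_pos, t_neg


def _sample_iid(p: np.ndarray, length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(_N_RES, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


def _sample_markov(
    transition: np.ndarray, length: int, rng: np.random.Generator
) -> str:
    idx = np.empty(length, dtype=int)
    idx[0] = rng.integers(_N_RES)  # uniform stationary start
    for k in range(1, length):
        idx[k] = rng.choice(_N_RES, p=transition[idx[k - 1]])
    return "".join(ALPHABET[i] for i in idx)


def generate(config: SyntheticConfig) -> tuple[list[ProteinRecord], AnnotationTable]:
    """Generate labeled records plus an annotation table, reproducibly.

    The annotation table marks every record vertebrate / no SP / no TM
    except for an ``annotation_noise`` fraction per class, which is randomly
    flagged with one of the three gate-triggering conditions. Locations are
    drawn uniformly (one, two, or no compartments).
    """
    rng = np.random.default_rng(config.seed)
    if config.signal_mode == "aa_bias":
        p_pos, p_neg = _aa_bias_distributions(config.bias_strength, rng)
        samplers = {
            1: lambda L: _sample_iid(p_pos, L, rng),
            0: lambda L: _sample_iid(p_neg, L, rng),
        }
    else:
        t_pos, t_neg = _dipeptide_bias_transitions(config.bias_strength)
        samplers = {
            1: lambda L: _sample_markov(t_pos, L, rng),
            0: lambda L: _sample_markov(t_neg, L, rng),
        }

    lo, hi = config.length_range
    records: list[ProteinRecord] = []
    annotations = AnnotationTable()
    locations_pool = ("nucleus", "cytosol", "ER", "GA", "mitochondrion", "other")
    for label, count, prefix in ((1, config.n_pos, "pos"), (0, config.n_neg, "neg")):
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            rec_id = f"{prefix}_{i:04d}"
            records.append(
                ProteinRecord(
                    id=rec_id,
                    sequence=samplers[label](length),
                    description=f"synthetic {config.signal_mode} class={label}",
                    label=label,
                )
            )
            flagged = rng.random() < config.annotation_noise
            if flagged:
                which = rng.integers(3)
                entry = AnnotationEntry(
                    is_vertebrate=which != 0,
                    has_signal_peptide=which == 1,
                    has_transmembrane=which == 2,
                )
            else:
                n_locs = int(rng.integers(0, 3))
                locs = frozenset(
                    rng.choice(locations_pool, size=n_locs, replace=False).tolist()
                )
                entry = AnnotationEntry(
                    is_vertebrate=True,
                    has_signal_peptide=False,
                    has_transmembrane=False,
                    locations=locs,
                    uniprot_id=f"SYN{label}{i:05d}",
                )
            annotations[rec_id] = entry
    return records, annotations


# Hand-checkable sequences with their exact nonzero AA / DP components.
_WORKED_EXAMPLES = (
    ("AAAA", {"AA_A": 1.0}, {"DP_AA": 1.0}),
    ("ACAC", {"AA_A": 0.5, "AA_C": 0.5}, {"DP_AC": 2 / 3, "DP_CA": 1 / 3}),
    ("ACDEFGHIKLMNPQRSTVWY", {f"AA_{a}": 0.05 for a in ALPHABET}, None),
    ("AAA", {"AA_A": 1.0}, {"DP_AA": 1.0}),
    ("AC", {"AA_A": 0.5, "AA_C": 0.5}, {"DP_AC": 1.0}),
    ("WWWW", {"AA_W": 1.0}, {"DP_WW": 1.0}),
)


def worked_example_set() -> list[dict]:
    """Tiny fixed dataset with golden expected feature components.

    Each item holds the sequence, the exact nonzero amino-acid-composition
    components, and (where defined) the exact nonzero dipeptide components;
    all other components are exactly zero.
    """
    out = []
    for i, (seq, aa_expected, dp_expected) in enumerate(_WORKED_EXAMPLES):
        out.append(
            {
                "record": ProteinRecord(id=f"golden_{i}", sequence=seq),
                "aa_nonzero": dict(aa_expected),
                "dp_nonzero": None if dp_expected is None else dict(dp_expected),
            }
        )
    return out
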