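"""The 74-element sequence + structure feature encoding.

Layout (S1..S74):

* S1..S64 — 3-mer frequencies over {A, C, G, U} in strict lexicographic
  order (AAA, AAC, AAG, AAU, ACA, ...), each count divided by the number
  of 3-mer windows (L − 2); the block sums to 1.
* S65 — GC content, (N_G + N_C) / L.
* S66 — MFE, min-normalized over the fitted corpus (mfe / min_mfe).
* S67 — count of unbranched stems (contiguous stacks without branches).
* S68 — count of branched stems.
* S69 / S70 — counts of left / right internal loops.
* S71 — count of hairpin loops.
* S72 / S73 — counts of left / right bulges.
* S74 — fraction of unpaired NTs (exterior/junction; hairpin, bulge and
  loop NTs are counted in their own elements, not here).

Count features S67..S73 are max-normalized over the combined corpus the
:class:`CorpusNormalizer` was fitted on, so a trained model carries its
normalizer and applies training-time scaling to new sequences.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .structure import SecondaryStructure, StructureDecomposition, parse_dot

ALPHABET = "ACGU"
KMER_ORDER = ["".join(p) for p in itertools.product(ALPHABET, repeat=3)]
_KMER_INDEX = {k: i for i, k in enumerate(KMER_ORDER)}

STRUCTURAL_NAMES = [
    "MFE", "N_unbranched_stacks", "N_branched_stacks", "N_loops_L",
    "N_loops_R", "N_hairpins", "N_bulges_L", "N_bulges_R", "frac_unpaired",
]

#: Column header for the full 74-feature vector, in order.
FEATURE_NAMES = KMER_ORDER + ["GC_content"] + STRUCTURAL_NAMES

N_FEATURES = 74
#: Index (0-based) where the 9 structural features start (S66 == index 65).
STRUCT_SLICE = slice(65, 74)


def kmer_frequencies(sequence: str, k: int = 3) -> np.ndarray:
    """Length-normalized k-mer frequencies in lexicographic ACGU order.

    Counts are divided by the number of windows (L − k + 1, i.e. L − 2
    for 3-mers), so the vector sums to 1 for any sequence of length ≥ k.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    if k != 3:
        index = {"".join(p): i for i, p in enumerate(itertools.product(ALPHABET, repeat=k))}
    else:
        index = _KMER_INDEX
    counts = np.zeros(len(index))
    for i in range(len(sequence) - k + 1):
        counts[index[sequence[i:i + k]]] += 1
    return counts / (len(sequence) - k + 1)


def gc_content(sequence: str) -> float:
    """(N_G + N_C) / L."""
    if not sequence:
        raise ValueError("empty sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def structural_features(ss: SecondaryStructure,
                        decomp: StructureDecomposition | None = None) -> np.ndarray:
    """Raw (pre-normalization) 9-vector of structural features.

    ``[MFE, N_unbranched, N_branched, N_loops_L, N_loops_R, N_hairpins,
    N_bulges_L, N_bulges_R, unpaired_fraction]``; the unpaired fraction
    uses the structure's own length as denominator.
    """
    d = decomp if decomp is not None else parse_dot(ss.dot)
    return np.array([
        ss.mfe,
        d.n_unbranched_stems,
        d.n_branched_stems,
        len(d.loops_left),
        len(d.loops_right),
        d.n_hairpins,
        len(d.bulges_left),
        len(d.bulges_right),
        d.n_unpaired / len(ss.dot),
    ])


@dataclass
class CorpusNormalizer:
    """Corpus-wide scaling for the structural feature block.

    ``min_mfe`` is the most negative MFE seen; S66 = mfe / min_mfe
    (clipped to [0, 1], positive MFEs clipped to 0 first).  ``max_counts``
    are per-feature maxima for S67..S73; counts divide by them (a feature
    never observed nonzero stays 0).
    """

    min_mfe: float = 0.0
    max_counts: np.ndarray = field(default_factory=lambda: np.zeros(7))
    fingerprint: str = ""
    fitted: bool = False

    def fit(self, raw_structural: np.ndarray, fingerprint: str = "") -> "CorpusNormalizer":
        """Fit on an (n, 9) matrix of raw structural vectors."""
        raw = np.asarray(raw_structural, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != 9:
            raise ValueError("expected an (n, 9) raw structural feature matrix")
        self.min_mfe = float(min(raw[:, 0].min(), 0.0))
        self.max_counts = raw[:, 1:8].max(axis=0)
        self.fingerprint = fingerprint
        self.fitted = True
        return self

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Normalize one raw 9-vector (or (n, 9) matrix) to [0, 1]."""
        if not self.fitted:
            raise ValueError("normalizer is not fitted")
        was_1d = np.asarray(raw).ndim == 1
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        out = np.empty_like(raw)
        mfe = np.minimum(raw[:, 0], 0.0)
        out[:, 0] = np.clip(mfe / self.min_mfe, 0.0, 1.0) if self.min_mfe < 0 else 0.0
        denom = np.where(self.max_counts > 0, self.max_counts, 1.0)
        out[:, 1:8] = np.clip(raw[:, 1:8] / denom, 0.0, 1.0)
        out[:, 8] = np.clip(raw[:, 8], 0.0, 1.0)
        return out[0] if was_1d else out

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({
                "min_mfe": self.min_mfe,
                "max_counts": self.max_counts.tolist(),
                "fingerprint": self.fingerprint,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CorpusNormalizer":
        with open(path) as fh:
            d = json.load(fh)
        obj = cls(min_mfe=d["min_mfe"], max_counts=np.asarray(d["max_counts"], float),
                  fingerprint=d.get("fingerprint", ""))
        obj.fitted = True
        return obj


def fit_normalizer(structures: list[SecondaryStructure],
                   fingerprint: str = "") -> CorpusNormalizer:
    raw = np.vstack([structural_features(ss) for ss in structures])
    return CorpusNormalizer().fit(raw, fingerprint=fingerprint)


def featurize(sequence: str, ss: SecondaryStructure,
              normalizer: CorpusNormalizer) -> np.ndarray:
    """Full 74-vector for one (sequence, structure) pair.

    Deterministic given its inputs; all entries lie in [0, 1].
    """
    if len(ss.dot) != len(sequence):
        raise ValueError("structure length does not match sequence length")
    raw = structural_features(ss)
    normed = normalizer.transform(raw.reshape(1, 9))[0]
    return np.concatenate([
        kmer_frequencies(sequence), [gc_content(sequence)], normed,
    ])


def featurize_corpus(records, structures: dict[str, SecondaryStructure],
                     normalizer: CorpusNormalizer) -> np.ndarray:
    """Stack feature vectors for records (structures keyed by record id)."""
    return np.vstack([featurize(r.sequence, structures[r.id], normalizer) for r in records])


def ks_distance(samples_a: np.ndarray, samples_b: np.ndarray) -> np.ndarray:
    """Two-sample Kolmogorov–Smirnov statistic per feature column.

    Both inputs are (n, d) matrices over the same d features; returns a
    length-d vector of KS statistics in [0, 1].
    """
    a = np.atleast_2d(np.asarray(samples_a, float))
    b = np.atleast_2d(np.asarray(samples_b, float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty sample")
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimension mismatch")
    return np.array([ks_2samp(a[:, j], b[:, j]).statistic for j in range(a.shape[1])])
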