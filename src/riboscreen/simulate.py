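"""Synthetic corpora for exercising the screening pipeline end to end.

The generators emulate the shape of the real training data without any
download: a *structured* positive class of stem-rich sequences carrying
a skewed ligand-class distribution (one dominant class near 23%, a long
tail of classes below 2%), an *unlabeled* class mixing mildly structured
and unstructured sequences, plus random-nucleotide and exon-like
negative controls length-matched to the positive set.  Every generator
is a pure function of (spec, seed): identical inputs give byte-identical
output.

Structured sequences are built by planting complementary stem arms, so
their hairpin-rich dot-bracket structures are known by construction and
are emitted alongside the sequences.  Pipeline tests therefore fold
through a precomputed table of these planted structures instead of a
thermodynamic engine; a pseudo-MFE proportional to the planted base
pairs (≈ −1.8 kcal/mol per pair, jittered) stands in for a computed MFE.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .corpus import SequenceRecord
from .structure import SecondaryStructure, SuffixTableBackend

__all__ = [
    "FixtureSpec", "DEFAULT_LIGAND_PROPORTIONS", "generate_structured",
    "generate_unlabeled", "generate_random", "generate_exonlike",
    "generate_riboswitch_utrs", "generate_pu_tabular", "fixture_backend",
    "random_dot",
]

#: Skewed ligand-class proportions shaped like the reference corpus:
#: ten classes at or above 2% representation, a tail below 2%.
DEFAULT_LIGAND_PROPORTIONS: dict[str, float] = {
    "cobalamin": 0.232, "TPP": 0.184, "SAM": 0.128, "glycine": 0.071,
    "FMN": 0.063, "purine": 0.039, "lysine": 0.034, "fluoride": 0.029,
    "zmp-ztp": 0.027, "guanidine": 0.024,
    "Mg2+": 0.019, "molybdenum": 0.017, "unknown": 0.017,
    "glucosamine": 0.015, "glutamine": 0.012, "Mn2+": 0.012,
    "homocysteine": 0.012, "tetrahydrofolate": 0.009, "Pre-Q1": 0.009,
    "Ni/Co": 0.008, "GMP": 0.008, "cyclic-di-GMP": 0.008,
}


@dataclass
class FixtureSpec:
    """Conditions for the synthetic corpora.

    Counts default to the reference-corpus scale; tests pass smaller
    ``n`` values explicitly.  Positive-like lengths are drawn from a
    clipped normal (mean 150 NT within [25, 476]); UTR-like lengths cap
    at 300 NT.  ``stem_intensity`` scales how many stems are planted per
    100 NT of structured sequence.
    """

    n_positive: int = 67683
    n_unlabeled: int = 48031
    n_random: int = 60000
    n_exonlike: int = 5946
    ligand_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIGAND_PROPORTIONS))
    length_mean: float = 150.0
    length_sd: float = 75.0
    length_min: int = 25
    length_max: int = 476
    utr_length_max: int = 300
    stem_intensity: float = 1.0
    unlabeled_structured_frac: float = 0.3
    seed: int = 0


_BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _class_motif(ligand: str, length: int = 6) -> str:
    """Deterministic per-class loop motif (stable across runs/platforms)."""
    digest = hashlib.md5(ligand.encode()).digest()
    return "".join("ACGU"[b % 4] for b in digest[:length])


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _draw_length(rng: np.random.Generator, spec: FixtureSpec,
                 max_len: int | None = None) -> int:
    hi = max_len if max_len is not None else spec.length_max
    L = int(round(rng.normal(spec.length_mean, spec.length_sd)))
    return int(np.clip(L, spec.length_min, hi))


def _pseudo_mfe(rng: np.random.Generator, n_pairs: int) -> float:
    if n_pairs == 0:
        return 0.0
    return round(min(-0.1, -1.8 * n_pairs + rng.normal(0.0, 0.4)), 2)


def _plant_structure(rng: np.random.Generator, length: int, motif: str | None,
                     intensity: float = 1.0, allow_branch: bool = True,
                     ) -> tuple[str, str, int]:
    """Assemble one stem-rich sequence of exactly ``length`` NT.

    Returns (sequence, dot, n_pairs).  Stems (arm 4–10 bp, loop 4–8 NT,
    optional 1-NT left bulge) are placed left to right with unpaired
    spacers; with some probability a branched unit (an outer helix
    enclosing two hairpin stems) is emitted instead.  The class motif,
    when given, is written into the first hairpin loop.
    """
    state = {"first_loop": True}

    def loop_seq(n: int) -> str:
        if motif is not None and state["first_loop"] and n >= len(motif):
            state["first_loop"] = False
            return motif + _rand_seq(rng, n - len(motif), gc=0.4)
        return _rand_seq(rng, n, gc=0.4)

    def hairpin_unit(max_room: int) -> tuple[str, str, int]:
        """One hairpin stem as (seq, dot, n_pairs); empty if no room."""
        arm = int(rng.integers(4, 11))
        loop = int(rng.integers(4, 9))
        bulge = bool(rng.random() < 0.4) and arm >= 6
        if 2 * arm + loop + (1 if bulge else 0) > max_room:
            arm, loop, bulge = 4, 4, False
            if 12 > max_room:
                return "", "", 0
        left = _rand_seq(rng, arm, gc=0.6)
        if bulge:
            k = int(rng.integers(2, arm - 1))
            s5 = left[:k] + _rand_seq(rng, 1) + left[k:]
            d5 = "(" * k + "." + "(" * (arm - k)
        else:
            s5, d5 = left, "(" * arm
        lp = loop_seq(loop)
        return s5 + lp + _revcomp(left), d5 + "." * loop + ")" * arm, arm

    def branched_unit(max_room: int) -> tuple[str, str, int]:
        """Outer helix enclosing two hairpin stems; empty if no room."""
        outer = int(rng.integers(4, 7))
        gaps = [int(rng.integers(2, 5)) for _ in range(3)]
        room = max_room - 2 * outer - sum(gaps)
        if room < 24:
            return "", "", 0
        h1 = hairpin_unit(room // 2)
        h2 = hairpin_unit(room - len(h1[0]))
        if not h1[0] or not h2[0]:
            return "", "", 0
        left = _rand_seq(rng, outer, gc=0.6)
        seq = (left + _rand_seq(rng, gaps[0], gc=0.4) + h1[0]
               + _rand_seq(rng, gaps[1], gc=0.4) + h2[0]
               + _rand_seq(rng, gaps[2], gc=0.4) + _revcomp(left))
        dot = ("(" * outer + "." * gaps[0] + h1[1] + "." * gaps[1] + h2[1]
               + "." * gaps[2] + ")" * outer)
        return seq, dot, outer + h1[2] + h2[2]

    seq_parts: list[str] = []
    dot_parts: list[str] = []
    n_pairs = 0
    budget = length
    n_target = max(1, int(round(intensity * length / 70.0)))
    planted = 0
    while planted < n_target and budget >= 15:
        sp = int(rng.integers(3, 9))
        if budget - sp < 12:
            break
        seq_parts.append(_rand_seq(rng, sp, gc=0.4))
        dot_parts.append("." * sp)
        budget -= sp
        if allow_branch and rng.random() < 0.25 and budget >= 60:
            s, d, bp = branched_unit(budget)
        else:
            s, d, bp = hairpin_unit(budget)
        seq_parts.append(s)
        dot_parts.append(d)
        n_pairs += bp
        budget -= len(s)
        planted += 1
    if budget > 0:
        seq_parts.append(_rand_seq(rng, budget, gc=0.4))
        dot_parts.append("." * budget)
    s, d = "".join(seq_parts), "".join(dot_parts)
    assert len(s) == len(d) == length
    return s, d, n_pairs


def generate_structured(spec: FixtureSpec, n: int | None = None,
                        seed: int | None = None, role: str = "positive",
                        prefix: str = "RS",
                        ) -> tuple[list[SequenceRecord],
                                   dict[str, SecondaryStructure],
                                   dict[str, str]]:
    """Positive-like stem-rich sequences with ligand class labels.

    Ligands are drawn from the spec's skewed proportions; each class
    biases its sequences through a fixed loop motif so classes are
    statistically distinguishable.  Returns (records, structures keyed
    by id, ligand table id → class).
    """
    n = n if n is not None else spec.n_positive
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    classes = list(spec.ligand_proportions)
    probs = np.array([spec.ligand_proportions[c] for c in classes], float)
    probs = probs / probs.sum()
    records, structures, ligands = [], {}, {}
    for i in range(n):
        ligand = str(rng.choice(classes, p=probs))
        L = _draw_length(rng, spec)
        s, d, n_bp = _plant_structure(rng, L, _class_motif(ligand),
                                      intensity=spec.stem_intensity)
        rid = f"{prefix}{i:05d}"
        records.append(SequenceRecord(id=rid, sequence=s, role=role, ligand=ligand))
        structures[rid] = SecondaryStructure(dot=d, mfe=_pseudo_mfe(rng, n_bp),
                                             source="planted")
        ligands[rid] = ligand
    return records, structures, ligands


def generate_unlabeled(spec: FixtureSpec, n: int | None = None,
                       seed: int | None = None, prefix: str = "UTR",
                       ) -> tuple[list[SequenceRecord], dict[str, SecondaryStructure]]:
    """UTR-like unlabeled corpus: a mix of mildly structured and
    unstructured sequences, lengths capped at the UTR limit."""
    n = n if n is not None else spec.n_unlabeled
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    records, structures = [], {}
    for i in range(n):
        L = _draw_length(rng, spec, max_len=spec.utr_length_max)
        rid = f"{prefix}{i:05d}"
        if rng.random() < spec.unlabeled_structured_frac:
            s, d, n_bp = _plant_structure(rng, L, motif=None,
                                          intensity=0.4, allow_branch=False)
            mfe = _pseudo_mfe(rng, n_bp)
        else:
            s, d, mfe = _rand_seq(rng, L), "." * L, 0.0
        records.append(SequenceRecord(id=rid, sequence=s, role="unlabeled"))
        structures[rid] = SecondaryStructure(dot=d, mfe=mfe, source="planted")
    return records, structures


def generate_random(n: int, spec: FixtureSpec | None = None,
                    seed: int = 0, prefix: str = "RND",
                    ) -> tuple[list[SequenceRecord], dict[str, SecondaryStructure]]:
    """i.i.d. uniform-nucleotide negative controls, length-matched to the
    positive distribution; their toy structures are fully unpaired."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed + 2)
    records, structures = [], {}
    for i in range(n):
        L = _draw_length(rng, spec)
        rid = f"{prefix}{i:05d}"
        records.append(SequenceRecord(
            id=rid, sequence="".join(rng.choice(_BASES, size=L)),
            role="negative_control"))
        structures[rid] = SecondaryStructure(dot="." * L, mfe=0.0, source="planted")
    return records, structures


def generate_exonlike(n: int, gc_target: float = 0.52,
                      spec: FixtureSpec | None = None, seed: int = 0,
                      prefix: str = "EXN",
                      ) -> tuple[list[SequenceRecord], dict[str, SecondaryStructure]]:
    """Codon-periodic Markov-chain negative controls (synthetic stand-in
    for exon sequences): frame-dependent base composition tuned to the
    target GC, with a mild repeat-avoidance dependence on the previous
    base.  Length-matched to the positive distribution."""
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed + 3)
    # frame-specific GC weight, averaging to gc_target over a codon
    frame_gc = np.clip(np.array([0.9, 0.75, 1.35]) * gc_target, 0.05, 0.95)
    frame_gc *= 3 * gc_target / frame_gc.sum()
    frame_probs = []
    for g in frame_gc:
        # order ACGU; purine-rich first positions, GC-skewed wobble
        frame_probs.append(np.array([
            (1 - g) * 0.62, g * 0.45, g * 0.55, (1 - g) * 0.38,
        ]))
    records, structures = [], {}
    for i in range(n):
        L = _draw_length(rng, spec)
        chars = []
        prev = None
        for pos in range(L):
            p = frame_probs[pos % 3].copy()
            if prev is not None:
                p[prev] *= 0.7
            p /= p.sum()
            b = rng.choice(4, p=p)
            chars.append("ACGU"[b])
            prev = b
        rid = f"{prefix}{i:05d}"
        records.append(SequenceRecord(id=rid, sequence="".join(chars),
                                      role="negative_control"))
        structures[rid] = SecondaryStructure(dot="." * L, mfe=0.0, source="planted")
    return records, structures


def generate_riboswitch_utrs(spec: FixtureSpec, n: int, seed: int = 0,
                             prefix: str = "HIT", pad5: tuple[int, int] = (35, 60),
                             ) -> tuple[list[SequenceRecord],
                                        dict[str, SecondaryStructure]]:
    """Preprocessed-5'UTR-shaped records harboring a planted switch.

    Each record is an unstructured 5' pad, a strong structured core, a
    short 3' pad and the AUG + 22 NT coding-start anchor — the shape the
    truncation scanner expects.  Total length stays within the UTR cap.
    """
    rng = np.random.default_rng(seed + 4)
    records, structures = [], {}
    for i in range(n):
        pad = int(rng.integers(*pad5))
        core_len = int(rng.integers(90, min(150, spec.utr_length_max - pad - 35)))
        core_seq, core_dot, n_bp = _plant_structure(
            rng, core_len, motif=None, intensity=1.3)
        tail = _rand_seq(rng, 8)
        anchor = "AUG" + _rand_seq(rng, 22)
        seq = _rand_seq(rng, pad, gc=0.4) + core_seq + tail + anchor
        dot = "." * pad + core_dot + "." * (len(tail) + len(anchor))
        rid = f"{prefix}{i:05d}"
        records.append(SequenceRecord(id=rid, sequence=seq, role="unlabeled"))
        structures[rid] = SecondaryStructure(dot=dot, mfe=_pseudo_mfe(rng, n_bp),
                                             source="planted")
    return records, structures


def generate_pu_tabular(n: int, c_true: float, separation: float = 3.0,
                        seed: int = 0, d: int = 2,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two well-separated Gaussian clusters with a known labeling propensity.

    y is balanced Bernoulli; features are N(0, I) for y = 0 and shifted
    for y = 1 so that each cluster mean lies ``separation`` within-class
    standard deviations from the midpoint between the clusters (the
    signal-detection convention: means are 2·separation·σ apart, so at
    separation 3 the class posterior is essentially 0/1 everywhere — the
    regime the labeling-propensity identity assumes).  Exactly a
    ``c_true`` fraction of positives, chosen uniformly at random, get
    the known flag s = 1.  Returns (X, y, s).
    """
    if not 0 < c_true <= 1:
        raise ValueError("c_true must be in (0, 1]")
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    shift = 2.0 * separation / np.sqrt(d)
    X = rng.normal(size=(n, d)) + np.outer(y, np.full(d, shift))
    s = np.zeros(n, dtype=int)
    pos = np.flatnonzero(y == 1)
    n_label = int(round(c_true * len(pos)))
    s[rng.choice(pos, size=n_label, replace=False)] = 1
    return X, y, s


def fixture_backend(*structure_maps: dict[str, SecondaryStructure],
                    records: list[SequenceRecord] | None = None,
                    record_sets: list[list[SequenceRecord]] | None = None,
                    ) -> SuffixTableBackend:
    """Bundle planted structures into a suffix-capable table backend.

    ``record_sets`` (or ``records``) link ids to sequences so lookups
    work both by id and by sequence string (required for suffix folds).
    """
    backend = SuffixTableBackend()
    seq_of: dict[str, str] = {}
    for rs in (record_sets or ([] if records is None else [records])):
        for r in rs:
            seq_of[r.id] = r.sequence
    for smap in structure_maps:
        for rid, ss in smap.items():
            backend.by_id[rid] = (ss.dot, ss.mfe)
            if rid in seq_of:
                backend.by_sequence[seq_of[rid]] = (ss.dot, ss.mfe)
    return backend


def random_dot(rng: np.random.Generator, length: int,
               p_pair: float = 0.35, min_loop: int = 3) -> str:
    """A random balanced dot-bracket string (for property tests)."""
    def grow(n: int) -> str:
        if n < 2 * 1 + min_loop:
            return "." * n
        out = []
        i = 0
        while i < n:
            rem = n - i
            if rem >= 2 + min_loop and rng.random() < p_pair:
                inner = int(rng.integers(min_loop, rem - 1))
                out.append("(" + grow(inner) + ")")
                i += inner + 2
            else:
                out.append(".")
                i += 1
        return "".join(out)
    return grow(length)
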