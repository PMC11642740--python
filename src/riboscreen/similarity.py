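"""5'UTR-to-riboswitch similarity: D_L, D_struct, D_Lev and J_Sim.

A candidate 5'UTR is compared to each known riboswitch through three
distances — absolute length difference D_L, squared distance over the
nine structural features D_struct, and Levenshtein edit distance between
dot-bracket strings D_Lev — combined into a 0-to-1 similarity

    J_Sim = 1 − (1/3) (D_L/max D_L + D_Lev/max D_Lev + D_struct/max D_struct).

The normalizing maxima follow the corpus conventions: max D_L is the
span between the longest riboswitch and the shortest sequence in the
combined data (476 − 25 in the reference corpora); max D_Lev is
max((max D_L) − L_UTR, L_UTR); max D_struct is the largest structural
distance between the query and any riboswitch in the reference set.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .features import STRUCT_SLICE

__all__ = [
    "length_distance", "struct_distance", "levenshtein", "SimilarityContext",
    "SimilarityMatch", "j_sim", "top_matches",
]


def length_distance(l_utr: int, l_rs: int) -> int:
    """Absolute sequence-length difference |L_UTR − L_RS| in NT."""
    return abs(int(l_utr) - int(l_rs))


def struct_distance(f_utr: np.ndarray, f_rs: np.ndarray) -> float:
    """Σ over the structural block (S66..S74) of squared differences.

    Both vectors must be full 74-feature vectors produced with the same
    normalizer.
    """
    a = np.asarray(f_utr, float)
    b = np.asarray(f_rs, float)
    if a.shape != b.shape:
        raise ValueError("feature vectors have different shapes")
    d = a[STRUCT_SLICE] - b[STRUCT_SLICE]
    return float(np.dot(d, d))


def levenshtein(a: str, b: str) -> int:
    """Edit distance (insertions, deletions, substitutions) between strings.

    Exact dynamic-programming distance (via edlib); equals the classical
    recursive definition, including the empty-string bases
    lev("", b) = len(b) and lev(a, "") = len(a).
    """
    if not a or not b:
        return max(len(a), len(b)) if (a or b) else 0
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass
class SimilarityContext:
    """Corpus-level normalization constants for J_Sim.

    ``max_rs_length`` is the longest riboswitch; ``min_length`` the
    shortest sequence in the combined corpora; max D_L is their
    difference.  Derived from the loaded corpus rather than hard-coded.
    """

    max_rs_length: int
    min_length: int

    @property
    def max_dl(self) -> int:
        return self.max_rs_length - self.min_length

    def max_dlev(self, l_utr: int) -> int:
        """max(((max_RS − min) − L_UTR), L_UTR), per corpus convention."""
        return max(self.max_dl - l_utr, l_utr)

    @classmethod
    def from_corpus(cls, rs_lengths, utr_lengths) -> "SimilarityContext":
        all_lengths = list(rs_lengths) + list(utr_lengths)
        return cls(max_rs_length=int(max(rs_lengths)),
                   min_length=int(min(all_lengths)))


@dataclass
class SimilarityMatch:
    """One UTR-to-riboswitch comparison."""

    utr_id: str
    rs_id: str
    d_l: int
    d_struct: float
    d_lev: int
    j_sim: float
    rs_ligand: str | None = None


def j_sim(utr_id: str, utr_seq_len: int, utr_dot: str, utr_features: np.ndarray,
          rs_corpus: list[dict], context: SimilarityContext) -> list[SimilarityMatch]:
    """Score one query UTR against every riboswitch in the reference set.

    ``rs_corpus`` entries are dicts with keys ``id``, ``length``,
    ``dot``, ``features`` and optionally ``ligand``.  max D_struct is
    recomputed for this query as the maximum structural distance to any
    reference riboswitch.  J_Sim is clipped to [0, 1]; identity scores 1.
    """
    if not rs_corpus:
        raise ValueError("empty riboswitch reference set")
    d_ls, d_levs, d_structs = [], [], []
    for rs in rs_corpus:
        d_ls.append(length_distance(utr_seq_len, rs["length"]))
        d_levs.append(levenshtein(utr_dot, rs["dot"]))
        d_structs.append(struct_distance(utr_features, rs["features"]))
    max_dl = max(context.max_dl, 1)
    max_dlev = max(context.max_dlev(utr_seq_len), 1)
    max_dstruct = max(d_structs) or 1.0
    out = []
    for rs, dl, dlev, dstruct in zip(rs_corpus, d_ls, d_levs, d_structs):
        score = 1.0 - (dl / max_dl + dlev / max_dlev + dstruct / max_dstruct) / 3.0
        out.append(SimilarityMatch(
            utr_id=utr_id, rs_id=rs["id"], d_l=dl, d_struct=dstruct,
            d_lev=dlev, j_sim=float(np.clip(score, 0.0, 1.0)),
            rs_ligand=rs.get("ligand"),
        ))
    return out


def top_matches(utr_id: str, utr_seq_len: int, utr_dot: str,
                utr_features: np.ndarray, rs_corpus: list[dict],
                context: SimilarityContext, k: int = 3,
                tally: int = 20) -> tuple[list[SimilarityMatch], Counter]:
    """k highest-J_Sim matches plus a ligand tally over the top ``tally``.

    Ties break deterministically by riboswitch id (lexicographic).
    Requests beyond the corpus size return everything with a warning.
    """
    matches = j_sim(utr_id, utr_seq_len, utr_dot, utr_features, rs_corpus, context)
    matches.sort(key=lambda m: (-m.j_sim, m.rs_id))
    if k > len(matches):
        warnings.warn(f"k={k} exceeds reference corpus size {len(matches)}")
    ligand_tally = Counter(
        m.rs_ligand or "unknown" for m in matches[:tally]
    )
    return matches[:k], ligand_tally


def matches_to_frame(matches: list[SimilarityMatch]) -> pd.DataFrame:
    """Tabulate ranked matches for CSV output."""
    return pd.DataFrame([{
        "utr_id": m.utr_id, "rank": i + 1, "rs_id": m.rs_id, "D_L": m.d_l,
        "D_Lev": m.d_lev, "D_struct": m.d_struct, "J_sim": m.j_sim,
        "ligand": m.rs_ligand,
    } for i, m in enumerate(matches)])
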