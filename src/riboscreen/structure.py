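"""Secondary-structure prediction backends and dot-bracket decomposition.

A folding *backend* is anything that maps an RNA sequence to a
minimum-free-energy dot-bracket string and MFE value, deterministically
for fixed input and settings.  Built-in backends:

* :class:`TableBackend` — returns precomputed structures verbatim
  (bit-exact, the backend used throughout the test suite);
* :class:`SuffixTableBackend` — a table backend that additionally serves
  3'-anchored suffixes of its entries with pairs broken by the cut
  masked out, which is what the truncation scanner needs;
* :class:`ViennaBackend` — single-strand MFE folding through ViennaRNA
  (the ``RNA`` Python bindings, or the ``RNAfold`` executable).

:func:`parse_dot` decomposes a dot-bracket string into the structural
elements used by the feature encoding: helices grouped into stems,
hairpin loops, left/right bulges (single-NT interruptions), left/right
internal loops (≥2 NT), and exterior/junction unpaired positions.  Every
position receives exactly one category.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

__all__ = [
    "SecondaryStructure",
    "StructureDecomposition",
    "Stem",
    "TableBackend",
    "SuffixTableBackend",
    "ViennaBackend",
    "fold",
    "parse_dot",
    "pair_table",
    "mirror_dot",
]


class StructureError(ValueError):
    """Raised for unbalanced dot-bracket strings or backend failures."""


def pair_table(dot: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, from stack-matching a dot-bracket string.

    Raises :class:`StructureError` naming the 1-based position of the
    first unmatched bracket.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(dot):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {i + 1}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {i + 1}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1] + 1}")
    return sorted(pairs)


@dataclass
class SecondaryStructure:
    """A dot-bracket structure with its minimum free energy.

    ``mfe`` is in kcal/mol (≤ 0 for folded structures, 0 when fully
    unpaired); ``pairs`` is derived from ``dot`` on construction.
    """

    dot: str
    mfe: float
    source: str = "unspecified"
    pairs: list[tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pairs = pair_table(self.dot)

    def __len__(self) -> int:
        return len(self.dot)


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class TableBackend:
    """Precomputed-structure backend: fold() is the identity on its table.

    Entries are keyed by record id and/or by the sequence string itself.
    """

    name = "precomputed-table"

    def __init__(self, by_id: dict[str, tuple[str, float]] | None = None,
                 by_sequence: dict[str, tuple[str, float]] | None = None):
        self.by_id = dict(by_id or {})
        self.by_sequence = dict(by_sequence or {})

    def add(self, sequence: str, dot: str, mfe: float, id: str | None = None) -> None:
        self.by_sequence[sequence] = (dot, mfe)
        if id is not None:
            self.by_id[id] = (dot, mfe)

    def fold(self, sequence: str, id: str | None = None) -> tuple[str, float]:
        if id is not None and id in self.by_id:
            return self.by_id[id]
        if sequence in self.by_sequence:
            return self.by_sequence[sequence]
        raise StructureError(
            f"no precomputed structure for id={id!r} / sequence of length "
            f"{len(sequence)}; supply a structure table covering all inputs "
            "or use a thermodynamic backend"
        )


class SuffixTableBackend(TableBackend):
    """Table backend that also folds 3'-anchored suffixes of its entries.

    When a query sequence is a proper suffix of a stored sequence, the
    stored dot string is cut at the same point; base pairs broken by the
    cut become unpaired positions, and the MFE is scaled by the fraction
    of pairs retained.  This keeps truncation scans deterministic when
    the full-length structures are known (e.g. planted fixture stems).
    """

    name = "suffix-table"

    def fold(self, sequence: str, id: str | None = None) -> tuple[str, float]:
        try:
            return super().fold(sequence, id=id)
        except StructureError:
            pass
        for full_seq, (dot, mfe) in self.by_sequence.items():
            if full_seq.endswith(sequence) and len(full_seq) > len(sequence):
                cut = len(full_seq) - len(sequence)
                return _cut_structure(dot, mfe, cut)
        raise StructureError(
            f"sequence of length {len(sequence)} is not in the table nor a "
            "suffix of any table entry"
        )


def _cut_structure(dot: str, mfe: float, cut: int) -> tuple[str, float]:
    pairs = pair_table(dot)
    kept = [(i, j) for (i, j) in pairs if i >= cut]
    chars = ["."] * (len(dot) - cut)
    for i, j in kept:
        chars[i - cut] = "("
        chars[j - cut] = ")"
    scaled = mfe * (len(kept) / len(pairs)) if pairs else 0.0
    return "".join(chars), round(scaled, 2)


class ViennaBackend:
    """Single-strand MFE folding via ViennaRNA.

    Uses the ``RNA`` Python bindings when importable, otherwise the
    ``RNAfold`` executable.  Deterministic for fixed input (default
    model: 37 °C, Turner energies).
    """

    name = "viennarna"

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
            self._rna = RNA
        except ImportError:
            self._rna = None
            if shutil.which("RNAfold") is None:
                raise StructureError(
                    "no thermodynamic folder available: neither the 'RNA' "
                    "bindings nor 'RNAfold' were found; use a precomputed "
                    "structure table instead"
                )

    def fold(self, sequence: str, id: str | None = None) -> tuple[str, float]:
        if self._rna is not None:
            dot, mfe = self._rna.fold(sequence)
            return dot, round(float(mfe), 2)
        proc = subprocess.run(
            ["RNAfold", "--noPS"], input=sequence + "\n",
            capture_output=True, text=True, check=True,
        )
        lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
        dot, _, energy = lines[-1].partition(" ")
        return dot.strip(), round(float(energy.strip(" ()")), 2)


def fold(sequence: str, backend, id: str | None = None) -> SecondaryStructure:
    """Fold one sequence through a backend and validate the result."""
    dot, mfe = backend.fold(sequence, id=id)
    if len(dot) != len(sequence):
        raise StructureError(
            f"backend {backend.name!r} returned a structure of length "
            f"{len(dot)} for a sequence of length {len(sequence)}"
        )
    ss = SecondaryStructure(dot=dot, mfe=float(mfe), source=backend.name)
    return ss


# ---------------------------------------------------------------------------
# Dot-bracket decomposition
# ---------------------------------------------------------------------------

# Per-position category codes used in StructureDecomposition.categories.
CATEGORIES = {
    "paired": "P",
    "hairpin": "H",
    "bulge_L": "b",
    "bulge_R": "d",
    "loop_L": "q",
    "loop_R": "p",
    "unpaired": "U",
}


@dataclass
class Stem:
    """A maximal run of nested helices interrupted only by bulges/loops.

    ``outer`` is the outermost base pair, ``inner`` the innermost;
    ``helices`` lists (first_pair, last_pair) per contiguous helix.
    ``branched`` is True when the enclosed region past the innermost
    pair contains two or more child stems.
    """

    outer: tuple[int, int]
    inner: tuple[int, int]
    helices: list[tuple[tuple[int, int], tuple[int, int]]]
    branched: bool = False
    n_pairs: int = 0


@dataclass
class StructureDecomposition:
    """Full categorization of a dot-bracket string.

    Every position belongs to exactly one category; ``categories`` holds
    the per-position code string (see :data:`CATEGORIES`).
    """

    dot: str
    stems: list[Stem]
    hairpins: list[tuple[int, int]]          # half-open [start, end) runs
    bulges_left: list[int]                   # single positions
    bulges_right: list[int]
    loops_left: list[tuple[int, int]]        # half-open runs, size ≥ 2
    loops_right: list[tuple[int, int]]
    categories: str

    @property
    def n_unbranched_stems(self) -> int:
        return sum(not s.branched for s in self.stems)

    @property
    def n_branched_stems(self) -> int:
        return sum(s.branched for s in self.stems)

    @property
    def n_hairpins(self) -> int:
        return len(self.hairpins)

    @property
    def hairpin_nt(self) -> int:
        return self.categories.count(CATEGORIES["hairpin"])

    @property
    def n_unpaired(self) -> int:
        """Exterior/junction unpaired NTs (hairpin, bulge and loop NTs excluded)."""
        return self.categories.count(CATEGORIES["unpaired"])

    def category_counts(self) -> dict[str, int]:
        return {name: self.categories.count(code) for name, code in CATEGORIES.items()}


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into maximal contiguous helices (i+1, j-1 stacking)."""
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:  # pairs sorted by i
        if helices and helices[-1][-1] == (p[0] - 1, p[1] + 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def parse_dot(dot: str) -> StructureDecomposition:
    """Decompose a balanced dot-bracket string into structural elements.

    Rules (reading 5'→3'): a *helix* is a maximal run of stacked pairs; a
    *stem* chains helices whose interruptions contain no paired bases.
    An interruption contributes, independently per strand, a *bulge*
    (exactly 1 unpaired NT) or an *internal loop* (≥ 2 NT) — *left* on
    the opening strand, *right* on the closing strand.  The unpaired run
    closed by a leaf stem's innermost pair is its *hairpin*.  A stem
    whose innermost pair encloses ≥ 2 child stems is *branched*; the
    junction NTs inside it, like exterior NTs, are *unpaired*.
    """
    pairs = pair_table(dot)
    cat = [CATEGORIES["unpaired"]] * len(dot)
    for i, j in pairs:
        cat[i] = cat[j] = CATEGORIES["paired"]

    helices = _helices(pairs)
    # index helices by their outer-pair opening position
    helix_by_outer = {h[0][0]: h for h in helices}
    paired_pos = {i for p in pairs for i in p}

    def region_has_pair(lo: int, hi: int) -> bool:
        return any(lo <= q < hi for q in paired_pos)

    def child_helices(lo: int, hi: int) -> list[list[tuple[int, int]]]:
        """Helices whose outer pair starts directly inside [lo, hi)."""
        out = []
        q = lo
        while q < hi:
            if q in helix_by_outer:
                h = helix_by_outer[q]
                out.append(h)
                q = h[0][1] + 1  # skip past this helix's enclosure
            else:
                q += 1
        return out

    stems: list[Stem] = []
    hairpins: list[tuple[int, int]] = []
    bulges_left: list[int] = []
    bulges_right: list[int] = []
    loops_left: list[tuple[int, int]] = []
    loops_right: list[tuple[int, int]] = []

    def classify_gap(lo: int, hi: int, side: str) -> None:
        """Record the unpaired run [lo, hi) as a bulge or internal loop."""
        size = hi - lo
        if size <= 0:
            return
        if size == 1:
            (bulges_left if side == "L" else bulges_right).append(lo)
            code = CATEGORIES["bulge_L" if side == "L" else "bulge_R"]
        else:
            (loops_left if side == "L" else loops_right).append((lo, hi))
            code = CATEGORIES["loop_L" if side == "L" else "loop_R"]
        for q in range(lo, hi):
            cat[q] = code

    def build_stem(first_helix: list[tuple[int, int]]) -> None:
        chain = [first_helix]
        while True:
            k, l = chain[-1][-1]  # innermost pair so far
            kids = child_helices(k + 1, l)
            if len(kids) == 1 and not region_has_pair(k + 1, kids[0][0][0]) \
                    and not region_has_pair(kids[0][0][1] + 1, l):
                nxt = kids[0]
                classify_gap(k + 1, nxt[0][0], "L")
                classify_gap(nxt[0][1] + 1, l, "R")
                chain.append(nxt)
                continue
            break
        k, l = chain[-1][-1]
        kids = child_helices(k + 1, l)
        branched = len(kids) >= 2
        if not kids:  # leaf stem: terminal loop is the hairpin
            hairpins.append((k + 1, l))
            for q in range(k + 1, l):
                cat[q] = CATEGORIES["hairpin"]
        stems.append(Stem(
            outer=chain[0][0], inner=(k, l),
            helices=[(h[0], h[-1]) for h in chain],
            branched=branched,
            n_pairs=sum(len(h) for h in chain),
        ))
        for kid in kids:
            build_stem(kid)

    for h in child_helices(0, len(dot)):
        build_stem(h)

    return StructureDecomposition(
        dot=dot, stems=stems, hairpins=hairpins,
        bulges_left=bulges_left, bulges_right=bulges_right,
        loops_left=loops_left, loops_right=loops_right,
        categories="".join(cat),
    )


def mirror_dot(dot: str) -> str:
    """Reverse a dot string and swap bracket orientation (5'↔3' mirror)."""
    swap = {"(": ")", ")": "(", ".": "."}
    return "".join(swap[c] for c in reversed(dot))
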