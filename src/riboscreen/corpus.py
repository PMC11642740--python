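"""Corpus ingestion, sanitization and preprocessing.

Reads riboswitch and 5'UTR corpora into uniform :class:`SequenceRecord`
objects: IUPAC ambiguity codes are collapsed to unambiguous RNA, ligand
names are canonicalized against a controlled vocabulary, exact-duplicate
sequences are dropped, and 5'UTRs are extended with their coding-start
context and trimmed to a fixed 3'-anchored window.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: Minimum retained sequence length (NT). Shorter records are rejected;
#: this matches the smallest sequence observed in the reference corpora.
MIN_LENGTH = 25

#: Number of coding-region nucleotides appended to each 5'UTR
#: (the AUG start codon plus 22 downstream NT).
CDS_CONTEXT = 25

#: 3'-anchored length cap applied to preprocessed 5'UTRs (NT).
UTR_CAP = 300

# IUPAC ambiguity codes collapse to the first matching base in the
# order A, C, G, U.  T maps to U before this substitution is applied.
IUPAC_SUBSTITUTION = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "A",  # A/G
    "Y": "C",  # C/U
    "S": "G",  # C/G
    "W": "A",  # A/U
    "K": "G",  # G/U
    "M": "A",  # A/C
    "B": "C",  # C/G/U
    "D": "A",  # A/G/U
    "H": "A",  # A/C/U
    "V": "A",  # A/C/G
    "N": "A",  # any
}

ROLES = ("positive", "unlabeled", "negative_control")


class SequenceError(ValueError):
    """Raised for sequences that cannot be sanitized or preprocessed."""


@dataclass
class SequenceRecord:
    """One sanitized RNA sequence with its screening role.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header word).
    sequence : str
        RNA over {A, C, G, U}; sanitize on construction if needed.
    role : str
        ``"positive"`` (known riboswitch), ``"unlabeled"`` (5'UTR) or
        ``"negative_control"``.
    ligand : str, optional
        Canonical ligand class; required for positives.
    gene : str, optional
        Downstream gene symbol, if known.
    source_length : int, optional
        Length before any trimming; defaults to ``len(sequence)``.
    flags : list of str
        Non-fatal preprocessing flags (e.g. ``"cds_no_aug"``).
    """

    id: str
    sequence: str
    role: str = "unlabeled"
    ligand: str | None = None
    gene: str | None = None
    source_length: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.sequence = sanitize_sequence(self.sequence)
        if self.source_length is None:
            self.source_length = len(self.sequence)
        if len(self.sequence) < MIN_LENGTH:
            raise SequenceError(
                f"record {self.id!r}: length {len(self.sequence)} < minimum {MIN_LENGTH}"
            )
        if self.role == "positive" and self.ligand is None:
            raise ValueError(f"positive record {self.id!r} requires a ligand label")

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_sequence(raw: str) -> str:
    """Collapse an IUPAC nucleotide string to unambiguous uppercase RNA.

    T is mapped to U, then every ambiguity code is replaced by the first
    matching base in the order A, C, G, U (R→A, Y→C, S→G, W→A, K→G, M→A,
    B→C, D→A, H→A, V→A, N→A).  Length is preserved.  Idempotent.

    Raises
    ------
    SequenceError
        If ``raw`` is empty or contains a non-IUPAC character (the error
        message names the 1-based offending position).
    """
    if not raw:
        raise SequenceError("empty sequence")
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        ch = "U" if ch == "T" else ch
        try:
            out.append(IUPAC_SUBSTITUTION[ch])
        except KeyError:
            raise SequenceError(
                f"non-IUPAC character {ch!r} at position {pos}"
            ) from None
    return "".join(out)


# ---------------------------------------------------------------------------
# Ligand canonicalization
# ---------------------------------------------------------------------------

#: Ligand classes that are speculative or synthetic and collapse to "unknown".
_UNKNOWN_CLASSES = {"nha-i motif", "nha-i", "duf1646", "raia", "synthetic", "sul1", "blank", ""}

#: Exact lowercase synonym table applied before the rule-based passes.
_LIGAND_SYNONYMS = {
    "mn": "Mn2+",
    "manganese": "Mn2+",
    "mn2+": "Mn2+",
    "mg": "Mg2+",
    "magnesium": "Mg2+",
    "mg2+": "Mg2+",
    "ni/co": "Ni/Co",
    "nickel/cobalt": "Ni/Co",
    "thiamine pyrophosphate": "TPP",
    "tpp": "TPP",
    "thf": "tetrahydrofolate",
    "s-adenosyl methionine": "SAM",
    "s-adenosylmethionine": "SAM",
    "sam": "SAM",
    "fmn": "FMN",
    "flavin mononucleotide": "FMN",
    "zmp-ztp": "zmp-ztp",
    "zmp/ztp": "zmp-ztp",
    "ado-cbl": "cobalamin",
    "aqcbl": "cobalamin",
    "gmp": "GMP",
    "ppgpp": "(p)ppGpp",
    "(p)ppgpp": "(p)ppGpp",
    "pre-q1": "Pre-Q1",
    "preq1": "Pre-Q1",
}


def canonicalize_ligand(raw_ligand: str) -> str:
    """Map a raw ligand annotation onto the controlled vocabulary.

    Synonyms referring to the same small molecule merge (``"mn"``,
    ``"manganese"`` and ``"Mn2+"`` all become ``"Mn2+"``), cobalamin
    subtypes merge under ``"cobalamin"``, protein-specific ligands under
    ``"protein"``, tRNA variants under ``"tRNA"``, and speculative or
    synthetic classes become ``"unknown"``.  Idempotent; unrecognized
    names pass through verbatim with a logged note.
    """
    name = raw_ligand.strip()
    low = name.lower()
    if low in _UNKNOWN_CLASSES:
        return "unknown"
    if low in _LIGAND_SYNONYMS:
        return _LIGAND_SYNONYMS[low]
    if "cobalamin" in low or low in {"b12", "vitamin b12"}:
        return "cobalamin"
    if "trna" in low:
        return "tRNA"
    if "protein" in low or low.startswith("ribosomal protein"):
        return "protein"
    # Title-cased members of the vocabulary come through unchanged but
    # case-folded consistently when they are already canonical.
    if name != low and name == name.upper():
        return name
    return name


def load_ligand_table(path: str | os.PathLike) -> dict[str, str]:
    """Read a delimited annotation table (id, ligand[, gene]) to a dict.

    The delimiter is inferred from the extension (.tsv/.txt → tab,
    otherwise comma); ligands are canonicalized on load.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "id" not in df.columns or "ligand" not in df.columns:
        raise ValueError(f"annotation table {path} must have 'id' and 'ligand' columns")
    out = {}
    for _, row in df.iterrows():
        canon = canonicalize_ligand(row["ligand"])
        if canon == row["ligand"].strip():
            pass
        elif canon not in ("unknown",) and canon.lower() != row["ligand"].strip().lower():
            log.debug("ligand %r canonicalized to %r", row["ligand"], canon)
        out[row["id"]] = canon
    return out


def write_ligand_table(mapping: dict[str, str], path: str | os.PathLike) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(
        {"id": list(mapping), "ligand": list(mapping.values())}
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Deduplication and UTR preprocessing
# ---------------------------------------------------------------------------

def deduplicate(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Drop exact-sequence duplicates, keeping the first occurrence.

    Order-stable and idempotent; identity is the full sequence string.
    """
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def preprocess_utr(utr: str, cds: str) -> tuple[str, list[str]]:
    """Append the coding-start context to a 5'UTR and apply the length cap.

    The first :data:`CDS_CONTEXT` (25) NT of the coding sequence — the AUG
    start codon plus 22 downstream NT — are appended to the sanitized UTR.
    If the result exceeds :data:`UTR_CAP` (300) NT only the last 300 NT are
    kept, anchored at the 3' end so the start-codon context always
    survives.  Output length is therefore ``min(len(utr) + 25, 300)``.

    Returns
    -------
    (sequence, flags)
        The processed sequence and a list of non-fatal flags
        (``"cds_no_aug"`` when the CDS does not begin with a start codon).

    Raises
    ------
    SequenceError
        If the CDS is shorter than 25 NT.
    """
    utr = sanitize_sequence(utr)
    cds = sanitize_sequence(cds)
    if len(cds) < CDS_CONTEXT:
        raise SequenceError(
            f"coding sequence has {len(cds)} NT; need at least {CDS_CONTEXT} "
            "(start codon + 22 downstream)"
        )
    flags = []
    if not cds.startswith("AUG"):
        warnings.warn("coding sequence does not begin with AUG; record flagged")
        flags.append("cds_no_aug")
    merged = utr + cds[:CDS_CONTEXT]
    if len(merged) > UTR_CAP:
        merged = merged[-UTR_CAP:]
    return merged, flags


# ---------------------------------------------------------------------------
# FASTA and table I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, role: str = "unlabeled",
               ligands: dict[str, str] | None = None,
               min_length: int = MIN_LENGTH) -> list[SequenceRecord]:
    """Read a FASTA file into sanitized records.

    Sequences are uppercased and sanitized; records shorter than
    ``min_length`` after sanitization are dropped with a warning.  For
    ``role="positive"`` a ligand mapping must supply each id's label;
    ids missing from the mapping get ligand ``"unknown"``.
    """
    path = os.fspath(path)
    _validate_fasta(path)
    records = []
    n_short = 0
    for seq_rec in SeqIO.parse(path, "fasta"):
        seq = str(seq_rec.seq)
        ligand = None
        if role == "positive":
            ligand = (ligands or {}).get(seq_rec.id, "unknown")
        try:
            records.append(
                SequenceRecord(id=seq_rec.id, sequence=seq, role=role, ligand=ligand)
            )
        except SequenceError:
            n_short += 1
    if n_short:
        warnings.warn(f"{path}: dropped {n_short} record(s) shorter than {min_length} NT")
    if not records:
        warnings.warn(f"{path}: no usable records")
    return records


def _validate_fasta(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, expected '>' header at line {lineno}"
                    )
                return
    # empty file: handled by the caller as an empty record list


def write_fasta(records: Sequence[SequenceRecord], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        os.fspath(path),
        "fasta",
    )


def read_structure_table(path: str | os.PathLike) -> dict[str, tuple[str, float]]:
    """Read a precomputed-structure table: CSV columns id, dot, mfe."""
    df = pd.read_csv(path, dtype={"id": str, "dot": str})
    return {row["id"]: (row["dot"], float(row["mfe"])) for _, row in df.iterrows()}


def write_structure_table(structures: dict[str, tuple[str, float]],
                          path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(k, d, m) for k, (d, m) in structures.items()],
        columns=["id", "dot", "mfe"],
    ).to_csv(path, index=False)


def write_results_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an ensemble/similarity result table as CSV."""
    df.to_csv(path, index=False)


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
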