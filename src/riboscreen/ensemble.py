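"""Ligand-holdout ensemble training, J_Ensemble scoring and truncation scans.

The screening ensemble is built from leave-ligand-out splits of the
positive (riboswitch) corpus: one PU classifier per split, each trained
on all positives except a withheld ligand class (or pair of classes, or
the joint set of rare classes) against the unlabeled corpus.  Validating
each member on the structural class it never saw estimates how well the
ensemble extrapolates to riboswitches outside the training data.

Per sequence, the ensemble reports each member's raw PU output, the
ensemble score

    J_Ensemble(x) = (1/m) Σ_i  PU_i(x) / max_i,

where max_i is member i's maximum output over all known positives, and
a hit flag that is true only when every member's *raw* output reaches
the hit threshold (default 0.95).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd

from .features import CorpusNormalizer, featurize
from .pu import ElkanNotoClassifier, default_base_learner
from .structure import fold

__all__ = [
    "REFERENCE_LIGAND_PAIRS", "HoldoutSplit", "build_holdout_splits", "EnsembleConfig",
    "Ensemble", "train_ensemble", "score_ensemble", "cut_sites",
    "subsequence_scan", "save_ensemble", "load_ensemble",
]

#: The nine ligand pairs withheld by the double-holdout members.
REFERENCE_LIGAND_PAIRS: list[tuple[str, str]] = [
    ("FMN", "glycine"), ("FMN", "SAM"), ("FMN", "TPP"), ("FMN", "cobalamin"),
    ("TPP", "cobalamin"), ("TPP", "glycine"), ("TPP", "SAM"),
    ("cobalamin", "SAM"), ("cobalamin", "TPP"),
]


@dataclass(frozen=True)
class HoldoutSplit:
    """One train/validation split defined by withheld ligand classes."""

    name: str
    withheld: frozenset[str]
    kind: str  # "single" | "pair" | "other"


def build_holdout_splits(ligands: list[str] | np.ndarray,
                         threshold: float = 0.02,
                         pairs: list[tuple[str, str]] | None = None,
                         ) -> list[HoldoutSplit]:
    """Leave-ligand-out splits from a positive corpus' ligand labels.

    One *single* split per class at or above ``threshold`` representation
    (most-represented first), one *pair* split per entry of ``pairs``
    whose members are both present (missing pairs are skipped with a
    warning), and one *other* split jointly withholding every
    under-represented class (skipped with a warning when no class falls
    below the threshold).
    """
    ligands = [str(x) for x in ligands]
    counts = pd.Series(ligands).value_counts()
    frac = counts / counts.sum()
    majors = [c for c in counts.index if frac[c] >= threshold]
    minors = [c for c in counts.index if frac[c] < threshold]
    splits = [HoldoutSplit(c, frozenset([c]), "single") for c in majors]
    for a, b in (REFERENCE_LIGAND_PAIRS if pairs is None else pairs):
        if a in counts.index and b in counts.index:
            splits.append(HoldoutSplit(f"{a}+{b}", frozenset([a, b]), "pair"))
        else:
            warnings.warn(f"pair ({a}, {b}) skipped: member absent from corpus")
    if minors:
        splits.append(HoldoutSplit("other", frozenset(minors), "other"))
    else:
        warnings.warn("no class below threshold; 'other' split skipped")
    return splits


@dataclass
class EnsembleConfig:
    """Tunable knobs for training and hit calling.

    ``val_threshold`` scores validation/training accuracy (output ≥ 0.5
    counts as a riboswitch call); ``hit_threshold`` is the stricter raw
    output cut (0.95) every member must reach for a hit.
    """

    val_threshold: float = 0.5
    hit_threshold: float = 0.95
    holdout_fraction: float = 0.1
    seed: int = 0
    base_learner_factory: object = None  # callable(seed) -> estimator


@dataclass
class Ensemble:
    """A fitted ligand-holdout ensemble with its scoring context."""

    members: list[ElkanNotoClassifier]
    splits: list[HoldoutSplit]
    member_max: np.ndarray          # max_i over all training positives
    normalizer: CorpusNormalizer
    config: EnsembleConfig
    report: pd.DataFrame = field(default=None, repr=False)

    def raw_outputs(self, X: np.ndarray) -> np.ndarray:
        """(n, m) matrix of raw member PU outputs."""
        if not self.members:
            raise ValueError("ensemble has no members")
        return np.column_stack([m.predict_proba(X) for m in self.members])


def train_ensemble(X_pos: np.ndarray, pos_ligands: list[str] | np.ndarray,
                   X_unl: np.ndarray, splits: list[HoldoutSplit] | None = None,
                   config: EnsembleConfig | None = None,
                   normalizer: CorpusNormalizer | None = None) -> Ensemble:
    """Train one PU classifier per leave-ligand-out split.

    Member i trains on (positives minus its withheld class(es)) flagged
    s = 1 versus the unlabeled corpus flagged s = 0, with per-member seed
    ``config.seed + i`` so parallel and sequential runs agree.  The
    returned report holds, per split, the training accuracy on its
    training positives and the validation accuracy on the withheld
    positives (fraction with raw output ≥ ``val_threshold``).
    """
    config = config or EnsembleConfig()
    X_pos = np.asarray(X_pos, float)
    X_unl = np.asarray(X_unl, float)
    if X_unl.shape[0] == 0:
        raise ValueError("empty unlabeled set")
    ligarr = np.asarray([str(x) for x in pos_ligands])
    if splits is None:
        splits = build_holdout_splits(ligarr)

    members, rows = [], []
    for i, split in enumerate(splits):
        withheld_mask = np.isin(ligarr, list(split.withheld))
        train_mask = ~withheld_mask
        if train_mask.sum() < 2:
            raise ValueError(f"split {split.name!r} leaves fewer than 2 training positives")
        X_train = np.vstack([X_pos[train_mask], X_unl])
        s = np.concatenate([np.ones(train_mask.sum(), int), np.zeros(len(X_unl), int)])
        factory = config.base_learner_factory or default_base_learner
        clf = ElkanNotoClassifier(
            base_learner=factory(config.seed + i),
            holdout_fraction=config.holdout_fraction,
            seed=config.seed + i,
        ).fit(X_train, s)
        members.append(clf)

        train_out = clf.predict_proba(X_pos[train_mask])
        val_out = clf.predict_proba(X_pos[withheld_mask]) if withheld_mask.any() else np.array([])
        rows.append({
            "split": split.name, "kind": split.kind,
            "n_train_pos": int(train_mask.sum()),
            "n_withheld": int(withheld_mask.sum()),
            "train_accuracy": float(np.mean(train_out >= config.val_threshold)),
            "validation_accuracy": float(np.mean(val_out >= config.val_threshold))
            if val_out.size else np.nan,
            "c": clf.c_,
        })

    ens = Ensemble(members=members, splits=list(splits),
                   member_max=np.ones(len(members)), normalizer=normalizer,
                   config=config, report=pd.DataFrame(rows))
    # Eq.-3 normalizers: each member's maximum over ALL positives,
    # including its own withheld class.
    ens.member_max = ens.raw_outputs(X_pos).max(axis=0)
    return ens


def score_ensemble(ens: Ensemble, X: np.ndarray,
                   ids: list[str] | None = None) -> pd.DataFrame:
    """Score sequences: member outputs, J_Ensemble, n_calling, hit flag.

    J_Ensemble averages per-member outputs normalized by that member's
    maximum over all known positives (each ratio clipped to [0, 1]);
    ``hit`` requires every member's raw output ≥ the hit threshold, and
    ``n_calling`` counts members individually reaching it.
    """
    raw = ens.raw_outputs(np.asarray(X, float))
    denom = np.where(ens.member_max > 0, ens.member_max, 1.0)
    j = np.clip(raw / denom, 0.0, 1.0).mean(axis=1)
    thr = ens.config.hit_threshold
    df = pd.DataFrame(raw, columns=[f"pu_{s.name}" for s in ens.splits])
    df.insert(0, "id", ids if ids is not None else np.arange(len(raw)))
    df["J_ensemble"] = j
    df["n_calling"] = (raw >= thr).sum(axis=1)
    df["hit"] = (raw >= thr).all(axis=1)
    return df


# ---------------------------------------------------------------------------
# Sub-sequence truncation scan
# ---------------------------------------------------------------------------

def cut_sites(length: int, offset: int = 30, n_bins: int = 20,
              anchor: int = 25) -> list[int]:
    """5'-truncation points for the sub-sequence scan.

    ``n_bins`` evenly spaced integer positions in ``[offset,
    start_codon)``, where the start codon sits at ``length - anchor``;
    the first cut is exactly ``offset``, and the anchored start-codon
    context (``anchor`` NT) is never truncated.  If the sequence is too
    short to place ``n_bins`` distinct cuts, fewer are returned with a
    warning.
    """
    start_pos = length - anchor
    if start_pos <= offset:
        raise ValueError(
            f"sequence of length {length} too short to scan (start codon at "
            f"{start_pos} is not past the {offset} NT offset)"
        )
    sites = np.unique(np.floor(
        np.linspace(offset, start_pos, n_bins, endpoint=False)
    ).astype(int))
    if len(sites) < n_bins:
        warnings.warn(
            f"only {len(sites)} distinct cut sites available for length {length}"
        )
    return sites.tolist()


def subsequence_scan(record, ens: Ensemble, backend,
                     normalizer: CorpusNormalizer | None = None,
                     n_bins: int = 20, offset: int = 30,
                     anchor: int = 25, rescue_bins: int = 5) -> pd.DataFrame:
    """Score 3'-anchored truncations of one preprocessed 5'UTR.

    Each suffix past a cut site is refolded with ``backend``,
    refeaturized and scored; the result is long-format with one row per
    bin plus a ``full`` row for the untruncated sequence.  The
    ``rescued`` attribute of the returned frame marks sequences that are
    not full-length hits yet reach J_Ensemble ≥ hit threshold in at
    least ``rescue_bins`` bins.
    """
    normalizer = normalizer or ens.normalizer
    if normalizer is None:
        raise ValueError("a fitted normalizer is required for the scan")
    seq = record.sequence
    sites = cut_sites(len(seq), offset=offset, n_bins=n_bins, anchor=anchor)
    rows = []
    for bin_no, cut in enumerate([0] + sites):
        sub = seq[cut:]
        ss = fold(sub, backend, id=record.id if cut == 0 else None)
        vec = featurize(sub, ss, normalizer).reshape(1, -1)
        scored = score_ensemble(ens, vec, ids=[record.id]).iloc[0]
        rows.append({
            "id": record.id,
            "bin": "full" if cut == 0 else bin_no - 1,
            "cut": cut,
            "fraction_retained": len(sub) / len(seq),
            "J_ensemble": scored["J_ensemble"],
            "hit": bool(scored["hit"]),
        })
    df = pd.DataFrame(rows)
    full_hit = bool(df.loc[df["bin"] == "full", "hit"].iloc[0])
    n_high = int((df.loc[df["bin"] != "full", "J_ensemble"]
                  >= ens.config.hit_threshold).sum())
    df.attrs["rescued"] = (not full_hit) and n_high >= rescue_bins
    df.attrs["n_high_bins"] = n_high
    return df


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_ensemble(ens: Ensemble, out_dir: str | os.PathLike) -> None:
    """Write members, Eq.-3 maxima, normalizer and report to a directory."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    joblib.dump(ens.members, os.path.join(out_dir, "members.joblib"))
    meta = {
        "splits": [{"name": s.name, "withheld": sorted(s.withheld), "kind": s.kind}
                   for s in ens.splits],
        "member_max": ens.member_max.tolist(),
        "config": {
            "val_threshold": ens.config.val_threshold,
            "hit_threshold": ens.config.hit_threshold,
            "holdout_fraction": ens.config.holdout_fraction,
            "seed": ens.config.seed,
        },
    }
    with open(os.path.join(out_dir, "ensemble.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    if ens.normalizer is not None:
        ens.normalizer.to_json(os.path.join(out_dir, "normalizer.json"))
    if ens.report is not None:
        ens.report.to_csv(os.path.join(out_dir, "validation_report.csv"), index=False)


def load_ensemble(out_dir: str | os.PathLike) -> Ensemble:
    out_dir = os.fspath(out_dir)
    with open(os.path.join(out_dir, "ensemble.json")) as fh:
        meta = json.load(fh)
    members = joblib.load(os.path.join(out_dir, "members.joblib"))
    norm_path = os.path.join(out_dir, "normalizer.json")
    normalizer = CorpusNormalizer.from_json(norm_path) if os.path.exists(norm_path) else None
    report_path = os.path.join(out_dir, "validation_report.csv")
    report = pd.read_csv(report_path) if os.path.exists(report_path) else None
    cfg = EnsembleConfig(**meta["config"])
    splits = [HoldoutSplit(d["name"], frozenset(d["withheld"]), d["kind"])
              for d in meta["splits"]]
    return Ensemble(members=members, splits=splits,
                    member_max=np.asarray(meta["member_max"], float),
                    normalizer=normalizer, config=cfg, report=report)
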