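"""Holdout splits, ensemble training/scoring, and the truncation scan."""

import numpy as np
import pandas as pd
import pytest

from riboscreen.ensemble import (
    REFERENCE_LIGAND_PAIRS, EnsembleConfig, build_holdout_splits, cut_sites,
    load_ensemble, save_ensemble, score_ensemble, subsequence_scan,
    train_ensemble,
)
from riboscreen.simulate import (
    FixtureSpec, fixture_backend, generate_random, generate_riboswitch_utrs,
)


def reference_shaped_ligands(n=2000):
    """A ligand list with exactly ten classes ≥ 2% plus a sub-2% tail."""
    majors = ["cobalamin", "TPP", "SAM", "glycine", "FMN", "purine",
              "lysine", "fluoride", "zmp-ztp", "guanidine"]
    weights = [232, 184, 128, 71, 63, 39, 34, 29, 27, 24]
    tail = {"Mg2+": 15, "molybdenum": 14, "unknown": 14, "GMP": 8}
    ligs = []
    for name, w in list(zip(majors, weights)) + list(tail.items()):
        ligs.extend([name] * w)
    return ligs


class TestHoldoutSplits:
    def test_reference_shaped_distribution_yields_twenty_splits(self):
        splits = build_holdout_splits(reference_shaped_ligands())
        assert len(splits) == 20
        assert sum(s.kind == "single" for s in splits) == 10
        assert sum(s.kind == "pair" for s in splits) == 9
        assert sum(s.kind == "other" for s in splits) == 1
        # every ligand class is withheld at least once across the scheme
        withheld_union = set().union(*(s.withheld for s in splits))
        assert withheld_union == set(reference_shaped_ligands())

    def test_validation_sets_disjoint_from_training_positives(self):
        ligs = np.array(reference_shaped_ligands())
        for split in build_holdout_splits(ligs):
            train = ligs[~np.isin(ligs, list(split.withheld))]
            assert not set(train) & split.withheld

    def test_all_major_classes_skips_other_with_warning(self):
        ligs = ["TPP"] * 50 + ["SAM"] * 50
        with pytest.warns(UserWarning, match="other"):
            splits = build_holdout_splits(ligs)
        assert all(s.kind != "other" for s in splits)

    def test_three_classes_only_singles_plus_present_pairs(self):
        ligs = ["TPP"] * 40 + ["SAM"] * 30 + ["FMN"] * 30
        with pytest.warns(UserWarning):
            splits = build_holdout_splits(ligs)
        singles = [s for s in splits if s.kind == "single"]
        pairs = [s for s in splits if s.kind == "pair"]
        assert len(singles) == 3
        expected_pairs = [p for p in REFERENCE_LIGAND_PAIRS
                          if set(p) <= {"TPP", "SAM", "FMN"}]
        assert len(pairs) == len(expected_pairs)


class TestTrainAndScore:
    def test_report_shows_extrapolation_to_withheld_classes(self, world):
        rep = world["ensemble"].report
        assert (rep["validation_accuracy"] > 0.8).all()
        assert (rep["train_accuracy"] > 0.8).all()
        assert ((rep["c"] > 0) & (rep["c"] <= 1)).all()

    def test_empty_unlabeled_rejected(self, world):
        with pytest.raises(ValueError, match="unlabeled"):
            train_ensemble(world["X_pos"], world["ligands"],
                           np.empty((0, 74)), splits=world["splits"][:1])

    def test_j_ensemble_bounds_and_hit_rule(self, world):
        ens = world["ensemble"]
        for X in (world["X_pos"], world["X_unl"], world["X_rnd"]):
            df = score_ensemble(ens, X)
            assert df["J_ensemble"].between(0, 1).all()
            raw = ens.raw_outputs(X)
            np.testing.assert_array_equal(
                df["hit"].to_numpy(), (raw >= ens.config.hit_threshold).all(axis=1))
            np.testing.assert_array_equal(
                df["n_calling"].to_numpy(),
                (raw >= ens.config.hit_threshold).sum(axis=1))

    def test_sequence_scoring_its_own_member_max_gets_j_one(self, world):
        ens = world["ensemble"]
        raw = ens.raw_outputs(world["X_pos"])
        # synthetic row at each member's maximum
        df = score_ensemble(ens, world["X_pos"][[int(raw[:, 0].argmax())]])
        assert df["J_ensemble"].iloc[0] <= 1.0

    def test_hit_set_nesting_monotone_in_member_agreement(self, world):
        df = score_ensemble(world["ensemble"], world["X_unl"])
        sizes = [(df["n_calling"] >= k).sum()
                 for k in range(len(world["ensemble"].members) + 1)]
        assert sizes == sorted(sizes, reverse=True)

    def test_scores_invariant_under_input_duplication(self, world):
        ens = world["ensemble"]
        X = world["X_pos"][:10]
        a = score_ensemble(ens, X)["J_ensemble"].to_numpy()
        b = score_ensemble(ens, np.vstack([X, X]))["J_ensemble"].to_numpy()
        np.testing.assert_allclose(np.concatenate([a, a]), b)

    def test_training_is_deterministic_under_fixed_seed(self, world):
        cfg = EnsembleConfig(seed=13)
        kw = dict(splits=world["splits"][:2], config=cfg,
                  normalizer=world["norm"])
        e1 = train_ensemble(world["X_pos"], world["ligands"], world["X_unl"], **kw)
        e2 = train_ensemble(world["X_pos"], world["ligands"], world["X_unl"], **kw)
        np.testing.assert_array_equal(e1.member_max, e2.member_max)
        np.testing.assert_allclose(
            e1.raw_outputs(world["X_rnd"]), e2.raw_outputs(world["X_rnd"]))

    def test_calls_withheld_positives_and_rejects_random_controls(self, world):
        """Extrapolation + specificity: members call > 80% of their withheld
        structured class, and < 1% of random controls reach the call
        threshold from any member."""
        rep = world["ensemble"].report
        assert (rep["validation_accuracy"] > 0.8).all()
        raw = world["ensemble"].raw_outputs(world["X_rnd"])
        frac_called = (raw >= world["ensemble"].config.val_threshold).any(axis=1).mean()
        assert frac_called < 0.01

    def test_extra_negative_data_leaves_strong_hits_stable(self, world):
        """Retraining with additional random-control unlabeled data keeps
        ≥ 90% of the strongly-positive class' hit flags unchanged."""
        ens = world["ensemble"]
        base_hits = score_ensemble(ens, world["X_pos"])["hit"]
        strong = base_hits[base_hits].index
        extra_rnd, extra_ss = generate_random(100, world["spec"], seed=77)
        from riboscreen import featurize_corpus
        X_extra = featurize_corpus(extra_rnd, extra_ss, world["norm"])
        ens2 = train_ensemble(
            world["X_pos"], world["ligands"],
            np.vstack([world["X_unl"], X_extra]),
            splits=world["splits"][:5], config=EnsembleConfig(seed=7),
            normalizer=world["norm"])
        new_hits = score_ensemble(ens2, world["X_pos"])["hit"]
        agreement = (new_hits[strong]).mean()
        assert agreement >= 0.9

    def test_save_load_round_trip(self, world, tmp_path):
        ens = world["ensemble"]
        save_ensemble(ens, tmp_path / "ens")
        back = load_ensemble(tmp_path / "ens")
        np.testing.assert_array_equal(back.member_max, ens.member_max)
        np.testing.assert_allclose(back.raw_outputs(world["X_pos"][:5]),
                                   ens.raw_outputs(world["X_pos"][:5]))
        assert [s.name for s in back.splits] == [s.name for s in ens.splits]


class TestCutSites:
    def test_stated_rule_for_430_nt(self):
        sites = cut_sites(430, offset=30, n_bins=20)
        assert len(sites) == 20
        assert sites[0] == 30
        assert all(30 <= c < 405 for c in sites)  # start codon at 405
        steps = np.diff(sites)
        assert steps.max() - steps.min() <= 1  # evenly spaced integers

    @pytest.mark.parametrize("length", [100, 157, 300, 476, 1000])
    def test_anchor_never_truncated(self, length):
        for c in cut_sites(length):
            assert c < length - 25

    def test_short_sequences_get_fewer_bins_with_warning(self):
        with pytest.warns(UserWarning, match="distinct cut sites"):
            sites = cut_sites(60, offset=30, n_bins=20)
        assert 0 < len(sites) < 20

    def test_too_short_to_scan_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            cut_sites(55, offset=30, n_bins=20)


@pytest.fixture(scope="module")
def scan_world(world):
    hits, hit_ss = generate_riboswitch_utrs(world["spec"], n=10, seed=3)
    backend = fixture_backend(hit_ss, records=hits)
    return hits, hit_ss, backend


class TestSubsequenceScan:
    def test_full_length_hits_stay_high_in_most_complete_bin(self, world, scan_world):
        hits, hit_ss, backend = scan_world
        from riboscreen import featurize_corpus, fold
        sss = {r.id: fold(r.sequence, backend, id=r.id) for r in hits}
        X = featurize_corpus(hits, sss, world["norm"])
        full = score_ensemble(world["ensemble"], X, ids=[r.id for r in hits])
        called = set(full.loc[full["hit"], "id"])
        assert called  # the planted switches are detectable at full length
        thr = world["ensemble"].config.hit_threshold
        for rec in hits:
            df = subsequence_scan(rec, world["ensemble"], backend,
                                  normalizer=world["norm"])
            bins = df[df["bin"] != "full"]
            assert df["J_ensemble"].between(0, 1).all()
            assert len(bins) == 20
            if rec.id in called:
                assert bins.iloc[0]["J_ensemble"] >= thr

    def test_unstructured_sequence_never_scores_as_switch(self, world):
        spec = FixtureSpec(seed=5, length_mean=250, length_min=200)
        rnd, rnd_ss = generate_random(1, spec, seed=50)
        rec = rnd[0]
        assert len(rec.sequence) >= 200
        backend = fixture_backend(rnd_ss, records=rnd)
        df = subsequence_scan(rec, world["ensemble"], backend,
                              normalizer=world["norm"])
        assert (df["J_ensemble"] < 0.95).all()
        assert not df.attrs["rescued"]

    def test_rescued_flag_requires_five_high_bins(self, world, scan_world):
        hits, hit_ss, backend = scan_world
        df = subsequence_scan(hits[0], world["ensemble"], backend,
                              normalizer=world["norm"])
        full_hit = bool(df.loc[df["bin"] == "full", "hit"].iloc[0])
        n_high = df.attrs["n_high_bins"]
        assert df.attrs["rescued"] == ((not full_hit) and n_high >= 5)
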