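"""Jaccard robustness, classifier scores, R-squared, MI, entropy, annotation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countseg.binning import CountMatrix, make_bins
from countseg.hmm import Posterior, Segmentation
from countseg.validation import (
    AnnotationConfig,
    average_jaccard,
    categorical_r2,
    classifier_scores,
    mutual_information,
    posterior_entropy_profile,
    supervised_annotate,
)


def seg_from(labels_by_chrom, k, bin_size=200, offset=0):
    scheme = make_bins(
        {c: len(v) * bin_size for c, v in labels_by_chrom.items()},
        bin_size=bin_size,
        offset=offset,
    )
    return Segmentation(
        scheme=scheme, k=k, labels={c: np.asarray(v) for c, v in labels_by_chrom.items()}
    )


def brute_force_jaccard(seg_a, seg_b):
    """Maximum average Jaccard over all one-to-one matchings, by enumeration."""
    a, b = seg_a.stacked(), seg_b.stacked()
    wa = np.concatenate([seg_a.scheme.bin_widths(c) for c in seg_a.scheme.chrom_names])
    ka, kb = seg_a.k, seg_b.k
    inter = np.zeros((ka, kb))
    np.add.at(inter, (a, b), wa)
    size_a, size_b = inter.sum(axis=1), inter.sum(axis=0)
    best = 0.0
    small, large = (ka, kb) if ka <= kb else (kb, ka)
    for perm in itertools.permutations(range(large), small):
        total = 0.0
        for i, j in enumerate(perm):
            ai, bj = (i, j) if ka <= kb else (j, i)
            union = size_a[ai] + size_b[bj] - inter[ai, bj]
            if union > 0:
                total += inter[ai, bj] / union
        best = max(best, total / max(ka, kb))
    return best


class TestAverageJaccard:
    def test_identity(self):
        seg = seg_from({"c": [0, 1, 2, 1, 0]}, k=3)
        match = average_jaccard(seg, seg)
        assert match.jaccard == pytest.approx(1.0)
        assert match.mapping == {0: 0, 1: 1, 2: 2}

    def test_permuted_labels_recovered(self):
        labels = np.array([0, 1, 2, 0, 1, 2, 2, 0])
        perm = np.array([1, 2, 0])
        seg_a = seg_from({"c": labels}, k=3)
        seg_b = seg_from({"c": perm[labels]}, k=3)
        match = average_jaccard(seg_a, seg_b)
        assert match.jaccard == pytest.approx(1.0)
        assert match.mapping == {s: int(perm[s]) for s in range(3)}

    def test_hand_example(self):
        """Overlaps {A0B0=4, A0B1=1, A1B0=1, A1B1=4} over 10 equal bins give
        J = ((4/6) + (4/6)) / 2 = 2/3 under the identity matching."""
        seg_a = seg_from({"c": [0] * 5 + [1] * 5}, k=2)
        seg_b = seg_from({"c": [0] * 4 + [1] + [0] + [1] * 4}, k=2)
        match = average_jaccard(seg_a, seg_b)
        assert match.jaccard == pytest.approx(2 / 3)
        assert match.jaccard == pytest.approx(brute_force_jaccard(seg_a, seg_b))

    @given(
        labels_a=st.lists(st.integers(0, 3), min_size=4, max_size=40),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_and_symmetry(self, labels_a, data):
        labels_b = data.draw(
            st.lists(st.integers(0, 2), min_size=len(labels_a), max_size=len(labels_a))
        )
        seg_a = seg_from({"c": labels_a}, k=4)
        seg_b = seg_from({"c": labels_b}, k=3)
        ab = average_jaccard(seg_a, seg_b).jaccard
        ba = average_jaccard(seg_b, seg_a).jaccard
        assert ab == pytest.approx(ba, abs=1e-12)
        assert ab == pytest.approx(brute_force_jaccard(seg_a, seg_b), abs=1e-12)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(0)
        la, lb = rng.integers(0, 3, 60), rng.integers(0, 3, 60)
        base = average_jaccard(seg_from({"c": la}, k=3), seg_from({"c": lb}, k=3)).jaccard
        perm = np.array([2, 0, 1])
        again = average_jaccard(
            seg_from({"c": perm[la]}, k=3), seg_from({"c": lb}, k=3)
        ).jaccard
        assert base == pytest.approx(again, abs=1e-12)

    def test_offset_schemes_compared_at_base_pair_level(self):
        """Identical genomes binned at offsets 0 and 100 remain comparable."""
        seg_a = seg_from({"c": [0] * 5 + [1] * 5}, k=2, bin_size=200)
        scheme_b = make_bins({"c": 2000}, bin_size=200, offset=100)
        assert scheme_b.n_bins("c") == 11
        seg_b = Segmentation(
            scheme=scheme_b, k=2, labels={"c": np.array([0] * 6 + [1] * 5)}
        )
        match = average_jaccard(seg_a, seg_b, unit="bp")
        # boundaries differ by 100 bp: state 0 spans [0,1000) vs [0,1100)
        assert match.per_state[0] == pytest.approx(1000 / 1100)

    def test_different_genomes_rejected(self):
        seg_a = seg_from({"c": [0, 1]}, k=2)
        seg_b = seg_from({"d": [0, 1]}, k=2)
        with pytest.raises(ValueError):
            average_jaccard(seg_a, seg_b)


class TestClassifierScores:
    def test_perfect_state(self):
        seg = seg_from({"c": [0, 0, 1, 1]}, k=2)
        mask = {"c": np.array([True, True, False, False])}
        scores, best = classifier_scores(seg, mask)
        assert scores[0].tolist() == [1.0, 1.0]
        assert best == 0

    def test_hand_tally(self):
        """State 0 covers 5 bins, 3 positive of 4 total -> precision 0.6,
        sensitivity 0.75; the complement state scores 0.2 / 0.25."""
        seg = seg_from({"c": [0] * 5 + [1] * 5}, k=2)
        mask = {"c": np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0], dtype=bool)}
        scores, best = classifier_scores(seg, mask)
        assert scores[0, 0] == pytest.approx(0.6)
        assert scores[0, 1] == pytest.approx(0.75)
        assert scores[1, 0] == pytest.approx(0.2)
        assert scores[1, 1] == pytest.approx(0.25)
        assert best == 0

    def test_true_positives_partition_positives(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, 100)
        mask = {"c": rng.random(100) < 0.3}
        seg = seg_from({"c": labels}, k=4)
        scores, _ = classifier_scores(seg, mask)
        assert np.all((scores >= 0) & (scores <= 1))
        assert scores[:, 1].sum() == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        seg = seg_from({"c": [0, 1]}, k=2)
        with pytest.raises(ValueError):
            classifier_scores(seg, {"c": np.zeros(2, dtype=bool)})


class TestCategoricalR2:
    def test_response_constant_within_states(self):
        seg = seg_from({"c": [0, 0, 1, 1, 2, 2]}, k=3)
        r2 = categorical_r2(seg, {"c": np.array([5.0, 5.0, 1.0, 1.0, 9.0, 9.0])})
        assert r2 == pytest.approx(1.0)

    def test_hand_ols(self):
        """labels [0,0,0,1,1,1], response [1,2,3,11,12,13]: R^2 = 75/77."""
        seg = seg_from({"c": [0, 0, 0, 1, 1, 1]}, k=2)
        r2 = categorical_r2(seg, {"c": np.array([1.0, 2, 3, 11, 12, 13])})
        assert r2 == pytest.approx(75 / 77, abs=1e-12)

    def test_independent_response_near_zero(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, 20_000)
        seg = seg_from({"c": labels}, k=3)
        r2 = categorical_r2(seg, {"c": rng.normal(size=20_000)})
        assert 0 <= r2 < 0.001

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, 500)
        y = rng.normal(size=500) + labels
        seg = seg_from({"c": labels}, k=3)
        a = categorical_r2(seg, {"c": y})
        b = categorical_r2(seg, {"c": 3.5 * y - 11.0})
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_statsmodels_ols(self):
        """Cross-check against an independent OLS fit with state dummies."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, 300)
        y = rng.normal(size=300) + 2.0 * labels
        seg = seg_from({"c": labels}, k=4)
        dummies = np.eye(4)[labels]
        fit = sm.OLS(y, dummies).fit()
        assert categorical_r2(seg, {"c": y}) == pytest.approx(fit.rsquared, abs=1e-10)

    def test_zero_variance_rejected(self):
        seg = seg_from({"c": [0, 1]}, k=2)
        with pytest.raises(ValueError):
            categorical_r2(seg, {"c": np.array([3.0, 3.0])})


class TestMutualInformation:
    def test_independent_table_zero(self):
        # labels and annotation in a perfect product layout
        labels = np.repeat([0, 1], 8)
        ann = np.tile(np.repeat(["x", "y"], 4), 2)
        seg = seg_from({"c": labels}, k=2)
        assert mutual_information(seg, {"c": ann}, exclude=()) == pytest.approx(0.0, abs=1e-12)

    def test_identical_uniform_four_class(self):
        labels = np.repeat([0, 1, 2, 3], 10)
        ann = np.repeat(["a", "b", "c", "d"], 10)
        seg = seg_from({"c": labels}, k=4)
        assert mutual_information(seg, {"c": ann}, exclude=()) == pytest.approx(2.0)

    def test_small_table_against_direct_sum(self):
        """2x2 table [[2,1],[1,2]] computed by the plug-in formula by hand."""
        labels = np.array([0, 0, 0, 1, 1, 1])
        ann = np.array(["a", "a", "b", "a", "b", "b"])
        seg = seg_from({"c": labels}, k=2)
        expected = 0.0
        joint = np.array([[2, 1], [1, 2]]) / 6
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        expected = float((joint * np.log2(joint / (px * py))).sum())
        assert mutual_information(seg, {"c": ann}, exclude=()) == pytest.approx(expected, abs=1e-12)

    def test_excluded_labels_dropped(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        ann = np.array(["a", "gap", "b", "b", "unannotated", "b"])
        seg = seg_from({"c": labels}, k=2)
        mi = mutual_information(seg, {"c": ann})
        # remaining 4 bins map states to labels deterministically: MI = H(state)
        h = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert mi == pytest.approx(h, abs=1e-12)

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, 400)
        ann = np.array(list("abcd"))[rng.integers(0, 4, 400)]
        seg = seg_from({"c": labels}, k=3)
        mi = mutual_information(seg, {"c": ann}, exclude=())

        def entropy(v):
            _, c = np.unique(v, return_counts=True)
            p = c / c.sum()
            return -(p * np.log2(p)).sum()

        assert 0 <= mi <= min(entropy(labels), entropy(ann)) + 1e-12


class TestEntropyProfile:
    def _posterior(self, gamma):
        return Posterior(gamma={"c": gamma}, log_likelihood={"c": 0.0})

    def _cm(self, totals):
        mats = {"c": np.asarray(totals, dtype=np.int64)[:, None]}
        scheme = make_bins({"c": len(totals) * 200}, bin_size=200)
        return CountMatrix(scheme=scheme, mark_names=("m",), counts=mats)

    def test_certain_and_uniform_rows(self):
        gamma = np.array([[1.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3], [0.5, 0.5, 0.0]])
        ent, cov, _ = posterior_entropy_profile(
            self._posterior(gamma), self._cm([0, 5, 9]), min_group=1
        )
        assert ent[0] == pytest.approx(0.0)
        assert ent[1] == pytest.approx(np.log2(3))
        assert ent[2] == pytest.approx(1.0)

    def test_grouping_respects_min_size(self):
        rng = np.random.default_rng(6)
        n = 5000
        gamma = rng.dirichlet(np.ones(3), size=n)
        totals = rng.integers(0, 50, n)
        _, _, curve = posterior_entropy_profile(
            self._posterior(gamma), self._cm(totals), min_group=500
        )
        assert np.all(curve[:, 2] >= 500)
        assert curve[:, 2].sum() == n
        assert np.all(np.diff(curve[:, 0]) > 0)  # coverage strictly increasing

    def test_entropy_bounds(self, fixture_results):
        ent, _, curve = fixture_results.entropy_profile()
        k = fixture_results.model.k
        assert np.all((ent >= -1e-12) & (ent <= np.log2(k) + 1e-12))
        assert np.all(curve[:, 1] <= np.log2(k) + 1e-12)


class TestSupervisedAnnotation:
    def _scheme(self, nb=100):
        return make_bins({"c": nb * 200}, bin_size=200)

    def test_all_zero_signals(self):
        scheme = self._scheme()
        nb = 100
        zeros = {"c": np.zeros(nb)}
        gap = {"c": np.zeros(nb, dtype=bool)}
        gap["c"][:5] = True
        ann = supervised_annotate(zeros, zeros, {"c": np.array([0])}, gap, scheme)
        assert set(ann["c"]) <= {"gap", "intergenic", "unannotated"}
        assert np.all(ann["c"][:5] == "gap")

    def test_hand_trace(self):
        """One high-DNase bin at a TSS plus a downstream high-RNA block.

        The background DNase ramp (1..10 repeated) pins the quantiles: the
        0.95 quantile is 10 so only the 1000-count bin is a DNase bin, and the
        0.60 quantile is 5 so the RNA block (DNase forced to 2 there) stays
        below the permissive threshold.
        """
        scheme = self._scheme(100)
        dnase = np.tile(np.arange(1.0, 11.0), 10)
        dnase[40:70] = 2.0
        dnase[10] = 1000.0  # the single DNase bin, at the TSS
        rna = np.zeros(100)
        rna[40:70] = 50.0  # a 6 kb transcribed block
        gap = {"c": np.zeros(100, dtype=bool)}
        cfg = AnnotationConfig(
            dnase_stringent_q=0.95,
            dnase_permissive_q=0.60,
            rna_stringent_q=0.60,
            d_tss=200,
            d_rna=2000,
            d_int=10_000,
        )
        ann = supervised_annotate(
            {"c": dnase}, {"c": rna}, {"c": np.array([10 * 200 + 50])}, gap, scheme, cfg
        )["c"]
        assert ann[10] == "DNase+TSS"
        # RNA bins need 2,000 bp (10 bins) clearance from the block edges at
        # 40 and 69, leaving exactly bins 49..60
        assert np.all(ann[49:61] == "RNA")
        assert np.all(ann[40:49] != "RNA") and np.all(ann[61:70] != "RNA")
        # nothing is far enough from signal to be intergenic on this chromosome
        assert "intergenic" not in set(ann)

    def test_all_dnase_near_tss(self):
        scheme = self._scheme(20)
        dnase = {"c": np.linspace(1, 100, 20)}  # strictly increasing, top bins pass
        rna = {"c": np.zeros(20)}
        tss = {"c": (np.arange(20) * 200 + 100)}
        gap = {"c": np.zeros(20, dtype=bool)}
        ann = supervised_annotate(dnase, rna, tss, gap, scheme)["c"]
        above = np.flatnonzero(dnase["c"] > np.quantile(dnase["c"], 0.95))
        assert np.all(ann[above] == "DNase+TSS")

    def test_dnase_far_from_tss_is_enhancer_like(self):
        scheme = self._scheme(100)
        dnase = np.zeros(100)
        dnase[80] = 100.0
        gap = {"c": np.zeros(100, dtype=bool)}
        cfg = AnnotationConfig(d_tss=1000)
        ann = supervised_annotate(
            {"c": dnase}, {"c": np.zeros(100)}, {"c": np.array([0])}, gap, scheme, cfg
        )["c"]
        assert ann[80] == "DNase-TSS"

    def test_bad_quantile_rejected(self):
        with pytest.raises(ValueError):
            AnnotationConfig(dnase_stringent_q=1.5)

    def test_empty_tss_rejected(self):
        scheme = self._scheme(10)
        z = {"c": np.zeros(10)}
        with pytest.raises(ValueError, match="TSS"):
            supervised_annotate(z, z, {"c": np.array([])}, {"c": np.zeros(10, bool)}, scheme)
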