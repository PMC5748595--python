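import numpy as np
import pandas as pd
import pytest

from brafsig import (
    CohortSpec,
    ExpressionMatrix,
    ValidationError,
    align_to_signature,
    build_templates,
    cohort_composition,
    confusion_metrics,
    expected_specificity,
    generate_cohort,
    loocv_scores,
    make_signature,
    optimize_threshold,
    prescreen_select,
    score_cohort,
    score_sample,
)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i}" for i in range(values.shape[0])],
            columns=[f"S{j}" for j in range(values.shape[1])],
        )
    )


def test_loocv_equals_explicit_fold_loop(rng):
    values = rng.normal(size=(10, 6))
    m = _matrix(values)
    labels = np.array(["mutated"] * 3 + ["wildtype"] * 3)
    got = loocv_scores(m, labels)
    for j in range(6):
        keep = [k for k in range(6) if k != j]
        t = build_templates(
            ExpressionMatrix(m.data.iloc[:, keep]), labels[keep]
        )
        assert got.iloc[j] == pytest.approx(score_sample(values[:, j], t), abs=1e-12)


def test_duplicated_sample_scores_like_full_template(small_cohort):
    """Leaving the duplicate out reproduces the original full-cohort templates."""
    aligned, _, labels, _ = small_cohort
    dup = aligned.data.copy()
    dup["DUP"] = dup.iloc[:, 0]
    m2 = ExpressionMatrix(dup)
    labels2 = np.append(labels, labels[0])
    full_t = build_templates(aligned, labels)
    expected = score_sample(aligned.values[:, 0], full_t)
    got = loocv_scores(m2, labels2)["DUP"]
    assert got == pytest.approx(expected, abs=1e-6)


def test_loocv_degenerate_inputs():
    m = _matrix(np.ones((5, 8)))
    labels = np.array(["mutated"] * 4 + ["wildtype"] * 4)
    with pytest.raises(ValidationError):
        loocv_scores(m, labels)  # zero variance everywhere
    with pytest.raises(ValidationError, match=">= 3"):
        loocv_scores(_matrix(np.random.default_rng(0).normal(size=(5, 4))),
                     ["mutated", "mutated", "wildtype", "wildtype"])


def test_threshold_separable_and_two_point_cases():
    thr = optimize_threshold([1.0, -1.0], ["mutated", "wildtype"])
    assert thr == pytest.approx(0.0)
    acc = np.mean((np.array([1.0, -1.0]) > thr) == np.array([True, False]))
    assert acc == 1.0
    # perfectly separated: lowest optimal midpoint, accuracy 1
    scores = [-3.0, -2.0, 2.0, 3.0]
    labels = ["wildtype", "wildtype", "mutated", "mutated"]
    assert optimize_threshold(scores, labels) == pytest.approx(0.0)


def test_threshold_matches_exhaustive_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 40))
        scores = rng.normal(size=n).round(2)  # rounding forces ties
        labels = rng.choice(["mutated", "wildtype"], size=n)
        if len(set(labels)) < 2:
            continue
        got = optimize_threshold(scores, labels)
        is_mut = labels == "mutated"
        distinct = np.unique(scores)
        cands = np.concatenate(
            ([distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1])
        )
        accs = np.array([np.mean((scores > t) == is_mut) for t in cands])
        best = accs.max()
        assert np.mean((scores > got) == is_mut) == pytest.approx(best)
        assert got == pytest.approx(cands[accs == best].min())


def test_confusion_counts_and_rates(rng):
    calls = rng.choice(["mutation_like", "wildtype_like"], size=50)
    labels = rng.choice(["mutated", "wildtype"], size=50)
    c = confusion_metrics(calls, labels)
    tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for call, lab in zip(calls, labels):
        key = ("t" if (call == "mutation_like") == (lab == "mutated") else "f") + (
            "p" if call == "mutation_like" else "n"
        )
        tally[key] += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (tally["tp"], tally["fp"], tally["fn"], tally["tn"])
    assert c.accuracy == pytest.approx((c.tp + c.tn) / 50)


def test_all_correct_confusion():
    c = confusion_metrics(["mutation_like", "wildtype_like"], ["mutated", "wildtype"])
    assert c.sensitivity == 1.0 and c.specificity == 1.0


def test_expected_specificity_edge_cases():
    assert expected_specificity(0, 245) == 1.0
    assert expected_specificity(245, 245) == 0.0
    with pytest.raises(ValidationError):
        expected_specificity(10, 0)


def test_prescreen_counts_and_determinism(rng):
    scores = pd.Series(rng.normal(size=602), index=[f"P{i}" for i in range(602)])
    sel1 = prescreen_select(scores, 96, 206, seed=4)
    sel2 = prescreen_select(scores, 96, 206, seed=4)
    assert sel1 == sel2 and len(sel1) == 302 and len(set(sel1)) == 302
    top = sorted(scores.sort_values(ascending=False).index[:96])
    assert sorted(sel1[:96]) == top
    # identity selection
    assert set(prescreen_select(scores, len(scores), 0, seed=0)) == set(scores.index)
    with pytest.raises(ValidationError):
        prescreen_select(scores, 600, 3, seed=0)


def test_prescreen_enriches_mutants():
    """Score-ranked selection raises the mutant fraction above the pool's."""
    enriched = 0
    for seed in range(20):
        matrix, ann, _ = generate_cohort(CohortSpec(n_samples=300, n_background_genes=0, seed=seed))
        sig = make_signature(58)
        aligned = align_to_signature(matrix, sig)
        t = build_templates(aligned, ann["braf_status"].to_numpy())
        scores = pd.Series(
            score_cohort(aligned, t, 0.0).score_values, index=aligned.sample_ids
        )
        selected = prescreen_select(scores, 48, 102, seed=seed)
        ann_i = ann.set_index("sample_id")
        sel_frac = (ann_i.loc[selected, "braf_status"] == "mutated").mean()
        pool_frac = (ann["braf_status"] == "mutated").mean()
        enriched += sel_frac > pool_frac
    assert enriched >= 18  # enrichment in essentially every replicate


def test_cohort_composition_tallies():
    ann = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(10)],
            "braf_status": ["mutated"] * 3 + ["wildtype"] * 7,
            "cohort_tag": ["prescreen"] * 4 + ["random"] * 6,
        }
    )
    comp = cohort_composition(ann)
    assert comp.loc["prescreen", "n"] == 4 and comp.loc["prescreen", "n_mutated"] == 3
    assert comp.loc["random", "n_mutated"] == 0
    assert comp.loc["total", "fraction_mutated"] == pytest.approx(0.3)
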