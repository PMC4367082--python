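"""Confusion tabulation and the seven performance statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predbench.harmonization import CanonicalCall, HarmonizedCall
from predbench.metrics import (
    ConfusionSummary,
    compute_metrics,
    metrics_table,
    per_class_correct,
    pool,
    round_report,
    tabulate,
)
from predbench.variant_model import CredibilityLabel

PATH = CredibilityLabel.CREDIBLY_PATHOGENIC
BEN = CredibilityLabel.CREDIBLY_BENIGN
D, P, B, M = (
    CanonicalCall.DAMAGING,
    CanonicalCall.POSSIBLY_DAMAGING,
    CanonicalCall.BENIGN,
    CanonicalCall.MISSING,
)


def hc(vid, call, reliable=True, program="p"):
    return HarmonizedCall(vid, program, call, reliable)


def test_tabulate_perfect_predictor():
    calls = [hc("v1", D), hc("v2", D), hc("v3", D), hc("v4", B)]
    labels = {"v1": PATH, "v2": PATH, "v3": PATH, "v4": BEN}
    cs = tabulate(calls, labels, "p")
    assert (cs.TP, cs.TN, cs.FP, cs.FN) == (3, 1, 0, 0)
    assert cs.VarUse == cs.VarCall == 4


def test_tabulate_mixed_usability():
    """Possible, unreliable and missing calls widen VarCall but not VarUse."""
    calls = [
        hc("v1", D),
        hc("v2", D),
        hc("v3", P),
        hc("v4", D, reliable=False),
        hc("v5", M),
    ]
    labels = {f"v{i}": PATH for i in range(1, 6)}
    cs = tabulate(calls, labels, "p")
    assert cs.TP == 2 and cs.VarUse == 2 and cs.VarCall == 4 and cs.N_dataset == 5


def test_tabulate_empty():
    cs = tabulate([], {}, "p")
    assert (cs.TP, cs.FP, cs.TN, cs.FN, cs.VarUse, cs.VarCall) == (0,) * 6


def test_tabulate_errors():
    with pytest.raises(ValueError, match="no credibility label"):
        tabulate([hc("v1", D)], {}, "p")
    with pytest.raises(ValueError, match="duplicate"):
        tabulate([hc("v1", D), hc("v1", B)], {"v1": PATH}, "p")
    with pytest.raises(ValueError, match="unclassified"):
        tabulate([hc("v1", D)], {"v1": CredibilityLabel.UNCLASSIFIED}, "p")


def test_compute_metrics_known_row():
    """A 27/2/16/2 matrix over 47 usable of 54 emitted calls yields the
    published seven-statistic row for a high-coverage aligner-style program."""
    cs = ConfusionSummary("p", "d", TP=27, FP=2, TN=16, FN=2, VarUse=47, VarCall=54, N_dataset=54)
    m = compute_metrics(cs)
    rounded = [
        round_report(x, 3)
        for x in (m.sensitivity, m.specificity, m.PPV, m.NPV, m.accuracy, m.pweight, m.waccuracy)
    ]
    assert rounded == [0.931, 0.889, 0.931, 0.889, 0.915, 0.870, 0.796]


def test_undefined_metrics_propagate():
    cs = ConfusionSummary("p", "d", TP=5, FP=0, TN=0, FN=0, VarUse=5, VarCall=5, N_dataset=5)
    m = compute_metrics(cs)
    assert m.NPV is None and m.specificity is None
    assert m.waccuracy == 1.0
    empty = compute_metrics(
        ConfusionSummary("p", "d", 0, 0, 0, 0, VarUse=0, VarCall=0, N_dataset=3)
    )
    assert empty.accuracy is None and empty.waccuracy is None and empty.pweight is None


valid_matrices = st.tuples(
    st.integers(0, 100), st.integers(0, 100), st.integers(0, 100),
    st.integers(0, 100), st.integers(0, 50),
).filter(lambda t: sum(t[:4]) > 0)


@settings(max_examples=200, deadline=None)
@given(valid_matrices)
def test_waccuracy_identity(counts):
    """accuracy x pweight == (TP+TN)/VarCall on unrounded arithmetic."""
    tp, fp, tn, fn, extra = counts
    varuse = tp + fp + tn + fn
    cs = ConfusionSummary(
        "p", "d", tp, fp, tn, fn, VarUse=varuse, VarCall=varuse + extra,
        N_dataset=varuse + extra,
    )
    m = compute_metrics(cs)
    assert m.waccuracy == pytest.approx((tp + tn) / cs.VarCall, abs=1e-12)
    for v in (m.PPV, m.NPV, m.specificity, m.sensitivity, m.accuracy, m.pweight, m.waccuracy):
        assert v is None or 0.0 <= v <= 1.0


def test_pweight_is_one_when_every_call_usable():
    calls = [hc("v1", D), hc("v2", B)]
    m = compute_metrics(tabulate(calls, {"v1": PATH, "v2": BEN}, "p"))
    assert m.pweight == 1.0


def test_brute_force_oracle_on_random_datasets():
    """tabulate + compute_metrics agree exactly with a record-by-record
    counting loop on random datasets up to 200 variants x 5 programs."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        n = int(rng.integers(1, 201))
        labels = {f"v{i}": (PATH if rng.random() < 0.5 else BEN) for i in range(n)}
        for prog in [f"p{j}" for j in range(5)]:
            calls = []
            for i in range(n):
                call = [D, P, B, M][int(rng.integers(0, 4))]
                calls.append(hc(f"v{i}", call, bool(rng.random() < 0.8), prog))
            # oracle: independent tallies
            o = {"TP": 0, "FP": 0, "TN": 0, "FN": 0, "varcall": 0, "varuse": 0}
            for c in calls:
                if c.call != M:
                    o["varcall"] += 1
                if c.call in (D, B) and c.reliable:
                    o["varuse"] += 1
                    is_path = labels[c.variant_id] == PATH
                    key = ("T" if (c.call == D) == is_path else "F") + (
                        "P" if c.call == D else "N"
                    )
                    o[key] += 1
            cs = tabulate(calls, labels, prog)
            assert (cs.TP, cs.FP, cs.TN, cs.FN) == (o["TP"], o["FP"], o["TN"], o["FN"])
            assert cs.VarUse == o["varuse"] and cs.VarCall == o["varcall"]
            m = compute_metrics(cs)
            if o["varuse"]:
                assert m.accuracy == (o["TP"] + o["TN"]) / o["varuse"]
            if o["varcall"]:
                assert m.waccuracy is None or m.waccuracy == pytest.approx(
                    (o["TP"] + o["TN"]) / o["varcall"], abs=1e-12
                )


def test_per_class_correct_examples():
    labels = {"v1": PATH, "v2": PATH, "v3": PATH, "v4": BEN}
    perfect = [hc("v1", D), hc("v2", D), hc("v3", D), hc("v4", B)]
    pc = per_class_correct(perfect, labels, "p")
    assert pc.pct_pathogenic_correct == 1.0 and pc.pct_benign_correct == 1.0

    all_damaging = [hc(v, D) for v in labels]
    pc = per_class_correct(all_damaging, labels, "p")
    assert pc.pct_pathogenic_correct == 1.0 and pc.pct_benign_correct == 0.0


def test_per_class_denominator_counts_all_non_missing_output():
    """Unreliable and possible calls enter the denominator (variants with
    output) but never the numerator — unlike the VarUse denominator."""
    labels = {f"v{i}": PATH for i in range(10)}
    calls = (
        [hc(f"v{i}", D) for i in range(4)]  # correct usable
        + [hc("v4", B), hc("v5", B)]  # incorrect usable
        + [hc("v6", P), hc("v7", D, reliable=False)]  # output, not usable
        + [hc("v8", M), hc("v9", M)]  # no output
    )
    pc = per_class_correct(calls, labels, "p")
    assert pc.n_pathogenic_with_output == 8
    assert pc.pct_pathogenic_correct == pytest.approx(4 / 8)


@pytest.mark.parametrize(
    "x, places, expected",
    [
        (0.8235, 3, 0.824),  # half-up, not banker's
        (56 / 68, 3, 0.824),
        (0.5, 0, 1.0),
        (100 / 121 * 100, 1, 82.6),
        (0.91489, 3, 0.915),
    ],
)
def test_round_report_half_up(x, places, expected):
    assert round_report(x, places) == expected


def test_pool_sums_counts_not_metrics():
    a = ConfusionSummary("p", "A", 28, 0, 16, 0, VarUse=44, VarCall=53, N_dataset=54)
    b = ConfusionSummary("p", "B", 31, 3, 25, 2, VarUse=61, VarCall=68, N_dataset=68)
    pooled = pool([a, b])["p"]
    assert pooled.VarCall == 121 and pooled.TP == 59
    m = compute_metrics(pooled)
    assert round_report(100 * m.waccuracy, 1) == 82.6


def test_metrics_table_renders_na_and_unrounded():
    cs = ConfusionSummary("p", "d", 5, 0, 0, 0, VarUse=5, VarCall=6, N_dataset=6)
    df = metrics_table([cs])
    assert df.loc[0, "NPV"] is None or np.isnan(df.loc[0, "NPV"])
    assert df.loc[0, "WAccuracy_unrounded"] == pytest.approx(5 / 6)
    tsv = df.to_csv(sep="\t", na_rep="NA")
    assert "NA" in tsv


def test_confusion_summary_invariants_enforced():
    with pytest.raises(ValueError):
        ConfusionSummary("p", "d", 1, 0, 0, 0, VarUse=2, VarCall=2, N_dataset=2)
    with pytest.raises(ValueError):
        ConfusionSummary("p", "d", 1, 0, 0, 0, VarUse=1, VarCall=0, N_dataset=2)
    with pytest.raises(ValueError):
        ConfusionSummary("p", "d", -1, 1, 0, 0, VarUse=0, VarCall=0, N_dataset=0)
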