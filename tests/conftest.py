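import pandas as pd
import pytest

from dxmetrics import AnalysisConfig, SubjectTable, table_from_counts

# Published 2x2 cell counts used as fixtures throughout the suite:
# three dried-blood-spot viral-load assays (and one cross-platform run)
# against plasma viral load at the 1000 copies/mL virologic-failure cutoff,
# and five machine-learning classifiers for coronary artery disease at a
# probability cutoff of 0.5.
DBS_COUNTS = {
    "mdbs": (213, 26, 23, 480),
    "vdbs": (219, 35, 24, 475),
    "ddbs": (208, 28, 28, 480),
    "capctm_vdbs": (219, 343, 13, 169),
}
CAD_COUNTS = {
    "bagging": (50, 4, 4, 17),
    "knn": (51, 15, 3, 6),
    "svm": (52, 1, 2, 20),
    "rf": (52, 4, 2, 17),
    "lr": (51, 4, 3, 17),
}


@pytest.fixture
def mdbs_table():
    return table_from_counts(*DBS_COUNTS["mdbs"])


@pytest.fixture
def default_config():
    return AnalysisConfig(truth_cut=1000.0, test_cut=1000.0)


def expand_counts(a, b, c, d, truth_cut=1000.0, test_cut=1000.0):
    """Subject-level table whose dichotomization reproduces the given cells.

    Each cell pattern is repeated its count times: (truth, test) values on
    the positive side equal the cutoff, on the negative side 0.
    """
    hi_t, lo_t = truth_cut, 0.0
    hi_x, lo_x = test_cut, 0.0
    rows = (
        [(hi_t, hi_x)] * a + [(lo_t, hi_x)] * b + [(hi_t, lo_x)] * c + [(lo_t, lo_x)] * d
    )
    frame = pd.DataFrame(rows, columns=["truth", "test_1"])
    return SubjectTable(data=frame, truth_column="truth", test_columns=["test_1"])


def brute_force_measure(a, b, c, d, which):
    """Direct evaluation of each accuracy-measure formula, independent of the
    package's code path. Returns None when the formula is undefined."""
    n1, n2, m1, m2 = a + b, c + d, a + c, b + d
    n = a + b + c + d

    def div(x, y):
        return x / y if y else None

    if which == "sensitivity":
        return div(a, m1)
    if which == "specificity":
        return div(d, m2)
    if which == "ppv":
        return div(a, n1)
    if which == "npv":
        return div(d, n2)
    if which == "fpr":
        return div(b, m2)
    if which == "fnr":
        return div(c, m1)
    if which == "for":
        return div(c, n2)
    if which == "fdr":
        return div(b, n1)
    if which == "accuracy":
        return div(a + d, n)
    if which == "prevalence":
        return div(m1, n)
    if which == "lr_pos":
        sens, spec = div(a, m1), div(d, m2)
        if sens is None or spec is None or spec == 1:
            return None
        return sens / (1 - spec)
    if which == "lr_neg":
        sens, spec = div(a, m1), div(d, m2)
        if sens is None or spec in (None, 0):
            return None
        return (1 - sens) / spec
    if which == "dor":
        return div(a * d, b * c)
    if which == "youden":
        sens, spec = div(a, m1), div(d, m2)
        if sens is None or spec is None:
            return None
        return sens + spec - 1
    if which == "fscore":
        return div(2 * a, 2 * a + b + c)
    if which == "kappa":
        if n == 0:
            return None
        po = (a + d) / n
        pe = (m1 * n1 + m2 * n2) / n**2
        return None if pe == 1 else (po - pe) / (1 - pe)
    raise ValueError(which)


def pair_count_auroc(truth, scores):
    """Mann-Whitney AUROC oracle: count positive/negative pairs directly."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
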