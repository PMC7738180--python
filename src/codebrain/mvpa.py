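"""MVPA decoding of for-vs-if function identity with permutation-bootstrap inference.

Per subject and ROI, the 96 real-function beta patterns are standardized per
condition (one grand mean/sd over each condition's 48 x |ROI| block), then a
linear SVM (hinge loss, C = 5.0) is scored over repeated stratified 90/10
splits.  Group significance combines a per-subject label-permutation null
with a bootstrap over subjects: each bootstrap iteration draws one Fisher-z
transformed null accuracy per subject and recomputes the one-sample t
statistic against (Fisher-z transformed) chance; the empirical p is the
fraction of bootstrap t values at or above the observed t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

__all__ = [
    "PatternMatrix",
    "DecoderConfig",
    "DecodingResult",
    "normalize_per_condition",
    "split_train_test",
    "decode",
    "permutation_null",
    "fisher_z",
    "group_bootstrap_test",
    "compare_roi_accuracies",
]


@dataclass
class PatternMatrix:
    """Functions x vertices beta patterns for one subject and ROI.

    ``labels`` holds the condition of each row ('for' / 'if'); the full
    design has 96 balanced rows but any even, balanced row count is accepted
    so reduced problems can run through the same code path.
    """

    data: np.ndarray
    labels: np.ndarray
    subject: str = ""
    roi: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 2 or self.data.shape[0] != self.labels.size:
            raise ValueError("data rows and labels must align")
        if np.isnan(self.data).any():
            raise ValueError("pattern matrix contains missing values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size != 2 or counts[0] != counts[1]:
            raise ValueError("labels must hold exactly two balanced classes")

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class DecoderConfig:
    """Decoding and group-inference settings (defaults are the full-scale analysis)."""

    train_fraction: float = 0.9
    n_splits: int = 100
    C: float = 5.0
    n_perm: int = 1000
    n_boot: int = 1_000_000
    chance: float = 0.5
    seed: int = 0
    tol: float = 1e-4
    normalize_within_split: bool = False  # split-wise standardization variant

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.C <= 0:
            raise ValueError("C must be positive")
        for name in ("n_splits", "n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class DecodingResult:
    subject: str
    roi: str
    observed: float
    null: np.ndarray = field(default_factory=lambda: np.empty(0))


def normalize_per_condition(patterns: PatternMatrix) -> PatternMatrix:
    """Standardize each condition's block to grand mean 0, grand sd 1.

    One scalar mean and one scalar sd are computed over all entries of each
    condition's rows jointly (not per vertex), removing condition baseline
    differences while preserving within-condition spatial patterns.
    """
    out = patterns.data.copy()
    for cls in np.unique(patterns.labels):
        block = out[patterns.labels == cls]
        sd = block.std()
        if sd == 0:
            raise ValueError(f"condition {cls!r} block has zero variance")
        out[patterns.labels == cls] = (block - block.mean()) / sd
    return PatternMatrix(data=out, labels=patterns.labels.copy(),
                         subject=patterns.subject, roi=patterns.roi)


def split_train_test(labels: np.ndarray, config: DecoderConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test split: equal class counts on both sides.

    For 96 balanced patterns at train_fraction 0.9 this yields 86 training
    (43 + 43) and 10 test (5 + 5) items.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n_per_class = labels.size // classes.size
    n_test_per_class = int(round(n_per_class * (1 - config.train_fraction)))
    if n_test_per_class < 1 or n_test_per_class >= n_per_class:
        raise ValueError("train_fraction leaves an empty train or test side")
    train_idx, test_idx = [], []
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(labels == cls))
        test_idx.append(idx[:n_test_per_class])
        train_idx.append(idx[n_test_per_class:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _fit_score(X: np.ndarray, y: np.ndarray, train: np.ndarray, test: np.ndarray,
               config: DecoderConfig) -> float:
    if config.normalize_within_split:
        Xw = X.copy()
        for cls in (0, 1):
            rows = train[y[train] == cls]
            mu, sd = Xw[rows].mean(), Xw[rows].std()
            if sd == 0:
                raise ValueError("zero-variance training block")
            for side in (train, test):
                sel = side[y[side] == cls]
                Xw[sel] = (Xw[sel] - mu) / sd
        X = Xw
    # libsvm max-margin SVM (hinge loss, unpenalized intercept); the iteration
    # cap only bites on inseparable label-shuffled data where the decision
    # value has long since stabilized.
    clf = SVC(kernel="linear", C=config.C, tol=config.tol, max_iter=20_000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X[train], y[train])
    return float((clf.predict(X[test]) == y[test]).mean())


def decode(patterns: PatternMatrix, config: DecoderConfig,
           rng: np.random.Generator | None = None,
           labels: np.ndarray | None = None) -> float:
    """Mean test accuracy of the linear SVM over ``config.n_splits`` stratified splits."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lab = patterns.labels if labels is None else np.asarray(labels)
    y = (lab == np.unique(lab)[1]).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training labels are single-class")
    accs = []
    for _ in range(config.n_splits):
        train, test = split_train_test(lab, config, rng)
        if np.unique(y[train]).size < 2:
            raise ValueError("degenerate single-class training set")
        accs.append(_fit_score(patterns.data, y, train, test, config))
    return float(np.mean(accs))


def permutation_null(patterns: PatternMatrix, config: DecoderConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Label-permutation null: ``n_perm`` full decode() runs on shuffled labels.

    Each shuffle permutes the label vector (preserving the 48/48 balance);
    the entry recorded is the mean accuracy over ``n_splits`` splits of the
    shuffled data.  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_perm)
    for i in range(config.n_perm):
        shuffled = patterns.labels[rng.permutation(patterns.n)]
        null[i] = decode(patterns, config, rng=rng, labels=shuffled)
    return null


def fisher_z(a):
    """Variance-stabilizing Fisher-z transform, arctanh(a), for a in (0, 1)."""
    arr = np.asarray(a, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("accuracy must lie strictly inside (0, 1)")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(a) or arr.ndim == 0 else out


def _one_sample_t(values: np.ndarray, popmean: float, axis: int = -1) -> np.ndarray:
    n = values.shape[axis]
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=1)
    return (mean - popmean) / (sd / np.sqrt(n))


def group_bootstrap_test(observed: np.ndarray, nulls: np.ndarray,
                         config: DecoderConfig,
                         rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Combined permutation-bootstrap group test of decoding accuracy vs chance.

    ``t_obs`` is the one-sample t of Fisher-z observed accuracies against
    Fisher-z chance.  Each of ``n_boot`` iterations draws (with replacement,
    independently per subject) one Fisher-z null accuracy per subject and
    recomputes the t statistic; ``p`` is the proportion of null t values
    >= t_obs (one-sided).
    """
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    n_subj = observed.size
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    if nulls.shape != (n_subj, config.n_perm):
        raise ValueError("nulls must be (n_subjects, n_perm)")
    # Finite-resolution guard: with few splits an accuracy can hit exactly 0
    # or 1, where arctanh diverges; clip just inside the open interval.
    eps = 1e-6
    obs_clip = np.clip(observed, eps, 1 - eps)
    if np.allclose(observed.std(ddof=1), 0) and np.allclose(observed, config.chance):
        t_obs = 0.0
    else:
        if observed.std(ddof=1) == 0:
            raise ValueError("zero variance across subjects")
        t_obs = float(_one_sample_t(fisher_z(obs_clip), fisher_z(config.chance)))

    if rng is None:
        rng = np.random.default_rng(config.seed)
    znulls = np.arctanh(np.clip(nulls, eps, 1 - eps))
    zc = fisher_z(config.chance)
    count = 0
    chunk = 100_000
    remaining = config.n_boot
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.integers(0, config.n_perm, size=(m, n_subj))
        samples = znulls[np.arange(n_subj), draws]  # m x n_subj
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = _one_sample_t(samples, zc, axis=1)
        count += int(np.sum(t_null >= t_obs))
        remaining -= m
    return t_obs, count / config.n_boot


def run_subject(patterns: PatternMatrix, config: DecoderConfig,
                rng: np.random.Generator | None = None) -> DecodingResult:
    """Normalize, decode, and build the permutation null for one subject/ROI."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    normed = patterns if config.normalize_within_split else normalize_per_condition(patterns)
    observed = decode(normed, config, rng=rng)
    null = permutation_null(normed, config, rng=rng)
    return DecodingResult(subject=patterns.subject, roi=patterns.roi,
                          observed=observed, null=null)


def compare_roi_accuracies(acc_table: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of decoding accuracy across ROI columns.

    Degrees of freedom follow the between/within convention for a
    subjects x ROIs table: (k - 1, N - k); for 15 subjects x 4 ROIs this is
    (3, 56).
    """
    acc = np.asarray(acc_table, dtype=float)
    if acc.ndim != 2 or acc.shape[1] < 2:
        raise ValueError("need a complete subjects x ROIs table with >= 2 columns")
    if np.isnan(acc).any():
        raise ValueError("accuracy table has missing cells")
    F, p = stats.f_oneway(*[acc[:, j] for j in range(acc.shape[1])])
    n, k = acc.shape
    if np.isnan(F):  # identical columns with zero within-group variance
        F, p = 0.0, 1.0
    return float(F), (k - 1, n * k - k), float(p)


def reduced(config: DecoderConfig, factor: int = 10) -> DecoderConfig:
    """A scaled-down copy of a config (resampling counts divided by ``factor``)."""
    return replace(config,
                   n_splits=max(1, config.n_splits // factor),
                   n_perm=max(2, config.n_perm // factor),
                   n_boot=max(100, config.n_boot // factor))
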