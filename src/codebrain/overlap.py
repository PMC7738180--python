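"""Cosine overlap between binary activation maps, with empirical bounds.

For each subject and hemisphere the code-comprehension map is compared with
each localizer map (logic, math, language, MSIT) via the cosine similarity of
their 0/1 vertex vectors, |A n B| / sqrt(|A| |B|).  Because the measure
normalizes by each map's active count, it controls for overall activation
extent.  Inference uses:

* an empirical lower bound -- the localizer map's vertex assignment is
  shuffled (active count preserved) and the cosine with the intact code map
  recorded, 100 times;
* a bootstrap group p -- each iteration draws one null cosine per subject
  and records the null group mean; p is the fraction of null means at or
  above the observed group mean;
* a split-half upper bound -- the code data are split into the 10 unordered
  3/3 partitions of the six runs, each half is pooled (fixed effects) and
  FDR-binarized, and the self-similarity across halves is averaged;
* a repeated-measures ANOVA across tasks with BH-FDR corrected post-hoc
  paired t-tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .glm import BinaryActivationMap, RunStats, combine_fixed_effects, fdr_binarize, z_to_pmap

__all__ = [
    "OverlapResult",
    "cosine_similarity",
    "shuffle_null",
    "group_bootstrap_p",
    "split_half_partitions",
    "split_half_upper_bound",
    "compare_tasks",
]

LOCALIZER_CONTRASTS = {
    "language": "language>math",
    "math": "math>language",
    "logic": "logic>language",
    "msit": "hard>easy",
}


@dataclass
class OverlapResult:
    task: str
    hemisphere: str
    per_subject: np.ndarray
    nulls: np.ndarray  # subjects x n_shuffle
    p: float
    upper_bound: float | None = None
    extras: dict = field(default_factory=dict)


def _binary_vector(m: BinaryActivationMap, hemisphere: str | None) -> np.ndarray:
    v = m.values if hemisphere is None else m.hemi(hemisphere)
    return v.astype(float)


def cosine_similarity(a: BinaryActivationMap, b: BinaryActivationMap,
                      hemisphere: str | None = None) -> float:
    """Cosine of two binary maps: |A n B| / sqrt(|A| |B|) over their active sets."""
    va, vb = _binary_vector(a, hemisphere), _binary_vector(b, hemisphere)
    if va.shape != vb.shape:
        raise ValueError("maps live on different vertex spaces")
    na, nb = va.sum(), vb.sum()
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for an all-zero map")
    return float((va @ vb) / np.sqrt(na * nb))


def shuffle_null(code_map: BinaryActivationMap, localizer_map: BinaryActivationMap,
                 n_shuffle: int = 100, seed: int = 0,
                 hemisphere: str | None = "L",
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Null cosines from uniformly permuting the localizer map's vertex labels.

    Each draw permutes the localizer vector within the analyzed hemisphere
    (preserving its active count) and records the cosine with the intact code
    map.  Under this null the expected cosine is sqrt(|A| |B|) / N.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    vc = _binary_vector(code_map, hemisphere)
    vl = _binary_vector(localizer_map, hemisphere)
    if vc.shape != vl.shape:
        raise ValueError("maps live on different vertex spaces")
    na, nb = vc.sum(), vl.sum()
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for an all-zero map")
    denom = np.sqrt(na * nb)
    out = np.empty(n_shuffle)
    for i in range(n_shuffle):
        out[i] = (vc @ vl[rng.permutation(vl.size)]) / denom
    return out


def group_bootstrap_p(observed: np.ndarray, nulls: np.ndarray,
                      n_boot: int = 1_000_000, seed: int = 0,
                      rng: np.random.Generator | None = None) -> float:
    """Bootstrap group p: fraction of null group-mean cosines >= the observed mean."""
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if observed.size == 0 or nulls.size == 0:
        raise ValueError("empty inputs")
    if nulls.shape[0] != observed.size:
        raise ValueError("nulls must be (n_subjects, n_shuffle)")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs_mean = observed.mean()
    n_subj, n_shuffle = nulls.shape
    count = 0
    chunk = 200_000
    remaining = n_boot
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.integers(0, n_shuffle, size=(m, n_subj))
        means = nulls[np.arange(n_subj), draws].mean(axis=1)
        count += int(np.sum(means >= obs_mean))
        remaining -= m
    return count / n_boot


def split_half_partitions(n_runs: int = 6) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered equal partitions of run indices 0..n_runs-1 (10 for six runs)."""
    if n_runs % 2:
        raise ValueError("need an even number of runs")
    half = n_runs // 2
    runs = tuple(range(n_runs))
    parts = []
    for combo in itertools.combinations(runs[1:], half - 1):
        first = (0,) + combo
        second = tuple(r for r in runs if r not in first)
        parts.append((first, second))
    return parts


def split_half_upper_bound(run_stats_per_subject: list[list[RunStats]],
                           hemispheres: np.ndarray, q: float = 0.05,
                           hemisphere: str | None = "L",
                           pooled: bool = False) -> float:
    """Split-half self-similarity of the code contrast: the empirical ceiling.

    For each subject, each of the 10 unordered 3/3 partitions of the six runs
    is pooled half-by-half with fixed effects, FDR-binarized at level q, and
    the cosine of the two half-maps recorded.  By default values are averaged
    within subject first and then across subjects (``pooled=True`` averages
    all subject x partition values in one pass).
    """
    per_subject_means = []
    all_values = []
    for run_stats in run_stats_per_subject:
        if len(run_stats) != 6:
            raise ValueError("split-half ceiling expects exactly 6 runs per subject")
        vals = []
        for first, second in split_half_partitions(6):
            maps = []
            for half in (first, second):
                _, pmap = combine_fixed_effects([run_stats[r] for r in half], hemispheres)
                maps.append(fdr_binarize(pmap, q=q))
            vals.append(cosine_similarity(maps[0], maps[1], hemisphere=hemisphere))
        per_subject_means.append(np.mean(vals))
        all_values.extend(vals)
    return float(np.mean(all_values) if pooled else np.mean(per_subject_means))


def compare_tasks(cos_table: pd.DataFrame | np.ndarray) -> dict:
    """Repeated-measures ANOVA across tasks plus BH-corrected post-hoc paired t-tests.

    ``cos_table`` is subjects x tasks.  The ANOVA treats subject as the
    blocking factor, df = (k-1, (k-1)(n-1)); for 15 subjects and 4 tasks this
    is (3, 42).
    """
    if isinstance(cos_table, np.ndarray):
        cos_table = pd.DataFrame(cos_table,
                                 columns=[f"task{j}" for j in range(cos_table.shape[1])])
    if cos_table.isna().any().any():
        raise ValueError("missing cells in the task table")
    n, k = cos_table.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 tasks and >= 2 subjects")

    long = cos_table.reset_index(names="subject").melt(
        id_vars="subject", var_name="task", value_name="cosine"
    )
    if np.allclose(long.groupby("subject")["cosine"].std(ddof=0), 0):
        # identical task columns: no task effect by construction
        F, p = 0.0, 1.0
    else:
        table = AnovaRM(long, depvar="cosine", subject="subject", within=["task"]).fit().anova_table
        F = float(table["F Value"].iloc[0])
        p = float(table["Pr > F"].iloc[0])
    df = (k - 1, (k - 1) * (n - 1))

    pairs, raw_p, tvals = [], [], []
    for a, b in itertools.combinations(cos_table.columns, 2):
        if np.allclose(cos_table[a], cos_table[b]):
            t, pv = 0.0, 1.0
        else:
            t, pv = stats.ttest_rel(cos_table[a], cos_table[b])
        pairs.append((a, b))
        tvals.append(float(t))
        raw_p.append(float(pv))
    _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    posthoc = pd.DataFrame(
        {
            "task_a": [a for a, _ in pairs],
            "task_b": [b for _, b in pairs],
            "t": tvals,
            "p": raw_p,
            "p_fdr": p_adj,
        }
    )
    return {"F": F, "df": df, "p": p, "posthoc": posthoc}
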