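"""Synthetic multi-subject vertex data with planted ground truth.

The generator emulates the measured structure of the study -- 15 subjects,
six runs, 96 real-function patterns (48 for / 48 if) plus 24 fake per
subject, and five contrast maps (code, language, math, logic, MSIT) on a
two-hemisphere vertex sheet -- while planting effects every downstream stage
can be checked against:

* **pattern separation**: inside the code-active vertex set the for and if
  mean patterns differ by ``pattern_effect_d`` noise-sd units per vertex, so
  decoding accuracy is a known function of the effect size (0.5 at d = 0,
  1.0 in the noiseless limit);
* **map overlap**: each contrast's active vertex set is constructed from
  disjoint pairwise shared pools sized analytically so that the cosine
  similarity of the binary indicator vectors hits ``overlap_targets``;
* **laterality**: each contrast's active count is split across hemispheres
  as n_L/(n_L + n_R) = (1 + LI)/2, so the ground-truth count-based LI equals
  the planted LI; per-subject code and language LIs are drawn from a
  bivariate normal with mean ``laterality_mu`` and correlation
  ``laterality_rho``.

Run-level contrast estimates are emitted directly (beta = truth + noise with
known variance) for the statistical stages, and full vertex time series can
be rendered from a trial schedule (design matrix x true betas + iid Gaussian
noise) for end-to-end GLM tests.  Noise is iid Gaussian per vertex; there is
no spatial autocorrelation or cortical geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designgen import TrialSchedule, build_code_schedule
from scipy import stats as _stats

from .glm import (
    BinaryActivationMap,
    RunStats,
    VertexMap,
    build_design,
    combine_fixed_effects,
    fdr_binarize,
)

__all__ = [
    "CONTRASTS",
    "SynthConfig",
    "SubjectDataset",
    "plant_active_sets",
    "generate_subject",
    "generate_group",
    "generate_timeseries",
]

CONTRASTS = ("code", "language", "math", "logic", "msit")

# Default pairwise overlap targets for the five contrasts' active sets,
# mirroring the study's qualitative ordering: code overlaps most with logic,
# then math, least with MSIT and language.
DEFAULT_OVERLAP_TARGETS = pd.DataFrame(
    [
        [1.00, 0.10, 0.25, 0.40, 0.15],
        [0.10, 1.00, 0.08, 0.08, 0.05],
        [0.25, 0.08, 1.00, 0.25, 0.15],
        [0.40, 0.08, 0.25, 1.00, 0.15],
        [0.15, 0.05, 0.15, 0.15, 1.00],
    ],
    index=CONTRASTS,
    columns=CONTRASTS,
)

# Mean planted LI per contrast: code and language strongly left-lateralized,
# logic/math moderately, MSIT bilateral.
DEFAULT_LATERALITY_MU = {"code": 0.45, "language": 0.40, "math": 0.2, "logic": 0.2, "msit": 0.0}


@dataclass
class SynthConfig:
    """Ground-truth parameters of the synthetic study.

    ``pattern_effect_d`` is the per-vertex standardized mean difference of
    the for vs if patterns inside the code-active ROI portion (in noise-sd
    units); ``contrast_snr`` is the fixed-effects z attained by a truly
    active vertex after pooling all runs; ``laterality_mu``/``laterality_rho``
    control the planted code/language LIs.
    """

    n_subjects: int = 15
    n_vertices_per_hemi: int = 2000
    n_runs: int = 6
    pattern_effect_d: float = 0.25
    contrast_snr: float = 5.0
    active_fraction: float = 0.15
    overlap_targets: pd.DataFrame = field(default_factory=lambda: DEFAULT_OVERLAP_TARGETS.copy())
    laterality_mu: float = 0.45
    laterality_rho: float = 0.8
    laterality_sd: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.overlap_targets, dtype=float)
        if t.shape != (len(CONTRASTS), len(CONTRASTS)):
            raise ValueError("overlap_targets must be 5x5 over the five contrasts")
        if not np.allclose(t, t.T) or not np.allclose(np.diag(t), 1.0):
            raise ValueError("overlap_targets must be symmetric with unit diagonal")
        if np.any((t < 0) | (t > 1)):
            raise ValueError("overlap_targets entries must lie in [0, 1]")
        for name in ("pattern_effect_d", "contrast_snr", "noise_sd", "laterality_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must be in (0, 1)")

    @property
    def n_vertices(self) -> int:
        return 2 * self.n_vertices_per_hemi

    @property
    def hemispheres(self) -> np.ndarray:
        return np.repeat(["L", "R"], self.n_vertices_per_hemi)


@dataclass
class SubjectDataset:
    """One synthetic subject: true active sets / LIs, run-level contrast stats, patterns."""

    subject: str
    config: SynthConfig
    active_sets: dict[str, np.ndarray]  # contrast -> global vertex indices
    true_li: dict[str, float]
    realized_overlap: pd.DataFrame
    run_stats: dict[str, list[RunStats]]  # contrast -> one RunStats per run
    patterns: np.ndarray  # 96 x n_vertices real-function betas
    pattern_labels: np.ndarray  # 'for'/'if' per row
    fake_patterns: np.ndarray  # 24 x n_vertices
    run_of_pattern: np.ndarray  # 1-based run label per real pattern

    @property
    def hemispheres(self) -> np.ndarray:
        return self.config.hemispheres

    def contrast_zmap(self, contrast: str) -> VertexMap:
        zmap, _ = combine_fixed_effects(self.run_stats[contrast], self.hemispheres, contrast)
        return zmap

    def contrast_binary(self, contrast: str, q: float = 0.05) -> BinaryActivationMap:
        _, pmap = combine_fixed_effects(self.run_stats[contrast], self.hemispheres, contrast)
        return fdr_binarize(pmap, q=q)


def _pairwise_pool_sizes(sizes: dict[str, int], targets: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Shared-pool sizes: |A_i n A_j| = round(target_ij * sqrt(|A_i| |A_j|))."""
    shared = {}
    for i, a in enumerate(CONTRASTS):
        for b in CONTRASTS[i + 1 :]:
            s = int(round(float(targets.loc[a, b]) * np.sqrt(sizes[a] * sizes[b])))
            shared[(a, b)] = min(s, sizes[a], sizes[b])
    return shared


def plant_active_sets(config: SynthConfig, rng: np.random.Generator | None = None,
                      sizes: dict[str, int] | None = None,
                      vertex_pool: np.ndarray | None = None,
                      strict: bool = True,
                      ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Construct five active-vertex sets with prescribed pairwise cosines.

    Each unordered pair of contrasts gets a disjoint shared pool of
    ``round(target * sqrt(|A| |B|))`` vertices belonging to both sets only;
    the remainder of each set is unique.  The realized cosine of the binary
    indicator vectors is then ``shared / sqrt(|A| |B|)``, within rounding
    (0.02) of the target.  Raises when the requested sizes/targets are
    infeasible (shared pools exceeding a set's size or the vertex pool).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if vertex_pool is None:
        vertex_pool = np.arange(config.n_vertices)
    if sizes is None:
        base = int(config.active_fraction * len(vertex_pool))
        sizes = {c: base for c in CONTRASTS}
    targets = config.overlap_targets

    shared = _pairwise_pool_sizes(sizes, targets)
    # Feasibility: each contrast's shared pools must fit inside its size.  In
    # strict mode an infeasible request is an error; otherwise (used for the
    # minor hemisphere of strongly lateralized subjects, where set sizes are
    # small and unequal) the offending contrast's shared pools are shrunk
    # proportionally until everything fits.
    for _ in range(len(CONTRASTS) * 2):
        over = None
        for c in CONTRASTS:
            s = sum(v for (a, b), v in shared.items() if c in (a, b))
            if s > sizes[c]:
                over = (c, s)
                break
        if over is None:
            break
        c, s = over
        if strict:
            raise ValueError(
                f"infeasible overlap targets: contrast {c!r} needs {s} shared vertices "
                f"but only has size {sizes[c]}"
            )
        scale = sizes[c] / s
        for key in shared:
            if c in key:
                shared[key] = int(np.floor(shared[key] * scale))
    unique = {c: sizes[c] - sum(v for k, v in shared.items() if c in k) for c in CONTRASTS}
    total = sum(shared.values()) + sum(unique.values())
    if total > len(vertex_pool):
        raise ValueError(
            f"infeasible overlap targets: need {total} vertices, pool has {len(vertex_pool)}"
        )

    pool = rng.permutation(vertex_pool)
    cursor = 0
    members: dict[str, list[np.ndarray]] = {c: [] for c in CONTRASTS}
    for (a, b), s in shared.items():
        chunk = pool[cursor : cursor + s]
        cursor += s
        members[a].append(chunk)
        members[b].append(chunk)
    for c, u in unique.items():
        chunk = pool[cursor : cursor + u]
        cursor += u
        members[c].append(chunk)

    sets = {c: np.sort(np.concatenate(members[c])) if members[c] else np.empty(0, int)
            for c in CONTRASTS}
    realized = pd.DataFrame(np.eye(len(CONTRASTS)), index=CONTRASTS, columns=CONTRASTS)
    for i, a in enumerate(CONTRASTS):
        for b in CONTRASTS[i + 1 :]:
            inter = np.intersect1d(sets[a], sets[b], assume_unique=True).size
            cos = inter / np.sqrt(sizes[a] * sizes[b]) if sizes[a] and sizes[b] else 0.0
            realized.loc[a, b] = realized.loc[b, a] = cos
    return sets, realized


def _subject_rng(config: SynthConfig, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, subject_id]))


def _draw_lis(config: SynthConfig, rng: np.random.Generator) -> dict[str, float]:
    """Per-subject planted LIs; code and language correlated at laterality_rho."""
    mus = dict(DEFAULT_LATERALITY_MU)
    mus["code"] = config.laterality_mu
    mus["language"] = min(config.laterality_mu, DEFAULT_LATERALITY_MU["language"])
    rho = config.laterality_rho
    cov = config.laterality_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    code_li, lang_li = rng.multivariate_normal([mus["code"], mus["language"]], cov)
    lis = {
        "code": code_li,
        "language": lang_li,
        "math": rng.normal(mus["math"], config.laterality_sd),
        "logic": rng.normal(mus["logic"], config.laterality_sd),
        "msit": rng.normal(mus["msit"], config.laterality_sd),
    }
    return {c: float(np.clip(v, -0.95, 0.95)) for c, v in lis.items()}


def generate_subject(config: SynthConfig, subject_id: int) -> SubjectDataset:
    """Generate one subject's ground truth, run-level contrast stats, and patterns.

    Reproducible given ``(config.seed, subject_id)``.
    """
    rng = _subject_rng(config, subject_id)
    lis = _draw_lis(config, rng)

    n_hemi = config.n_vertices_per_hemi
    base = int(config.active_fraction * n_hemi)
    # Split each contrast's total active count (2 * base, i.e. one base-sized
    # set per hemisphere at LI = 0) across hemispheres per the planted LI.
    total_active = {c: 2 * base for c in CONTRASTS}
    sizes_l = {c: int(round(total_active[c] * (1 + lis[c]) / 2)) for c in CONTRASTS}
    sizes_r = {c: total_active[c] - sizes_l[c] for c in CONTRASTS}

    sets_l, overlap_l = plant_active_sets(
        config, rng, sizes=sizes_l, vertex_pool=np.arange(n_hemi), strict=False
    )
    sets_r, _ = plant_active_sets(
        config, rng, sizes=sizes_r, vertex_pool=np.arange(n_hemi, 2 * n_hemi), strict=False
    )
    active_sets = {c: np.sort(np.concatenate([sets_l[c], sets_r[c]])) for c in CONTRASTS}
    true_li = {
        c: (sizes_l[c] - sizes_r[c]) / (sizes_l[c] + sizes_r[c]) for c in CONTRASTS
    }

    # Run-level contrast estimates: beta = amplitude * indicator + noise, with
    # known per-run variance.  Amplitude is set so the fixed-effects z of a
    # truly active vertex equals contrast_snr after pooling n_runs runs.  In
    # the noiseless limit a unit reference scale keeps amplitudes and the
    # stored variances finite (maps become exact indicators at z = snr).
    run_sd = config.noise_sd
    ref_sd = run_sd if run_sd > 0 else 1.0
    amplitude = config.contrast_snr * ref_sd / np.sqrt(config.n_runs)
    run_stats: dict[str, list[RunStats]] = {}
    n_v = config.n_vertices
    for c in CONTRASTS:
        truth = np.zeros(n_v)
        truth[active_sets[c]] = amplitude
        runs = []
        for _r in range(config.n_runs):
            beta = truth.copy()
            if run_sd > 0:
                beta += rng.normal(0, run_sd, size=n_v)
            var = np.full(n_v, ref_sd**2)
            t = beta / ref_sd
            p = 2 * _stats.norm.sf(np.abs(t))
            runs.append(RunStats(beta=beta, variance=var, t=t, p=p, df=10**6))
        run_stats[c] = runs

    # Real-function beta patterns: condition mean +/- d/2 per code-active
    # vertex (sign fixed per vertex per subject), plus iid noise.
    signs = rng.choice([-1.0, 1.0], size=active_sets["code"].size)
    delta = np.zeros(n_v)
    delta[active_sets["code"]] = signs * config.pattern_effect_d * ref_sd / 2
    base_activation = np.zeros(n_v)
    base_activation[active_sets["code"]] = amplitude

    labels = np.array(["for"] * 48 + ["if"] * 48)
    order = rng.permutation(96)
    labels = labels[order]
    run_of_pattern = np.tile(np.arange(1, 7), 16)  # 16 real functions per run
    patterns = np.empty((96, n_v))
    for i, lab in enumerate(labels):
        mean = base_activation + (delta if lab == "for" else -delta)
        patterns[i] = mean + rng.normal(0, config.noise_sd, size=n_v)

    # Fake-code trials activate an independent (memory-task proxy) vertex set,
    # so real > fake contrasts are nontrivial; no code-set activation.
    fake_set = rng.choice(
        np.setdiff1d(np.arange(n_v), active_sets["code"]),
        size=active_sets["code"].size, replace=False,
    )
    fake_mean = np.zeros(n_v)
    fake_mean[fake_set] = amplitude
    fake_patterns = fake_mean + rng.normal(0, config.noise_sd, size=(24, n_v))

    return SubjectDataset(
        subject=f"sub-{subject_id:02d}",
        config=config,
        active_sets=active_sets,
        true_li=true_li,
        realized_overlap=overlap_l,
        run_stats=run_stats,
        patterns=patterns,
        pattern_labels=labels,
        fake_patterns=fake_patterns,
        run_of_pattern=run_of_pattern,
    )


def generate_group(config: SynthConfig) -> list[SubjectDataset]:
    """All subjects of one synthetic study."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def generate_timeseries(schedule: TrialSchedule, dataset: SubjectDataset,
                        tr_s: float = 2.0, noise_sd: float | None = None,
                        vertices: np.ndarray | None = None) -> dict[int, dict]:
    """Render per-run vertex time series from a schedule and true betas.

    For each run, a per-function design matrix (24 s function-phase boxcars
    convolved with the canonical HRF) is multiplied by the true function
    patterns and iid Gaussian noise is added.  Returns
    ``{run: {"Y": samples x vertices, "design": DesignMatrix,
    "function_ids": [...]}}`` suitable for :func:`codebrain.glm.fit_run`.
    """
    if noise_sd is None:
        noise_sd = dataset.config.noise_sd
    if vertices is None:
        vertices = np.arange(dataset.config.n_vertices)
    rng = _subject_rng(dataset.config, int(dataset.subject.split("-")[1]) + 10_000)

    events = dataset_events_by_run(schedule)
    id_to_row = _match_functions_to_patterns(schedule, dataset)

    out = {}
    for run, run_sched in events.items():
        run_events = run_sched.function_events()
        end = (run_events["onset"] + run_events["duration"]).max() + 30
        n_samples = int(np.ceil(end / tr_s))
        design = build_design(run_sched, tr_s, n_samples, per_function=True,
                              include_derivative=False)
        B = np.zeros((len(design.names), len(vertices)))
        for j, name in enumerate(design.names):
            if name == "intercept":
                continue
            fid = int(name)
            if fid in id_to_row:
                B[j] = dataset.patterns[id_to_row[fid]][vertices]
            else:  # fake function
                fake_row = fid % dataset.fake_patterns.shape[0]
                B[j] = dataset.fake_patterns[fake_row][vertices]
        Y = design.matrix @ B
        if noise_sd > 0:
            Y = Y + rng.normal(0, noise_sd, size=Y.shape)
        out[run] = {"Y": Y, "design": design,
                    "function_ids": [n for n in design.names if n != "intercept"]}
    return out


def dataset_events_by_run(schedule: TrialSchedule) -> dict[int, TrialSchedule]:
    """Split a session schedule into per-run schedules with run-relative onsets."""
    out = {}
    for run, df in schedule.trials.groupby("run"):
        df = df.copy()
        df["onset"] = df["onset"] - df["onset"].min()
        out[int(run)] = TrialSchedule(trials=df.reset_index(drop=True), group=schedule.group)
    return out


def _match_functions_to_patterns(schedule: TrialSchedule, dataset: SubjectDataset) -> dict[int, int]:
    """Assign schedule function ids to pattern rows, keeping for/if structure aligned."""
    ev = schedule.function_events()
    real = ev[~ev["trial_type"].str.startswith("fake")]
    id_to_row: dict[int, int] = {}
    for structure in ("for", "if"):
        fids = sorted(
            int(f)
            for f in real[real["trial_type"].str.startswith(structure)]["function_id"].unique()
        )
        rows = np.flatnonzero(dataset.pattern_labels == structure)
        if len(fids) > rows.size:
            raise ValueError("schedule has more functions than the dataset has patterns")
        for fid, row in zip(fids, rows):
            id_to_row[fid] = int(row)
    return id_to_row


def save_dataset(dataset: SubjectDataset, outdir) -> None:
    """Persist one subject as portable array files plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "patterns.npy", dataset.patterns)
    np.save(outdir / "fake_patterns.npy", dataset.fake_patterns)
    for c in CONTRASTS:
        np.save(outdir / f"runbeta_{c}.npy", np.stack([r.beta for r in dataset.run_stats[c]]))
        np.save(outdir / f"runvar_{c}.npy", np.stack([r.variance for r in dataset.run_stats[c]]))
    manifest = {
        "subject": dataset.subject,
        "n_vertices_per_hemi": dataset.config.n_vertices_per_hemi,
        "hemispheres": ["L", "R"],
        "pattern_labels": dataset.pattern_labels.tolist(),
        "run_of_pattern": dataset.run_of_pattern.tolist(),
        "contrasts": list(CONTRASTS),
        "true_li": dataset.true_li,
        "active_sets": {c: dataset.active_sets[c].tolist() for c in CONTRASTS},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh)


def load_dataset(subject_dir) -> dict:
    """Load one subject saved by :func:`save_dataset`.

    Returns a dict with ``patterns``, ``pattern_labels``, ``hemispheres``,
    and per-contrast ``run_stats`` (reconstructed from the stored run betas
    and variances).
    """
    subject_dir = Path(subject_dir)
    with open(subject_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    n_hemi = manifest["n_vertices_per_hemi"]
    hemis = np.repeat(["L", "R"], n_hemi)
    run_stats: dict[str, list[RunStats]] = {}
    for c in manifest["contrasts"]:
        betas = np.load(subject_dir / f"runbeta_{c}.npy")
        variances = np.load(subject_dir / f"runvar_{c}.npy")
        runs = []
        for beta, var in zip(betas, variances):
            sd = np.sqrt(var)
            t = beta / sd
            p = 2 * _stats.norm.sf(np.abs(t))
            runs.append(RunStats(beta=beta, variance=var, t=t, p=p, df=10**6))
        run_stats[c] = runs
    return {
        "subject": manifest["subject"],
        "manifest": manifest,
        "hemispheres": hemis,
        "patterns": np.load(subject_dir / "patterns.npy"),
        "fake_patterns": np.load(subject_dir / "fake_patterns.npy"),
        "pattern_labels": np.asarray(manifest["pattern_labels"]),
        "run_stats": run_stats,
    }


def load_group(data_dir) -> list[dict]:
    """Load every subject directory (sub-*) under ``data_dir``, sorted."""
    dirs = sorted(Path(data_dir).glob("sub-*"))
    if not dirs:
        raise FileNotFoundError(f"no sub-* directories under {data_dir}")
    return [load_dataset(d) for d in dirs]
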